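import numpy as np
import pytest

from zfuse import (
    VOID_INDEX,
    BlockDepthMap,
    ConfidenceMap,
    FocusStack,
    FusionParams,
    assemble_fused,
    fuse,
    index_to_depth,
    information_filling,
    init_pixel_index,
    segment_blocks,
    smooth_edges,
)

from conftest import random_stack


class TestInitPixelIndex:
    def test_broadcast_to_tiles(self):
        grid = segment_blocks(4, 4, 2, 2)
        depth = BlockDepthMap(np.array([[1, 3], [5, 7]]), grid)
        pix = init_pixel_index(depth, grid)
        np.testing.assert_array_equal(pix[:2, :2], 1)
        np.testing.assert_array_equal(pix[:2, 2:], 3)
        np.testing.assert_array_equal(pix[2:, :2], 5)
        np.testing.assert_array_equal(pix[2:, 2:], 7)

    def test_void_block_propagates(self):
        grid = segment_blocks(4, 4, 2, 2)
        depth = BlockDepthMap(np.array([[0, VOID_INDEX], [0, 0]]), grid)
        pix = init_pixel_index(depth, grid)
        assert (pix[:2, 2:] == VOID_INDEX).all()

    def test_matches_per_pixel_lookup(self):
        rng = np.random.default_rng(6)
        grid = segment_blocks(21, 17, 5, 4)
        depth = BlockDepthMap(rng.integers(0, 9, size=grid.shape), grid)
        pix = init_pixel_index(depth, grid)
        for r in range(21):
            for c in range(17):
                assert pix[r, c] == depth.index[r // 5, c // 4]


def _two_block_case(idx1, idx2, n_frames=21):
    """Two horizontally adjacent 2x2 blocks in a 2x4 image."""
    frames = np.zeros((n_frames, 2, 4), dtype=np.uint8)
    grid = segment_blocks(2, 4, 2, 2)
    depth = BlockDepthMap(np.array([[idx1, idx2]]), grid)
    conf = ConfidenceMap(np.array([[1, 1]], dtype=np.uint8), 60)
    return frames, grid, depth, conf


class TestInformationFilling:
    params = FusionParams(threshold3=10, threshold4=80)

    def test_dark_pixel_adopts_brighter_neighbor_frame(self):
        frames, grid, depth, conf = _two_block_case(0, 20)
        frames[0, 0, 0] = 50   # pixel's value in its current frame
        frames[20, 0, 0] = 120  # brighter in the neighbor block's frame
        stack = FocusStack(frames)
        pix = init_pixel_index(depth, grid)
        out, n = information_filling(stack, pix, depth, conf, self.params)
        assert out[0, 0] == 20
        assert n >= 1

    def test_bright_pixel_is_protected(self):
        frames, grid, depth, conf = _two_block_case(0, 20)
        frames[0, 0, 0] = 90   # >= threshold4: never reassigned
        frames[20, 0, 0] = 200
        stack = FocusStack(frames)
        pix = init_pixel_index(depth, grid)
        out, _ = information_filling(stack, pix, depth, conf, self.params)
        assert out[0, 0] == 0

    def test_close_depths_skip_pair(self):
        frames, grid, depth, conf = _two_block_case(5, 10)
        frames[5] = 10
        frames[10] = 200
        stack = FocusStack(frames)
        pix = init_pixel_index(depth, grid)
        out, n = information_filling(stack, pix, depth, conf, self.params)
        np.testing.assert_array_equal(out, pix)
        assert n == 0

    def test_unconfident_pair_skipped(self):
        frames, grid, depth, conf = _two_block_case(0, 20)
        conf.C[:] = 0
        frames[0, 0, 0] = 50
        frames[20, 0, 0] = 120
        stack = FocusStack(frames)
        pix = init_pixel_index(depth, grid)
        out, n = information_filling(stack, pix, depth, conf, self.params)
        assert n == 0

    def test_void_block_pair_skipped(self):
        frames, grid, depth, conf = _two_block_case(0, 20)
        depth.index[0, 1] = VOID_INDEX
        stack = FocusStack(frames)
        pix = init_pixel_index(depth, grid)
        out, n = information_filling(stack, pix, depth, conf, self.params)
        assert n == 0
        assert (out[:, 2:] == VOID_INDEX).all()

    def test_guard_invariant_on_random_stack(self):
        rng = np.random.default_rng(44)
        stack = random_stack(seed=44, n=30, h=32, w=32)
        grid = segment_blocks(32, 32, 8, 8)
        depth = BlockDepthMap(rng.integers(0, 30, size=grid.shape), grid)
        conf = ConfidenceMap(np.ones(grid.shape, dtype=np.uint8), 60)
        pix = init_pixel_index(depth, grid)
        out, _ = information_filling(stack, pix, depth, conf, self.params)
        rows, cols = np.nonzero(
            stack.frames[pix, np.arange(32)[:, None], np.arange(32)[None, :]] >= 80
        )
        # pixels whose current-source value is >= threshold4 never move
        np.testing.assert_array_equal(out[rows, cols], pix[rows, cols])


class TestAssembleFused:
    def test_single_source(self):
        stack = random_stack(1, n=1, h=8, w=8)
        pix = np.zeros((8, 8), dtype=np.int64)
        np.testing.assert_array_equal(assemble_fused(stack, pix), stack.frames[0])

    def test_checkerboard_selection(self):
        stack = random_stack(2, n=2, h=8, w=8)
        pix = np.indices((8, 8)).sum(axis=0) % 2
        fused = assemble_fused(stack, pix)
        for r in range(8):
            for c in range(8):
                assert fused[r, c] == stack.frames[(r + c) % 2, r, c]

    def test_void_renders_zero(self):
        stack = random_stack(3, n=2, h=4, w=4)
        pix = np.full((4, 4), VOID_INDEX)
        np.testing.assert_array_equal(assemble_fused(stack, pix), 0)


class TestSmoothEdges:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        grid = segment_blocks(16, 16, 4, 4)
        pix = rng.integers(0, 3, size=(16, 16))
        out, _ = smooth_edges(img, pix, grid, 0.0)
        np.testing.assert_array_equal(out, img)

    def test_uniform_index_map_untouched(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        grid = segment_blocks(16, 16, 4, 4)
        out, _ = smooth_edges(img, np.zeros((16, 16), dtype=int), grid, 1.0)
        np.testing.assert_array_equal(out, img)

    def test_step_seam_blends_between_levels(self):
        grid = segment_blocks(16, 16, 4, 8)
        img = np.full((16, 16), 10, dtype=np.uint8)
        img[:, 8:] = 200
        pix = np.zeros((16, 16), dtype=int)
        pix[:, 8:] = 5
        depth = img.astype(np.float32)
        out, out_depth = smooth_edges(img, pix, grid, 1.0, depth)
        band = out != img
        assert band.any() and band[:, :5].sum() == 0  # only near the seam
        assert (out[band] > 10).all() and (out[band] < 200).all()
        changed = out_depth != depth
        assert (out_depth[changed] > 10).all() and (out_depth[changed] < 200).all()

    def test_index_change_off_grid_line_not_smoothed(self):
        # discontinuity inside a block (from filling) is not a block seam
        grid = segment_blocks(16, 16, 8, 8)
        img = np.full((16, 16), 10, dtype=np.uint8)
        img[:, 4:] = 200
        pix = np.zeros((16, 16), dtype=int)
        pix[:, 4:] = 5
        out, _ = smooth_edges(img, pix, grid, 1.0)
        np.testing.assert_array_equal(out, img)


class TestIndexToDepth:
    def test_affine_map(self):
        pix = np.array([[3]])
        assert index_to_depth(pix, z0=10.0, z_step=2.0)[0, 0] == 16.0

    def test_void_maps_to_zero(self):
        pix = np.array([[VOID_INDEX, 2]])
        depth = index_to_depth(pix, z0=10.0, z_step=2.0)
        assert depth[0, 0] == 0.0 and depth[0, 1] == 14.0

    def test_zero_stride_collapses_to_z0(self):
        pix = np.arange(6).reshape(2, 3)
        np.testing.assert_array_equal(index_to_depth(pix, 7.0, 0.0), 7.0)

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError, match="z metadata"):
            index_to_depth(np.zeros((2, 2), dtype=int), None, 1.0)

    def test_descending_stack_negates_stride(self):
        pix = np.array([[2]])
        assert index_to_depth(pix, 10.0, 1.5, descending=True)[0, 0] == 7.0


class TestFusePipeline:
    def test_identical_frames_reproduce_frame(self):
        rng = np.random.default_rng(12)
        frame = rng.integers(100, 256, size=(30, 30)).astype(np.uint8)
        stack = FocusStack(np.stack([frame] * 4), z0=0.0, z_step=1.0)
        result = fuse(stack, FusionParams(block_h=10, block_w=10))
        assert (result.pixel_index == 0).all()
        np.testing.assert_array_equal(result.fused, frame)

    def test_blocking_confidence_threshold_voids_everything(self):
        stack = random_stack(5, n=3, h=16, w=16)
        params = FusionParams(block_h=4, block_w=4, threshold0=1e9)
        result = fuse(stack, params)
        assert (result.pixel_index == VOID_INDEX).all()
        np.testing.assert_array_equal(result.fused_raw, 0)

    def test_pixel_provenance_pre_smoothing(self, two_plane_case):
        _, stack, _ = two_plane_case
        params = FusionParams(block_h=16, block_w=16, threshold1=2)
        result = fuse(stack, params)
        rows, cols = np.nonzero(result.valid_mask)
        np.testing.assert_array_equal(
            result.fused_raw[rows, cols],
            stack.frames[result.pixel_index[rows, cols], rows, cols],
        )

    def test_two_plane_depth_recovered(self, two_plane_case):
        scene, stack, truth = two_plane_case
        params = FusionParams(block_h=16, block_w=16, threshold1=2)
        result = fuse(stack, params)
        # away from the boundary band, per-pixel depth equals ground truth
        interior = np.ones_like(truth, dtype=bool)
        interior[:, 56:72] = False
        assert (result.pixel_index[interior] == truth[interior]).all()
        assert result.depth is not None  # synthetic stacks carry z metadata
        np.testing.assert_array_equal(
            result.depth_raw[interior], truth[interior].astype(np.float32)
        )

    def test_stage_log_counts_present(self, two_plane_case):
        _, stack, _ = two_plane_case
        result = fuse(stack, FusionParams(block_h=16, block_w=16))
        for key in ("n_confident_blocks", "n_blocks_adjusted", "n_blocks_filled",
                    "n_pixels_refilled", "n_pixels_void"):
            assert key in result.stage_log

    def test_determinism(self):
        stack = random_stack(9, n=4, h=32, w=32)
        params = FusionParams(block_h=8, block_w=8)
        a = fuse(stack, params)
        b = fuse(stack, params)
        np.testing.assert_array_equal(a.fused, b.fused)
        np.testing.assert_array_equal(a.pixel_index, b.pixel_index)
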