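"""Per-pixel refinement, fused-image assembly and depth conversion.

A block depth map assigns one source frame per block, which produces
visible seams wherever an object boundary crosses a block.  Information
filling relaxes this: for every edge-adjacent block pair whose depths
differ by more than ``threshold3`` (and with at least one confident
member), a pixel switches to the neighboring block's frame when its
current source value is dark (< ``threshold4``) and the neighboring frame
is brighter there — dark pixels in the selected frame are exactly the ones
whose true depth belongs to the other side of the boundary.  Remaining
seams are softened by Gaussian smoothing restricted to a narrow band
around block edges where the source index changes, applied to both the
fused image and the depth raster (never to the integer index map, which
would invent source frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .depthmap import (
    BlockDepthMap,
    ConfidenceMap,
    adjust_depth,
    confidence_map,
    fill_unconfident,
    rough_depth,
)
from .io import VOID_INDEX, FocusStack, FusionParams
from .sharpness import BlockGrid, segment_blocks, sharpness_tensor


@dataclass
class FusedResult:
    """Output of the fusion pipeline.

    ``fused`` is the final (edge-smoothed) all-in-focus image and
    ``fused_raw`` the pre-smoothing assembly, in which every non-void pixel
    is a bit-copy of the corresponding pixel of its source frame.
    ``pixel_index`` maps each pixel to its source frame (``VOID_INDEX``
    where no confident source exists); ``depth``/``depth_raw`` are physical
    depth rasters in micrometers (void pixels 0), present only when the
    stack carried z metadata.  ``stage_log`` counts the work each stage did.
    """

    fused: np.ndarray
    fused_raw: np.ndarray
    pixel_index: np.ndarray
    depth: np.ndarray | None
    depth_raw: np.ndarray | None
    params: FusionParams
    stage_log: dict = field(default_factory=dict)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.pixel_index != VOID_INDEX


def init_pixel_index(depth: BlockDepthMap, grid: BlockGrid) -> np.ndarray:
    """Broadcast the block depth map to a per-pixel source-index map."""
    pix = np.empty((grid.height, grid.width), dtype=np.int64)
    for j, k, (r0, r1, c0, c1) in grid.iter_blocks():
        pix[r0:r1, c0:c1] = depth.index[j, k]
    return pix


def information_filling(
    stack: FocusStack,
    pix: np.ndarray,
    depth: BlockDepthMap,
    conf: ConfidenceMap,
    params: FusionParams,
) -> tuple[np.ndarray, int]:
    """Reassign boundary pixels between depth-discordant adjacent blocks.

    Block pairs are edge-adjacent (4-connectivity) and processed in raster
    order, horizontal pairs then vertical; updates are immediate, so a
    pixel revised by one pair is seen at its new index by later pairs.
    Within a pair, a pixel switches to the *other block's* block-level
    index ``x`` iff its value in its current frame is below ``threshold4``
    and below its value in frame ``x``.  Pairs in which either block is
    void are skipped (there is no frame to compare against).  Returns the
    revised map and the number of pixel switches.
    """
    grid = depth.grid
    idx = depth.index
    C = conf.C
    frames = stack.frames
    out = pix.copy()
    n_switched = 0

    def spans_pairs():
        J, K = grid.shape
        for j in range(J):  # horizontal neighbors
            for k in range(K - 1):
                yield (j, k), (j, k + 1)
        for j in range(J - 1):  # vertical neighbors
            for k in range(K):
                yield (j, k), (j + 1, k)

    rows_grid, cols_grid = np.indices((grid.height, grid.width))

    def fill_side(span, x):
        nonlocal n_switched
        r0, r1, c0, c1 = span
        d = out[r0:r1, c0:c1]
        rr = rows_grid[r0:r1, c0:c1]
        cc = cols_grid[r0:r1, c0:c1]
        valid = d != VOID_INDEX
        vd = np.where(valid, frames[d.clip(min=0), rr, cc], 0)
        vx = frames[x, r0:r1, c0:c1]
        switch = valid & (vd < params.threshold4) & (vd < vx)
        d[switch] = x
        n_switched += int(switch.sum())

    for b1, b2 in spans_pairs():
        i1, i2 = idx[b1], idx[b2]
        if i1 == VOID_INDEX or i2 == VOID_INDEX:
            continue
        if not (C[b1] == 1 or C[b2] == 1):
            continue
        if abs(int(i1) - int(i2)) <= params.threshold3:
            continue
        fill_side(grid.span(*b1), int(i2))
        fill_side(grid.span(*b2), int(i1))
    return out, n_switched


def assemble_fused(stack: FocusStack, pix: np.ndarray) -> np.ndarray:
    """Pick each pixel from its source frame; void pixels render as 0."""
    if pix.shape != (stack.height, stack.width):
        raise ValueError("pixel index map does not match stack shape")
    fused = np.zeros((stack.height, stack.width), dtype=stack.frames.dtype)
    rows, cols = np.nonzero(pix != VOID_INDEX)
    fused[rows, cols] = stack.frames[pix[rows, cols], rows, cols]
    return fused


def _seam_band(pix: np.ndarray, grid: BlockGrid, half_width: int = 2) -> np.ndarray:
    """Pixels within ``half_width`` of a block edge where the index changes."""
    seam = np.zeros(pix.shape, dtype=bool)
    for r in grid.row_starts[1:]:
        change = pix[r - 1, :] != pix[r, :]
        seam[r - 1, change] = True
        seam[r, change] = True
    for c in grid.col_starts[1:]:
        change = pix[:, c - 1] != pix[:, c]
        seam[change, c - 1] = True
        seam[change, c] = True
    if not seam.any():
        return seam
    return ndimage.binary_dilation(
        seam, structure=np.ones((3, 3), dtype=bool), iterations=half_width - 1
    )


def smooth_edges(
    fused: np.ndarray,
    pix: np.ndarray,
    grid: BlockGrid,
    sigma: float,
    depth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Gaussian-smooth seams in the fused image (and depth raster).

    Smoothing of width ``sigma`` is applied only inside a band of +/-2
    pixels around block boundaries at which the per-pixel source index
    changes; ``sigma=0`` is the identity.  Integer images are rounded back
    to their dtype so the working bit depth is preserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return fused.copy(), None if depth is None else depth.copy()
    band = _seam_band(pix, grid)

    def apply(img):
        sm = ndimage.gaussian_filter(img.astype(np.float64), sigma)
        out = np.where(band, sm, img.astype(np.float64))
        if np.issubdtype(img.dtype, np.integer):
            info = np.iinfo(img.dtype)
            out = np.clip(np.rint(out), info.min, info.max)
        return out.astype(img.dtype)

    return apply(fused), None if depth is None else apply(depth)


def index_to_depth(
    pix: np.ndarray, z0: float, z_step: float, descending: bool = False
) -> np.ndarray:
    """Convert a source-index raster to physical depth in micrometers.

    ``depth = z0 + index * z_step`` (minus for a descending stack); void
    pixels map to depth 0, the conventional value for regions with no
    fluorescence evidence.
    """
    if z0 is None or z_step is None:
        raise ValueError("z metadata (z0, z_step) is required for depth conversion")
    step = -z_step if descending else z_step
    depth = (z0 + pix.astype(np.float64) * step).astype(np.float32)
    depth[pix == VOID_INDEX] = 0.0
    return depth


def fuse(
    stack: FocusStack, params: FusionParams, criterion: str = "proposed"
) -> FusedResult:
    """Run the full block-based fusion pipeline on a stack.

    Stages: block segmentation -> per-patch sharpness -> per-block argmax
    depth -> confidence map -> voting adjustment -> unconfident filling ->
    per-pixel initialization -> information filling -> assembly -> seam
    smoothing -> physical depth conversion (when z metadata is present).
    """
    grid = segment_blocks(stack.height, stack.width, params.block_h, params.block_w)
    tensor = sharpness_tensor(stack, grid, criterion)
    rough = rough_depth(tensor)
    conf = confidence_map(stack, grid, rough, params.threshold0)
    adjusted = adjust_depth(rough, conf, params)
    filled = fill_unconfident(adjusted, conf, params.kernel)

    pix0 = init_pixel_index(filled, grid)
    pix, n_pixels_refilled = information_filling(stack, pix0, filled, conf, params)
    fused_raw = assemble_fused(stack, pix)

    depth_raw = None
    if stack.has_z:
        z0 = 0.0 if stack.z0 is None else stack.z0
        depth_raw = index_to_depth(pix, z0, stack.z_step, stack.descending)

    fused, depth = smooth_edges(fused_raw, pix, grid, params.smoothing_sigma, depth_raw)

    stage_log = {
        "grid_shape": list(grid.shape),
        "n_confident_blocks": int(conf.C.sum()),
        "n_blocks_adjusted": int((adjusted.index != rough.index).sum()),
        "n_blocks_filled": int(
            ((filled.index != adjusted.index) & (filled.index != VOID_INDEX)).sum()
        ),
        "n_blocks_void": int((filled.index == VOID_INDEX).sum()),
        "n_pixels_refilled": n_pixels_refilled,
        "n_pixels_void": int((pix == VOID_INDEX).sum()),
    }
    return FusedResult(
        fused=fused,
        fused_raw=fused_raw,
        pixel_index=pix,
        depth=depth,
        depth_raw=depth_raw,
        params=params,
        stage_log=stage_log,
    )
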