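import numpy as np
import pytest

from zfuse import (
    BlockGrid,
    FocusStack,
    make_scene,
    render_stack,
    segment_blocks,
)


def blocks_fully_inside(mask: np.ndarray, grid: BlockGrid) -> np.ndarray:
    """Boolean (J, K) map of blocks whose every pixel lies in ``mask``."""
    out = np.zeros(grid.shape, dtype=bool)
    for j, k, (r0, r1, c0, c1) in grid.iter_blocks():
        out[j, k] = bool(mask[r0:r1, c0:c1].all())
    return out


def random_stack(seed: int, n: int = 5, h: int = 64, w: int = 64) -> FocusStack:
    rng = np.random.default_rng(seed)
    return FocusStack(rng.integers(0, 256, size=(n, h, w), dtype=np.uint8))


@pytest.fixture(scope="session")
def two_plane_case():
    """Noiseless two-plane scene with a block-aligned depth boundary."""
    scene = make_scene("two_plane", 128, 128, 12, seed=11)
    stack, truth = render_stack(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def hemisphere_noisy_case():
    """Noisy hemisphere scene at the reference evaluation size."""
    scene = make_scene("hemisphere", 256, 256, 20, seed=2, noise_sigma=2.0)
    stack, truth = render_stack(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def contamination_case():
    """Bright blob next to a dim textured region at a different depth."""
    scene = make_scene("blob_and_dim_texture", 160, 160, 20, seed=3)
    stack, truth = render_stack(scene)
    return scene, stack, truth


@pytest.fixture()
def grid_16(two_plane_case):
    _, stack, _ = two_plane_case
    return segment_blocks(stack.height, stack.width, 16, 16)
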