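"""Block depth map, confidence map, voting adjustment and filling.

The frame index in which a block scores highest sharpness is a rough
per-block depth estimate.  Because out-of-focus fluorescence can dominate
dark regions, a binary confidence map marks blocks whose selected patch is
bright enough to be trusted, and a local voting pass repairs blocks whose
depth disagrees with a confident neighborhood majority.  Unconfident
blocks inherit the mean depth of confident neighbors, or become void when
they have none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import VOID_INDEX, FocusStack, FusionParams
from .sharpness import BlockGrid, SharpnessTensor


@dataclass
class BlockDepthMap:
    """Per-block source-frame index (``VOID_INDEX`` where unknown)."""

    index: np.ndarray  # (J, K) int
    grid: BlockGrid

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.int64)
        if self.index.shape != self.grid.shape:
            raise ValueError("depth map shape does not match its grid")

    def copy(self) -> "BlockDepthMap":
        return BlockDepthMap(self.index.copy(), self.grid)


@dataclass
class ConfidenceMap:
    """Binary per-block trust map: 1 where the selected patch is bright."""

    C: np.ndarray  # (J, K) of {0, 1}
    threshold0: float

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.uint8)
        if not np.isin(self.C, (0, 1)).all():
            raise ValueError("confidence map must be binary")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def rough_depth(tensor: SharpnessTensor) -> BlockDepthMap:
    """Per-block argmax of sharpness over frames (smallest index on ties)."""
    index = np.argmax(tensor.values, axis=0).astype(np.int64)
    return BlockDepthMap(index, tensor.grid)


def confidence_map(
    stack: FocusStack,
    grid: BlockGrid,
    depth: BlockDepthMap,
    threshold0: float,
) -> ConfidenceMap:
    """Mark blocks whose winning patch is brighter than ``threshold0``.

    The score is the maximum pixel value of the selected patch, i.e. of the
    block's pixels in the frame the depth map picked; confidence is 1 only
    on a strict exceedance.
    """
    C = np.zeros(grid.shape, dtype=np.uint8)
    for j, k, (r0, r1, c0, c1) in grid.iter_blocks():
        i = depth.index[j, k]
        if i == VOID_INDEX:
            continue
        m = stack.frames[i, r0:r1, c0:c1].max()
        if m > threshold0:
            C[j, k] = 1
    return ConfidenceMap(C, threshold0)


def adjust_depth(
    depth: BlockDepthMap, conf: ConfidenceMap, params: FusionParams
) -> BlockDepthMap:
    """Repair blocks whose depth disagrees with a confident local majority.

    For each block, confident blocks in the ``(2*kernel+1)^2`` window
    (clipped at grid borders) vote; those whose index differs from the
    center by more than ``threshold1`` vote *positive*.  When positives
    exceed ``ratio`` of the voters and there are more than ``threshold2``
    voters, the center index is replaced by the mean index of the positive
    voters, rounded half-up.  All windows read the input map (synchronous
    update), so the result is independent of block scan order.
    """
    idx = depth.index
    C = conf.C
    J, K = idx.shape
    r = params.kernel
    out = idx.copy()
    for j in range(J):
        j0, j1 = max(0, j - r), min(J, j + r + 1)
        for k in range(K):
            center = idx[j, k]
            if center == VOID_INDEX:
                continue
            k0, k1 = max(0, k - r), min(K, k + r + 1)
            win_idx = idx[j0:j1, k0:k1]
            confident = (C[j0:j1, k0:k1] == 1) & (win_idx != VOID_INDEX)
            vote_num = int(confident.sum())
            positive = confident & (np.abs(win_idx - center) > params.threshold1)
            pos_vote = int(positive.sum())
            if pos_vote > params.ratio * vote_num and vote_num > params.threshold2:
                out[j, k] = _round_half_up(float(win_idx[positive].mean()))
    return BlockDepthMap(out, depth.grid)


def fill_unconfident(
    depth: BlockDepthMap, conf: ConfidenceMap, kernel: int
) -> BlockDepthMap:
    """Give every unconfident block the mean depth of confident neighbors.

    Uses the same ``(2*kernel+1)^2`` window as the voting pass; the mean is
    rounded half-up.  Unconfident blocks with no confident block in their
    window become void.  Reads the input map throughout (synchronous).
    """
    idx = depth.index
    C = conf.C
    J, K = idx.shape
    out = idx.copy()
    for j in range(J):
        j0, j1 = max(0, j - kernel), min(J, j + kernel + 1)
        for k in range(K):
            if C[j, k] == 1:
                continue
            k0, k1 = max(0, k - kernel), min(K, k + kernel + 1)
            win_idx = idx[j0:j1, k0:k1]
            confident = (C[j0:j1, k0:k1] == 1) & (win_idx != VOID_INDEX)
            if confident.any():
                out[j, k] = _round_half_up(float(win_idx[confident].mean()))
            else:
                out[j, k] = VOID_INDEX
    return BlockDepthMap(out, depth.grid)
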