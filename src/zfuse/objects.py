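"""Optional object-wise fusion: detect, size, mask, fuse per class, merge.

When the visible area holds several well-separated objects of different
scales (e.g. individual pollen grains), one global block size is a
compromise.  This step detects objects on the maximum projection, picks a
block size per object from a candidate ladder according to the object's
bounding-box scale, merges objects sharing a block size into a class,
completes the partition by nearest-class assignment, and reruns the
fusion pipeline per class on masked source frames (pixels outside the
class mask are set to 0) before compositing the fused images and depth
maps back through the masks.

The clustering backends are DBSCAN and plain connected components;
friends-of-friends linking is exposed as the ``min_samples=1`` special
case of DBSCAN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import DBSCAN

from .fusion import FusedResult, fuse, index_to_depth, smooth_edges
from .io import VOID_INDEX, FocusStack, FusionParams
from .sharpness import max_projection, segment_blocks


@dataclass
class ObjectStats:
    bbox: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    n_pixels: int
    block_size: tuple[int, int] | None = None


@dataclass
class ObjectPartition:
    """Label raster plus per-object statistics.

    Label 0 means "not yet assigned"; after :func:`complete_partition`
    every pixel carries exactly one object label >= 1.
    """

    labels: np.ndarray  # (H, W) int, 0 = unassigned
    stats: dict[int, ObjectStats] = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return len(self.stats)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def is_complete(self) -> bool:
        return bool((self.labels > 0).all())


def _stats_from_labels(labels: np.ndarray) -> dict[int, ObjectStats]:
    stats: dict[int, ObjectStats] = {}
    for label in np.unique(labels):
        if label == 0:
            continue
        rows, cols = np.nonzero(labels == label)
        stats[int(label)] = ObjectStats(
            bbox=(int(rows.min()), int(rows.max()) + 1,
                  int(cols.min()), int(cols.max()) + 1),
            n_pixels=int(rows.size),
        )
    return stats


def detect_objects(
    stack: FocusStack,
    lum_threshold: float,
    clustering: str = "dbscan",
    eps: float = 5.0,
    min_samples: int = 5,
) -> ObjectPartition:
    """Cluster bright pixels of the max projection into object labels.

    Pixels of the maximum projection above ``lum_threshold`` are clustered
    spatially; each cluster becomes one label (1-based).  Below-threshold
    pixels (and DBSCAN noise points) stay unlabeled.  ``clustering`` is
    ``"dbscan"``, ``"fof"`` (DBSCAN with ``min_samples=1``, the
    friends-of-friends linking case) or ``"connected_components"``.
    """
    proj = max_projection(stack)
    bright = proj > lum_threshold
    labels = np.zeros(proj.shape, dtype=np.int32)
    if not bright.any():
        warnings.warn("no pixels above luminosity threshold; empty partition",
                      stacklevel=2)
        return ObjectPartition(labels)

    if clustering == "connected_components":
        labels, _ = ndimage.label(bright)
        labels = labels.astype(np.int32)
    elif clustering in ("dbscan", "fof"):
        if clustering == "fof":
            min_samples = 1
        coords = np.column_stack(np.nonzero(bright))
        fit = DBSCAN(eps=eps, min_samples=min_samples).fit(coords)
        keep = fit.labels_ >= 0
        labels[coords[keep, 0], coords[keep, 1]] = fit.labels_[keep] + 1
    else:
        raise ValueError(f"unknown clustering backend {clustering!r}")
    return ObjectPartition(labels, _stats_from_labels(labels))


def choose_block_size(
    stats: ObjectStats,
    size_ladder: tuple[int, ...] = (5, 10, 15, 20, 25),
    divisor: float = 10.0,
    min_block: int = 5,
) -> tuple[int, int]:
    """Pick a block size for one object from its bounding-box scale.

    Target scale is ``max(min_block, min(bbox_h, bbox_w) / divisor)``; the
    result is the largest ladder entry not exceeding the target (the
    smallest ladder entry if none qualifies).  Square blocks are returned;
    the rule is deterministic and monotone in the object scale.
    """
    if stats.n_pixels == 0:
        raise ValueError("cannot choose a block size for an empty object")
    r0, r1, c0, c1 = stats.bbox
    target = max(float(min_block), min(r1 - r0, c1 - c0) / divisor)
    ladder = sorted(size_ladder)
    fitting = [s for s in ladder if s <= target]
    m = fitting[-1] if fitting else ladder[0]
    return (m, m)


def complete_partition(partition: ObjectPartition) -> ObjectPartition:
    """Assign every unlabeled pixel to the nearest labeled object.

    Nearest is Euclidean distance to the object's pixels; ties go to the
    smaller label.  Already-assigned pixels are never reassigned.
    """
    labels = partition.labels
    if partition.n_objects == 0:
        raise ValueError("partition has no labeled objects to complete")
    if partition.is_complete():
        return ObjectPartition(labels.copy(), dict(partition.stats))
    label_ids = sorted(partition.stats)
    dists = np.stack([
        ndimage.distance_transform_edt(labels != lab) for lab in label_ids
    ])
    nearest = np.asarray(label_ids, dtype=labels.dtype)[np.argmin(dists, axis=0)]
    out = np.where(labels > 0, labels, nearest)
    return ObjectPartition(out, dict(partition.stats))


def fuse_by_objects(
    stack: FocusStack,
    params: FusionParams,
    partition: ObjectPartition,
) -> FusedResult:
    """Fuse each object class at its own block size and composite.

    Objects sharing a block size form one class; the class mask is the
    union of its members' completed regions.  For each class the source
    frames are masked (outside pixels -> 0) and the full pipeline runs at
    the class block size without seam smoothing; the per-class fused
    images, index maps and depth rasters are composited through the masks
    and the composite is seam-smoothed once at the end.  With a single
    class covering the whole image this reduces bit-exactly (pre-
    smoothing) to :func:`zfuse.fusion.fuse` at that block size.
    """
    if not partition.is_complete():
        partition = complete_partition(partition)
    for label, st in partition.stats.items():
        if st.block_size is None:
            st.block_size = choose_block_size(
                st, params.size_ladder, params.divisor, params.min_block
            )

    classes: dict[tuple[int, int], list[int]] = {}
    for label, st in sorted(partition.stats.items()):
        classes.setdefault(st.block_size, []).append(label)

    H, W = stack.height, stack.width
    pix = np.full((H, W), VOID_INDEX, dtype=np.int64)
    fused_raw = np.zeros((H, W), dtype=stack.frames.dtype)
    class_log = {}
    for block_size, members in sorted(classes.items()):
        mask = np.isin(partition.labels, members)
        masked = FocusStack(
            stack.frames * mask,
            z0=stack.z0, z_step=stack.z_step,
            pixel_pitch=stack.pixel_pitch, descending=stack.descending,
        )
        sub_params = params.replace(
            block_h=block_size[0], block_w=block_size[1], smoothing_sigma=0.0
        )
        sub = fuse(masked, sub_params)
        pix[mask] = sub.pixel_index[mask]
        fused_raw[mask] = sub.fused_raw[mask]
        class_log[f"class_{block_size[0]}x{block_size[1]}"] = {
            "members": members, **sub.stage_log
        }

    depth_raw = None
    if stack.has_z:
        z0 = 0.0 if stack.z0 is None else stack.z0
        depth_raw = index_to_depth(pix, z0, stack.z_step, stack.descending)
    grid = segment_blocks(H, W, params.block_h, params.block_w)
    fused, depth = smooth_edges(fused_raw, pix, grid, params.smoothing_sigma, depth_raw)
    return FusedResult(
        fused=fused, fused_raw=fused_raw, pixel_index=pix,
        depth=depth, depth_raw=depth_raw, params=params,
        stage_log={"classes": class_log, "n_objects": partition.n_objects},
    )
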