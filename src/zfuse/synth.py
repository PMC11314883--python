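"""Synthetic fluorescence z-stacks with known ground-truth depth.

No public benchmark with per-pixel depth truth exists for epifluorescence
focus stacks, so every pipeline stage is exercised on rendered scenes.
The renderer emulates the two properties of widefield fluorescence optics
the fusion method relies on:

* the in-focus plane of a surface element is both its sharpest *and*
  brightest appearance — blur grows linearly and brightness falls off
  hyperbolically with defocus distance;
* out-of-focus light is not rejected (no confocal pinhole), so a bright
  structure smears into neighboring regions in frames focused far from it.

A scene is a per-pixel height map ``Z`` (in frame-index units), an
emission texture ``E >= 0``, and three physics knobs.  Frame ``i`` is

    frame_i = clip( gain(.,i) * GaussianBlur(E, sigma(.,i)) + noise )

with ``sigma(p,i) = blur_rate * |i - Z(p)|`` and
``gain(p,i) = 1 / (1 + atten_rate * |i - Z(p)|)``, rendered to 8-bit.
At the in-focus frame the gain is maximal (1) and the blur minimal (0).
The hyperbolic (rather than Gaussian) brightness falloff keeps dim
regions above zero at every plane, so confidence thresholds stay
exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import FocusStack
from .sharpness import BlockGrid

SCENE_KINDS = ("two_plane", "staircase", "hemisphere", "blob_and_dim_texture")

#: Rendering quantization of the height map, in frame-index units.  The
#: spatially varying blur is realized per quantized depth level.
_Z_QUANTUM = 0.5


@dataclass
class SyntheticScene:
    """A renderable scene: height map, emission texture and physics."""

    height_map: np.ndarray  # Z(p), frame-index units
    emission: np.ndarray    # E(p) >= 0, 8-bit-scale intensities
    n_frames: int
    blur_rate: float = 2.0       # px of blur sigma per frame of defocus
    atten_rate: float = 0.05     # brightness falloff per frame of defocus
    noise_sigma: float = 0.0     # additive Gaussian read noise, 8-bit DN
    seed: int = 0
    kind: str = "custom"
    #: Named regions of interest (boolean masks) the scene guarantees,
    #: e.g. the contamination scene's bright blob and dim neighbor region.
    regions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.height_map = np.asarray(self.height_map, dtype=np.float64)
        self.emission = np.asarray(self.emission, dtype=np.float64)
        if self.height_map.shape != self.emission.shape:
            raise ValueError("height map and emission texture shapes differ")
        if (self.emission < 0).any():
            raise ValueError("emission texture must be >= 0")
        if self.n_frames < 2:
            raise ValueError("a scene needs at least 2 focal planes")


def make_scene(
    kind: str,
    height: int = 128,
    width: int = 128,
    n_frames: int = 12,
    seed: int = 0,
    noise_sigma: float = 0.0,
    blur_rate: float = 2.0,
    atten_rate: float = 0.05,
) -> SyntheticScene:
    """Build one of the standard test scenes, deterministically from seed.

    ``two_plane``: two depth levels split at the vertical midline (block-
    aligned for any block width dividing ``width/2``).  ``staircase``:
    four depth terraces.  ``hemisphere``: a spherical cap spanning the
    full depth range [0, N-1] over a shallow background.
    ``blob_and_dim_texture``: a bright disc at a deep plane next to a dim
    textured region at a shallow plane — the scenario in which smeared
    out-of-focus light from the blob overwhelms per-pixel brightest-frame
    selection in the dim region while block sharpness does not care.
    """
    if kind not in SCENE_KINDS:
        raise ValueError(f"unknown scene kind {kind!r}; choose from {SCENE_KINDS}")
    rng = np.random.default_rng(seed)
    H, W, N = height, width, n_frames
    regions: dict = {}

    if kind == "two_plane":
        z_a, z_b = N // 4, (3 * N) // 4
        Z = np.full((H, W), float(z_a))
        Z[:, W // 2:] = float(z_b)
        E = rng.uniform(40.0, 220.0, size=(H, W))
        regions["plane_a"] = Z == z_a
        regions["plane_b"] = Z == z_b
    elif kind == "staircase":
        levels = np.linspace(0, N - 1, 4)
        Z = np.zeros((H, W))
        for step, z in enumerate(levels):
            Z[:, step * W // 4:(step + 1) * W // 4] = z
        E = rng.uniform(40.0, 220.0, size=(H, W))
    elif kind == "hemisphere":
        yy, xx = np.mgrid[0:H, 0:W]
        radius = 0.45 * min(H, W)
        r2 = ((yy - H / 2) ** 2 + (xx - W / 2) ** 2) / radius**2
        cap = np.clip(1.0 - r2, 0.0, None)
        Z = (N - 1) * np.sqrt(cap)
        inside = r2 < 1.0
        E = np.where(inside,
                     rng.uniform(60.0, 220.0, size=(H, W)),
                     rng.uniform(20.0, 55.0, size=(H, W)))
        regions["cap"] = inside
    else:  # blob_and_dim_texture
        z_dim = N // 4          # shallow, true depth of the dim surround
        z_blob = z_dim + min(10, N - 1 - z_dim)   # deep bright blob
        yy, xx = np.mgrid[0:H, 0:W]
        r_blob = min(H, W) * 0.18
        dist = np.hypot(yy - H / 2, xx - W / 2)
        blob = dist <= r_blob
        dim_ring = (dist > r_blob) & (dist <= r_blob + 24)
        Z = np.full((H, W), float(z_dim))
        Z[blob] = float(z_blob)
        E = rng.uniform(0.0, 70.0, size=(H, W))
        E[blob] = rng.uniform(200.0, 255.0, size=(H, W))[blob]
        regions["blob"] = blob
        regions["dim"] = dim_ring
        regions["depth_blob"] = z_blob
        regions["depth_dim"] = z_dim

    return SyntheticScene(
        height_map=Z, emission=E, n_frames=N,
        blur_rate=blur_rate, atten_rate=atten_rate,
        noise_sigma=noise_sigma, seed=seed, kind=kind, regions=regions,
    )


def render_stack(
    scene: SyntheticScene, z0: float = 0.0, z_step: float = 1.0,
    pixel_pitch: float = 1.0,
) -> tuple[FocusStack, np.ndarray]:
    """Render a scene to an 8-bit focus stack; also return the truth map.

    The depth-dependent blur is realized per quantized height level: for
    each frame and each distinct level ``z`` the full emission texture is
    blurred with ``sigma = blur_rate * |i - z|`` and scaled by the
    brightness gain, and pixels at that level copy from that rendering —
    so light from *all* structures, in-focus or not, lands in every frame.
    Deterministic given the scene (noise is seeded from ``scene.seed``).
    """
    H, W = scene.height_map.shape
    N = scene.n_frames
    zq = np.round(scene.height_map / _Z_QUANTUM) * _Z_QUANTUM
    levels = np.unique(zq)
    rng = np.random.default_rng(scene.seed)

    frames = np.empty((N, H, W), dtype=np.uint8)
    for i in range(N):
        out = np.empty((H, W), dtype=np.float64)
        for z in levels:
            dz = abs(i - z)
            sigma = scene.blur_rate * dz
            blurred = ndimage.gaussian_filter(scene.emission, sigma) if sigma > 0 \
                else scene.emission
            gain = 1.0 / (1.0 + scene.atten_rate * dz)
            sel = zq == z
            out[sel] = blurred[sel] * gain
        if scene.noise_sigma > 0:
            out = out + rng.normal(0.0, scene.noise_sigma, size=(H, W))
        frames[i] = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    stack = FocusStack(frames, z0=z0, z_step=z_step, pixel_pitch=pixel_pitch)
    return stack, scene.height_map.copy()


def depth_rmse(
    recovered: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Root-mean-square depth error over a mask, in the rasters' units."""
    recovered = np.asarray(recovered, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if recovered.shape != truth.shape:
        raise ValueError("recovered and truth rasters must share a shape")
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != truth.shape:
            raise ValueError("mask shape must match the rasters")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    diff = recovered[mask] - truth[mask]
    return float(np.sqrt(np.mean(diff**2)))


def block_truth(truth: np.ndarray, grid: BlockGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-block mean and peak-to-peak spread of a ground-truth depth map.

    The spread identifies discontinuity-free blocks (small spread), the
    only blocks for which a single per-block depth is well defined.
    """
    mean = np.empty(grid.shape, dtype=np.float64)
    spread = np.empty(grid.shape, dtype=np.float64)
    for j, k, (r0, r1, c0, c1) in grid.iter_blocks():
        tile = truth[r0:r1, c0:c1]
        mean[j, k] = tile.mean()
        spread[j, k] = tile.max() - tile.min()
    return mean, spread
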