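"""Stack, raster, parameter and point-cloud I/O.

All file-format handling for the package lives here: z-stacks come in as
multi-page TIFFs or directories of single-page TIFF/PNG frames; fused
images, per-pixel source-index maps and physical depth maps go out as
TIFFs; surfaces go out as ASCII PLY point clouds; fusion parameters are
read from and written to YAML/JSON files.

Intensities keep their native integer range (8- or 16-bit) rather than
being rescaled to [0, 1]: the confidence and information-filling
thresholds are expressed in raw intensity units, so they scale with the
bit depth of the input and the defaults below assume 8-bit-style data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: Sentinel for "no source frame" in block- and pixel-index maps.  -1 rather
#: than 0 because 0 is a valid frame index; void entries are mapped to depth 0
#: only when a depth image or point cloud is exported.
VOID_INDEX = -1

#: ITU-R BT.601 luma weights applied when an RGB frame must be collapsed to
#: a single grayscale channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class FocusStack:
    """An ordered z-stack of co-registered grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(N, H, W)``; frame order corresponds to
        monotonically increasing object distance unless ``descending``.
    z0
        Object distance of frame 0 in micrometers, if known.
    z_step
        Spacing between consecutive focal planes in micrometers, if known.
    pixel_pitch
        Lateral size of one pixel in micrometers, if known.
    descending
        Set when frame order corresponds to decreasing object distance.
    """

    frames: np.ndarray
    z0: float | None = None
    z_step: float | None = None
    pixel_pitch: float | None = None
    descending: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (N, H, W) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("a FocusStack needs at least one frame")
        if np.issubdtype(self.frames.dtype, np.floating) and (self.frames < 0).any():
            raise ValueError("frame intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def has_z(self) -> bool:
        return self.z_step is not None


@dataclass
class FusionParams:
    """Tunable parameters of the fusion pipeline.

    Defaults are the reference operating point for 8-bit stacks: block
    15x15 px, confidence cut at intensity 60, a 5x5-block voting window
    (kernel 2) with depth-disagreement threshold 40 frames, majority ratio
    0.5 and minimum 4 confident voters, and information filling between
    blocks more than 10 frames apart for pixels darker than 80.
    Intensity thresholds (``threshold0``, ``threshold4``) are in raw
    intensity units and must be rescaled for 16-bit data; index thresholds
    (``threshold1``, ``threshold3``) are in frame-index units.
    """

    block_h: int = 15
    block_w: int = 15
    threshold0: float = 60.0
    kernel: int = 2
    threshold1: float = 40.0
    threshold2: float = 4.0
    ratio: float = 0.5
    threshold3: float = 10.0
    threshold4: float = 80.0
    smoothing_sigma: float = 1.0
    use_objects: bool = False
    # object-step knobs (used only when use_objects is set)
    lum_threshold: float = 60.0
    clustering: str = "dbscan"
    eps: float = 5.0
    min_samples: int = 5
    size_ladder: tuple[int, ...] = (5, 10, 15, 20, 25)
    divisor: float = 10.0
    min_block: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.size_ladder, list):
            self.size_ladder = tuple(self.size_ladder)
        if self.block_h < 2 or self.block_w < 2:
            raise ValueError("block size must be at least 2x2")
        if self.kernel < 1:
            raise ValueError("kernel (window radius) must be >= 1")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")
        for name in ("threshold0", "threshold1", "threshold2", "threshold3",
                     "threshold4", "smoothing_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **changes) -> "FusionParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_ladder"] = list(self.size_ladder)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FusionParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "FusionParams":
        """Load parameters from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _to_gray(arr: np.ndarray, origin: str) -> np.ndarray:
    """Collapse an RGB(A) frame to luminance; pass grayscale through."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        lum = rgb @ np.asarray(LUMA_WEIGHTS)
        if np.issubdtype(arr.dtype, np.integer):
            lum = np.rint(lum).astype(arr.dtype)
        return lum
    raise ValueError(f"cannot interpret {origin}: shape {arr.shape} is not an image")


def read_stack(
    path: str | Path,
    z0: float | None = None,
    z_step: float | None = None,
    pixel_pitch: float | None = None,
    frame_order: Sequence[str] | None = None,
) -> FocusStack:
    """Read a z-stack from a multi-page TIFF or a directory of frames.

    Directory frames are ordered by lexicographic filename sort (assumed to
    follow ascending object distance) unless ``frame_order`` gives an
    explicit list of filenames.  RGB frames are converted to luminance with
    BT.601 weights.  All frames are promoted to a single common dtype.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack path does not exist: {path}")

    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if frame_order is not None:
            files = [path / name for name in frame_order]
            missing = [str(p) for p in files if not p.exists()]
            if missing:
                raise FileNotFoundError(f"frame(s) listed but absent: {missing}")
        if len(files) < 2:
            raise ValueError(
                f"{path} holds {len(files)} readable frame(s); a stack needs >= 2"
            )
        frames = []
        for f in files:
            if f.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(f)
            else:
                arr = iio.imread(f)
            frames.append(_to_gray(np.asarray(arr), str(f)))
        h, w = frames[0].shape
        for f, arr in zip(files, frames):
            if arr.shape != (h, w):
                raise ValueError(
                    f"frame {f} has shape {arr.shape}, expected {(h, w)}"
                )
        dtype = np.result_type(*[a.dtype for a in frames])
        stacked = np.stack([a.astype(dtype) for a in frames])
    else:
        arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 2:
            raise ValueError(f"{path} holds a single page; a stack needs >= 2")
        if arr.ndim == 4:  # pages x H x W x channels
            arr = np.stack([_to_gray(page, str(path)) for page in arr])
        if arr.ndim != 3:
            raise ValueError(f"{path}: cannot interpret shape {arr.shape} as a stack")
        if arr.shape[0] < 2:
            raise ValueError(f"{path} holds {arr.shape[0]} page(s); a stack needs >= 2")
        stacked = arr

    return FocusStack(stacked, z0=z0, z_step=z_step, pixel_pitch=pixel_pitch)


def write_outputs(result, out_dir: str | Path) -> dict[str, Path]:
    """Write a fused result to ``out_dir`` as TIFF rasters.

    Writes ``fused.tif`` in the working bit depth, ``index.tif`` as signed
    16-bit (void sentinel preserved as -1), and — when z metadata was
    available — ``depth.tif`` as 32-bit float micrometers with void pixels
    at 0.  Returns a mapping of output name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    fused_path = out_dir / "fused.tif"
    tifffile.imwrite(fused_path, np.asarray(result.fused))
    written["fused"] = fused_path

    index_path = out_dir / "index.tif"
    tifffile.imwrite(index_path, np.asarray(result.pixel_index, dtype=np.int16))
    written["index"] = index_path

    if result.depth is not None:
        depth_path = out_dir / "depth.tif"
        tifffile.imwrite(depth_path, np.asarray(result.depth, dtype=np.float32))
        written["depth"] = depth_path
    else:
        logger.warning("no z metadata on result; depth.tif not written")
    return written


def export_point_cloud(
    depth_map: np.ndarray,
    path: str | Path,
    pixel_pitch: float,
    mask: np.ndarray | None = None,
) -> int:
    """Export a depth raster as an ASCII PLY point cloud.

    One vertex ``(x=col*pitch, y=row*pitch, z=depth)`` is written per
    included pixel.  Pixels excluded by ``mask`` (False) or holding a
    non-finite depth (the void convention on export) are skipped.  Returns
    the number of vertices written.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be > 0")
    depth_map = np.asarray(depth_map, dtype=np.float64)
    keep = np.isfinite(depth_map)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != depth_map.shape:
            raise ValueError("mask shape must match depth map shape")
        keep &= mask
    rows, cols = np.nonzero(keep)
    n = rows.size
    if n == 0:
        warnings.warn("point cloud is empty: no valid pixels", stacklevel=2)

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {n}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        for r, c, z in zip(rows, cols, depth_map[rows, cols]):
            fh.write(f"{c * pixel_pitch:.6g} {r * pixel_pitch:.6g} {z:.6g}\n")
    return n
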