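"""Image-sequence I/O, bounding boxes, and normalized patch extraction.

Conventions
-----------
Coordinates are 0-based with the origin at the top-left pixel center; a
bounding box is ``(x, y, w, h)`` = (left, top, width, height) in pixels and
may be fractional.  OTB-style annotation files are 1-based and are converted
at the I/O boundary (subtract 1 on read, add 1 on write).

Every frame is a single-channel intensity grid scaled to [0, 1]; RGB input
is collapsed with the Rec. 601 luma weights.  Patches are 32x32 crops
obtained by bilinear resampling with zero fill outside the frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Frame",
    "BoundingBox",
    "Patch",
    "PATCH_SIZE",
    "read_sequence",
    "read_annotations",
    "write_trajectory",
    "extract_patch",
    "extract_patches",
]

#: side length of the normalized patch every appearance computation sees
PATCH_SIZE = 32

_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Frame:
    """A single grayscale video frame with intensities in [0, 1]."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"frame pixels must be a 2-D grid, got shape {px.shape}")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``(x, y, w, h)``; edges may be fractional."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box width/height must be positive, got w={self.w}, h={self.h}")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.w, self.h)


@dataclass(frozen=True)
class Patch:
    """A 32x32 normalized grayscale patch and the box it was cut from."""

    pixels: np.ndarray
    source_box: BoundingBox | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch must be {PATCH_SIZE}x{PATCH_SIZE}, got {px.shape}")
        object.__setattr__(self, "pixels", px)


def _natural_key(path: Path) -> list:
    """Sort key treating digit runs numerically (img2 < img10)."""
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an image array to 2-D float64 intensities in [0, 1]."""
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.integer):
        scale = float(np.iinfo(a.dtype).max)
        a = a.astype(np.float64) / scale
    else:
        a = a.astype(np.float64)
    if a.ndim == 3:
        if a.shape[-1] == 4:  # drop alpha
            a = a[..., :3]
        if a.shape[-1] == 3:
            a = a @ _REC601
        elif a.shape[-1] == 1:
            a = a[..., 0]
        else:
            raise ValueError(f"cannot interpret image with shape {a.shape}")
    elif a.ndim != 2:
        raise ValueError(f"cannot interpret image with shape {a.shape}")
    return np.clip(a, 0.0, 1.0)


def _load_file(path: Path) -> list[np.ndarray]:
    """Load one image file; multi-page TIFFs expand into several arrays."""
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
            # a 3-D tiff with a non-color trailing axis is a page stack
            if arr.ndim == 3 and arr.shape[-1] not in (1, 3, 4):
                return [a for a in arr]
            if arr.ndim == 4:
                return [a for a in arr]
            return [arr]
        return [iio.imread(str(path))]
    except Exception as exc:  # readers raise a zoo of backend-specific errors
        raise OSError(f"could not read image file {path}: {exc}") from exc


def read_sequence(source: str | Path) -> list[Frame]:
    """Read an ordered image sequence from a directory or a glob pattern.

    Files are sorted by natural filename order; each becomes one grayscale
    :class:`Frame` (multi-page TIFFs contribute one frame per page).
    """
    src = Path(source)
    if src.is_dir():
        candidates = [p for p in src.iterdir() if p.is_file()]
        candidates = [
            p for p in candidates
            if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp")
        ]
    else:
        candidates = [Path(p) for p in sorted(src.parent.glob(src.name))]
        candidates = [p for p in candidates if p.is_file()]
    if not candidates:
        raise FileNotFoundError(f"empty sequence: no image files matched {source!r}")
    candidates.sort(key=_natural_key)
    frames: list[Frame] = []
    for path in candidates:
        for arr in _load_file(path):
            frames.append(Frame(to_grayscale(arr), index=len(frames)))
    return frames


_LINE_SPLIT = re.compile(r"[,\s]+")


def read_annotations(path: str | Path) -> list[BoundingBox]:
    """Read OTB-dialect annotations (1-based ``x,y,w,h`` per line)."""
    boxes: list[BoundingBox] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = [f for f in _LINE_SPLIT.split(line) if f]
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 numbers per line, got {len(fields)}"
                )
            try:
                x, y, w, h = (float(f) for f in fields)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from exc
            if w <= 0 or h <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive box size w={w}, h={h}")
            boxes.append(BoundingBox(x - 1.0, y - 1.0, w, h))
    return boxes


def _fmt(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def write_trajectory(path: str | Path, boxes: Sequence[BoundingBox]) -> None:
    """Write boxes in the 1-based OTB dialect; inverse of :func:`read_annotations`."""
    if not boxes:
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{_fmt(b.x + 1.0)},{_fmt(b.y + 1.0)},{_fmt(b.w)},{_fmt(b.h)}\n")


def _rounded_rect(box: BoundingBox) -> tuple[int, int, int, int]:
    x0 = int(round(box.x))
    y0 = int(round(box.y))
    w = max(1, int(round(box.w)))
    h = max(1, int(round(box.h)))
    return x0, y0, w, h


def _sample_grid(box: BoundingBox, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col coordinates mapping patch pixel centers onto the rounded box."""
    x0, y0, w, h = _rounded_rect(box)
    cols = x0 + (np.arange(size) + 0.5) * (w / size) - 0.5
    rows = y0 + (np.arange(size) + 0.5) * (h / size) - 0.5
    return rows, cols


def extract_patch(frame: Frame, box: BoundingBox, size: int = PATCH_SIZE) -> Patch:
    """Cut ``box`` out of ``frame`` and resample it to ``size`` x ``size``.

    The box is rounded to whole pixels, bilinearly resampled with
    pixel-center alignment, and any area outside the frame reads as 0.
    """
    x0, y0, w, h = _rounded_rect(box)
    if x0 + w <= 0 or y0 + h <= 0 or x0 >= frame.width or y0 >= frame.height:
        raise ValueError(f"box {box.as_tuple()} lies entirely out of frame")
    rows, cols = _sample_grid(box, size)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    # explicit 1-px zero border so interpolation blends to 0 at the frame edge
    padded = np.pad(frame.pixels, 1)
    out = ndimage.map_coordinates(
        padded, [rr + 1.0, cc + 1.0], order=1, mode="constant", cval=0.0
    )
    return Patch(out, source_box=box)


def extract_patches(frame: Frame, boxes: Iterable[BoundingBox],
                    size: int = PATCH_SIZE) -> np.ndarray:
    """Batch form of :func:`extract_patch`: ``(n, size, size)`` float array.

    Bit-identical to calling :func:`extract_patch` per box; boxes entirely
    outside the frame yield all-zero patches instead of raising (the caller
    decides how to weight them).
    """
    boxes = list(boxes)
    n = len(boxes)
    rr = np.empty((n, size, size))
    cc = np.empty((n, size, size))
    for i, b in enumerate(boxes):
        rows, cols = _sample_grid(b, size)
        rr[i], cc[i] = np.meshgrid(rows, cols, indexing="ij")
    padded = np.pad(frame.pixels, 1)
    out = ndimage.map_coordinates(
        padded, [rr.ravel() + 1.0, cc.ravel() + 1.0], order=1,
        mode="constant", cval=0.0
    )
    return out.reshape(n, size, size)
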