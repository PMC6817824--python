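"""Frame-sequence loading, arena geometry, and trinarized-mask I/O.

A recording is an ordered stack of RGB photographs of a circular petri-dish
arena taken at a fixed interval (typically every 5 minutes for 35 hours).
All physical quantities downstream are expressed in millimetres through the
``mm_per_px`` scale carried by :class:`ArenaMask`; the scale comes from the
known arena diameter, never from image metadata.

Conventions: coordinates are (row, col), 0-based, with pixel centers at
integer positions.  Frame order is the lexicographic filename order unless
an explicit manifest overrides it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from PIL import Image

from .labels import LABEL_PALETTE, Label

__all__ = [
    "FrameSequence",
    "ArenaMask",
    "load_sequence",
    "make_arena",
    "detect_arena",
    "write_trinarized",
    "read_trinarized",
]


@dataclass
class FrameSequence:
    """Ordered RGB frames with a fixed sampling interval.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W, 3), uint8
        The image stack; all frames share dimensions.
    interval_min : float
        Sampling interval in minutes, > 0.
    paths : list of Path, optional
        Source file of each frame, when loaded from disk.
    """

    frames: np.ndarray
    interval_min: float
    paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(
                f"frames must have shape (T, H, W, 3); got {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit RGB (uint8)")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def times_min(self) -> np.ndarray:
        """Timestamps in minutes: index times the sampling interval."""
        return np.arange(len(self)) * float(self.interval_min)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ArenaMask:
    """Circular analysis region with its physical pixel scale.

    ``mm_per_px`` is fixed by the known arena diameter:
    ``mm_per_px = arena_diameter_mm / (2 * radius_px)``.
    """

    center_px: tuple[float, float]
    radius_px: float
    mm_per_px: float
    mask: np.ndarray

    @property
    def n_px(self) -> int:
        """Number of pixels inside the arena."""
        return int(self.mask.sum())

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        r0, c0 = self.center_px
        return (rows - r0) ** 2 + (cols - c0) ** 2 <= self.radius_px**2


def _decode_frame(path: Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2 or (img.ndim == 3 and img.shape[-1] == 1):
        raise ValueError(f"grayscale image not supported: {path}")
    if img.ndim != 3 or img.shape[-1] not in (3, 4):
        raise ValueError(f"unsupported channel layout {img.shape} in {path}")
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    if img.dtype != np.uint8:
        # 16-bit TIFF and friends: rescale to 8 bit
        from skimage.util import img_as_ubyte

        img = img_as_ubyte(img)
    return img


def load_sequence(
    source: str | os.PathLike | Sequence[str | os.PathLike],
    interval_min: float,
    manifest: str | os.PathLike | None = None,
) -> FrameSequence:
    """Load an ordered image sequence from a directory or explicit file list.

    Files are taken in lexicographic order of their names (temporal order by
    convention); a *manifest* — a text file listing one filename per line —
    overrides the sort.  At least two frames are required; all frames must be
    RGB with identical dimensions.

    Raises
    ------
    ValueError
        On fewer than two frames, a grayscale frame, or mixed dimensions
        (the offending file is named in the message).
    """
    if isinstance(source, (str, os.PathLike)):
        root = Path(source)
        if not root.is_dir():
            raise ValueError(f"not a directory: {root}")
        exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
        files = sorted(p for p in root.iterdir() if p.suffix.lower() in exts)
        if manifest is not None:
            order = [
                line.strip()
                for line in Path(manifest).read_text().splitlines()
                if line.strip()
            ]
            files = [root / name for name in order]
    else:
        files = [Path(p) for p in source]

    if len(files) < 2:
        raise ValueError(f"need at least 2 frames, found {len(files)}")

    frames = []
    shape: tuple[int, ...] | None = None
    for p in files:
        img = _decode_frame(p)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(
                f"frame dimensions {img.shape} of {p} do not match first frame {shape}"
            )
        frames.append(img)
    return FrameSequence(np.stack(frames), interval_min, paths=list(files))


def make_arena(
    center_px: tuple[float, float],
    radius_px: float,
    arena_diameter_mm: float,
    image_shape: tuple[int, int],
) -> ArenaMask:
    """Build the circular arena mask and its mm-per-pixel scale.

    A pixel belongs to the arena when its center lies inside (or on) the
    circle.  The circle must fit entirely within the image bounds.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    if arena_diameter_mm <= 0:
        raise ValueError("arena_diameter_mm must be > 0")
    h, w = image_shape
    r0, c0 = center_px
    if r0 - radius_px < 0 or r0 + radius_px > h - 1 or c0 - radius_px < 0 or c0 + radius_px > w - 1:
        raise ValueError(
            f"arena circle (center={center_px}, radius={radius_px}) exceeds "
            f"image bounds {image_shape}"
        )
    rows, cols = np.ogrid[:h, :w]
    mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px**2
    mm_per_px = arena_diameter_mm / (2.0 * radius_px)
    return ArenaMask((float(r0), float(c0)), float(radius_px), mm_per_px, mask)


def detect_arena(
    frame: np.ndarray,
    arena_diameter_mm: float,
    radius_bounds_frac: tuple[float, float] = (0.3, 0.49),
    n_radii: int = 12,
) -> ArenaMask:
    """Best-effort circular-contour autodetection (Hough transform on edges).

    Provided as a convenience only: the supported workflow is to supply the
    arena geometry explicitly (the dish contour is identified manually),
    and this helper is never invoked by default.
    """
    from skimage.color import rgb2gray
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    gray = rgb2gray(frame)
    edges = canny(gray, sigma=2.0)
    h, w = gray.shape
    lo = int(min(h, w) * radius_bounds_frac[0])
    hi = int(min(h, w) * radius_bounds_frac[1])
    radii = np.unique(np.linspace(lo, hi, n_radii).astype(int))
    accum = hough_circle(edges, radii)
    _, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    return make_arena((float(cy[0]), float(cx[0])), float(rad[0]), arena_diameter_mm, gray.shape)


def _flat_palette() -> list[int]:
    pal = [0] * 768
    for lab, rgb in LABEL_PALETTE.items():
        pal[3 * int(lab) : 3 * int(lab) + 3] = list(rgb)
    return pal


def write_trinarized(
    label_grids: Sequence[np.ndarray] | Sequence["object"],
    out_dir: str | os.PathLike,
    prefix: str = "trin",
) -> list[Path]:
    """Write trinarized label grids as palette-indexed PNGs.

    The pixel values are the label codes themselves (UNEXPLORED=0, SLIME=1,
    MUCUS=2) so that reading the files back reproduces the label grids
    exactly; the attached palette only controls how viewers display them.
    Files are named ``<prefix>_<index>.png`` with a zero-padded frame index.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pal = _flat_palette()
    width = max(4, len(str(len(label_grids) - 1)))
    paths = []
    for i, grid in enumerate(label_grids):
        arr = np.asarray(getattr(grid, "labels", grid), dtype=np.uint8)
        if arr.ndim != 2 or not np.isin(arr, [0, 1, 2]).all():
            raise ValueError(f"frame {i}: labels must be a 2-D grid of codes 0/1/2")
        img = Image.fromarray(arr, mode="P")
        img.putpalette(pal)
        p = out / f"{prefix}_{i:0{width}d}.png"
        img.save(p)
        paths.append(p)
    return paths


def read_trinarized(paths: Sequence[str | os.PathLike]) -> list[np.ndarray]:
    """Read palette PNGs written by :func:`write_trinarized` back into label grids."""
    grids = []
    for p in paths:
        with Image.open(p) as img:
            if img.mode != "P":
                raise ValueError(f"not a palette-indexed image: {p}")
            grids.append(np.asarray(img, dtype=np.uint8))
    return grids
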