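"""Reading and writing of height images.

Supported formats are single-channel float TIFF, plain whitespace-separated
text matrices (``#`` comment lines allowed), and 8/16-bit grayscale PNG.
Integer inputs are promoted to float without rescaling so the algorithm sees
the recorded scale. Proprietary SPM containers are not parsed; export to
TIFF or text first.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "HeightImage",
    "read_height_image",
    "write_height_image",
    "write_visualization",
]

MIN_SIDE = 8


@dataclass
class HeightImage:
    """A real-valued 2D surface height (or intensity) map.

    Parameters
    ----------
    data : ndarray
        Float matrix of heights, row-major, finite everywhere, at least
        8x8 (smaller grids make the spectral windows and histograms
        degenerate).
    height_unit : str
        Free-text physical unit of the values, e.g. ``"nm"``.
    pixel_size : tuple of float, optional
        Physical length per pixel along (row, col), if known.
    """

    data: np.ndarray
    height_unit: str = ""
    pixel_size: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"height image must be 2D, got shape {arr.shape}")
        if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
            raise ValueError(
                f"height image must be at least {MIN_SIDE}x{MIN_SIDE}, "
                f"got {arr.shape[0]}x{arr.shape[1]}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("height image contains NaN or Inf values")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _infer_format(path: str, format_hint: str | None) -> str:
    if format_hint is not None:
        fmt = format_hint.lower()
        if fmt not in ("tiff", "text", "png"):
            raise ValueError(f"unknown format hint {format_hint!r}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return "tiff"
    if ext in (".txt", ".dat", ".asc", ".mat"):
        return "text"
    if ext == ".png":
        return "png"
    raise ValueError(f"cannot infer image format from {path!r}; pass format_hint")


def _read_text_matrix(path: str) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in stripped.split()])
            except ValueError as exc:
                raise ValueError(f"{path}: unparsable value on line {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: no numeric data")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (row lengths {sorted(widths)})")
    return np.array(rows, dtype=float)


def read_height_image(
    path: str,
    format_hint: str | None = None,
    height_unit: str = "",
) -> HeightImage:
    """Read a single-channel image file into a :class:`HeightImage`.

    Integer pixel formats are promoted to float without rescaling.
    Multi-channel images are rejected.
    """
    fmt = _infer_format(path, format_hint)
    if fmt == "text":
        arr = _read_text_matrix(path)
    elif fmt == "tiff":
        arr = np.asarray(tifffile.imread(path))
    else:  # png
        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, got shape {arr.shape}")
    arr = arr.astype(float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: image contains NaN or Inf values")
    return HeightImage(arr, height_unit=height_unit)


def write_height_image(image: HeightImage, path: str, format: str = "tiff") -> None:
    """Write ``image`` as 32-bit float TIFF or full-precision text.

    Text round-trips exactly; TIFF round-trips to float32 precision.
    """
    fmt = format.lower()
    if fmt not in ("tiff", "text"):
        raise ValueError(f"unknown output format {format!r}")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    if fmt == "tiff":
        tifffile.imwrite(path, image.data.astype(np.float32))
    else:
        header = f"# {image.data.shape[0]} x {image.data.shape[1]}"
        if image.height_unit:
            header += f", unit {image.height_unit}"
        np.savetxt(path, image.data, fmt="%.17g", header=header.lstrip("# "))


def write_visualization(
    image: HeightImage,
    path: str,
    range: tuple[float, float] | None = None,
) -> None:
    """Write a 16-bit grayscale PNG mapping ``[lo, hi]`` linearly to [0, 65535].

    Defaults to the image min/max; values outside the range are clipped.
    A constant image with no explicit range maps to uniform black with a
    warning (the degenerate range ``[v, v+1]`` is substituted).
    """
    data = image.data
    if range is None:
        lo, hi = float(data.min()), float(data.max())
        if lo == hi:
            warnings.warn(
                "constant image with no explicit range; using [v, v+1]",
                stacklevel=2,
            )
            hi = lo + 1.0
    else:
        lo, hi = float(range[0]), float(range[1])
        if not lo < hi:
            raise ValueError(f"range must satisfy lo < hi, got ({lo}, {hi})")
    scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    gray = np.rint(scaled * 65535.0).astype(np.uint16)
    iio.imwrite(path, gray)
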