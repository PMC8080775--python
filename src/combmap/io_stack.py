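"""Reading image-stack recordings and spatial preprocessing.

A recording is a 3-D array of fluorescence intensities indexed
``[row, col, frame]`` together with the frame interval in milliseconds and
an optional boolean validity mask.  Intensities are converted to
double-precision floating point on read regardless of the source bit depth
so that all downstream numerics are uniform.  The frame interval is always
supplied by the caller; any timing metadata embedded in the files is
ignored.

Missing values in all derived 2-D maps are marked with IEEE NaN; the CSV
writer emits them as empty cells.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "Recording",
    "ReadError",
    "FormatError",
    "read_tif_stack",
    "read_image_folder",
    "write_tif_stack",
    "spatial_bin",
    "apply_mask",
    "max_contrast_image",
    "write_map_csv",
    "read_map_csv",
    "write_map_tiff",
]

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


class ReadError(OSError):
    """The input file or folder could not be read."""


class FormatError(ValueError):
    """The input was readable but violates the expected layout."""


@dataclass
class Recording:
    """A fluorescence movie: ``data[row, col, frame]`` plus time base.

    Parameters
    ----------
    data
        3-D float array of intensities, indexed ``[row, col, frame]``.
    frame_interval_ms
        Duration of one frame in milliseconds (> 0).
    mask
        Optional boolean array of shape ``(rows, cols)``; ``True`` marks
        pixels included in analysis.  The mask is carried alongside the
        data, never applied destructively to the intensities.
    """

    data: np.ndarray
    frame_interval_ms: float
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"recording data must be 3-D, got ndim={self.data.ndim}")
        rows, cols, frames = self.data.shape
        if rows < 1 or cols < 1 or frames < 2:
            raise FormatError(
                f"recording needs >=1 row, >=1 col and >=2 frames, got {self.data.shape}"
            )
        if not self.frame_interval_ms > 0:
            raise ValueError("frame_interval_ms must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (rows, cols):
                raise ValueError(
                    f"mask shape {self.mask.shape} != spatial shape {(rows, cols)}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def effective_mask(self) -> np.ndarray:
        """Boolean mask of analyzed pixels (all-true when no mask is set)."""
        if self.mask is None:
            return np.ones(self.data.shape[:2], dtype=bool)
        return self.mask

    def pixel_trace(self, row: int, col: int) -> np.ndarray:
        return self.data[row, col, :]


def read_tif_stack(path: str | os.PathLike, frame_interval_ms: float) -> Recording:
    """Read a multi-page TIFF stack (one page per frame) into a Recording.

    Pages are kept in file order.  8/16-bit unsigned and 32-bit float
    samples are all promoted to float64.
    """
    path = Path(path)
    if not path.is_file():
        raise ReadError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # corrupt/truncated file
        raise ReadError(f"cannot read TIFF stack {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise FormatError(f"{path}: a stack needs >=2 slices, found 1")
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected greyscale pages, got shape {arr.shape}")
    # tifffile gives [frame, row, col]; reorder to [row, col, frame]
    data = np.moveaxis(arr.astype(np.float64), 0, -1)
    return Recording(data=data, frame_interval_ms=frame_interval_ms)


def read_image_folder(path: str | os.PathLike, frame_interval_ms: float) -> Recording:
    """Read a folder of single-frame TIF/PNG/JPG images as a Recording.

    Frames are ordered by lexicographic filename sort, so zero-padded
    frame numbers (``f_000.png`` ...) reproduce acquisition order
    regardless of file timestamps.
    """
    path = Path(path)
    if not path.is_dir():
        raise ReadError(f"no such folder: {path}")
    names = sorted(
        p for p in path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if len(names) < 2:
        raise ReadError(f"{path}: need >=2 image frames, found {len(names)}")
    frames = []
    for p in names:
        try:
            img = iio.imread(p)
        except Exception as exc:
            raise ReadError(f"cannot read frame {p}: {exc}") from exc
        img = np.asarray(img, dtype=np.float64)
        if img.ndim == 3:  # RGB(A) -> luminance by channel mean
            img = img.mean(axis=2)
        frames.append(img)
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"{path}: frames have inconsistent shapes {sorted(shapes)}")
    data = np.stack(frames, axis=-1)
    return Recording(data=data, frame_interval_ms=frame_interval_ms)


def write_tif_stack(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as a multi-page 32-bit float TIFF (one page per frame)."""
    arr = np.moveaxis(rec.data, -1, 0).astype(np.float32)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def spatial_bin(rec: Recording, factor: int) -> Recording:
    """Average ``factor x factor`` pixel blocks in every frame.

    Output spatial dimensions are ``floor(dim / factor)``; trailing rows or
    columns that do not fill a complete block are discarded (no padded,
    partially-averaged edge pixels).  A mask pixel in the output is True
    only if every contributing input pixel is True.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    rows, cols, frames = rec.data.shape
    if factor > rows or factor > cols:
        raise ValueError(
            f"bin factor {factor} exceeds spatial dimensions {(rows, cols)}"
        )
    if factor == 1:
        return Recording(rec.data.copy(), rec.frame_interval_ms,
                         None if rec.mask is None else rec.mask.copy())
    r_out, c_out = rows // factor, cols // factor
    trimmed = rec.data[: r_out * factor, : c_out * factor, :]
    binned = trimmed.reshape(r_out, factor, c_out, factor, frames).mean(axis=(1, 3))
    mask = None
    if rec.mask is not None:
        mt = rec.mask[: r_out * factor, : c_out * factor]
        mask = mt.reshape(r_out, factor, c_out, factor).all(axis=(1, 3))
    return Recording(binned, rec.frame_interval_ms, mask)


def apply_mask(rec: Recording, mask: np.ndarray) -> Recording:
    """Attach a boolean validity mask to a Recording.

    Masked-out (False) pixels are skipped by every downstream per-pixel
    analysis and appear as NaN in all output maps; the raw intensities are
    left untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rec.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} != spatial shape {rec.data.shape[:2]}"
        )
    return Recording(rec.data, rec.frame_interval_ms, mask)


def max_contrast_image(rec: Recording) -> np.ndarray:
    """Per-pixel temporal contrast (max - min), rescaled to span [0, 1].

    Intended for drawing analysis masks: pixels carrying signal light up,
    background stays dark.  The contrast definition is a documented choice
    (range of the trace); if all analyzed pixels have equal contrast the
    rescaling is degenerate and the image is all zeros.  Masked-out pixels
    are NaN.
    """
    contrast = rec.data.max(axis=2) - rec.data.min(axis=2)
    m = rec.effective_mask()
    out = np.full(contrast.shape, np.nan)
    vals = contrast[m]
    if vals.size == 0:
        return out
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo <= 0:
        out[m] = 0.0
        return out
    out[m] = (contrast[m] - lo) / (hi - lo)
    return out


def write_map_csv(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D map as CSV, one row per image row; NaN becomes an empty cell."""
    image = np.asarray(image, dtype=float)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in image:
            writer.writerow(["" if np.isnan(v) else repr(float(v)) for v in row])


def read_map_csv(path: str | os.PathLike) -> np.ndarray:
    """Read a 2-D map written by :func:`write_map_csv` (empty cells -> NaN)."""
    rows = []
    with open(path, newline="") as fh:
        for line in csv.reader(fh):
            rows.append([np.nan if cell == "" else float(cell) for cell in line])
    return np.asarray(rows, dtype=float)


def write_map_tiff(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D map as a single-page 32-bit float TIFF (NaN preserved)."""
    tifffile.imwrite(
        Path(path), np.asarray(image, dtype=np.float32), photometric="minisblack"
    )
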