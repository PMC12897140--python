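"""Reading array scans and writing result tables.

Scans come in as TIFF (recommended: lossless, preserves bit depth) or PNG.
Internally every image is a 2-D float array of non-negative intensities in
which spots are *bright* local maxima on a dark background.  Scans acquired
with dark spots on a light background (e.g. film-developed chemiluminescent
blots) are harmonized with ``invert=True``, which maps every pixel p to
(max - p).

Coordinate convention used throughout the package: 0-based pixel indices,
x = column index increasing rightward, y = row index increasing downward
(raster order of TIFF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import FormatError, MeasurementError

#: smallest scan dimension accepted; anything below this cannot hold a grid
MIN_DIM = 64

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


@dataclass
class ArrayImage:
    """A 2-D intensity matrix with its acquisition metadata.

    Parameters
    ----------
    pixels
        Float array, shape (height, width), all values finite and >= 0.
    bit_depth
        Bits of the source data (8 or 16).
    polarity
        ``"bright_spots"`` after harmonization; ``"dark_spots"`` only as a
        marker on freshly loaded, un-inverted film scans.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    polarity: str = "bright_spots"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("image contains non-finite intensities")
        if self.pixels.min() < 0:
            raise FormatError("image contains negative intensities")
        if self.height < MIN_DIM or self.width < MIN_DIM:
            raise FormatError(
                f"degenerate scan: {self.height}x{self.width} "
                f"(minimum {MIN_DIM}x{MIN_DIM})"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def inverted(self) -> "ArrayImage":
        """Return a copy with polarity flipped: p -> max(p) - p."""
        return ArrayImage(
            self.pixels.max() - self.pixels,
            bit_depth=self.bit_depth,
            polarity="bright_spots",
        )


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    # float TIFFs: infer from dynamic range
    return 16 if np.nanmax(arr, initial=0) > 255 else 8


def read_image(path: str | Path, invert: bool = False) -> ArrayImage:
    """Load a TIFF or PNG scan into an :class:`ArrayImage`.

    RGB inputs are converted to a single channel by an unweighted channel
    mean (array scans are effectively monochrome).  ``invert=True`` flips
    polarity so that spots become bright maxima.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    elif suffix in _PNG_SUFFIXES:
        with Image.open(path) as im:
            arr = np.asarray(im)
    else:
        raise FormatError(
            f"unsupported format {suffix!r}: only lossless TIFF/PNG are accepted"
        )
    if arr.ndim == 3:
        # RGB(A): drop alpha, average color channels
        arr = arr[..., :3].mean(axis=2)
    elif arr.ndim != 2:
        raise FormatError(f"cannot interpret image of shape {arr.shape}")
    depth = _bit_depth_of(np.asarray(arr))
    img = ArrayImage(np.asarray(arr, dtype=float), bit_depth=depth)
    if invert:
        img = img.inverted()
    return img


def write_image(img: ArrayImage, path: str | Path) -> None:
    """Write an image as TIFF (uint of its bit depth) or PNG."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = np.clip(np.rint(img.pixels), 0, 2**img.bit_depth - 1).astype(dtype)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() in _PNG_SUFFIXES:
        Image.fromarray(arr).save(path)
    else:
        raise FormatError(f"unsupported output format: {path.suffix}")


def write_table(table: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Export an intensity or differential table as CSV or XLSX.

    CSV round-trips numeric fields to 12 significant digits; XLSX stores
    numeric cells exactly.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        table.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "xlsx":
        table.to_excel(path, index=False, engine="openpyxl")
    else:
        raise FormatError(f"unsupported table format: {fmt!r} (csv or xlsx)")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        return pd.read_excel(path, engine="openpyxl")
    return pd.read_csv(path)
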