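"""Core raster container shared by every pipeline stage.

An :class:`ImageGrid` couples a 2-D intensity array with the physical size
of one pixel, which is what turns pixel areas into nm^2 and particle counts
into surface densities.  Coordinates are 0-based with ``x`` = column and
``y`` = row, origin at the top-left corner; sub-pixel positions are real
numbers in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ImageGrid"]


@dataclass
class ImageGrid:
    """A single-channel intensity raster with a physical pixel size.

    Parameters
    ----------
    values : numpy.ndarray
        2-D array of finite, non-negative intensities.  Integer dtypes
        (8/16-bit acquisitions) and floats (filtered intermediates) are
        both accepted.
    pixel_size_nm : float
        Edge length of one pixel in nanometres (0.83 nm for the dark-field
        STEM acquisition geometry this package models).
    """

    values: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(
                f"image must be a 2-D single-channel raster, got ndim={self.values.ndim}"
            )
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not np.issubdtype(self.values.dtype, np.number):
            raise ValueError(f"image dtype must be numeric, got {self.values.dtype}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("image contains non-finite values")
        if float(self.pixel_size_nm) <= 0:
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        self.pixel_size_nm = float(self.pixel_size_nm)

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, columns) of the raster."""
        return self.values.shape  # type: ignore[return-value]

    @property
    def area_um2(self) -> float:
        """Physical area of the full frame in square micrometres."""
        ny, nx = self.values.shape
        return ny * nx * (self.pixel_size_nm / 1000.0) ** 2

    def astype_float(self) -> "ImageGrid":
        """Return a float64 copy (filtering stages work in floating point)."""
        return ImageGrid(self.values.astype(np.float64), self.pixel_size_nm)
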