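"""Square pixel grids with physical spacing.

Coordinate convention used throughout the package: the physical origin is
at the grid centre, x points rightward, y points upward, and row 0 is the
top row of the array.  A pixel at (row r, column c) of an n x n grid with
pixel size h therefore has its centre at

    x = (c + 0.5 - n / 2) * h,      y = (n / 2 - r - 0.5) * h.

Pixel values are linear-attenuation-like densities (water ~ 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid"]


@dataclass(frozen=True)
class ImageGrid:
    """An n x n image with square pixels of physical size ``pixel_size`` cm.

    ``values`` is stored as a 2-D array (row-major, row 0 at the top); the
    flattened row-major view is the vector f of the imaging model.
    """

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"image must be square 2-D, got shape {values.shape}")
        if values.shape[0] < 1:
            raise ValueError("image must have at least one pixel")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        """Side length in pixels."""
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.size

    @property
    def half_extent(self) -> float:
        """Half the physical side length of the grid bounding box, in cm."""
        return 0.5 * self.n * self.pixel_size

    def as_vector(self) -> np.ndarray:
        """Row-major flattening (the vector f of the linear model)."""
        return self.values.ravel()

    def with_values(self, values: np.ndarray) -> "ImageGrid":
        """A new grid with the same spacing and new pixel values."""
        values = np.asarray(values)
        if values.size == self.n_pixels and values.ndim == 1:
            values = values.reshape(self.values.shape)
        return ImageGrid(values, self.pixel_size)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) physical coordinates of all pixel centres, shape (n, n)."""
        n, h = self.n, self.pixel_size
        c = (np.arange(n) + 0.5 - n / 2) * h
        x = np.broadcast_to(c[None, :], (n, n))
        y = np.broadcast_to(-c[:, None], (n, n))
        return x, y
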