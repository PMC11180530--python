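"""Parallel-beam acquisition geometry and the basic array containers.

World coordinates are centered on the rotation axis.  A view with angle
``theta`` has its detector axis along ``u = (cos theta, sin theta)`` and its
rays travel along ``d = (-sin theta, cos theta)``; the detector offset ``s``
of bin ``k`` is ``(k - (n_bins - 1) / 2) * bin_spacing``, so the detector
array is symmetric about the rotation axis.  Pixel ``(row i, col j)`` of the
square image grid has its center at world
``x = (j - (n - 1) / 2) * pixel_size``, ``y = ((n - 1) / 2 - i) * pixel_size``
(row 0 is the top of the image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParallelGeometry", "Sinogram", "Image2D", "make_geometry"]


@dataclass(frozen=True)
class ParallelGeometry:
    """Parallel-beam scan description: view angles, detector and image grid.

    Parameters
    ----------
    angles
        Strictly increasing view angles in radians, all in ``[0, pi)``.
    n_bins
        Number of detector bins per view.
    image_size
        Pixels per side of the square reconstruction grid.
    bin_spacing, pixel_size
        Detector pitch and pixel side in world units (both default to 1).
    """

    angles: np.ndarray
    n_bins: int
    image_size: int
    bin_spacing: float = 1.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if angles[0] < 0 or angles[-1] >= np.pi:
            raise ValueError("angles must lie in [0, pi)")
        if self.n_bins < 1 or self.image_size < 1:
            raise ValueError("n_bins and image_size must be >= 1")
        if self.bin_spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("bin_spacing and pixel_size must be > 0")
        object.__setattr__(self, "angles", angles)

    @property
    def n_views(self) -> int:
        return len(self.angles)

    @property
    def bin_offsets(self) -> np.ndarray:
        """World offsets of bin centers along the detector axis (sym. about 0)."""
        k = np.arange(self.n_bins, dtype=float)
        return (k - (self.n_bins - 1) / 2.0) * self.bin_spacing

    @property
    def field_of_view(self) -> float:
        """Side length of the image grid in world units."""
        return self.image_size * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World ``(x, y)`` coordinate grids of the pixel centers."""
        n = self.image_size
        c = (n - 1) / 2.0
        j = np.arange(n, dtype=float)
        x = (j - c) * self.pixel_size
        y = (c - j) * self.pixel_size
        return np.meshgrid(x, y, indexing="xy")


def make_geometry(n_views: int, n_bins: int, image_size: int) -> ParallelGeometry:
    """Uniform half-circle geometry: angles ``k * pi / n_views``, unit pitch.

    The reference configuration is ``make_geometry(8, 256, 256)``: eight views
    over 180 degrees starting at 0, with 256 detector bins matching a
    256 x 256 pixel grid at one world unit per pixel and per bin.
    """
    if n_views < 1 or n_bins < 1 or image_size < 1:
        raise ValueError("n_views, n_bins and image_size must all be >= 1")
    angles = np.arange(n_views, dtype=float) * (np.pi / n_views)
    return ParallelGeometry(angles=angles, n_bins=n_bins, image_size=image_size)


@dataclass
class Sinogram:
    """Line-integral measurements, one row per view, one column per bin."""

    data: np.ndarray
    geometry: ParallelGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        expected = (self.geometry.n_views, self.geometry.n_bins)
        if data.shape != expected:
            raise ValueError(
                f"sinogram shape {data.shape} does not match geometry {expected}"
            )
        self.data = data

    def copy(self) -> "Sinogram":
        return Sinogram(self.data.copy(), self.geometry)


@dataclass
class Image2D:
    """Square attenuation map on the reconstruction grid."""

    data: np.ndarray
    geometry: ParallelGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        n = self.geometry.image_size
        if data.shape != (n, n):
            raise ValueError(f"image shape {data.shape} does not match grid {(n, n)}")
        self.data = data

    def copy(self) -> "Image2D":
        return Image2D(self.data.copy(), self.geometry)
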