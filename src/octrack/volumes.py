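"""Grid containers shared across the pipeline.

All volumes follow the ``(z, y, x)`` axis convention with 0-based indices:
the slice index is ``z`` and the physical coordinate of a voxel center is
``index * spacing``. Spacing is ``(dz, dy, dx)`` in micrometers per voxel;
the default matches a spectral-domain OCT acquisition with 2.52 um
transverse step and 2.68 um axial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

Spacing = Tuple[float, float, float]

#: (dz, dy, dx) in um/voxel for the reference OCT geometry.
DEFAULT_SPACING: Spacing = (2.68, 2.52, 2.52)

AXIS_NAMES = {"z": 0, "y": 1, "x": 2}


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class RawVolume:
    """A 3-D scalar intensity grid with physical voxel spacing.

    Intensities are either integer counts (16-bit range, as acquired) or
    unit-interval reals (inside the preprocessing chain). They must be
    finite and non-negative.
    """

    data: np.ndarray
    spacing: Spacing = DEFAULT_SPACING
    timepoint_day: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3-D array, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray) -> "RawVolume":
        """Same geometry and timepoint, different intensities."""
        return RawVolume(data, self.spacing, self.timepoint_day)


@dataclass
class LabelVolume:
    """A 3-D grid of organoid instance labels sharing a RawVolume's geometry.

    Label 0 is background; positive labels need not be consecutive.
    """

    labels: np.ndarray
    spacing: Spacing = DEFAULT_SPACING
    timepoint_day: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def positive_labels(self) -> np.ndarray:
        """Sorted array of the labels present, excluding background."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class BinaryVolume:
    """A 3-D boolean organoid/background mask with the source geometry."""

    mask: np.ndarray
    spacing: Spacing = DEFAULT_SPACING
    timepoint_day: Optional[int] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.mask.shape}")
        if self.mask.dtype != bool:
            self.mask = self.mask != 0
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mask.shape
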