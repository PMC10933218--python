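"""In-memory imaging containers.

Arrays use (z, y, x) index order with z the craniocaudal scanner axis:
slice index 0 is the most caudal slice and the physical position of
slice ``i`` spans ``[i*t, (i+1)*t)`` mm, ``t`` being the z spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing!r}")
    return spacing


@dataclass
class CTVolume:
    """A 3-D CT intensity grid in Hounsfield units.

    Parameters
    ----------
    data
        Array of shape (z, y, x) holding HU values.
    spacing
        Voxel spacing in mm per axis, ordered (z, y, x).
    """

    data: np.ndarray
    spacing: Spacing = (3.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume expects a 3-D array, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[0]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[1] * self.spacing[2]

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx


@dataclass
class LabelMask:
    """A binary 3-D mask aligned to a :class:`CTVolume` grid."""

    data: np.ndarray
    spacing: Spacing = (3.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMask expects a 3-D array, got ndim={self.data.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[1] * self.spacing[2]

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[0]

    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "LabelMask | CTVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)
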