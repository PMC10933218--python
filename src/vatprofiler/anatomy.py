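"""Vertebral landmarks, representative slice selection, and lumbar height.

Analysis slices are anchored to the lumbar spine: a fixed number of
evenly spaced slices per lumbar vertebra (L1..L5) plus a block of pelvic
slices between the inferior endplate of L5 and the pubic symphysis. With
the defaults (5 per vertebra, 10 pelvic) this yields the 35 representative
levels labelled ``L1-1`` .. ``L5-5`` and ``Pelvis-1`` .. ``Pelvis-10``.

Landmark convention
-------------------
``LandmarkTable`` stores seven craniocaudal positions (mm, z increasing
toward the head):

* ``L1-1`` .. ``L5-1`` — the superior boundary of each lumbar vertebra
  (vertebrae are treated as contiguous, so ``L2-1`` is also the inferior
  boundary of L1);
* ``L5-5`` — the inferior boundary of L5;
* ``pubic_symphysis`` — the caudal end of the analysis range.

The lumbar height used to standardize fat areas is the vertical distance
between ``L1-1`` and ``L5-5``, in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VERTEBRAE = ("L1", "L2", "L3", "L4", "L5")
SUPERIOR_LABELS = tuple(f"{v}-1" for v in VERTEBRAE)
REQUIRED_LABELS = SUPERIOR_LABELS + ("L5-5", "pubic_symphysis")


@dataclass
class LandmarkTable:
    """Craniocaudal landmark positions keyed by level label."""

    positions: dict[str, float]

    def __post_init__(self) -> None:
        self.positions = {str(k): float(v) for k, v in self.positions.items()}
        missing = [lab for lab in REQUIRED_LABELS if lab not in self.positions]
        if missing:
            raise ValueError(f"missing landmark(s): {missing}")
        z = [self.positions[lab] for lab in REQUIRED_LABELS]
        if not all(a > b for a, b in zip(z, z[1:])):
            raise ValueError(
                "landmark z-positions must strictly decrease from L1-1 through "
                f"L5-5 to the pubic symphysis, got {dict(zip(REQUIRED_LABELS, z))}"
            )

    def __getitem__(self, label: str) -> float:
        try:
            return self.positions[label]
        except KeyError:
            raise KeyError(f"landmark {label!r} not present") from None

    def vertebra_span(self, vertebra: str) -> tuple[float, float]:
        """Return (inferior_z, superior_z) of one lumbar vertebra in mm."""
        if vertebra not in VERTEBRAE:
            raise ValueError(f"unknown vertebra {vertebra!r}")
        sup = self.positions[f"{vertebra}-1"]
        idx = VERTEBRAE.index(vertebra)
        inf_label = "L5-5" if vertebra == "L5" else f"{VERTEBRAE[idx + 1]}-1"
        return self.positions[inf_label], sup

    def translated(self, dz_mm: float) -> "LandmarkTable":
        return LandmarkTable({k: v + dz_mm for k, v in self.positions.items()})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level_label": list(self.positions), "z_mm": list(self.positions.values())}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkTable":
        df = pd.read_csv(path, comment="#")
        for col in ("level_label", "z_mm"):
            if col not in df.columns:
                raise ValueError(f"landmark CSV missing required column {col!r}")
        if df["level_label"].duplicated().any():
            raise ValueError("duplicate level labels in landmark CSV")
        return cls(dict(zip(df["level_label"], df["z_mm"])))


@dataclass
class SliceRef:
    level_label: str
    slice_index: int
    z_mm: float
    thickness_mm: float
    lumbar: bool


@dataclass
class SlicePlan:
    """Ordered representative slices, cranial to caudal."""

    slices: list[SliceRef] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    @property
    def lumbar_slices(self) -> list[SliceRef]:
        return [s for s in self.slices if s.lumbar]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_label": [s.level_label for s in self.slices],
                "slice_index": [s.slice_index for s in self.slices],
                "z_mm": [s.z_mm for s in self.slices],
                "thickness_mm": [s.thickness_mm for s in self.slices],
                "lumbar": [s.lumbar for s in self.slices],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _nearest_slice_index(z_mm: float, thickness_mm: float) -> int:
    # slice i spans [i*t, (i+1)*t); equidistant ties go to the cranial
    # (higher-index) slice, which floor() delivers directly
    return int(np.floor(z_mm / thickness_mm))


def select_slices(
    landmarks: LandmarkTable,
    spacing_mm: float,
    n_per_vertebra: int = 5,
    n_pelvic: int = 10,
    n_slices: int | None = None,
) -> SlicePlan:
    """Build the representative slice plan from vertebral landmarks.

    Within each region, slice positions sit at the midpoints of
    ``n`` equal subdivisions of the span, so ``n_per_vertebra=1`` places a
    single slice at the vertebral midpoint. Positions are snapped to the
    nearest acquired slice index given the z spacing.

    Parameters
    ----------
    landmarks
        Vertebral boundary positions.
    spacing_mm
        Slice thickness / z spacing of the acquired volume, mm.
    n_per_vertebra, n_pelvic
        Slices per lumbar vertebra and in the L5-to-pubic-symphysis block.
    n_slices
        If given, the number of acquired slices; plan indices outside
        ``[0, n_slices)`` raise ``ValueError``.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if n_per_vertebra < 0 or n_pelvic < 0:
        raise ValueError("slice counts must be non-negative")

    refs: list[SliceRef] = []
    for vert in VERTEBRAE:
        inf, sup = landmarks.vertebra_span(vert)
        span = sup - inf
        for j in range(1, n_per_vertebra + 1):
            z = sup - (j - 0.5) * span / n_per_vertebra
            refs.append(
                SliceRef(
                    level_label=f"{vert}-{j}",
                    slice_index=_nearest_slice_index(z, spacing_mm),
                    z_mm=z,
                    thickness_mm=spacing_mm,
                    lumbar=True,
                )
            )
    if n_pelvic:
        sup = landmarks["L5-5"]
        inf = landmarks["pubic_symphysis"]
        span = sup - inf
        for j in range(1, n_pelvic + 1):
            z = sup - (j - 0.5) * span / n_pelvic
            refs.append(
                SliceRef(
                    level_label=f"Pelvis-{j}",
                    slice_index=_nearest_slice_index(z, spacing_mm),
                    z_mm=z,
                    thickness_mm=spacing_mm,
                    lumbar=False,
                )
            )

    if n_slices is not None:
        bad = [r for r in refs if not 0 <= r.slice_index < n_slices]
        if bad:
            raise ValueError(
                f"landmarks place {len(bad)} slice(s) outside the volume "
                f"(first: {bad[0].level_label} at index {bad[0].slice_index}, "
                f"volume has {n_slices} slices)"
            )
    return SlicePlan(refs)


def lumbar_height(landmarks: LandmarkTable) -> float:
    """Vertical height between L1-1 and L5-5 in meters."""
    h = abs(landmarks["L1-1"] - landmarks["L5-5"]) / 1000.0
    if h <= 0:
        raise ValueError("lumbar height must be strictly positive")
    return h
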