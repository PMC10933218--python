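"""Visceral fat indicators: VFA, volume, VAI, VAT ratio, lumbar statistics.

All areas are cm², volumes cm³, heights m, thicknesses mm. The
distribution indicators reflect *where* fat sits along the spine rather
than how much there is:

* VAI — visceral adipose index, the per-slice fat area standardized by
  the squared lumbar height (cm²/m²);
* VAT ratio — the share of total visceral fat volume contributed by one
  slice, (VFA × thickness)/volume × 100%;
* lumbar mean/SD/CV — moments of per-slice fat areas over every acquired
  slice between L1-1 and L5-5, the CV (SD/mean × 100) being the
  distribution-heterogeneity biomarker;
* cv_35 — the same CV restricted to the 35 representative plan slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anatomy import LandmarkTable, SlicePlan, lumbar_height as _lumbar_height
from .core import LabelMask


class DistributionStats(NamedTuple):
    mean: float
    sd: float
    cv: float  # percent; NaN when the mean is zero


@dataclass
class SliceMeasurement:
    level_label: str
    slice_index: int
    vfa_cm2: float
    thickness_mm: float
    vai_cm2_m2: float
    vat_ratio_pct: float


@dataclass
class SubjectMetrics:
    """Full indicator set for one subject's VAT mask."""

    vat_volume_cm3: float
    lumbar_mean_cm2: float
    lumbar_sd_cm2: float
    lumbar_cv_pct: float
    cv_35_pct: float
    lumbar_height_m: float
    slices: list[SliceMeasurement] = field(default_factory=list)

    def slice_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_label": [s.level_label for s in self.slices],
                "slice_index": [s.slice_index for s in self.slices],
                "vfa_cm2": [s.vfa_cm2 for s in self.slices],
                "thickness_mm": [s.thickness_mm for s in self.slices],
                "vai_cm2_m2": [s.vai_cm2_m2 for s in self.slices],
                "vat_ratio_pct": [s.vat_ratio_pct for s in self.slices],
            }
        )

    def summary_row(self) -> dict[str, float]:
        return {
            "vat_volume_cm3": self.vat_volume_cm3,
            "lumbar_mean_cm2": self.lumbar_mean_cm2,
            "lumbar_sd_cm2": self.lumbar_sd_cm2,
            "lumbar_cv_pct": self.lumbar_cv_pct,
            "cv_35_pct": self.cv_35_pct,
            "lumbar_height_m": self.lumbar_height_m,
        }


def vfa(mask_slice: np.ndarray, pixel_area_mm2: float) -> float:
    """Fat area of one axial mask slice in cm²."""
    mask_slice = np.asarray(mask_slice).astype(bool)
    if mask_slice.ndim != 2:
        raise ValueError("vfa expects a 2-D slice")
    return float(mask_slice.sum()) * pixel_area_mm2 / 100.0


def vat_volume(mask: LabelMask | np.ndarray, voxel_volume_mm3: float | None = None) -> float:
    """Total mask volume in cm³ (voxel count × voxel volume)."""
    if isinstance(mask, LabelMask):
        voxel_volume_mm3 = mask.voxel_volume_mm3
        data = mask.data
    else:
        if voxel_volume_mm3 is None:
            raise ValueError("voxel_volume_mm3 required for a bare array")
        data = np.asarray(mask).astype(bool)
    return float(data.sum()) * voxel_volume_mm3 / 1000.0


def vai(vfa_cm2: float, lumbar_height_m: float) -> float:
    """Visceral adipose index, VFA / lumbar height² (cm²/m²)."""
    if lumbar_height_m <= 0:
        raise ValueError("lumbar height must be positive")
    return vfa_cm2 / lumbar_height_m**2


def vat_ratio(vfa_cm2: float, thickness_mm: float, volume_cm3: float) -> float:
    """One slice's percentage share of total VAT volume."""
    if volume_cm3 <= 0:
        raise ValueError("VAT volume must be positive")
    return (vfa_cm2 * thickness_mm / 10.0) / volume_cm3 * 100.0


def distribution_stats(areas: Sequence[float]) -> DistributionStats:
    """Arithmetic mean, sample SD (n−1), and CV (%) of per-slice areas.

    The CV is undefined (NaN) when the mean is zero.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < 2:
        raise ValueError("need at least two areas")
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1))
    cv = sd / mean * 100.0 if mean > 0 else float("nan")
    return DistributionStats(mean, sd, cv)


def inter_subject_cv(level_vfas: Sequence[float]) -> float:
    """Sample CV (%) of one anatomical level's VFA across subjects."""
    return distribution_stats(level_vfas).cv


def level_volume_correlation(
    level_vfas: Sequence[float],
    volumes: Sequence[float],
    method: str = "pearson",
) -> float:
    """Correlation between per-subject VFA at one level and VAT volume."""
    x = np.asarray(level_vfas, dtype=float)
    y = np.asarray(volumes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired observations required")
    if x.size < 3:
        raise ValueError("need at least three subjects")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def subject_metrics(
    vat_mask: LabelMask,
    landmarks: LandmarkTable,
    plan: SlicePlan,
) -> SubjectMetrics:
    """Compute the full indicator set for one subject.

    The lumbar mean/SD/CV use every acquired slice whose centre lies
    between L1-1 and L5-5; ``cv_35`` uses the representative plan
    slices only.
    """
    area = vat_mask.pixel_area_mm2
    t = vat_mask.slice_thickness_mm
    per_slice = vat_mask.data.reshape(vat_mask.shape[0], -1).sum(axis=1) * area / 100.0
    volume = vat_volume(vat_mask)
    height = _lumbar_height(landmarks)

    centers = (np.arange(vat_mask.shape[0]) + 0.5) * t
    in_lumbar = (centers >= landmarks["L5-5"]) & (centers <= landmarks["L1-1"])
    if in_lumbar.sum() < 2:
        raise ValueError("fewer than two acquired slices inside the lumbar range")
    lum = distribution_stats(per_slice[in_lumbar])

    measurements = []
    for ref in plan:
        if not 0 <= ref.slice_index < vat_mask.shape[0]:
            raise ValueError(f"plan slice {ref.level_label} outside the volume")
        a = float(per_slice[ref.slice_index])
        measurements.append(
            SliceMeasurement(
                level_label=ref.level_label,
                slice_index=ref.slice_index,
                vfa_cm2=a,
                thickness_mm=ref.thickness_mm,
                vai_cm2_m2=vai(a, height),
                vat_ratio_pct=vat_ratio(a, ref.thickness_mm, volume) if volume > 0 else float("nan"),
            )
        )
    plan_areas = [m.vfa_cm2 for m in measurements]
    cv35 = distribution_stats(plan_areas).cv if len(plan_areas) >= 2 else float("nan")

    return SubjectMetrics(
        vat_volume_cm3=volume,
        lumbar_mean_cm2=lum.mean,
        lumbar_sd_cm2=lum.sd,
        lumbar_cv_pct=lum.cv,
        cv_35_pct=cv35,
        lumbar_height_m=height,
        slices=measurements,
    )
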