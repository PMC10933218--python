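"""Rule-based fat segmentation and overlap scoring.

The semi-automatic quantification this package emulates reduces to three
deterministic steps on a calibrated HU volume: threshold the fat window,
delineate the body against the air background, and split fat into the
subcutaneous rim (connected to the body boundary shell) versus the
visceral remainder inside the cavity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume, LabelMask

logger = logging.getLogger(__name__)

#: 26-connectivity structuring element for 3-D morphology and labelling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

#: HU below which a voxel is considered air for body delineation
BODY_THRESHOLD_HU = -500.0


@dataclass(frozen=True)
class FatWindow:
    """Inclusive HU window classifying adipose tissue.

    The default [−190, −30] HU is the de-facto standard body-composition
    window for fat on non-contrast-calibrated CT.
    """

    low: float = -190.0
    high: float = -30.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"fat window needs low < high, got [{self.low}, {self.high}]")
        if not (-1024 <= self.low and self.high <= 1024):
            raise ValueError("fat window must lie within [-1024, 1024] HU")


@dataclass(frozen=True)
class OverlapScores:
    """Dice and Jaccard agreement between two masks."""

    dice: float
    jaccard: float

    def __post_init__(self) -> None:
        if not (0 <= self.jaccard <= self.dice <= 1):
            raise ValueError(f"invalid overlap scores dice={self.dice}, jaccard={self.jaccard}")


def threshold_fat(volume: CTVolume, window: FatWindow = FatWindow()) -> LabelMask:
    """Mark every voxel whose HU lies inside the (inclusive) fat window."""
    data = volume.data
    if data.min() < -2000 or data.max() > 4000:
        logger.warning(
            "intensities span [%.0f, %.0f]; input may not be HU-scaled",
            data.min(),
            data.max(),
        )
    return LabelMask((data >= window.low) & (data <= window.high), volume.spacing)


def body_mask(volume: CTVolume) -> LabelMask:
    """Largest connected non-air component after hole filling.

    Voxels above −500 HU are body candidates; interior holes (bowel gas,
    fat that dips under the threshold) are filled before keeping the
    largest 26-connected component.
    """
    candidates = volume.data > BODY_THRESHOLD_HU
    if not candidates.any():
        raise ValueError("no body found: volume contains only air")
    filled = ndimage.binary_fill_holes(candidates)
    labels, n = ndimage.label(filled, structure=_STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        filled = labels == counts.argmax()
    return LabelMask(filled, volume.spacing)


def separate_compartments(
    fat: LabelMask,
    body: LabelMask,
    shell_thickness: int = 2,
) -> tuple[LabelMask, LabelMask]:
    """Partition fat into visceral and subcutaneous compartments.

    The body boundary shell is the ``shell_thickness``-voxel rim the body
    loses under morphological erosion. Every 26-connected fat component
    touching that shell is subcutaneous; the rest is visceral. A
    component bridging shell and cavity therefore resolves to SAT, which
    keeps the rule deterministic and traversal-order independent.

    Returns ``(vat, sat)`` with ``vat ∪ sat = fat`` and ``vat ∩ sat = ∅``.
    """
    if fat.shape != body.shape:
        raise ValueError(f"shape mismatch: fat {fat.shape} vs body {body.shape}")
    if np.any(fat.data & ~body.data):
        raise ValueError("fat mask extends outside the body mask")
    if shell_thickness < 1:
        raise ValueError("shell thickness must be >= 1 voxel")

    # border_value=1 keeps the z faces of a body spanning the whole stack
    # from being counted as boundary shell
    eroded = ndimage.binary_erosion(
        body.data, structure=_STRUCT_26, iterations=shell_thickness, border_value=1
    )
    shell = body.data & ~eroded

    labels, n = ndimage.label(fat.data, structure=_STRUCT_26)
    if n == 0:
        empty = np.zeros(fat.shape, dtype=bool)
        return LabelMask(empty, fat.spacing), LabelMask(empty.copy(), fat.spacing)
    touching = np.unique(labels[shell & fat.data])
    is_sat = np.zeros(n + 1, dtype=bool)
    is_sat[touching[touching > 0]] = True
    sat = is_sat[labels]
    vat = fat.data & ~sat
    return LabelMask(vat, fat.spacing), LabelMask(sat, fat.spacing)


def overlap_scores(a: LabelMask, b: LabelMask) -> OverlapScores:
    """Dice and Jaccard between two aligned masks.

    Two empty masks agree perfectly (both scores 1); an empty versus a
    non-empty mask scores 0.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return OverlapScores(1.0, 1.0)
    inter = int((a.data & b.data).sum())
    dice = 2 * inter / (na + nb)
    jaccard = inter / (na + nb - inter)
    return OverlapScores(dice, jaccard)
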