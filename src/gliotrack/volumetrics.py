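"""Tumor volumes and Dice agreement from binary segmentation masks.

A segmentation is a 3-D binary voxel array plus its physical voxel spacing in
mm.  Volume is voxel count times voxel volume.  Agreement between two
segmentations of the same image grid is the Dice–Sørensen coefficient
``2|A∩B| / (|A| + |B|)``; cohort-level agreement reports (AI vs gold
standard, inter-user, intra-user) average Dice over mask pairs, taking a
designated reviewer — by convention the first listed — as the gold standard,
and express variability as ``1 - mean Dice``.

Masks are compared strictly voxelwise: reviewers edit the same image grid, so
matching shape and spacing is a precondition, not something this module fixes
by registration or resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationMask",
    "DiceReport",
    "mask_volume",
    "dice",
    "agreement_report",
    "load_nifti_mask",
]


@dataclass(frozen=True)
class SegmentationMask:
    """3-D binary mask (1 = tumor) with voxel spacing in mm per axis."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    frame_id: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3-D, got {vox.ndim}-D")
        if not np.isin(vox, (0, 1)).all():
            bad = np.unique(vox[~np.isin(vox, (0, 1))])
            raise ValueError(f"mask voxels must be binary (0/1); found values {bad[:5]}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths in mm, got {self.spacing}")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def comparable_with(self, other: "SegmentationMask") -> bool:
        return self.voxels.shape == other.voxels.shape and self.spacing == other.spacing


@dataclass
class DiceReport:
    """Pairwise Dice scores, their mean, and variability = 1 - mean.

    Scores are fractions in [0, 1] unless the report was requested in
    percent, in which case all three fields share the percent scale.
    """

    pair_scores: list[tuple[str, float]]
    mean_score: float
    variability: float
    scale: str = "fraction"


def mask_volume(mask: SegmentationMask) -> float:
    """Tumor volume in mm^3: (number of 1-voxels) x (voxel volume)."""
    return float(mask.voxels.sum()) * mask.voxel_volume_mm3


def _check_comparable(a: SegmentationMask, b: SegmentationMask) -> None:
    if a.voxels.shape != b.voxels.shape:
        raise ValueError(f"mask shapes differ: {a.voxels.shape} vs {b.voxels.shape}")
    if a.spacing != b.spacing:
        raise ValueError(f"mask spacings differ: {a.spacing} vs {b.spacing}")


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Dice–Sørensen overlap 2|A∩B| / (|A| + |B|) of two comparable masks.

    Two empty masks score 1.0 (perfect agreement on an empty finding).
    """
    _check_comparable(a, b)
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def agreement_report(
    mask_sets: Iterable[Sequence[SegmentationMask]],
    percent: bool = False,
) -> DiceReport:
    """Average Dice agreement across groups of comparable masks.

    Each group holds segmentations of one scan; the first-listed mask is the
    gold standard and every other member of the group is scored against it.
    The mean is taken over all pairs of all groups and variability is
    ``1 - mean`` on the same scale.  Groups with fewer than two masks are
    skipped with a warning.
    """
    pairs: list[tuple[str, float]] = []
    for g, group in enumerate(mask_sets):
        group = list(group)
        if len(group) < 2:
            logger.warning("agreement_report: group %d has %d mask(s); skipped", g, len(group))
            continue
        gold = group[0]
        for other in group[1:]:
            pair_id = f"{gold.frame_id or g}|{other.frame_id or '?'}"
            pairs.append((pair_id, dice(gold, other)))
    if not pairs:
        raise ValueError("no group contained two or more masks")
    mean = float(np.mean([s for _, s in pairs]))
    if percent:
        pairs = [(pid, 100.0 * s) for pid, s in pairs]
        return DiceReport(pairs, 100.0 * mean, 100.0 * (1.0 - mean), scale="percent")
    return DiceReport(pairs, mean, 1.0 - mean, scale="fraction")


def load_nifti_mask(path: str, frame_id: str | None = None) -> SegmentationMask:
    """Read a binary mask from NIfTI, taking spacing from the header zooms.

    Any nonzero voxel is binarized to 1; the number of non-binary input
    voxels is logged.
    """
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    nonbinary = int(np.sum(~np.isin(data, (0, 1))))
    if nonbinary:
        logger.info("%s: binarized %d non-binary voxels to 1", path, nonbinary)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SegmentationMask(
        voxels=(data != 0).astype(np.uint8),
        spacing=spacing,
        frame_id=frame_id if frame_id is not None else str(path),
    )
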