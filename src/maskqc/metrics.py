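"""Evaluation harness: Dice, 95th-percentile Hausdorff distance, sanity
labels, and confusion-matrix summaries of QC verdicts.

The sanity set is the collection of candidate masks known to be faulty
relative to their ground truth — Dice < 0.95 or HD95 > 15 mm — and serves as
the expected-fail labels when measuring sensitivity/specificity of the QC
verdicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError, GridMismatchError, InsufficientDataError
from .mask import BrainMask

__all__ = [
    "EvalRecord",
    "ConfusionSummary",
    "surface_voxels",
    "dice",
    "hd95",
    "sanity_label",
    "outcome_label",
    "confusion_summary",
    "pass_rate_table",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _check_grid(a: BrainMask, b: BrainMask) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise GridMismatchError(
            f"grid mismatch: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )


def surface_voxels(vox: np.ndarray) -> np.ndarray:
    """Boolean map of foreground voxels with ≥ 1 face-adjacent background
    neighbor; outside the volume counts as background."""
    eroded = ndimage.binary_erosion(vox, structure=_FACE_STRUCT, border_value=0)
    return vox & ~eroded


def dice(a: BrainMask, b: BrainMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|). Two empty masks agree perfectly (1);
    one empty mask scores 0."""
    _check_grid(a, b)
    na, nb = a.foreground_count, b.foreground_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def _directed_hd95(src: np.ndarray, tree: cKDTree) -> float:
    dists, _ = tree.query(src, k=1)
    return float(np.percentile(dists, 95.0))  # linear interpolation


def hd95(a: BrainMask, b: BrainMask) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask surfaces, mm.

    Each direction takes the 95th percentile (linear interpolation) of the
    distances from every surface voxel of one mask to the nearest surface
    voxel of the other; the result is the max of the two directions.
    """
    _check_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise EmptyMaskError("hd95 requires two non-empty masks")
    spacing = np.asarray(a.spacing)
    pts_a = np.argwhere(surface_voxels(a.voxels)) * spacing
    pts_b = np.argwhere(surface_voxels(b.voxels)) * spacing
    tree_a, tree_b = cKDTree(pts_a), cKDTree(pts_b)
    return max(_directed_hd95(pts_a, tree_b), _directed_hd95(pts_b, tree_a))


def sanity_label(
    dice_value: float, hd95_value: float, dice_thresh: float = 0.95, hd_thresh: float = 15.0
) -> bool:
    """True (expected to fail QC) iff Dice < 0.95 or HD95 > 15 mm.

    Both inequalities are strict, so a mask sitting exactly on either
    threshold is still considered acceptable.
    """
    return dice_value < dice_thresh or hd95_value > hd_thresh


def outcome_label(sanity_positive: bool, verdict: str) -> str:
    """TP/FP/TN/FN of one QC verdict against the sanity label.

    Positives are expected to *fail* QC, so a flagged faulty mask is a TP.
    """
    failed = verdict == "fail"
    if sanity_positive:
        return "TP" if failed else "FN"
    return "FP" if failed else "TN"


@dataclass(frozen=True)
class EvalRecord:
    """Dice, HD95, sanity label and QC verdict for one (ground-truth, candidate) pair."""

    mask_id: str
    dice: float
    hd95: float
    sanity_positive: bool
    verdict: str

    @property
    def outcome(self) -> str:
        return outcome_label(self.sanity_positive, self.verdict)


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts plus the four classification ratios; undefined ratios are NaN."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
        }


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_summary(records: Sequence[EvalRecord]) -> ConfusionSummary:
    """Aggregate TP/FP/TN/FN counts and ratios over evaluation records."""
    if len(records) == 0:
        raise InsufficientDataError("no evaluation records to summarize")
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for rec in records:
        counts[rec.outcome] += 1
    tp, fp, tn, fn = counts["TP"], counts["FP"], counts["TN"], counts["FN"]
    return ConfusionSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
        precision=_safe_ratio(tp, tp + fp),
        accuracy=_safe_ratio(tp + tn, tp + fp + tn + fn),
    )


def pass_rate_table(scores_by_group: Mapping) -> pd.Series:
    """Fraction of masks with verdict "pass" per group.

    ``scores_by_group`` maps a group key (e.g. a (method, modality) tuple) to
    a sequence of QCScore-like objects exposing ``verdict``. Scores carrying
    an error count as not passing.
    """
    rates = {}
    for group, scores in scores_by_group.items():
        scores = list(scores)
        if not scores:
            raise InsufficientDataError(f"group {group!r} has no scores")
        rates[group] = sum(s.verdict == "pass" for s in scores) / len(scores)
    return pd.Series(rates, name="pass_rate")
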