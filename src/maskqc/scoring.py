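"""Similarity scoring of candidate masks against a fitted baseline.

A candidate's normalized feature vector v is compared to every baseline
cluster via the Mahalanobis distance d(v, C_i); the minimum distance d_min
captures local similarity (closeness to *some* plausible shape cluster) and
the weighted mean d̄ captures global similarity to the whole baseline. Both
are normalized by the baseline's own nth-percentile thresholds t_min, t_mu
and squashed through an arctan into the similarity score

    r = (2/π) · arctan( γ·d_min/t_min + (1−γ)·d̄/t_mu )  ∈ [0, 1)

so that a mask sitting exactly on both thresholds lands at r = 0.5, the
default pass/fail cutoff r_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .baseline import ClusterSet
from .errors import ConfigError, DataError
from .mask import BrainMask

__all__ = [
    "QCScore",
    "mahalanobis",
    "distance_stats",
    "similarity_r",
    "classify",
    "score_masks",
]

D_BAR_MODES = ("inverse_size", "size_weighted", "median")
ARCTAN_MODES = ("normalized", "literal")


@dataclass(frozen=True)
class QCScore:
    """Distances, similarity score and verdict for one mask."""

    mask_id: str
    d_min: float
    d_bar: float
    r: float
    verdict: str
    per_cluster_distances: np.ndarray | None = None
    error: str | None = None

    @classmethod
    def error_score(cls, mask_id: str, error: str) -> "QCScore":
        return cls(mask_id, math.nan, math.nan, math.nan, "fail", None, error)


def mahalanobis(x: np.ndarray, mean: np.ndarray, inv_cov: np.ndarray) -> float:
    """√((x−Ȳ)ᵀ S⁻¹ (x−Ȳ)); tiny negative round-off is clipped to 0."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    inv_cov = np.asarray(inv_cov, dtype=float)
    if x.shape != mean.shape or inv_cov.shape != (x.size, x.size):
        raise ConfigError(
            f"dimension mismatch: x {x.shape}, mean {mean.shape}, inv_cov {inv_cov.shape}"
        )
    delta = x - mean
    d2 = float(delta @ inv_cov @ delta)
    return math.sqrt(max(d2, 0.0))


def distance_stats(
    v: np.ndarray, clusters: ClusterSet, d_bar_mode: str = "inverse_size"
) -> tuple[float, float, np.ndarray]:
    """(d_min, d̄, per-cluster distances) of a normalized vector.

    d_min = min_i d(v, C_i). The default d̄ = Σ_i d(v, C_i)/|C_i| weights each
    cluster's distance by the inverse of its size; ``size_weighted`` gives the
    conventional mean Σ|C_i|·d_i / Σ|C_i| and ``median`` the median
    per-cluster distance.
    """
    if d_bar_mode not in D_BAR_MODES:
        raise ConfigError(f"d_bar_mode must be one of {D_BAR_MODES}, got {d_bar_mode!r}")
    dists = np.array(
        [
            mahalanobis(v, clusters.means[i], clusters.inv_covariances[i])
            for i in range(clusters.k)
        ]
    )
    d_min = float(dists.min())
    if d_bar_mode == "inverse_size":
        d_bar = float((dists / clusters.sizes).sum())
    elif d_bar_mode == "size_weighted":
        d_bar = float((dists * clusters.sizes).sum() / clusters.sizes.sum())
    else:
        d_bar = float(np.median(dists))
    return d_min, d_bar, dists


def similarity_r(
    d_min: float,
    d_bar: float,
    t_min: float,
    t_mu: float,
    gamma: float = 0.75,
    arctan_constant: str = "normalized",
) -> float:
    """Arctan-squashed similarity score of threshold-normalized distances.

    With the default ``normalized`` constant 2/π the score lies in [0, 1) and
    equals exactly 0.5 when both distances sit on their thresholds, which is
    what makes the default cutoff r_max = 0.5 meaningful. The ``literal``
    mode uses the constant π/2 instead (range [0, π²/4)).
    """
    if t_min <= 0 or t_mu <= 0:
        raise ConfigError(f"thresholds must be positive, got t_min={t_min}, t_mu={t_mu}")
    if not 0.0 <= gamma <= 1.0:
        raise ConfigError(f"gamma must lie in [0, 1], got {gamma}")
    if arctan_constant not in ARCTAN_MODES:
        raise ConfigError(f"arctan_constant must be one of {ARCTAN_MODES}")
    arg = gamma * (d_min / t_min) + (1.0 - gamma) * (d_bar / t_mu)
    const = 2.0 / math.pi if arctan_constant == "normalized" else math.pi / 2.0
    return const * math.atan(arg)


def classify(r: float, r_max: float = 0.5) -> str:
    """Pass/fail verdict: a mask passes only if r ≤ r_max (boundary passes)."""
    return "pass" if r <= r_max else "fail"


def score_masks(masks: Iterable[BrainMask], model) -> list[QCScore]:
    """Score a batch of masks against a fitted model (see maskqc.model.MaskQC).

    Per-mask failures (e.g. an empty mask) become error rows with a "fail"
    verdict rather than aborting the batch.
    """
    scores = []
    for mask in masks:
        try:
            scores.append(model.score_mask(mask))
        except DataError as exc:
            scores.append(QCScore.error_score(mask.identifier, f"{type(exc).__name__}: {exc}"))
    return scores
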