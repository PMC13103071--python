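"""Baseline fitting: k selection by Rand-index stability and per-cluster
Gaussian statistics of the normalized ground-truth features.

The number of clusters k is chosen by a stability protocol: for each k in the
configured range, k-means is re-run many times from different seeded
initializations and the mean pairwise Rand index — in its chance-corrected
(adjusted) form, since the raw index inflates toward large k by chance
agreement alone — between the resulting partitions (over a seeded subsample
of run pairs) measures how reproducible the partition at that k is. The most
stable k wins; exact ties go to the *largest* tied k: every stable
coarsening of a genuinely clustered structure also saturates the stability
score, and among equally stable candidates the finest partition resolves
the most structure.

Each final cluster is summarized by its mean and a shrinkage-regularized
covariance, since clusters can hold fewer members than there are features
and the raw covariance would be singular. The shrinkage intensity is the
Ledoit-Wolf estimate floored at the cluster's dimension-to-sample ratio
p/n_c: the Ledoit-Wolf optimum targets the covariance itself and is far too
weak for the *inverse* needed by Mahalanobis distances when n_c ≈ p, leaving
out-of-sample distances inflated relative to the in-sample distances that
set the thresholds. The p/n_c floor vanishes for the large baselines the
method is meant for and only engages at small cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import pinvh
from sklearn.cluster import KMeans
from sklearn.covariance import ledoit_wolf
from sklearn.metrics import adjusted_rand_score

from .errors import ConfigError, DegenerateClusteringError, InsufficientDataError

__all__ = [
    "KSelectionReport",
    "ClusterSet",
    "select_k",
    "fit_cluster_set",
    "regularized_covariance",
    "score_baseline_thresholds",
]

_DEGENERATE_SPREAD = 1e-9  # max feature range below which data count as identical


@dataclass(frozen=True)
class KSelectionReport:
    """Outcome of the stability-based choice of the cluster count."""

    mean_rand_index: dict[int, float]
    chosen_k: int
    runs: int
    seed: int
    best_run_seed: dict[int, int]  # per k, the seed of the lowest-inertia run

    def __post_init__(self) -> None:
        best = max(self.mean_rand_index.values())
        assert self.mean_rand_index[self.chosen_k] == best


@dataclass
class ClusterSet:
    """Final k-means partition of the baseline with per-cluster Gaussian stats."""

    k: int
    assignments: np.ndarray
    sizes: np.ndarray
    means: np.ndarray  # (k, p)
    covariances: np.ndarray  # (k, p, p)
    inv_covariances: np.ndarray  # (k, p, p)

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "assignments": self.assignments.tolist(),
            "sizes": self.sizes.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "inv_covariances": self.inv_covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClusterSet":
        return cls(
            k=int(d["k"]),
            assignments=np.asarray(d["assignments"], dtype=int),
            sizes=np.asarray(d["sizes"], dtype=int),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
            inv_covariances=np.asarray(d["inv_covariances"], dtype=float),
        )


def _check_clusterable(X: np.ndarray, k_max: int) -> None:
    if len(X) <= k_max:
        raise DegenerateClusteringError(
            f"{len(X)} samples cannot support k up to {k_max}"
        )
    spread = float(np.ptp(X, axis=0).max()) if len(X) else 0.0
    if spread < _DEGENERATE_SPREAD:
        raise DegenerateClusteringError(
            "feature vectors are numerically identical; thresholds would degenerate to 0"
        )


def select_k(
    X: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    runs: int = 500,
    seed: int = 0,
    max_pairs: int = 200,
) -> KSelectionReport:
    """Choose the cluster count by run-to-run Rand-index stability.

    For each k in ``k_range`` (inclusive), fit ``runs`` single-init k-means
    models with distinct seeded initializations, then average the adjusted
    Rand index over a seeded subsample of at most ``max_pairs`` run pairs.
    Deterministic given ``seed``; exact ties break toward the largest k (the
    finest equally-stable partition).
    """
    X = np.asarray(X, dtype=float)
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if not 2 <= k_lo <= k_hi:
        raise ConfigError(f"invalid k range {k_range}")
    if runs < 2:
        raise ConfigError("need at least 2 clustering runs to measure stability")
    _check_clusterable(X, k_hi)

    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=(k_hi - k_lo + 1, runs))
    mean_ri: dict[int, float] = {}
    best_seed: dict[int, int] = {}
    for row, k in enumerate(range(k_lo, k_hi + 1)):
        labels = []
        inertias = []
        for s in run_seeds[row]:
            km = KMeans(n_clusters=k, n_init=1, random_state=int(s)).fit(X)
            labels.append(km.labels_)
            inertias.append(km.inertia_)
        pairs = [(i, j) for i in range(runs) for j in range(i + 1, runs)]
        if len(pairs) > max_pairs:
            picked = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[i] for i in picked]
        mean_ri[k] = float(
            np.mean([adjusted_rand_score(labels[i], labels[j]) for i, j in pairs])
        )
        best_seed[k] = int(run_seeds[row][int(np.argmin(inertias))])

    best = max(mean_ri.values())
    chosen = max(k for k, v in mean_ri.items() if v == best)
    return KSelectionReport(mean_ri, chosen, runs, seed, best_seed)


def regularized_covariance(
    Xc: np.ndarray, shrinkage_floor: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Shrinkage-regularized covariance of one cluster and its inverse.

    The empirical covariance is shrunk toward a scaled identity with
    intensity ``max(ledoit_wolf, p/n, shrinkage_floor)`` (capped at 1). The
    p/n floor keeps the inverse usable for out-of-sample Mahalanobis
    distances when the cluster barely outnumbers the features; it is
    negligible for large clusters. If inversion still fails (e.g. a cluster
    of identical points), the pseudo-inverse is used.
    """
    Xc = np.asarray(Xc, dtype=float)
    n, p = Xc.shape
    centered = Xc - Xc.mean(axis=0)
    emp = centered.T @ centered / n
    if n >= 2:
        _, lw_shrinkage = ledoit_wolf(Xc, assume_centered=False)
    else:
        lw_shrinkage = 1.0
    shrinkage = min(max(float(lw_shrinkage), p / n, shrinkage_floor), 1.0)
    mu = np.trace(emp) / p
    cov = (1.0 - shrinkage) * emp + shrinkage * mu * np.eye(p)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        inv = pinvh(cov)
    return cov, inv


def fit_cluster_set(
    X: np.ndarray,
    k: int,
    run_seed: int,
    shrinkage_floor: float = 1e-6,
) -> ClusterSet:
    """Final k-means fit at the chosen k plus per-cluster Gaussian statistics.

    Any cluster of size 1 triggers a refit at k−1 (down to k = 2, after which
    the baseline is declared degenerate): singleton clusters have no
    covariance and would make their own member's distance exactly zero.
    """
    X = np.asarray(X, dtype=float)
    while True:
        km = KMeans(n_clusters=k, n_init=1, random_state=run_seed).fit(X)
        labels = km.labels_
        sizes = np.bincount(labels, minlength=k)
        if sizes.min() >= 2:
            break
        if k <= 2:
            raise DegenerateClusteringError(
                "could not form clusters with >= 2 members each, even at k = 2"
            )
        k -= 1

    p = X.shape[1]
    means = np.empty((k, p))
    covs = np.empty((k, p, p))
    invs = np.empty((k, p, p))
    for i in range(k):
        members = X[labels == i]
        means[i] = members.mean(axis=0)
        covs[i], invs[i] = regularized_covariance(members, shrinkage_floor)
    return ClusterSet(k, labels, sizes, means, covs, invs)


def score_baseline_thresholds(
    X: np.ndarray,
    clusters: ClusterSet,
    percentile: float = 90.0,
    d_bar_mode: str = "inverse_size",
) -> tuple[float, float]:
    """Thresholds t_min and t_mu: the nth percentiles of the baseline's own
    distance distributions D_min = {d_min(b)} and D_mu = {d̄(b)}, b in B.

    Percentiles use linear interpolation between order statistics.
    """
    from .scoring import distance_stats  # cycle-free: scoring does not import baseline

    if not 0.0 < percentile < 100.0:
        raise ConfigError(f"percentile must lie in (0, 100), got {percentile}")
    d_mins = np.empty(len(X))
    d_bars = np.empty(len(X))
    for i, v in enumerate(np.asarray(X, dtype=float)):
        d_mins[i], d_bars[i], _ = distance_stats(v, clusters, d_bar_mode)
    t_min = float(np.percentile(d_mins, percentile))
    t_mu = float(np.percentile(d_bars, percentile))
    return t_min, t_mu
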