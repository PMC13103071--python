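"""The `MaskQC` estimator: the full training-free QC model in one object.

`MaskQC` follows the scikit-learn outlier-detector idiom (fit on the baseline
feature matrix; ``predict`` returns +1 for passing masks and −1 for flagged
ones; ``decision_function`` is positive inside the acceptance region), so it
composes with sklearn pipelines and model selection. Fitting comprises:

1. z-score normalization of the baseline features (population std),
2. choice of the cluster count k by Rand-index stability of repeated k-means
   runs over a configurable range,
3. a final k-means partition (the lowest-inertia run at the chosen k) with
   per-cluster means and shrinkage-regularized covariances,
4. thresholds t_min and t_mu: the nth percentiles of the baseline's own
   minimum and weighted-mean Mahalanobis distances.

Scoring a candidate mask normalizes its features with the *baseline* scaler,
computes cluster-conditional Mahalanobis distances, and maps them to the
similarity score r; the mask passes iff r ≤ r_max.
"""

from __future__ import annotations

import json
import os
from importlib.metadata import version as _pkg_version
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .baseline import (
    ClusterSet,
    KSelectionReport,
    fit_cluster_set,
    score_baseline_thresholds,
    select_k,
)
from .errors import ConfigError, InsufficientDataError
from .features import (
    DEFAULT_FEATURES,
    FeatureScaler,
    FeatureVector,
    extract_features,
    fit_scaler,
)
from .mask import BrainMask
from .scoring import QCScore, classify, distance_stats, similarity_r

__all__ = ["MaskQC", "fit_baseline", "save_model", "load_model"]


class MaskQC(OutlierMixin, BaseEstimator):
    """Unsupervised QC of brain-extraction masks against a ground-truth baseline.

    Parameters
    ----------
    gamma : float, default 0.75
        Weight of the local term d_min/t_min in the similarity score; 1−gamma
        weighs the global term d̄/t_mu. Values > 0.5 favor closeness to the
        nearest baseline cluster over conformity with the average trend.
    percentile : float, default 90
        Percentile of the baseline's own distance distributions used for the
        thresholds t_min and t_mu; lower values give stricter QC.
    r_max : float, default 0.5
        Pass/fail cutoff on the similarity score (boundary passes).
    k_min, k_max : int, defaults 2 and 10
        Inclusive range of cluster counts considered.
    clustering_runs : int, default 500
        Re-runs of k-means per candidate k for the stability score.
    feature_names : sequence of str or None
        Names of the feature columns; defaults to the 23-feature catalogue.
        Only used when fitting from masks / feature vectors and for
        serialization; ``fit`` accepts any numeric matrix.
    arctan_constant : {"normalized", "literal"}, default "normalized"
        2/π (score in [0,1), thresholds map to 0.5) or the literal π/2.
    d_bar_mode : {"inverse_size", "size_weighted", "median"}
        How per-cluster distances aggregate into the global statistic d̄.
    shrinkage_floor : float, default 1e-6
        Minimum shrinkage intensity of the per-cluster covariances.
    min_baseline : int, default 30
        Minimum number of baseline masks required to fit.
    random_state : int, default 0
        Seed for every stochastic step; identical inputs and seed give a
        bit-identical model.

    Attributes
    ----------
    scaler_ : FeatureScaler
    clusters_ : ClusterSet
    k_ : int
    k_selection_ : KSelectionReport
    t_min_, t_mu_ : float
    n_features_in_ : int
    """

    def __init__(
        self,
        gamma: float = 0.75,
        percentile: float = 90.0,
        r_max: float = 0.5,
        k_min: int = 2,
        k_max: int = 10,
        clustering_runs: int = 500,
        feature_names: Sequence[str] | None = None,
        arctan_constant: str = "normalized",
        d_bar_mode: str = "inverse_size",
        shrinkage_floor: float = 1e-6,
        min_baseline: int = 30,
        random_state: int = 0,
    ):
        self.gamma = gamma
        self.percentile = percentile
        self.r_max = r_max
        self.k_min = k_min
        self.k_max = k_max
        self.clustering_runs = clustering_runs
        self.feature_names = feature_names
        self.arctan_constant = arctan_constant
        self.d_bar_mode = d_bar_mode
        self.shrinkage_floor = shrinkage_floor
        self.min_baseline = min_baseline
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None) -> "MaskQC":
        """Fit the baseline model on a (n_masks, n_features) raw feature matrix."""
        X = check_array(X, dtype=float)
        if len(X) < self.min_baseline:
            raise InsufficientDataError(
                f"baseline needs >= {self.min_baseline} masks, got {len(X)}"
            )
        names = self._resolved_names(X.shape[1])
        vectors = [FeatureVector(names, row) for row in X]
        self.scaler_ = fit_scaler(vectors)
        Z = self.scaler_.transform_matrix(X)

        k_hi = min(self.k_max, len(Z) - 1)
        self.k_selection_ = select_k(
            Z, (self.k_min, k_hi), runs=self.clustering_runs, seed=self.random_state
        )
        chosen = self.k_selection_.chosen_k
        self.clusters_ = fit_cluster_set(
            Z, chosen, self.k_selection_.best_run_seed[chosen], self.shrinkage_floor
        )
        self.k_ = self.clusters_.k
        self.t_min_, self.t_mu_ = score_baseline_thresholds(
            Z, self.clusters_, self.percentile, self.d_bar_mode
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _resolved_names(self, n_features: int) -> tuple[str, ...]:
        if self.feature_names is not None:
            names = tuple(self.feature_names)
            if len(names) != n_features:
                raise ConfigError(
                    f"{len(names)} feature names but {n_features} feature columns"
                )
            return names
        if n_features == len(DEFAULT_FEATURES):
            return DEFAULT_FEATURES
        return tuple(f"feature_{i}" for i in range(n_features))

    # -------------------------------------------------------------- scoring

    def similarity(self, X) -> np.ndarray:
        """Similarity scores r for a raw feature matrix."""
        check_is_fitted(self, "clusters_")
        X = check_array(X, dtype=float)
        Z = self.scaler_.transform_matrix(X)
        out = np.empty(len(Z))
        for i, v in enumerate(Z):
            d_min, d_bar, _ = distance_stats(v, self.clusters_, self.d_bar_mode)
            out[i] = similarity_r(
                d_min, d_bar, self.t_min_, self.t_mu_, self.gamma, self.arctan_constant
            )
        return out

    def decision_function(self, X) -> np.ndarray:
        """r_max − r: positive for passing masks, negative for flagged ones."""
        return self.r_max - self.similarity(X)

    def score_samples(self, X) -> np.ndarray:
        """Higher is more normal: the negative similarity score −r."""
        return -self.similarity(X)

    def predict(self, X) -> np.ndarray:
        """+1 (pass) / −1 (fail) per the sklearn outlier-detector convention."""
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def score_mask(self, mask: BrainMask) -> QCScore:
        """Full QC record for one mask (features → normalize → distances → r)."""
        check_is_fitted(self, "clusters_")
        fv = extract_features(mask, self.scaler_.feature_names)
        v = self.scaler_.transform_matrix(fv.values)
        d_min, d_bar, per_cluster = distance_stats(v, self.clusters_, self.d_bar_mode)
        r = similarity_r(
            d_min, d_bar, self.t_min_, self.t_mu_, self.gamma, self.arctan_constant
        )
        return QCScore(mask.identifier, d_min, d_bar, r, classify(r, self.r_max), per_cluster)

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        check_is_fitted(self, "clusters_")
        return {
            "format": "maskqc-model",
            "versions": {
                "maskqc": _safe_version("maskqc"),
                "numpy": _safe_version("numpy"),
                "scikit-learn": _safe_version("scikit-learn"),
            },
            "params": _jsonable(self.get_params()),
            "scaler": self.scaler_.to_dict(),
            "clusters": self.clusters_.to_dict(),
            "t_min": self.t_min_,
            "t_mu": self.t_mu_,
            "k_selection": {
                "mean_rand_index": {str(k): v for k, v in self.k_selection_.mean_rand_index.items()},
                "chosen_k": self.k_selection_.chosen_k,
                "runs": self.k_selection_.runs,
                "seed": self.k_selection_.seed,
                "best_run_seed": {str(k): v for k, v in self.k_selection_.best_run_seed.items()},
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaskQC":
        if d.get("format") != "maskqc-model":
            raise ConfigError("not a maskqc model file")
        model = cls(**d["params"])
        model.scaler_ = FeatureScaler.from_dict(d["scaler"])
        model.clusters_ = ClusterSet.from_dict(d["clusters"])
        model.k_ = model.clusters_.k
        model.t_min_ = float(d["t_min"])
        model.t_mu_ = float(d["t_mu"])
        ks = d["k_selection"]
        model.k_selection_ = KSelectionReport(
            {int(k): v for k, v in ks["mean_rand_index"].items()},
            int(ks["chosen_k"]),
            int(ks["runs"]),
            int(ks["seed"]),
            {int(k): v for k, v in ks["best_run_seed"].items()},
        )
        model.n_features_in_ = len(model.scaler_.feature_names)
        return model


def _safe_version(name: str) -> str:
    try:
        return _pkg_version(name)
    except Exception:
        return "unknown"


def _jsonable(params: dict) -> dict:
    out = {}
    for key, value in params.items():
        if isinstance(value, tuple):
            value = list(value)
        out[key] = value
    return out


def fit_baseline(features: Sequence[FeatureVector], config=None) -> MaskQC:
    """Fit a `MaskQC` model from baseline feature vectors.

    ``config`` may be a `maskqc.config.QCConfig` or a plain dict of `MaskQC`
    parameters; omitted parameters take the defaults.
    """
    if not features:
        raise InsufficientDataError("no baseline feature vectors")
    names = features[0].names
    params = {}
    if config is not None:
        params = config.to_model_params() if hasattr(config, "to_model_params") else dict(config)
    params.setdefault("feature_names", names)
    X = np.stack([f.values for f in features])
    return MaskQC(**params).fit(X)


def save_model(model: MaskQC, path: str | os.PathLike) -> None:
    """Serialize a fitted model to a JSON sidecar, reloadable without the
    baseline masks."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str | os.PathLike) -> MaskQC:
    with open(path) as fh:
        return MaskQC.from_dict(json.load(fh))
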