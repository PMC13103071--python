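"""Configuration objects for the QC pipeline, round-trippable through YAML.

Every algorithm parameter is surfaced here — no hidden constants — because
the method is meant to be tuned per use case (γ, percentile, r_max, the
feature list, the d̄ statistic).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigError
from .features import DEFAULT_FEATURES

__all__ = ["QCConfig", "SynthConfig", "load_config", "save_config"]


class QCConfig(BaseModel):
    """All tunable parameters of the QC method.

    Defaults are the recommended operating point: γ = 0.75 (local similarity
    weighted above global), thresholds at the 90th percentile of the
    baseline's own distances, cutoff r_max = 0.5, k-means stability selection
    of k in 2..10 over 500 runs.
    """

    gamma: float = Field(default=0.75, ge=0.0, le=1.0)
    percentile: float = Field(default=90.0, gt=0.0, lt=100.0)
    r_max: float = Field(default=0.5, gt=0.0)
    k_min: int = Field(default=2, ge=2)
    k_max: int = Field(default=10, ge=2)
    clustering_runs: int = Field(default=500, ge=2)
    arctan_constant: Literal["normalized", "literal"] = "normalized"
    d_bar_mode: Literal["inverse_size", "size_weighted", "median"] = "inverse_size"
    features: tuple[str, ...] = DEFAULT_FEATURES
    shrinkage_floor: float = Field(default=1e-6, gt=0.0)
    min_baseline: int = Field(default=30, ge=4)
    seed: int = 0

    @field_validator("k_max")
    @classmethod
    def _k_order(cls, v, info):
        if "k_min" in info.data and v < info.data["k_min"]:
            raise ValueError("k_max must be >= k_min")
        return v

    def to_model_params(self) -> dict:
        """Parameters for `maskqc.model.MaskQC`."""
        return {
            "gamma": self.gamma,
            "percentile": self.percentile,
            "r_max": self.r_max,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "clustering_runs": self.clustering_runs,
            "feature_names": self.features,
            "arctan_constant": self.arctan_constant,
            "d_bar_mode": self.d_bar_mode,
            "shrinkage_floor": self.shrinkage_floor,
            "min_baseline": self.min_baseline,
            "random_state": self.seed,
        }


class SynthConfig(BaseModel):
    """Parameters of the synthetic cohort generator."""

    n_clean: int = Field(default=60, ge=1)
    n_corrupt: int = Field(default=40, ge=0)
    grid: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (30.0, 25.0, 21.0)
    modes: tuple[tuple[float, float, float], ...] = (
        (30.0, 25.0, 21.0),
        (34.0, 28.5, 23.5),
        (27.5, 26.5, 18.5),
    )
    axis_jitter: float = 0.035
    deform_amplitude: float = 0.03
    deform_scale: float = 24.0
    center_jitter: float = 1.5
    dice_band: tuple[float, float] = (0.70, 0.90)
    kinds: tuple[str, ...] = ("erode", "dilate", "punch_holes", "add_blob", "truncate_axial", "translate")
    seed: int = 0


def load_config(path, cls=QCConfig):
    """Load a YAML config file; unknown or invalid keys raise ConfigError."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def save_config(config: BaseModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
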