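"""Morphological feature extraction from 3D binary masks.

The QC method describes each mask by a fixed, ordered list of scalar shape
descriptors computed from the binary label alone (no image intensities). The
default catalogue holds 23 features; the scoring machinery is list-agnostic,
so any ordered subset of the supported catalogue may be configured instead.

Conventions
-----------
* Physical coordinates: 0-based voxel index × spacing (mm); the position of a
  voxel is its center.
* Central moments: ``sigma_G[a, b] = (1/m) Σ_i (x_i − x̄0)_a (x_i − x̄0)_b`` over
  foreground voxels with unit weights, i.e. the population covariance of the
  foreground voxel positions in mm. Diagonal entries are the conventional
  non-negative variances about the centroid. Eigenvalues are reported sorted
  descending (λ1 ≥ λ2 ≥ λ3, units mm²).
* Elongation = √(λ1/λ2) and flatness = √(λ2/λ3) with the larger eigenvalue in
  the numerator, so both are ≥ 1. (Two conventions circulate; this is the
  one used throughout this package.)
* Surface area is the total area of exposed voxel faces (6-connectivity);
  faces on the volume border count as exposed. This overestimates the area of
  smooth surfaces by a bounded factor, which is irrelevant for QC because the
  same convention is applied to baseline and candidate masks alike.
* Centroid features are offsets from the physical center of the volume, so
  they measure off-centering rather than scanner coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.special import gamma as gamma_fn

from .errors import ConfigError, EmptyMaskError, InsufficientDataError
from .mask import BrainMask

__all__ = [
    "CentralMomentMatrix",
    "FeatureVector",
    "FeatureScaler",
    "FEATURE_CATALOGUE",
    "DEFAULT_FEATURES",
    "compute_central_moments",
    "extract_features",
    "fit_scaler",
    "apply_scaler",
    "features_to_frame",
]

_EIG_FLOOR = 1e-30  # guards ratio features on degenerate (lower-dimensional) masks


@dataclass(frozen=True)
class CentralMomentMatrix:
    """Second central moments of a mask's foreground in physical coordinates.

    ``matrix`` is the symmetric 3×3 moment matrix σ_G (mm²); ``eigenvalues``
    are sorted descending with matching orthonormal ``eigenvectors`` as
    columns. ``reference_point`` is the foreground centroid (mm) and
    ``total_weight`` the foreground voxel count (unit weights).
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    reference_point: np.ndarray
    total_weight: float


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered morphological descriptors of one mask."""

    names: tuple[str, ...]
    values: np.ndarray
    mask_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise ConfigError("feature names and values disagree in length")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def compute_central_moments(mask: BrainMask) -> CentralMomentMatrix:
    """Second central moment matrix of the foreground, with eigen-decomposition.

    All foreground voxels enter with unit weight at their physical (mm)
    position. A single-voxel mask yields the zero matrix (all eigenvalues 0).

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground voxels.
    """
    coords = _foreground_coords(mask)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    sigma = centered.T @ centered / len(coords)
    sigma = (sigma + sigma.T) / 2.0  # exact symmetry
    evals, evecs = np.linalg.eigh(sigma)  # ascending
    order = slice(None, None, -1)
    return CentralMomentMatrix(
        matrix=sigma,
        eigenvalues=evals[order].copy(),
        eigenvectors=evecs[:, order].copy(),
        reference_point=centroid,
        total_weight=float(len(coords)),
    )


def _foreground_coords(mask: BrainMask) -> np.ndarray:
    if mask.is_empty():
        raise EmptyMaskError(f"mask {mask.identifier!r} has no foreground voxels")
    return np.argwhere(mask.voxels).astype(float) * np.asarray(mask.spacing)


def _surface_areas(vox: np.ndarray, spacing: Sequence[float]) -> tuple[float, float]:
    """(total exposed face area, exposed face area lying on the volume border)."""
    face_area = [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
    padded = np.pad(vox, 1).astype(np.int8)
    total = 0.0
    border = 0.0
    for ax in range(3):
        transitions = np.count_nonzero(np.diff(padded, axis=ax))
        total += transitions * face_area[ax]
        first = np.count_nonzero(np.take(vox, 0, axis=ax))
        last = np.count_nonzero(np.take(vox, -1, axis=ax))
        border += (first + last) * face_area[ax]
    return total, border


def _border_voxel_count(vox: np.ndarray) -> int:
    interior = vox[1:-1, 1:-1, 1:-1]
    return int(vox.sum() - interior.sum())


def _feret_diameter(mask: BrainMask) -> float:
    """Maximum caliper diameter: largest pairwise distance between surface
    voxel centers, computed over the convex hull vertices."""
    from .metrics import surface_voxels  # local import: metrics imports nothing from here

    pts = np.argwhere(surface_voxels(mask.voxels)).astype(float) * np.asarray(mask.spacing)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) point sets: brute force below
    return float(pdist(pts).max())


def _unit_ball_volume(n: int) -> float:
    """Volume of the unit n-ball via the gamma function, π^(n/2) / Γ(n/2 + 1)."""
    return pi ** (n / 2.0) / gamma_fn(n / 2.0 + 1.0)


def _equivalent_ellipsoid_diameters(eigenvalues: np.ndarray, volume: float) -> np.ndarray:
    """Diameters of the ellipsoid with the mask's volume and moment ratios.

    Semi-axes are proportional to √λ_i, scaled so the ellipsoid volume
    (unit-ball volume × ∏ semi-axes) matches the mask volume. Degenerate
    masks with a zero eigenvalue fall back to the equivalent sphere.
    """
    evals = np.maximum(np.asarray(eigenvalues, dtype=float), 0.0)
    prod_sqrt = float(np.sqrt(evals).prod())
    if prod_sqrt <= 0.0:
        return np.full(3, 2.0 * (volume / _unit_ball_volume(3)) ** (1.0 / 3.0) if volume > 0 else 0.0)
    scale = (volume / (_unit_ball_volume(3) * prod_sqrt)) ** (1.0 / 3.0)
    return 2.0 * np.sqrt(evals) * scale


def _ratio(num: float, den: float) -> float:
    if den <= _EIG_FLOOR:
        return 1.0 if num <= _EIG_FLOOR else float(np.sqrt(num / _EIG_FLOOR))
    return float(np.sqrt(num / den))


def _compute_all_features(mask: BrainMask) -> dict[str, float]:
    vox = mask.voxels
    spacing = np.asarray(mask.spacing)
    n_fg = mask.foreground_count
    volume = n_fg * mask.voxel_volume
    moments = compute_central_moments(mask)
    lam = moments.eigenvalues

    surface, border_surface = _surface_areas(vox, mask.spacing)
    eq_radius = (3.0 * volume / (4.0 * pi)) ** (1.0 / 3.0)
    eq_perimeter = 4.0 * pi * eq_radius**2
    ellipsoid_d = _equivalent_ellipsoid_diameters(lam, volume)

    volume_center = (np.asarray(vox.shape, dtype=float) - 1.0) / 2.0 * spacing
    centroid_offset = moments.reference_point - volume_center

    idx = np.argwhere(vox)
    bbox_extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing

    return {
        "voxel_count": float(n_fg),
        "physical_size": volume,
        "surface_area": surface,
        "border_surface_area": border_surface,
        "border_surface_ratio": border_surface / surface if surface > 0 else 0.0,
        "border_voxel_count": float(_border_voxel_count(vox)),
        "elongation": _ratio(lam[0], lam[1]),
        "flatness": _ratio(lam[1], lam[2]),
        "roundness": eq_perimeter / surface if surface > 0 else 0.0,
        "equivalent_spherical_radius": eq_radius,
        "equivalent_spherical_perimeter": eq_perimeter,
        "equivalent_ellipsoid_diameter_1": float(ellipsoid_d[0]),
        "equivalent_ellipsoid_diameter_2": float(ellipsoid_d[1]),
        "equivalent_ellipsoid_diameter_3": float(ellipsoid_d[2]),
        "feret_diameter": _feret_diameter(mask),
        "principal_moment_1": float(lam[0]),
        "principal_moment_2": float(lam[1]),
        "principal_moment_3": float(lam[2]),
        "centroid_offset_x": float(centroid_offset[0]),
        "centroid_offset_y": float(centroid_offset[1]),
        "centroid_offset_z": float(centroid_offset[2]),
        "bbox_extent_x": float(bbox_extent[0]),
        "bbox_extent_y": float(bbox_extent[1]),
        "bbox_extent_z": float(bbox_extent[2]),
    }


#: Every descriptor the extractor knows how to compute.
FEATURE_CATALOGUE: tuple[str, ...] = (
    "voxel_count",
    "physical_size",
    "surface_area",
    "border_surface_area",
    "border_surface_ratio",
    "border_voxel_count",
    "elongation",
    "flatness",
    "roundness",
    "equivalent_spherical_radius",
    "equivalent_spherical_perimeter",
    "equivalent_ellipsoid_diameter_1",
    "equivalent_ellipsoid_diameter_2",
    "equivalent_ellipsoid_diameter_3",
    "feret_diameter",
    "principal_moment_1",
    "principal_moment_2",
    "principal_moment_3",
    "centroid_offset_x",
    "centroid_offset_y",
    "centroid_offset_z",
    "bbox_extent_x",
    "bbox_extent_y",
    "bbox_extent_z",
)

#: The default 23-feature list. The full catalogue holds one extra descriptor
#: (border foreground voxel count), omitted here as redundant with the border
#: surface features.
DEFAULT_FEATURES: tuple[str, ...] = tuple(
    name for name in FEATURE_CATALOGUE if name != "border_voxel_count"
)


def extract_features(
    mask: BrainMask, feature_list: Sequence[str] = DEFAULT_FEATURES
) -> FeatureVector:
    """Compute the ordered morphological descriptors of one mask.

    All foreground voxels are treated as a single label — spurious
    disconnected blobs are precisely the failures QC must see, so no
    largest-component filtering is applied.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground.
    ConfigError
        If ``feature_list`` contains an unknown name.
    """
    unknown = [name for name in feature_list if name not in FEATURE_CATALOGUE]
    if unknown:
        raise ConfigError(f"unknown feature name(s): {unknown}")
    table = _compute_all_features(mask)
    values = np.array([table[name] for name in feature_list], dtype=float)
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in zip(feature_list, values) if not np.isfinite(v)]
        raise ConfigError(f"non-finite feature value(s) for {mask.identifier!r}: {bad}")
    return FeatureVector(tuple(feature_list), values, mask.identifier)


@dataclass
class FeatureScaler:
    """Per-feature z-scoring (remove mean, scale to unit variance).

    Fitted on the baseline set only, with the population (divide-by-N)
    standard deviation so the fitted set has exactly unit variance. Constant
    features get std 1 and are flagged, so they transform to 0.
    """

    feature_names: tuple[str, ...]
    means: np.ndarray
    stds: np.ndarray
    constant: np.ndarray  # bool flags for zero-variance features

    def transform_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != len(self.feature_names):
            raise ConfigError(
                f"expected {len(self.feature_names)} features, got {X.shape[-1]}"
            )
        return (X - self.means) / self.stds

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "constant": self.constant.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureScaler":
        return cls(
            tuple(d["feature_names"]),
            np.asarray(d["means"], dtype=float),
            np.asarray(d["stds"], dtype=float),
            np.asarray(d["constant"], dtype=bool),
        )


def fit_scaler(features: Sequence[FeatureVector]) -> FeatureScaler:
    """Fit z-score normalization on a set of feature vectors.

    Raises
    ------
    InsufficientDataError
        With fewer than 2 vectors the variance is meaningless.
    ConfigError
        If the vectors do not share one feature order.
    """
    if len(features) < 2:
        raise InsufficientDataError("need at least 2 feature vectors to fit a scaler")
    names = features[0].names
    if any(f.names != names for f in features):
        raise ConfigError("feature vectors have inconsistent feature orders")
    X = np.stack([f.values for f in features])
    means = X.mean(axis=0)
    stds = X.std(axis=0)  # population convention
    constant = stds == 0.0
    stds = np.where(constant, 1.0, stds)
    return FeatureScaler(names, means, stds, constant)


def apply_scaler(scaler: FeatureScaler, v: FeatureVector) -> np.ndarray:
    """Normalize one feature vector; the feature order must match the scaler."""
    if v.names != scaler.feature_names:
        raise ConfigError("feature order of vector does not match the fitted scaler")
    return scaler.transform_matrix(v.values)


def features_to_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    """One row per mask: mask_id plus the named features in catalogue order."""
    features = list(features)
    if not features:
        return pd.DataFrame(columns=["mask_id"])
    names = features[0].names
    rows = [{"mask_id": f.mask_id, **f.as_dict()} for f in features]
    return pd.DataFrame(rows, columns=["mask_id", *names])
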