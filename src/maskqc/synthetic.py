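"""Deterministic generator of brain-like 3D binary masks and corruptions.

Clean masks are smoothed, jittered ellipsoids: a quadratic implicit function
perturbed by band-limited Gaussian noise and thresholded, giving a single
connected, border-free foreground component whose shape varies across seeds
the way brain outlines vary across subjects. A clean *cohort* draws each
mask's base shape from a small set of discrete population modes
(`POPULATION_MODES`), emulating the multi-site, mixed pre-/post-operative
composition of real ground-truth cohorts; this mode structure is what gives
the baseline its genuine clusters. Corruptions emulate the
characteristic failures of skull-stripping algorithms: over-erosion and
over-inclusion (erode/dilate), internal holes, spurious extracranial blobs,
axial truncation, and misregistration-like translation. Corruption
magnitudes are solved (stepping or bisection) to land in a target Dice band
against the clean original, so cohort composition is controlled by
configuration, not luck.

The generator stands in for a curated multi-institutional ground-truth
cohort; it reproduces the feature-level contrast between plausible and
faulty masks, not anatomical detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, DataError
from .mask import BrainMask, save_mask
from .metrics import dice, hd95, sanity_label, surface_voxels

__all__ = [
    "MaskRecipe",
    "CorruptionSpec",
    "CORRUPTION_KINDS",
    "POPULATION_MODES",
    "generate_clean",
    "corrupt",
    "calibrate_corruption",
    "build_cohort",
    "generate_cohort",
]

CORRUPTION_KINDS = ("erode", "dilate", "punch_holes", "add_blob", "truncate_axial", "translate")

#: Base semi-axes (mm) of the discrete population modes a cohort draws from:
#: a typical adult brain, a larger-headed population, and a flatter post-
#: operative-like shape. Within-mode variation comes from MaskRecipe jitter.
POPULATION_MODES: tuple[tuple[float, float, float], ...] = (
    (30.0, 25.0, 21.0),
    (34.0, 28.5, 23.5),
    (27.5, 26.5, 18.5),
)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class MaskRecipe:
    """Parameters of one clean synthetic mask; same recipe + seed ⇒ bit-identical.

    The defaults put most inter-subject variation into a few global modes —
    per-axis size jitter and off-centering — with a mild large-scale smooth
    deformation on top, mirroring how real brain outlines differ mostly in
    overall size, proportions and position rather than in fine-grained
    independent surface noise.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (30.0, 25.0, 21.0)  # mm
    axis_jitter: float = 0.035  # fractional per-axis s.d.
    deform_amplitude: float = 0.03  # of the implicit function's unit level
    deform_scale: float = 24.0  # mm correlation length of the deformation
    center_jitter: float = 1.5  # mm s.d. of the center offset
    seed: int = 0


@dataclass(frozen=True)
class CorruptionSpec:
    """One corruption: a kind from `CORRUPTION_KINDS` plus magnitude parameters."""

    kind: str
    params: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CORRUPTION_KINDS:
            raise ConfigError(f"unknown corruption kind {self.kind!r}")


def generate_clean(recipe: MaskRecipe) -> BrainMask:
    """Generate one clean mask: a smoothed, jittered ellipsoid.

    With ``axis_jitter = deform_amplitude = center_jitter = 0`` this is the
    exact voxelized ellipsoid. The result is a single connected component
    that never touches the volume border.
    """
    rng = np.random.default_rng(recipe.seed)
    spacing = np.asarray(recipe.spacing, dtype=float)
    shape = np.asarray(recipe.shape, dtype=int)
    extent = (shape - 1) * spacing

    factors = np.clip(
        1.0 + recipe.axis_jitter * rng.standard_normal(3),
        1.0 - 2.0 * recipe.axis_jitter,
        1.0 + 2.0 * recipe.axis_jitter,
    )
    axes = np.asarray(recipe.semi_axes) * factors
    center = extent / 2.0 + recipe.center_jitter * rng.standard_normal(3)

    # the deformation moves the boundary by ~ amplitude*axis/2; demand margin
    pad = 1.0 + 2.0 * recipe.deform_amplitude
    if np.any(center - axes * pad < 2 * spacing) or np.any(center + axes * pad > extent - 2 * spacing):
        raise ConfigError("semi-axes too large for the grid (no border margin)")

    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij", sparse=True
    )
    quad = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    f = 1.0 - quad

    if recipe.deform_amplitude > 0:
        noise = rng.standard_normal(tuple(shape))
        noise = ndimage.gaussian_filter(noise, sigma=recipe.deform_scale / spacing)
        noise /= noise.std()
        f = f + recipe.deform_amplitude * noise

    vox = f > 0.0
    labels, n_comp = ndimage.label(vox, structure=_FACE_STRUCT)
    if n_comp > 1:  # keep the main body; satellites are a corruption, not a brain
        sizes = np.bincount(labels.ravel())[1:]
        vox = labels == (int(np.argmax(sizes)) + 1)
    if _touches_border(vox):
        raise ConfigError("generated mask touches the volume border; shrink the recipe")
    return BrainMask(vox, recipe.spacing, f"synthetic-{recipe.seed}")


def _touches_border(vox: np.ndarray) -> bool:
    return any(
        np.take(vox, 0, axis=ax).any() or np.take(vox, -1, axis=ax).any() for ax in range(3)
    )


# ------------------------------------------------------------- corruptions


def _sphere_indices(shape, center_vox, radius_mm, spacing) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center_vox, spacing))
    return d2 <= radius_mm**2


def _apply_corruption(vox: np.ndarray, spacing, spec: CorruptionSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    out = vox.copy()
    p = spec.params
    if spec.kind == "erode":
        it = int(p["iterations"])
        if it > 0:
            out = ndimage.binary_erosion(out, structure=_FACE_STRUCT, iterations=it)
    elif spec.kind == "dilate":
        it = int(p["iterations"])
        if it > 0:
            out = ndimage.binary_dilation(out, structure=_FACE_STRUCT, iterations=it)
    elif spec.kind == "punch_holes":
        radius = float(p.get("radius", 6.0))
        count = int(p["count"])
        # hole centers sit in the deep interior so holes stay internal cavities
        depth = ndimage.distance_transform_edt(vox, sampling=spacing)
        core = np.argwhere(depth > radius * 0.75)
        if len(core) == 0:
            raise DataError("mask too thin to punch holes of this radius")
        for _ in range(count):
            center = core[rng.integers(len(core))]
            out[_sphere_indices(vox.shape, center, radius, spacing)] = False
    elif spec.kind == "add_blob":
        radius = float(p.get("radius", 8.0))
        min_dist = float(p.get("min_distance", 25.0))
        dist_to_fg = ndimage.distance_transform_edt(~vox, sampling=spacing)
        margin = np.ceil(radius / np.asarray(spacing)).astype(int) + 1
        ok = dist_to_fg >= min_dist
        for ax, m in enumerate(margin):
            sl = [slice(None)] * 3
            sl[ax] = slice(0, m)
            ok[tuple(sl)] = False
            sl[ax] = slice(-m, None)
            ok[tuple(sl)] = False
        candidates = np.argwhere(ok)
        if len(candidates) == 0:
            raise DataError("no room for an extracranial blob at this distance")
        center = candidates[rng.integers(len(candidates))]
        out[_sphere_indices(vox.shape, center, radius, spacing)] = True
    elif spec.kind == "truncate_axial":
        fraction = float(p["fraction"])
        z = np.flatnonzero(vox.any(axis=(0, 1)))
        z0, z1 = int(z[0]), int(z[-1])
        n_cut = int(round(fraction * (z1 - z0 + 1)))
        if n_cut > 0:
            out[:, :, z1 - n_cut + 1 :] = False
    elif spec.kind == "translate":
        offset = tuple(int(o) for o in p["offset"])
        shifted = np.zeros_like(out)
        src = [slice(max(0, -o), out.shape[i] - max(0, o)) for i, o in enumerate(offset)]
        dst = [slice(max(0, o), out.shape[i] + min(0, o)) for i, o in enumerate(offset)]
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out


def corrupt(mask: BrainMask, spec: CorruptionSpec) -> tuple[BrainMask, float]:
    """Apply one corruption; returns the corrupted mask and its Dice against
    the input. Raises rather than returning an empty mask."""
    if mask.is_empty():
        raise DataError("cannot corrupt an empty mask")
    vox = _apply_corruption(mask.voxels, mask.spacing, spec)
    if not vox.any():
        raise DataError(f"corruption {spec.kind} emptied the mask")
    result = mask.with_voxels(vox, f"{mask.identifier}-{spec.kind}")
    return result, dice(mask, result)


def calibrate_corruption(
    mask: BrainMask,
    kind: str,
    dice_band: tuple[float, float] = (0.70, 0.90),
    seed: int = 0,
) -> tuple[BrainMask, CorruptionSpec, float]:
    """Solve the corruption magnitude so the achieved Dice lands in
    ``dice_band`` (or below its upper edge for discrete magnitudes).

    ``add_blob`` is distance-calibrated instead: the blob is placed far
    enough from the brain surface that HD95 exceeds 15 mm while Dice stays
    high, emulating spurious extracranial tissue.
    """
    lo, hi = dice_band
    if not 0.0 < lo < hi < 1.0:
        raise ConfigError(f"invalid dice band {dice_band}")
    target = (lo + hi) / 2.0

    if kind in ("erode", "dilate"):
        for it in range(1, 40):
            spec = CorruptionSpec(kind, {"iterations": it}, seed)
            result, d = corrupt(mask, spec)
            if d < hi:
                return result, spec, d
        raise DataError(f"{kind} could not reach Dice < {hi}")

    if kind == "punch_holes":
        for count in range(1, 60):
            spec = CorruptionSpec(kind, {"count": count, "radius": 6.0}, seed)
            result, d = corrupt(mask, spec)
            if d < hi:
                return result, spec, d
        raise DataError("punch_holes could not reach the Dice band")

    if kind == "add_blob":
        radius = 8.0
        for _ in range(4):
            spec = CorruptionSpec(kind, {"radius": radius, "min_distance": 25.0}, seed)
            result, d = corrupt(mask, spec)
            if hd95(mask, result) > 15.0:
                return result, spec, d
            radius += 2.0  # larger blob → bigger share of the surface distances
        raise DataError("add_blob could not push HD95 beyond 15 mm")

    if kind == "truncate_axial":
        f_lo, f_hi = 0.02, 0.8
        for _ in range(25):
            f_mid = (f_lo + f_hi) / 2.0
            spec = CorruptionSpec(kind, {"fraction": f_mid}, seed)
            result, d = corrupt(mask, spec)
            if abs(d - target) < 0.02 or f_hi - f_lo < 1e-3:
                return result, spec, d
            if d > target:
                f_lo = f_mid
            else:
                f_hi = f_mid
        return result, spec, d

    if kind == "translate":
        rng = np.random.default_rng(seed)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        m_lo, m_hi = 1.0, 30.0
        best = None
        for _ in range(25):
            m_mid = (m_lo + m_hi) / 2.0
            offset = np.rint(direction * m_mid / np.asarray(mask.spacing)).astype(int)
            spec = CorruptionSpec(kind, {"offset": offset.tolist()}, seed)
            result, d = corrupt(mask, spec)
            best = (result, spec, d)
            if abs(d - target) < 0.02 or m_hi - m_lo < 0.5:
                return best
            if d > target:
                m_lo = m_mid
            else:
                m_hi = m_mid
        return best

    raise ConfigError(f"unknown corruption kind {kind!r}")


# ------------------------------------------------------------------ cohorts


def _draw_subject(base: MaskRecipe, modes, seed: int) -> BrainMask:
    """One clean subject: pick a population mode, then generate with jitter."""
    if modes:
        mode_rng = np.random.default_rng(seed + 2**31)
        semi_axes = tuple(modes[mode_rng.integers(len(modes))])
    else:
        semi_axes = base.semi_axes
    return generate_clean(replace(base, semi_axes=semi_axes, seed=seed))


def build_cohort(
    n_clean: int,
    n_corrupt: int,
    recipe: MaskRecipe | None = None,
    seed: int = 0,
    kinds: Sequence[str] = CORRUPTION_KINDS,
    dice_band: tuple[float, float] = (0.70, 0.90),
    modes: Sequence[tuple[float, float, float]] | None = POPULATION_MODES,
) -> tuple[list[BrainMask], pd.DataFrame, dict[str, BrainMask]]:
    """Build an in-memory cohort of clean and calibrated-corrupt masks.

    Each subject's base semi-axes are drawn from ``modes`` (pass ``None`` or
    ``()`` to use the recipe's own semi-axes throughout); the recipe supplies
    everything else. Returns ``(masks, manifest, sources)``: the masks in
    manifest order, a manifest with one row per mask (mask_id, category,
    corruption, source_id, dice, hd95, sanity_positive), and the clean source
    mask of every corrupt mask (keyed by mask_id) for evaluation-harness use.
    Deterministic per seed.
    """
    if n_clean < 1 or n_corrupt < 0:
        raise ConfigError("cohort needs at least one clean mask")
    base = recipe or MaskRecipe()
    rng = np.random.default_rng(seed)
    mask_seeds = rng.integers(0, 2**31 - 1, size=n_clean + n_corrupt)
    corr_seeds = rng.integers(0, 2**31 - 1, size=max(n_corrupt, 1))

    masks: list[BrainMask] = []
    rows = []
    sources: dict[str, BrainMask] = {}

    for i in range(n_clean):
        clean = _draw_subject(base, modes, int(mask_seeds[i]))
        clean = clean.with_voxels(clean.voxels, f"clean_{i:03d}")
        masks.append(clean)
        rows.append(
            {
                "mask_id": clean.identifier,
                "category": "clean",
                "corruption": "",
                "source_id": clean.identifier,
                "dice": 1.0,
                "hd95": 0.0,
                "sanity_positive": False,
            }
        )

    for j in range(n_corrupt):
        source = _draw_subject(base, modes, int(mask_seeds[n_clean + j]))
        kind = kinds[j % len(kinds)]
        bad, _, d = calibrate_corruption(source, kind, dice_band, int(corr_seeds[j]))
        h = hd95(source, bad)
        bad = bad.with_voxels(bad.voxels, f"corrupt_{j:03d}_{kind}")
        masks.append(bad)
        sources[bad.identifier] = source
        rows.append(
            {
                "mask_id": bad.identifier,
                "category": "corrupt",
                "corruption": kind,
                "source_id": source.identifier,
                "dice": d,
                "hd95": h,
                "sanity_positive": sanity_label(d, h),
            }
        )

    return masks, pd.DataFrame(rows), sources


def generate_cohort(
    out_dir,
    n_clean: int,
    n_corrupt: int,
    recipe: MaskRecipe | None = None,
    seed: int = 0,
    kinds: Sequence[str] = CORRUPTION_KINDS,
    dice_band: tuple[float, float] = (0.70, 0.90),
    modes: Sequence[tuple[float, float, float]] | None = POPULATION_MODES,
) -> pd.DataFrame:
    """Write a cohort as NIfTI files plus ``manifest.csv``; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    masks, manifest, _ = build_cohort(n_clean, n_corrupt, recipe, seed, kinds, dice_band, modes)
    for mask in masks:
        save_mask(mask, out_dir / f"{mask.identifier}.nii.gz")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
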