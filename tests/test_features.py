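"""Morphological feature extraction: moment oracle, unit examples, and the
translation/spacing invariances that any pure shape descriptor must satisfy."""

import numpy as np
import pytest

import maskqc as mq
from maskqc.features import (
    DEFAULT_FEATURES,
    FEATURE_CATALOGUE,
    FeatureVector,
    compute_central_moments,
    extract_features,
)

from .conftest import make_mask, random_blob_mask


def moments_oracle(mask):
    """Naive voxel-by-voxel sum of the second central moments (unit weights,
    physical coordinates)."""
    coords = np.argwhere(mask.voxels).astype(float) * np.asarray(mask.spacing)
    centroid = coords.mean(axis=0)
    M = np.zeros((3, 3))
    for p in coords:
        d = p - centroid
        M += np.outer(d, d)
    return M / len(coords)


class TestCentralMoments:
    def test_cube_has_equal_eigenvalues(self):
        cube = make_mask((14, 14, 14), fill=(slice(2, 12),) * 3)
        cm = compute_central_moments(cube)
        assert cm.eigenvalues == pytest.approx([cm.eigenvalues[0]] * 3, rel=1e-9)

    def test_single_voxel_zero_matrix(self):
        m = make_mask((5, 5, 5), fill=(slice(2, 3),) * 3)
        cm = compute_central_moments(m)
        assert np.allclose(cm.matrix, 0.0)
        assert cm.total_weight == 1.0

    def test_box_long_axis_alignment_and_oracle(self):
        box = make_mask((24, 14, 14), fill=(slice(2, 22), slice(2, 12), slice(2, 12)))
        cm = compute_central_moments(box)
        assert abs(cm.eigenvectors[:, 0] @ [1, 0, 0]) > 0.999
        expected = np.sort(np.linalg.eigvalsh(moments_oracle(box)))[::-1]
        assert cm.eigenvalues == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_sum_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, shape=(14, 12, 16), spacing=(1.0, 1.2, 0.7))
        cm = compute_central_moments(mask)
        assert cm.matrix == pytest.approx(moments_oracle(mask), rel=1e-9, abs=1e-12)

    def test_trace_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(7)
        mask = random_blob_mask(rng)
        cm = compute_central_moments(mask)
        assert np.trace(cm.matrix) == pytest.approx(cm.eigenvalues.sum(), rel=1e-9)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(3)
        cm = compute_central_moments(random_blob_mask(rng))
        assert cm.eigenvectors.T @ cm.eigenvectors == pytest.approx(np.eye(3), abs=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(mq.EmptyMaskError):
            compute_central_moments(mq.BrainMask(np.zeros((4, 4, 4)), (1, 1, 1)))


class TestExtractFeatures:
    def test_cube_counting_and_spacing_scaling(self):
        cube = make_mask((14, 14, 14), fill=(slice(2, 12),) * 3)
        fv = extract_features(cube).as_dict()
        assert fv["voxel_count"] == 1000
        assert fv["physical_size"] == pytest.approx(1000.0)
        fv2 = extract_features(make_mask((14, 14, 14), (2, 1, 1), (slice(2, 12),) * 3)).as_dict()
        assert fv2["physical_size"] == pytest.approx(2000.0)
        assert fv2["voxel_count"] == 1000

    def test_sphere_equivalent_radius(self):
        shape = (26, 26, 26)
        grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
        d2 = sum((g - 12.5) ** 2 for g in grids)
        sphere = mq.BrainMask(d2 <= 10.0**2, (1, 1, 1), "sphere")
        fv = extract_features(sphere).as_dict()
        assert fv["equivalent_spherical_radius"] == pytest.approx(10.0, rel=0.02)

    def test_default_list_has_23_features_in_fixed_order(self):
        assert len(DEFAULT_FEATURES) == 23
        assert len(set(DEFAULT_FEATURES)) == 23
        assert set(DEFAULT_FEATURES) < set(FEATURE_CATALOGUE)
        fv = extract_features(make_mask())
        assert fv.names == DEFAULT_FEATURES
        assert np.all(np.isfinite(fv.values))

    def test_unknown_feature_raises_config_error(self):
        with pytest.raises(mq.ConfigError):
            extract_features(make_mask(), ["physical_size", "texture_entropy"])

    def test_empty_mask_raises(self):
        with pytest.raises(mq.EmptyMaskError):
            extract_features(mq.BrainMask(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        mask = random_blob_mask(rng, shape=(24, 24, 24))
        shifted = mq.BrainMask(np.roll(mask.voxels, (2, -1, 3), axis=(0, 1, 2)), mask.spacing)
        a = extract_features(mask).as_dict()
        b = extract_features(shifted).as_dict()
        for name in DEFAULT_FEATURES:
            if name.startswith("centroid_offset"):
                continue
            assert a[name] == pytest.approx(b[name], rel=1e-9, abs=1e-9), name
        assert a["border_surface_area"] == 0.0

    def test_spacing_covariance(self):
        rng = np.random.default_rng(13)
        mask = random_blob_mask(rng)
        doubled = mq.BrainMask(mask.voxels, (2, 2, 2))
        a, b = extract_features(mask).as_dict(), extract_features(doubled).as_dict()
        assert b["physical_size"] == pytest.approx(8 * a["physical_size"], rel=1e-12)
        assert b["surface_area"] == pytest.approx(4 * a["surface_area"], rel=1e-12)
        assert b["equivalent_spherical_radius"] == pytest.approx(
            2 * a["equivalent_spherical_radius"], rel=1e-12
        )
        assert b["voxel_count"] == a["voxel_count"]

    def test_elongation_flatness_at_least_one(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            fv = extract_features(random_blob_mask(rng)).as_dict()
            assert fv["elongation"] >= 1.0
            assert fv["flatness"] >= 1.0

    def test_disconnected_blob_moves_features(self):
        # spurious far-away components must be visible, not filtered away
        base = make_mask((30, 30, 30), fill=(slice(4, 14),) * 3)
        vox = base.voxels.copy()
        vox[24:28, 24:28, 24:28] = True
        a = extract_features(base).as_dict()
        b = extract_features(mq.BrainMask(vox, base.spacing)).as_dict()
        assert b["feret_diameter"] > a["feret_diameter"]
        assert b["bbox_extent_x"] > a["bbox_extent_x"]


class TestAgainstSimpleITK:
    def test_principal_moments_match_simpleitk(self):
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(23)
        mask = random_blob_mask(rng, shape=(20, 18, 16), spacing=(1.0, 1.1, 0.9))
        img = sitk.GetImageFromArray(mask.voxels.astype(np.uint8))
        # numpy (x,y,z) axes map to SimpleITK (z,y,x) spacing order
        img.SetSpacing(tuple(float(s) for s in mask.spacing[::-1]))
        f = sitk.LabelShapeStatisticsImageFilter()
        f.Execute(img)
        reference = np.sort(np.asarray(f.GetPrincipalMoments(1)))[::-1]
        cm = compute_central_moments(mask)
        assert cm.eigenvalues == pytest.approx(reference, rel=1e-6)


class TestScaler:
    def test_two_point_population_convention(self):
        names = ("a", "b")
        vs = [FeatureVector(names, [0.0, 5.0]), FeatureVector(names, [2.0, 5.0])]
        scaler = mq.fit_scaler(vs)
        assert scaler.means == pytest.approx([1.0, 5.0])
        assert scaler.stds[0] == pytest.approx(1.0)  # population std of {0, 2}
        assert scaler.constant.tolist() == [False, True]
        assert mq.apply_scaler(scaler, vs[0]) == pytest.approx([-1.0, 0.0])

    def test_random_table_normalizes_exactly(self):
        rng = np.random.default_rng(29)
        names = tuple(f"f{i}" for i in range(23))
        vs = [FeatureVector(names, rng.normal(5, 3, 23)) for _ in range(50)]
        scaler = mq.fit_scaler(vs)
        Z = np.stack([mq.apply_scaler(scaler, v) for v in vs])
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.var(axis=0) - 1).max() < 1e-10

    def test_identity_and_one_sigma_vectors(self):
        rng = np.random.default_rng(31)
        names = ("a", "b", "c")
        vs = [FeatureVector(names, rng.normal(size=3)) for _ in range(10)]
        scaler = mq.fit_scaler(vs)
        at_mean = FeatureVector(names, scaler.means)
        assert mq.apply_scaler(scaler, at_mean) == pytest.approx([0, 0, 0], abs=1e-12)
        above = FeatureVector(names, scaler.means + scaler.stds)
        assert mq.apply_scaler(scaler, above) == pytest.approx([1, 1, 1])

    def test_too_few_vectors(self):
        with pytest.raises(mq.InsufficientDataError):
            mq.fit_scaler([FeatureVector(("a",), [1.0])])

    def test_feature_order_mismatch(self):
        scaler = mq.fit_scaler(
            [FeatureVector(("a", "b"), [0, 1]), FeatureVector(("a", "b"), [1, 0])]
        )
        with pytest.raises(mq.ConfigError):
            mq.apply_scaler(scaler, FeatureVector(("b", "a"), [0, 1]))
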