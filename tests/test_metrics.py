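"""Dice / HD95 evaluation harness, checked against brute-force oracles."""

import math

import numpy as np
import pytest

import maskqc as mq
from maskqc.metrics import EvalRecord, outcome_label, surface_voxels

from .conftest import make_mask, random_blob_mask


def hd95_oracle(a, b):
    """All-pairs surface-distance computation of the symmetric HD95."""
    spacing = np.asarray(a.spacing)
    pa = np.argwhere(surface_voxels(a.voxels)) * spacing
    pb = np.argwhere(surface_voxels(b.voxels)) * spacing
    dists = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return max(
        np.percentile(dists.min(axis=1), 95.0),
        np.percentile(dists.min(axis=0), 95.0),
    )


def make_sphere(shape, center, radius, spacing=(1, 1, 1)):
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij", sparse=True)
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return mq.BrainMask(d2 <= radius**2, spacing)


class TestDice:
    def test_identical_and_disjoint(self):
        a = make_mask()
        assert mq.dice(a, a) == 1.0
        b = mq.BrainMask(~a.voxels, a.spacing)
        assert mq.dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[0, 0, :] = True  # 10 voxels... build |A|=|B|=100, |A∩B|=50
        a = np.zeros((10, 10, 10), bool)
        a[:, :, 0] = True  # 100
        b = np.zeros((10, 10, 10), bool)
        b[:5, :, 0] = True
        b[:5, :, 1] = True  # 100, overlap 50
        assert mq.dice(mq.BrainMask(a, (1, 1, 1)), mq.BrainMask(b, (1, 1, 1))) == 0.5

    def test_empty_conventions(self):
        empty = mq.BrainMask(np.zeros((6, 6, 6)), (1, 1, 1))
        assert mq.dice(empty, empty) == 1.0
        assert mq.dice(empty, make_mask((6, 6, 6))) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = random_blob_mask(rng), random_blob_mask(rng)
        assert mq.dice(a, b) == mq.dice(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(mq.GridMismatchError):
            mq.dice(make_mask((8, 8, 8)), make_mask((10, 10, 10)))
        with pytest.raises(mq.GridMismatchError):
            mq.dice(make_mask(), make_mask(spacing=(2, 1, 1)))

    def test_erosion_monotonically_decreases_dice(self):
        from scipy import ndimage

        base = make_mask((20, 20, 20), fill=(slice(3, 17),) * 3)
        prev = 1.0
        vox = base.voxels
        for _ in range(4):
            vox = ndimage.binary_erosion(vox)
            d = mq.dice(base, mq.BrainMask(vox, base.spacing))
            assert d <= prev
            prev = d


class TestHD95:
    def test_identical_masks_zero(self):
        a = make_mask()
        assert mq.hd95(a, a) == 0.0

    def test_shifted_cube_matches_brute_force(self):
        cube = make_mask((12, 12, 12), fill=(slice(2, 10),) * 3)
        shifted = mq.BrainMask(np.roll(cube.voxels, 1, axis=0), cube.spacing)
        assert mq.hd95(cube, shifted) == pytest.approx(hd95_oracle(cube, shifted), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = random_blob_mask(rng, shape=(14, 14, 14), spacing=(1.0, 0.8, 1.3))
        b = random_blob_mask(rng, shape=(14, 14, 14), spacing=(1.0, 0.8, 1.3))
        assert mq.hd95(a, b) == pytest.approx(hd95_oracle(a, b), abs=1e-12)

    def test_concentric_spheres_near_shell_distance(self):
        shape = (26, 26, 26)
        inner = make_sphere(shape, (12.5,) * 3, 6.0)
        outer = make_sphere(shape, (12.5,) * 3, 10.0)
        assert mq.hd95(inner, outer) == pytest.approx(4.0, abs=1.0)

    def test_empty_mask_raises(self):
        with pytest.raises(mq.EmptyMaskError):
            mq.hd95(make_mask(), mq.BrainMask(np.zeros((12, 12, 12)), (1, 1, 1)))


class TestSanityAndConfusion:
    @pytest.mark.parametrize(
        "dice_v,hd_v,expected",
        [
            (0.96, 10.0, False),
            (0.90, 5.0, True),
            (0.99, 20.0, True),
            (0.95, 15.0, False),  # boundary values are acceptable (strict inequalities)
        ],
    )
    def test_sanity_rule(self, dice_v, hd_v, expected):
        assert mq.sanity_label(dice_v, hd_v) is expected

    def test_outcome_mapping(self):
        assert outcome_label(True, "fail") == "TP"
        assert outcome_label(True, "pass") == "FN"
        assert outcome_label(False, "fail") == "FP"
        assert outcome_label(False, "pass") == "TN"

    def _records(self, tp, fp, tn, fn):
        recs = []
        recs += [EvalRecord(f"tp{i}", 0.5, 20, True, "fail") for i in range(tp)]
        recs += [EvalRecord(f"fp{i}", 0.99, 1, False, "fail") for i in range(fp)]
        recs += [EvalRecord(f"tn{i}", 0.99, 1, False, "pass") for i in range(tn)]
        recs += [EvalRecord(f"fn{i}", 0.5, 20, True, "pass") for i in range(fn)]
        return recs

    def test_perfect_classifier(self):
        s = mq.confusion_summary(self._records(10, 0, 90, 0))
        assert (s.sensitivity, s.specificity, s.precision, s.accuracy) == (1, 1, 1, 1)

    def test_all_positives_missed(self):
        s = mq.confusion_summary(self._records(0, 0, 90, 10))
        assert s.sensitivity == 0.0
        assert s.accuracy == pytest.approx(0.9)
        assert math.isnan(s.precision)  # no predicted positives: undefined, not 0

    def test_mixed_ratios(self):
        s = mq.confusion_summary(self._records(95, 20, 80, 5))
        assert s.sensitivity == pytest.approx(0.95)
        assert s.specificity == pytest.approx(0.80)
        assert s.precision == pytest.approx(95 / 115)
        assert s.accuracy == pytest.approx(0.875)

    def test_empty_records_raise(self):
        with pytest.raises(mq.InsufficientDataError):
            mq.confusion_summary([])


class TestPassRateTable:
    def test_counts_pass_fractions_per_group(self):
        from maskqc.scoring import QCScore

        def score(verdict):
            return QCScore("x", 1, 1, 0.4, verdict)

        groups = {
            ("BET", "T1"): [score("pass")] * 5 + [score("fail")] * 5,
            ("HD-BET", "T1"): [score("pass")] * 4,
        }
        rates = mq.pass_rate_table(groups)
        assert rates[("BET", "T1")] == 0.5
        assert rates[("HD-BET", "T1")] == 1.0

    def test_error_rows_do_not_pass(self):
        from maskqc.scoring import QCScore

        scores = [QCScore.error_score("bad", "EmptyMaskError"), QCScore("ok", 1, 1, 0.2, "pass")]
        assert mq.pass_rate_table({"g": scores})["g"] == 0.5

    def test_empty_group_raises(self):
        with pytest.raises(mq.InsufficientDataError):
            mq.pass_rate_table({"g": []})
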