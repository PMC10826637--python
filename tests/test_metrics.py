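"""Segmentation metrics: Dice, density correlation, bundle distances.

The distance-transform implementation is cross-checked against an O(n^2)
all-pairs brute-force oracle, and the frozen worked-example mask pair
reproduces its closed-form values.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_bd
from tractod import metrics
from tractod.phantom import toy_mask_pair


class TestDsc:
    def test_worked_example(self):
        a, b = toy_mask_pair()
        assert int(a.sum()) == 13
        assert int(b.sum()) == 12
        assert int((a & b).sum()) == 4
        assert metrics.dsc(a, b) == pytest.approx(2 * 4 / (13 + 12))
        assert round(metrics.dsc(a, b), 2) == 0.32

    def test_identical_masks(self):
        a = np.zeros((3, 3, 3), bool)
        a[1, 1, 1] = True
        assert metrics.dsc(a, a) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        b[2, 2, 2] = True
        assert metrics.dsc(a, b) == 0.0

    def test_symmetric(self, rng):
        a = rng.random((4, 4, 4)) > 0.5
        b = rng.random((4, 4, 4)) > 0.5
        assert metrics.dsc(a, b) == metrics.dsc(b, a)

    def test_both_empty_rejected(self):
        z = np.zeros((2, 2, 2), bool)
        with pytest.raises(ValueError, match="empty"):
            metrics.dsc(z, z)


class TestBundleDistance:
    def test_worked_example_closed_form(self):
        a, b = toy_mask_pair()
        bd = metrics.bundle_distance(a, b)
        bds = metrics.signed_bundle_distance(a, b)
        assert bd == pytest.approx((14 + 4 * np.sqrt(2) + 3 * np.sqrt(5)) / 17, abs=1e-12)
        assert bds == pytest.approx((2 - 2 * np.sqrt(2) - np.sqrt(5)) / 17, abs=1e-12)
        assert round(bd, 2) == 1.55
        assert round(bds, 2) == -0.18

    def test_worked_example_matches_brute_force(self):
        a, b = toy_mask_pair()
        bd_o, bds_o = brute_force_bd(a, b)
        assert metrics.bundle_distance(a, b) == pytest.approx(bd_o, abs=1e-9)
        assert metrics.signed_bundle_distance(a, b) == pytest.approx(bds_o, abs=1e-9)

    def test_identical_masks_zero(self):
        a = np.zeros((3, 3, 3), bool)
        a[1] = True
        assert metrics.bundle_distance(a, a) == 0.0
        assert metrics.signed_bundle_distance(a, a) == 0.0

    def test_strict_subset_positive_signed(self):
        b = np.zeros((5, 5, 5), bool)
        b[1:4, 1:4, 1:4] = True
        a = np.zeros((5, 5, 5), bool)
        a[2, 2, 2] = True
        assert metrics.signed_bundle_distance(a, b) > 0

    def test_empty_mask_rejected(self):
        a = np.zeros((3, 3, 3), bool)
        b = a.copy()
        b[0, 0, 0] = True
        with pytest.raises(ValueError, match="empty"):
            metrics.bundle_distance(a, b)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_masks_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 7, size=3))
        a = rng.random(shape) > 0.6
        b = rng.random(shape) > 0.6
        if not (a.any() and b.any()):
            return
        spacing = rng.uniform(0.5, 3.0, size=3)  # anisotropic voxels
        bd_o, bds_o = brute_force_bd(a, b, spacing)
        assert metrics.bundle_distance(a, b, spacing) == pytest.approx(bd_o, abs=1e-9)
        assert metrics.signed_bundle_distance(a, b, spacing) == pytest.approx(
            bds_o, abs=1e-9
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_signed_magnitude_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) > 0.6
        b = rng.random((5, 5, 5)) > 0.6
        if not (a.any() and b.any()):
            return
        bd = metrics.bundle_distance(a, b)
        bds = metrics.signed_bundle_distance(a, b)
        assert abs(bds) <= bd + 1e-12
        assert bds + metrics.signed_bundle_distance(b, a) == pytest.approx(0, abs=1e-12)
        assert bd == pytest.approx(metrics.bundle_distance(b, a), abs=1e-12)

    def test_translation_invariance(self):
        a0, b0 = toy_mask_pair()
        a = np.zeros((10, 14, 3), bool)
        b = np.zeros((10, 14, 3), bool)
        a[2:8, 3:13, 1:2] = a0
        b[2:8, 3:13, 1:2] = b0
        assert metrics.dsc(a, b) == metrics.dsc(a0, b0)
        assert metrics.bundle_distance(a, b) == pytest.approx(
            metrics.bundle_distance(a0, b0), abs=1e-12
        )
        assert metrics.signed_bundle_distance(a, b) == pytest.approx(
            metrics.signed_bundle_distance(a0, b0), abs=1e-12
        )

    def test_millimetre_scaling(self):
        a, b = toy_mask_pair()
        bd1 = metrics.bundle_distance(a, b, spacing=1.0)
        bd2 = metrics.bundle_distance(a, b, spacing=2.3)
        assert bd2 == pytest.approx(2.3 * bd1, rel=1e-12)


class TestDensityCorrelation:
    def test_proportional_maps(self, rng):
        m = rng.random((4, 4, 4))
        m[m < 0.3] = 0
        assert metrics.density_correlation(m, 2 * m) == pytest.approx(1.0)

    def test_anticorrelated_maps(self, rng):
        m = rng.random((4, 4, 4)) + 0.1
        c = float(m.max()) + 0.2
        assert metrics.density_correlation(m, c - m) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        m1 = rng.random((5, 5, 5))
        m2 = rng.random((5, 5, 5))
        m1[m1 < 0.2] = 0
        support = (m1 != 0) | (m2 != 0)
        x, y = m1[support], m2[support]
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert metrics.density_correlation(m1, m2) == pytest.approx(expected, abs=1e-12)

    def test_constant_map_rejected(self):
        m = np.ones((3, 3, 3))
        with pytest.raises(ValueError, match="constant"):
            metrics.density_correlation(m, m)

    def test_negative_values_rejected(self):
        m = np.ones((3, 3, 3))
        bad = m.copy()
        bad[0, 0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            metrics.density_correlation(m, bad)


class TestCompareAll:
    def test_identical_inputs(self, rng):
        m = rng.random((4, 4, 4))
        m[m < 0.5] = 0
        r = metrics.compare_all(m, m, "mask", "mask")
        assert r.dsc == 1.0
        assert r.bd == 0.0
        assert r.bds == 0.0
        assert r.density_correlation == pytest.approx(1.0)
        assert r.n_symmetric_difference == 0

    def test_kind_thresholds_applied(self):
        density = np.zeros((3, 3, 3))
        density[0, 0, 0] = 10.0  # exactly at threshold: excluded (strict >)
        density[1, 1, 1] = 11.0
        other = np.zeros((3, 3, 3))
        other[1, 1, 1] = 1.0
        r = metrics.compare_all(density, other, "density", "mask")
        assert r.threshold_a == 10.0
        assert r.n_a == 1  # only the 11.0 voxel survives
        assert r.dsc == 1.0

    def test_subthreshold_map_error_names_threshold(self):
        weak = np.full((3, 3, 3), 0.04)
        other = np.zeros((3, 3, 3))
        other[0, 0, 0] = 1.0
        with pytest.raises(ValueError, match="0.05"):
            metrics.compare_all(weak, other, "tractmap", "mask")

    def test_counts_consistent(self, rng):
        a = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        r = metrics.compare_all(a, b, "probability", "probability")
        assert r.n_symmetric_difference == r.n_a + r.n_b - 2 * r.n_intersection

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown map kind"):
            metrics.compare_all(np.ones((2, 2, 2)), np.ones((2, 2, 2)), "bogus", "mask")
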