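import numpy as np
import pytest

from mtdnet import (METRICS, MTDFeature, ThresholdGrid, derivative_curve,
                    extract_mtd, fit_penalized_spline, fuse_features,
                    fused_block_slices, group_difference_test, roughness,
                    select_penalty_gcv)

GRID = ThresholdGrid(0.01, 0.35, 0.01).values


class TestPenalizedSpline:
    def test_interpolation_limit(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(35)
        fit = fit_penalized_spline(GRID, y, n_basis=35, penalty=0.0)
        assert np.sum((fit(GRID) - y) ** 2) < 1e-10

    def test_huge_penalty_tends_to_straight_line(self):
        y = np.sin(8 * GRID) + GRID
        fit = fit_penalized_spline(GRID, y, n_basis=12, penalty=1e8)
        assert roughness(fit) < 1e-6
        # derivative of a straight line is constant
        deriv = derivative_curve(fit, GRID)
        assert np.ptp(deriv) < 1e-3

    def test_quadratic_recovered_with_moderate_penalty(self):
        y = GRID ** 2
        fit = fit_penalized_spline(GRID, y, n_basis=10, penalty=1e-6)
        assert np.abs(fit(GRID) - y).max() < 1e-3

    def test_penalty_ladder_monotonicity(self):
        rng = np.random.default_rng(5)
        y = np.cos(10 * GRID) + 0.1 * rng.standard_normal(35)
        rough_vals, rss_vals = [], []
        for lam in [1e-8, 1e-6, 1e-4, 1e-2, 1.0, 1e2]:
            fit = fit_penalized_spline(GRID, y, n_basis=12, penalty=lam)
            rough_vals.append(roughness(fit))
            rss_vals.append(float(np.sum((fit(GRID) - y) ** 2)))
        assert np.all(np.diff(rough_vals) <= 1e-9)
        assert np.all(np.diff(rss_vals) >= -1e-9)

    def test_excess_basis_without_penalty_rejected(self):
        with pytest.raises(ValueError, match="raise the penalty|lower n_basis"):
            fit_penalized_spline(GRID, np.ones(35), n_basis=40, penalty=0.0)

    def test_gcv_prefers_smooth_fit_for_noisy_line(self):
        rng = np.random.default_rng(7)
        y = 2 * GRID + 0.05 * rng.standard_normal(35)
        lam = select_penalty_gcv(GRID, y, n_basis=12)
        assert lam > 1e-6  # pure interpolation would chase the noise


class TestDerivativeCurve:
    def test_linear_function(self):
        fit = fit_penalized_spline(GRID, 3 * GRID + 1, n_basis=8, penalty=0.0)
        assert np.abs(derivative_curve(fit, GRID) - 3).max() < 1e-6

    def test_constant_function(self):
        fit = fit_penalized_spline(GRID, np.full(35, 2.7), n_basis=8, penalty=0.0)
        assert np.abs(derivative_curve(fit, GRID)).max() < 1e-8

    def test_sine_derivative_matches_cosine(self):
        fit = fit_penalized_spline(GRID, np.sin(GRID), n_basis=10, penalty=0.0)
        interior = GRID[2:-2]
        assert np.abs(derivative_curve(fit, interior) - np.cos(interior)).max() < 1e-2

    def test_linearity_in_coefficients(self):
        from dataclasses import replace
        f1 = fit_penalized_spline(GRID, np.sin(5 * GRID), n_basis=10, penalty=1e-6)
        f2 = fit_penalized_spline(GRID, GRID ** 2, n_basis=10, penalty=1e-6)
        combo = replace(f1, coefficients=2 * f1.coefficients + 3 * f2.coefficients)
        expect = 2 * derivative_curve(f1, GRID) + 3 * derivative_curve(f2, GRID)
        assert np.allclose(derivative_curve(combo, GRID), expect, atol=1e-10)

    def test_evaluation_outside_domain_rejected(self):
        fit = fit_penalized_spline(GRID, np.ones(35), n_basis=8, penalty=1e-6)
        with pytest.raises(ValueError, match="domain"):
            derivative_curve(fit, np.array([0.5]))


class TestExtractMtd:
    def test_vector_lengths_match_grid(self, small_curves):
        curves, grid = small_curves
        mtd = extract_mtd(curves)
        for feats in mtd.values():
            for m in METRICS:
                assert feats[m].values.shape == (35,)

    def test_identical_curves_identical_features(self, small_curves):
        curves, _ = small_curves
        mtd1 = extract_mtd(curves)
        mtd2 = extract_mtd(list(reversed(curves)))
        for sid in mtd1:
            for m in METRICS:
                assert np.array_equal(mtd1[sid][m].values, mtd2[sid][m].values)

    def test_group_mean_mtd_curves_differ(self, small_cohort, small_curves):
        curves, _ = small_curves
        mtd = extract_mtd(curves)
        cc = {s.subject_id: mtd[s.subject_id]["cc"].values for s in small_cohort.subjects}
        pos = np.mean([cc[s.subject_id] for s in small_cohort.subjects
                       if s.label == "positive"], axis=0)
        ctl = np.mean([cc[s.subject_id] for s in small_cohort.subjects
                       if s.label == "control"], axis=0)
        assert np.abs(pos - ctl).max() > 0.1


class TestFuseFeatures:
    def _features(self, sid="s1"):
        grid = ThresholdGrid(0.01, 0.35, 0.01)
        return [MTDFeature(sid, m, np.full(35, i), grid)
                for i, m in enumerate(METRICS)]

    def test_concatenation_order_and_length(self):
        fused = fuse_features(self._features())
        assert fused.values.shape == (140,)
        blocks = fused_block_slices(ThresholdGrid(0.01, 0.35, 0.01))
        for i, m in enumerate(METRICS):
            assert np.all(fused.values[blocks[m]] == i)

    def test_permuted_order_rejected(self):
        feats = self._features()
        with pytest.raises(ValueError, match="ordered"):
            fuse_features(feats[::-1])

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError, match="exactly"):
            fuse_features(self._features()[:1])

    def test_mixed_subjects_rejected(self):
        feats = self._features()
        other = self._features("s2")
        with pytest.raises(ValueError, match="single subject"):
            fuse_features(feats[:3] + [other[3]])


class TestGroupDifference:
    def _feat(self, sid, values):
        grid = ThresholdGrid(0.01, 0.05, 0.01)
        return MTDFeature(sid, "cc", np.asarray(values, dtype=float), grid)

    def test_identical_samples_null(self):
        feats = [self._feat(f"s{i}", [1, 2, 3, 1, 2]) for i in range(6)]
        labels = ["positive"] * 3 + ["control"] * 3
        res = group_difference_test(feats, labels)
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(21)
        feats, labels = [], []
        for i in range(40):
            feats.append(self._feat(f"p{i}", 1.0 + 0.2 * rng.standard_normal(5)))
            labels.append("positive")
        for i in range(40):
            feats.append(self._feat(f"c{i}", 0.2 * rng.standard_normal(5)))
            labels.append("control")
        assert group_difference_test(feats, labels).p_value < 0.05

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(3)
        feats = [self._feat(f"s{i}", rng.standard_normal(5) + (i % 2)) for i in range(20)]
        labels = ["positive" if i % 2 else "control" for i in range(20)]
        swapped = ["control" if l == "positive" else "positive" for l in labels]
        a = group_difference_test(feats, labels)
        b = group_difference_test(feats, swapped)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_tiny_group_rejected(self):
        feats = [self._feat(f"s{i}", [1, 2, 3, 4, 5]) for i in range(3)]
        with pytest.raises(ValueError, match="2 subjects"):
            group_difference_test(feats, ["positive", "control", "control"])
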