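"""Crescent metrics, perimeter extraction, linescans, and group comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_profile, pulse_profile, render_and_quantify
from oracles import crescent_oracle, mann_whitney_exact_oracle

from epiorient import cortical, synthetic
from epiorient.types import CrescentTruth, LinescanProfile


class TestComputeCrescentMetrics:
    def test_rectangular_pulse_worked_example(self):
        # 21 samples of 50 AU at positions 40..60, threshold 20:
        # 20 unit intervals of (30+30)/2 trapezoids
        m = cortical.compute_crescent_metrics(pulse_profile(40, 60, 50.0), threshold=20)
        assert m.coverage == 20.0
        assert m.max_fi == 50.0
        assert m.position == 50.0
        assert m.integrated_fi == pytest.approx(600.0, abs=1e-12)

    def test_all_subthreshold_gives_empty_metrics(self):
        m = cortical.compute_crescent_metrics(make_profile(np.full(100, 5.0)), threshold=20)
        assert m.coverage == 0.0 and m.integrated_fi == 0.0 and m.position is None

    def test_background_subtraction_applied_when_flagged_unsubtracted(self):
        v = np.zeros(100)
        v[40:61] = 70.0
        prof = make_profile(v + 20.0, background=20.0, subtracted=False)
        m = cortical.compute_crescent_metrics(prof, threshold=20)
        assert m.integrated_fi == pytest.approx(1000.0)
        assert m.max_fi == pytest.approx(70.0)

    def test_wraparound_run_crosses_seam(self):
        # basal crescent spanning 90..10 through the 0/100 seam
        m = cortical.compute_crescent_metrics(pulse_profile(90, 110, 50.0), threshold=20)
        assert m.coverage == 20.0
        assert m.position == 0.0
        assert m.integrated_fi == pytest.approx(600.0)

    def test_rotation_equivariance(self, rng):
        v = rng.uniform(0, 60, 100)
        base = cortical.compute_crescent_metrics(make_profile(v), threshold=20)
        for k in (1, 17, 50, 99):
            m = cortical.compute_crescent_metrics(make_profile(np.roll(v, k)), threshold=20)
            assert m.coverage == pytest.approx(base.coverage)
            assert m.max_fi == pytest.approx(base.max_fi)
            assert m.integrated_fi == pytest.approx(base.integrated_fi)
            if base.position is not None:
                assert m.position == pytest.approx((base.position + k) % 100.0)

    def test_matches_brute_force_oracle_on_random_profiles(self, rng):
        for _ in range(1000):
            v = rng.choice(
                [rng.uniform(0, 40, 100), rng.uniform(10, 30, 100), rng.normal(20, 15, 100)]
            )
            m = cortical.compute_crescent_metrics(make_profile(v), threshold=20)
            cov, integ, pos = crescent_oracle(v, 20)
            assert m.coverage == pytest.approx(cov, abs=1e-9)
            assert m.integrated_fi == pytest.approx(integ, rel=1e-9, abs=1e-9)
            if pos is None:
                assert m.position is None
            else:
                assert m.position == pytest.approx(pos, abs=1e-9)

    @given(st.lists(st.floats(0, 100), min_size=100, max_size=100),
           st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_coverage_monotone_in_threshold_adversarially(self, values, t1, t2):
        # every supra-threshold run shrinks as the threshold rises, so the
        # longest-run span can never grow — holds for arbitrary profiles
        lo, hi = sorted((t1, t2))
        prof = make_profile(values)
        m_lo = cortical.compute_crescent_metrics(prof, threshold=lo)
        m_hi = cortical.compute_crescent_metrics(prof, threshold=hi)
        assert m_hi.coverage <= m_lo.coverage + 1e-9

    def test_auc_monotone_in_threshold_on_crescent_profiles(self, rng):
        # for single-crescent profiles the longest run nests as the threshold
        # rises, so the trapezoid AUC is monotone as well (multi-island
        # pathologies where the longest run switches identity are excluded:
        # see the methods note)
        for _ in range(200):
            center = rng.uniform(0, 100)
            cov = rng.uniform(10, 60)
            amp = rng.uniform(30, 100)
            d = np.abs((np.arange(100.0) - center + 50) % 100 - 50)
            v = amp * 0.5 * (1 + np.cos(np.pi * np.minimum(d / (cov / 2), 1.0))) \
                + rng.normal(0, 2, 100)
            prof = make_profile(v)
            prev_cov, prev_auc = np.inf, np.inf
            for t in (10.0, 20.0, 30.0):
                m = cortical.compute_crescent_metrics(prof, threshold=t)
                assert m.coverage <= prev_cov + 1e-9
                assert m.integrated_fi <= prev_auc + 1e-9
                prev_cov, prev_auc = m.coverage, m.integrated_fi

    @given(st.lists(st.floats(-10, 80), min_size=100, max_size=100))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_coverage_threshold_consistency(self, values):
        m = cortical.compute_crescent_metrics(make_profile(values), threshold=20)
        if m.coverage > 0:
            assert m.max_fi > 20
        if m.max_fi <= 20:
            assert m.coverage == 0

    def test_nonfinite_intensities_rejected(self):
        v = np.zeros(100)
        v[3] = np.nan
        with pytest.raises(ValueError, match="3"):
            LinescanProfile(intensities=v)


class TestPerimeterAndLinescan:
    def test_circle_start_is_basal_and_apex_is_top(self, circle_geom):
        from skimage.draw import polygon as draw_polygon

        h, w = circle_geom.image_shape
        mask = np.zeros((h, w), bool)
        rr, cc = draw_polygon(circle_geom.boundary[:, 0], circle_geom.boundary[:, 1], (h, w))
        mask[rr, cc] = True
        contour = cortical.extract_perimeter(mask, circle_geom.basement_line)
        start = contour.points[0]
        assert start[0] == pytest.approx(mask.nonzero()[0].max(), abs=1.0)  # lowest point
        top = contour.point_at(50.0)[0]
        assert top[0] == pytest.approx(mask.nonzero()[0].min(), abs=1.0)  # topmost point
        # closure: position 100 returns to the start
        assert np.allclose(contour.point_at(100.0)[0], contour.points[0], atol=1e-9)

    def test_square_contour_length(self):
        mask = np.zeros((64, 64), bool)
        mask[10:41, 10:41] = True  # 31-px side
        contour = cortical.extract_perimeter(mask, ((63.0, 0.0), (63.0, 63.0)))
        assert contour.total_length == pytest.approx(4 * 31, rel=0.05)

    def test_multiple_or_zero_regions_rejected(self):
        mask = np.zeros((32, 32), bool)
        with pytest.raises(ValueError, match="0"):
            cortical.extract_perimeter(mask, ((31.0, 0.0), (31.0, 31.0)))
        mask[2:8, 2:8] = True
        mask[20:26, 20:26] = True
        with pytest.raises(ValueError, match="2"):
            cortical.extract_perimeter(mask, ((31.0, 0.0), (31.0, 31.0)))

    def test_uniform_image_linescan_constant(self, circle_geom):
        from skimage.draw import polygon as draw_polygon

        h, w = circle_geom.image_shape
        mask = np.zeros((h, w), bool)
        rr, cc = draw_polygon(circle_geom.boundary[:, 0], circle_geom.boundary[:, 1], (h, w))
        mask[rr, cc] = True
        contour = cortical.extract_perimeter(mask, circle_geom.basement_line)
        prof = cortical.sample_linescan(np.full((h, w), 7.5), contour)
        assert np.allclose(prof.intensities, 7.5)

    def test_rect_crescent_linescan_levels(self, circle_geom):
        truth = CrescentTruth(center_position=50, coverage=20, amplitude=50,
                              background=10, noise_sd=0)
        img, mask, _ = synthetic.generate_cell_image(circle_geom, truth, seed=0, window="rect")
        contour = cortical.extract_perimeter(mask, circle_geom.basement_line)
        prof = cortical.sample_linescan(img, contour)
        inside = prof.intensities[43:58]  # comfortably inside the window
        outside = np.concatenate([prof.intensities[:35], prof.intensities[65:]])
        # disk means at rasterized contour points include a few unpainted
        # out-of-band pixels, so allow ~5% dilution
        assert np.allclose(inside, 60.0, atol=3.0)
        assert np.allclose(outside, 10.0, atol=1.0)

    def test_refinement_consistency_50_vs_100_points(self, circle_geom):
        truth = CrescentTruth(center_position=50, coverage=40, amplitude=60,
                              background=10, noise_sd=0)
        img, mask, _ = synthetic.generate_cell_image(circle_geom, truth, seed=0)
        contour = cortical.extract_perimeter(mask, circle_geom.basement_line)
        m100 = cortical.compute_crescent_metrics(
            cortical.sample_linescan(img, contour, n_points=100, boundary_mask=mask))
        m50 = cortical.compute_crescent_metrics(
            cortical.sample_linescan(img, contour, n_points=50, boundary_mask=mask))
        assert m50.coverage == pytest.approx(m100.coverage, rel=0.05)
        assert m50.integrated_fi == pytest.approx(m100.integrated_fi, rel=0.05)
        assert m50.max_fi == pytest.approx(m100.max_fi, rel=0.05)


class TestBackground:
    def test_uniform_image(self):
        mask = np.zeros((40, 40), bool)
        mask[5:35, 5:35] = True
        assert cortical.estimate_background(np.full((40, 40), 3.0), mask) == 3.0

    def test_noiseless_synthetic_cell_exact(self, circle_geom):
        truth = CrescentTruth(center_position=50, coverage=30, amplitude=80,
                              background=12, noise_sd=0)
        img, mask, _ = synthetic.generate_cell_image(circle_geom, truth, seed=0)
        assert cortical.estimate_background(img, mask, cortical_band=6.0) == pytest.approx(12.0)

    def test_noisy_estimate_near_truth(self, circle_geom):
        # CLT: thousands of interior pixels, sd 5 -> error well under 1 AU
        errs = []
        for seed in range(5):
            truth = CrescentTruth(center_position=50, coverage=30, amplitude=80,
                                  background=12, noise_sd=5)
            img, mask, _ = synthetic.generate_cell_image(circle_geom, truth, seed=seed)
            errs.append(cortical.estimate_background(img, mask, cortical_band=6.0) - 12.0)
        assert abs(np.mean(errs)) < 1.0

    def test_band_too_wide_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        with pytest.raises(ValueError, match="smaller band"):
            cortical.estimate_background(np.ones((20, 20)), mask, cortical_band=10.0)


class TestClassifyLocalization:
    def test_rule_table(self):
        def mk(coverage, position):
            return cortical.CrescentMetrics(max_fi=50, integrated_fi=10 if coverage else 0,
                                            coverage=coverage, position=position, threshold=20)

        assert cortical.classify_localization(mk(0, None)) == "absent"
        assert cortical.classify_localization(mk(30, 50)) == "apical"
        assert cortical.classify_localization(mk(70, 50)) == "unpolarized"
        assert cortical.classify_localization(mk(30, 10)) == "nonapical_polarized"
        assert cortical.classify_localization(mk(30, 10), collapse=True) == "unpolarized"

    def test_recovery_confusion_on_synthetic_population(self, circle_geom, rng):
        # truth-driven labels: apical crescents (center near 50) vs absent cells
        wrong = 0
        n = 40
        for i in range(n):
            if i % 4 == 0:
                truth = CrescentTruth(center_position=50, coverage=0, amplitude=0,
                                      background=12, noise_sd=3)
                expected = "absent"
            else:
                truth = CrescentTruth(center_position=float(rng.uniform(35, 65)),
                                      coverage=float(rng.uniform(15, 50)),
                                      amplitude=float(rng.uniform(40, 100)),
                                      background=12, noise_sd=4)
                expected = "apical"
            m = render_and_quantify(circle_geom, truth, seed=100 + i, window="rect")
            if cortical.classify_localization(m) != expected:
                wrong += 1
        assert wrong / n <= 0.05


class TestAggregateMeanProfile:
    def test_constant_profiles(self):
        profs = [make_profile(np.full(100, 4.0)) for _ in range(5)]
        agg = cortical.aggregate_mean_profile(profs)
        assert np.allclose(agg["mean"], 4.0)
        assert np.allclose(agg["ci_high"] - agg["ci_low"], 0.0)

    def test_single_profile_ci_undefined(self):
        agg = cortical.aggregate_mean_profile([make_profile(np.arange(100.0))])
        assert np.allclose(agg["mean"], np.arange(100.0))
        assert agg["ci_low"].isna().all()

    def test_t_interval_covers_truth_curve(self, rng):
        truth_curve = 30 * np.exp(-((np.arange(100) - 50) ** 2) / 200.0)
        profs = [make_profile(truth_curve + rng.normal(0, 5, 100)) for _ in range(1000)]
        agg = cortical.aggregate_mean_profile(profs)
        covered = ((agg["ci_low"] <= truth_curve) & (truth_curve <= agg["ci_high"])).mean()
        assert covered >= 0.94


class TestMannWhitney:
    def test_identical_groups_exact_p_is_one(self):
        _, p = cortical.mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4], method="exact")
        assert p == 1.0

    def test_complete_separation_5v5(self):
        _, p = cortical.mann_whitney_u([10, 11, 12, 13, 14], [1, 2, 3, 4, 5], method="exact")
        assert p == pytest.approx(2 / 252)

    def test_exact_matches_enumeration_oracle_small_n(self, rng):
        for _ in range(30):
            na, nb = rng.integers(2, 7, 2)
            x = rng.integers(0, 6, na).astype(float)  # ties likely
            y = rng.integers(0, 6, nb).astype(float)
            _, p = cortical.mann_whitney_u(x, y, method="exact")
            assert p == pytest.approx(mann_whitney_exact_oracle(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_8v8(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            _, p_ex = cortical.mann_whitney_u(x, y, method="exact")
            _, p_as = cortical.mann_whitney_u(x, y, method="asymptotic")
            assert abs(p_ex - p_as) < 0.02


class TestThresholdSensitivity:
    def test_identical_groups_p_one(self):
        profs = [pulse_profile(40, 60, 50.0) for _ in range(4)]
        out = cortical.threshold_sensitivity(profs, list(profs), thresholds=[10, 20, 30])
        assert (out["p"] == 1.0).all()

    def test_separated_groups_small_p_and_monotone_auc(self, rng):
        strong = [pulse_profile(40, 60, 80.0 + rng.uniform(0, 2)) for _ in range(6)]
        weak = [pulse_profile(40, 60, 25.0 + rng.uniform(0, 2)) for _ in range(6)]
        out = cortical.threshold_sensitivity(strong, weak, thresholds=[10, 20])
        assert (out["p"] < 0.05).all()
        assert out["n_a"].tolist() == [6, 6]
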