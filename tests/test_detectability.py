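"""Task function, NPS correction, d' quadrature and SPF."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from ctiq import (FlatNPS, FrequencyCurve, GaussianMTF, SyntheticTruth,
                  TaskSpec, correct_nps, correction_factor,
                  detectability_index, generate_axial_stack, measure_delta_hu,
                  system_performance, task_function)


def j1_series(x, terms=40):
    """First-order Bessel function by its power series (independent oracle)."""
    total = 0.0
    for k in range(terms):
        total += ((-1) ** k / (math.factorial(k) *
                               math.factorial(k + 1))) * (x / 2) ** (2 * k + 1)
    return total


def flat_grid(f_max=20.0, n=4000):
    f = np.linspace(0.0, f_max, n)
    return FrequencyCurve(f, np.ones_like(f))


class TestCorrectionFactor:
    @pytest.mark.parametrize("ref,other,expected", [
        (1.26, 1.43, 1.13), (1.27, 1.68, 1.32), (1.43, 1.80, 1.26)])
    def test_reference_vs_thicker_slice_ratios(self, ref, other, expected):
        """Thicker-slice system's NPS scaled up: published 40 keV ratios."""
        from ctiq import round_half_up
        assert round_half_up(correction_factor(ref, other), 2) == expected

    def test_identity_when_equal(self):
        assert correction_factor(1.3, 1.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            correction_factor(0.0, 1.3)

    def test_correct_nps_scales_parseval_sum_linearly(self):
        curve = FrequencyCurve(np.linspace(0.01, 0.8, 60),
                               np.linspace(5.0, 1.0, 60))
        scaled = correct_nps(curve, 1.32)
        assert np.trapezoid(scaled.values, scaled.f) == pytest.approx(
            1.32 * np.trapezoid(curve.values, curve.f))


class TestTaskFunction:
    def test_zero_frequency_limit(self):
        """W(0) = pi/4 |dHU| d^2; for dHU=1, d=2 that is pi."""
        w = task_function(np.array([0.0]), TaskSpec(2.0, 1.0))
        assert w.values[0] == pytest.approx(np.pi, abs=1e-12)

    def test_first_zero_at_bessel_root(self):
        """First null at f = 3.8317/(pi d): bracketing-root oracle, d=5."""
        task = TaskSpec(5.0, 100.0)
        wf = lambda f: task_function(np.array([f]), task).values[0]
        root = brentq(wf, 0.15, 0.30, xtol=1e-10)
        assert root == pytest.approx(3.8317059702 / (np.pi * 5.0), abs=1e-6)

    @given(st.floats(0.01, 0.6), st.floats(1.0, 10.0), st.floats(1.0, 500.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_series_expansion(self, f, d, dhu):
        """W(f) agrees with an independent series J1 to 1e-8 relative.

        Arguments are kept below pi*d*f ~ 19 where the alternating power
        series is still numerically well conditioned.
        """
        w = task_function(np.array([f]), TaskSpec(d, dhu)).values[0]
        x = np.pi * d * f
        expected = (np.pi / 2) * dhu * d ** 2 * j1_series(x) / x
        assert w == pytest.approx(expected, rel=1e-8, abs=1e-10)


class TestMeasureDeltaHu:
    def test_noiseless_contrast_recovered(self, sharp_rod_stack):
        cx, cy = sharp_rod_stack.center_mm
        dhu = measure_delta_hu(sharp_rod_stack, (cx + 50, cy), (cx, cy),
                               rod_diameter_mm=30.0)
        assert dhu == pytest.approx(300.0, abs=0.1)

    def test_identical_rois_give_zero(self, sharp_rod_stack):
        cx, cy = sharp_rod_stack.center_mm
        assert measure_delta_hu(sharp_rod_stack, (cx, cy), (cx, cy)) == 0.0

    def test_roi_overlapping_rod_edge_rejected(self, sharp_rod_stack):
        cx, cy = sharp_rod_stack.center_mm
        with pytest.raises(ValueError, match="edge"):
            measure_delta_hu(sharp_rod_stack, (cx + 50, cy), (cx, cy),
                             roi_px=60, rod_diameter_mm=30.0)

    def test_estimator_noise_shrinks_with_slices_and_area(self, two_rod_spec):
        """sd of dHU over seeds ~ noise/sqrt(n_slices * 25^2 * 2)."""
        n0 = 343.0
        vals = []
        for seed in range(12):
            stack = generate_axial_stack(
                two_rod_spec, SyntheticTruth(nps_model=FlatNPS(n0), seed=seed),
                n_slices=4)
            cx, cy = stack.center_mm
            vals.append(measure_delta_hu(stack, (cx + 50, cy), (cx, cy),
                                         n_slices=4))
        pix_sd = np.sqrt(n0) / (300.0 / 512.0)
        expected = pix_sd * np.sqrt(2.0 / (4 * 25 * 25))
        assert np.std(vals) < 3.0 * expected
        assert np.mean(vals) == pytest.approx(300.0, abs=3.0 * expected)


class TestDetectabilityIndex:
    def test_closed_form_flat_case(self):
        """TTF=1, flat NPS: d' = |dHU| (d/2) sqrt(pi/N0) within 0.5%."""
        res = detectability_index(flat_grid(), flat_grid(), TaskSpec(2.0, 1.0),
                                  n_grid=512)
        assert res.d_prime == pytest.approx(np.sqrt(np.pi), rel=0.005)

    def test_closed_form_against_brute_force_quadrature(self):
        """Default 512-point trapezoid over the measurement band agrees
        with a 100x finer quadrature of the same integral."""
        task = TaskSpec(5.0, 100.0)
        coarse = detectability_index(flat_grid(), flat_grid(), task,
                                     f_max=0.853, n_grid=512)
        fine = detectability_index(flat_grid(), flat_grid(), task,
                                   f_max=0.853, n_grid=50001)
        assert coarse.d_prime == pytest.approx(fine.d_prime, rel=0.005)

    def test_zero_contrast_zero_dprime(self):
        res = detectability_index(flat_grid(), flat_grid(), TaskSpec(5.0, 0.0))
        assert res.d_prime == 0.0

    @given(st.floats(0.5, 400.0))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_linear_in_contrast(self, dhu):
        base = detectability_index(flat_grid(5.0, 800), flat_grid(5.0, 800),
                                   TaskSpec(5.0, 1.0)).d_prime
        res = detectability_index(flat_grid(5.0, 800), flat_grid(5.0, 800),
                                  TaskSpec(5.0, dhu)).d_prime
        assert res == pytest.approx(dhu * base, rel=1e-9)

    @given(st.floats(0.2, 8.0))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_nps_scaling_law(self, k):
        """NPS -> k NPS divides d' by sqrt(k) exactly."""
        t = flat_grid(5.0, 800)
        task = TaskSpec(5.0, 100.0)
        base = detectability_index(t, t, task).d_prime
        res = detectability_index(t, t.scaled(k), task).d_prime
        assert res == pytest.approx(base / np.sqrt(k), rel=1e-9)

    def test_correction_factor_above_one_lowers_dprime(self):
        t = flat_grid(5.0, 800)
        task = TaskSpec(5.0, 100.0)
        base = detectability_index(t, t, task).d_prime
        corr = detectability_index(t, t, task, correction=1.32).d_prime
        assert corr < base
        assert corr == pytest.approx(base / np.sqrt(1.32), rel=1e-9)

    def test_nonpositive_nps_rejected(self):
        f = np.linspace(0.0, 1.0, 64)
        nps = FrequencyCurve(f, np.linspace(1.0, -0.1, 64))
        with pytest.raises(ValueError, match="positive"):
            detectability_index(flat_grid(1.0, 64), nps, TaskSpec(5.0, 100.0))

    def test_f_max_beyond_curves_rejected(self):
        with pytest.raises(ValueError, match="f_max"):
            detectability_index(flat_grid(1.0), flat_grid(1.0),
                                TaskSpec(5.0, 100.0), f_max=2.0)


class TestSystemPerformance:
    def test_unit_curves_give_unit_spf(self):
        spf, spf2 = system_performance(flat_grid(1.0, 128), flat_grid(1.0, 128))
        assert np.allclose(spf.values, 1.0)
        assert np.allclose(spf2.values, 1.0)

    def test_spf_scales_inversely_with_nps(self):
        t = flat_grid(1.0, 128)
        spf_a, _ = system_performance(t, t)
        spf_b, _ = system_performance(t, t.scaled(4.0))
        assert np.allclose(spf_b.values, spf_a.values / 4.0)

    def test_spf2_is_square_binwise(self):
        f = np.linspace(0.0, 1.0, 128)
        ttf = FrequencyCurve(f, np.exp(-f))
        nps = FrequencyCurve(f, 1.0 + f)
        spf, spf2 = system_performance(ttf, nps)
        assert np.allclose(spf2.values, spf.values ** 2)

    def test_recovered_spf_tracks_truth_spf(self, two_rod_spec):
        """End to end: SPF from estimates vs SPF from the generator truths."""
        from ctiq import NPSEstimator, RampLowpassNPS, TTFEstimator, average_repeats
        mtf, nps_model = GaussianMTF(0.41), RampLowpassNPS(600.0, 0.22)
        stacks = [generate_axial_stack(
            two_rod_spec,
            SyntheticTruth(mtf_model=mtf, nps_model=nps_model, seed=k),
            n_slices=1) for k in range(32)]
        avg = average_repeats(stacks)
        ttf_est = TTFEstimator(
            approx_center_mm=(avg.center_mm[0] + 50, avg.center_mm[1])).fit(avg)
        water = generate_axial_stack(
            two_rod_spec, SyntheticTruth(mtf_model=mtf, nps_model=nps_model,
                                         seed=99),
            n_slices=40, mode="water_section")
        nps_est = NPSEstimator(detrend="mean", taper="hann").fit(water)
        spf, _ = system_performance(ttf_est.result_, nps_est.radial_)
        sel = (spf.f > 0.05) & (spf.f < 0.6 * 0.853)
        truth_spf = mtf(spf.f[sel]) ** 2 / nps_model(spf.f[sel])
        assert np.abs(spf.values[sel] / truth_spf - 1.0).max() < 0.12
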