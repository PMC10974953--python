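"""Wavelet decomposition and the energy-ratio adaptive threshold rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echovol import (
    SampledSignal,
    adaptive_threshold,
    add_white_noise,
    build_threshold_plan,
    denoise_signal,
    hard_threshold,
    noise_sigma,
    snr_db,
    soft_threshold,
    softness_exponent,
)
from echovol.denoise import ThresholdPlan, max_decomposition_levels
from echovol.exceptions import InvalidArgumentError


class TestNoiseSigma:
    def test_constant_coefficients_give_zero(self):
        assert noise_sigma([3.0, 3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed_bessel_case(self):
        # mean 0, sum of squares 4, n-1 = 3
        sigma = noise_sigma([1.0, -1.0, 1.0, -1.0])
        assert sigma == pytest.approx(math.sqrt(4.0 / 3.0))
        assert 3.0 * sigma == pytest.approx(3.4641, abs=1e-4)

    def test_matches_population_sigma_for_large_samples(self, rng):
        sigma = noise_sigma(rng.standard_normal(10_000))
        assert sigma == pytest.approx(1.0, abs=0.03)

    def test_too_few_coefficients_rejected(self):
        with pytest.raises(InvalidArgumentError):
            noise_sigma([1.0])


class TestSoftnessExponent:
    @pytest.mark.parametrize("en,ed,expected", [
        (1.0, 1.0, 11.0), (0.0, 1.0, 1.0), (0.5, 1.0, 6.0),
    ])
    def test_formula(self, en, ed, expected):
        assert softness_exponent(en, ed) == pytest.approx(expected)

    def test_zero_signal_energy_rejected(self):
        with pytest.raises(InvalidArgumentError):
            softness_exponent(1.0, 0.0)


class TestClassicThresholds:
    def test_hard_keep_or_kill(self):
        assert hard_threshold(2.0, 1.0) == 2.0
        assert hard_threshold(0.5, 1.0) == 0.0
        assert hard_threshold(-2.0, 1.0) == -2.0

    def test_soft_shrinks_by_lambda(self):
        assert soft_threshold(2.0, 1.0) == pytest.approx(1.0)
        assert soft_threshold(-2.0, 1.0) == pytest.approx(-1.0)
        assert soft_threshold(0.5, 1.0) == 0.0
        # constant bias for large coefficients
        assert soft_threshold(100.0, 1.0) == pytest.approx(99.0)

    def test_nonpositive_lambda_rejected(self):
        for fn in (hard_threshold, soft_threshold):
            with pytest.raises(InvalidArgumentError):
                fn(1.0, 0.0)


class TestAdaptiveThreshold:
    def test_zero_maps_to_zero(self):
        assert adaptive_threshold(0.0, 1.0, 10, 2.0) == 0.0

    def test_connection_value_beta_2_is_three_quarters_lambda(self):
        for lam in (0.5, 1.0, 3.0):
            assert adaptive_threshold(lam, lam, 2, 2.0) == pytest.approx(0.75 * lam)

    @pytest.mark.parametrize("beta", [2, 3, 5, 10, 50])
    def test_both_branches_agree_at_lambda(self, beta):
        lam, m = 1.0, 2.0
        expected = lam * (beta + 1) / (2 * beta)
        below = adaptive_threshold(lam * (1 - 1e-10), lam, beta, m)
        above = adaptive_threshold(lam * (1 + 1e-10), lam, beta, m)
        assert below == pytest.approx(expected, abs=1e-9)
        assert above == pytest.approx(expected, abs=1e-9)

    def test_connection_value_tends_to_half_lambda_for_large_beta(self):
        assert adaptive_threshold(1.0, 1.0, 1000, 2.0) == pytest.approx(0.5, abs=1e-3)

    def test_asymptotically_unbiased(self):
        d = 100.0
        t = adaptive_threshold(d, 1.0, 10, 2.0)
        assert abs(t - d) < 0.006

    @settings(derandomize=True, max_examples=60)
    @given(
        d=st.floats(-50.0, 50.0),
        lam=st.floats(0.1, 5.0),
        beta=st.integers(2, 10),
        m=st.floats(1.0, 50.0),
    )
    def test_odd_and_shrinking(self, d, lam, beta, m):
        t = adaptive_threshold(d, lam, beta, m)
        t_neg = adaptive_threshold(-d, lam, beta, m)
        assert t_neg == pytest.approx(-t, abs=1e-12)
        assert abs(t) <= abs(d) + 1e-12

    @pytest.mark.parametrize("beta", [2, 5, 10])
    @pytest.mark.parametrize("m", [1.0, 2.0, 10.0, 50.0])
    def test_monotone_on_dense_grid(self, beta, m):
        d = np.linspace(-6.0, 6.0, 4001)
        t = adaptive_threshold(d, 1.0, beta, m)
        assert np.all(np.diff(t) >= -1e-10)


class TestThresholdPlan:
    def test_mismatched_array_lengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ThresholdPlan(n_levels=3, lambdas=[1.0, 1.0],
                          softness_m=[1.0, 1.0, 1.0], sigmas=[1, 1])

    def test_depth_limit_enforced(self, benchmark_echo_signal):
        too_deep = max_decomposition_levels(len(benchmark_echo_signal)) + 1
        with pytest.raises(InvalidArgumentError):
            build_threshold_plan(benchmark_echo_signal, benchmark_echo_signal,
                                 n_levels=too_deep)

    def test_zero_reference_noise_gives_identity_plan(self, benchmark_echo_signal):
        silent = benchmark_echo_signal.copy_with(np.zeros(len(benchmark_echo_signal)))
        plan = build_threshold_plan(benchmark_echo_signal, silent)
        assert np.all(plan.lambdas == 0.0)
        assert np.all(plan.softness_m == 1.0)
        out = denoise_signal(benchmark_echo_signal, plan, mode="adaptive")
        np.testing.assert_allclose(out.samples, benchmark_echo_signal.samples,
                                   atol=1e-10)

    def test_lambda_is_three_sigma_of_reference_details(self, benchmark_echo_signal):
        noisy, ref = add_white_noise(benchmark_echo_signal, 5.0, seed=0)
        plan = build_threshold_plan(noisy, ref)
        np.testing.assert_allclose(plan.lambdas, 3.0 * plan.sigmas)
        assert np.all(plan.softness_m >= 1.0)

    def test_softness_smallest_in_signal_band(self, benchmark_echo_signal):
        # a 1 MHz echo at fs 10 MHz concentrates in the level-3 detail
        # band (0.625-1.25 MHz): that level is signal-dominated and gets
        # the softest rule, while the noise-dominated finest level is
        # shrunk much harder
        noisy, ref = add_white_noise(benchmark_echo_signal, 5.0, seed=3)
        plan = build_threshold_plan(noisy, ref)
        assert np.argmin(plan.softness_m) == 2
        assert plan.softness_m[0] > 2.0 * plan.softness_m[2]

    def test_length_mismatch_rejected(self, benchmark_echo_signal):
        short = SampledSignal(np.zeros(100), benchmark_echo_signal.sampling_rate)
        with pytest.raises(InvalidArgumentError):
            build_threshold_plan(benchmark_echo_signal, short)


class TestDenoiseSignal:
    def test_unknown_mode_rejected(self, benchmark_echo_signal):
        noisy, ref = add_white_noise(benchmark_echo_signal, 5.0, seed=0)
        plan = build_threshold_plan(noisy, ref)
        with pytest.raises(InvalidArgumentError):
            denoise_signal(noisy, plan, mode="median")

    def test_output_length_preserved(self, benchmark_echo_signal):
        noisy, ref = add_white_noise(benchmark_echo_signal, 5.0, seed=0)
        plan = build_threshold_plan(noisy, ref)
        for mode in ("adaptive", "soft", "hard"):
            assert len(denoise_signal(noisy, plan, mode)) == len(noisy)

    def test_adaptive_mode_gains_snr_at_5db(self, benchmark_echo_signal):
        gains = []
        for s in range(10):
            noisy, ref = add_white_noise(benchmark_echo_signal, 5.0, seed=s)
            plan = build_threshold_plan(noisy, ref)
            out = denoise_signal(noisy, plan, mode="adaptive")
            gains.append(snr_db(benchmark_echo_signal, out)
                         - snr_db(benchmark_echo_signal, noisy))
        assert np.mean(gains) > 0.0

    def test_pure_noise_input_mostly_removed(self, benchmark_echo_signal, rng):
        fs = benchmark_echo_signal.sampling_rate
        ratios = []
        for _ in range(10):
            noise = SampledSignal(rng.standard_normal(500), fs)
            ref = SampledSignal(rng.standard_normal(500), fs)
            plan = build_threshold_plan(noise, ref)
            out = denoise_signal(noise, plan, mode="adaptive")
            ratios.append(np.sum(out.samples**2) / np.sum(noise.samples**2))
        assert np.mean(ratios) < 0.20
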