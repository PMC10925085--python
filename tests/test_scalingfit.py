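"""Exponent estimation: double power law, truncated power laws, DCC."""

import numpy as np
import pytest

import avascale as av
from avascale.cascade import AvalancheSet
from avascale.scalingfit import (SizeDurationCurve, crackling_prediction,
                                 exponent_suite, fit_double_powerlaw,
                                 fit_powerlaw_binned, fit_truncated_powerlaw,
                                 mean_size_by_duration, rescue_map)


def dpl(d, C, s1, s2, phi, gamma=4.0):
    """Forward evaluation of the double power law (the fit's oracle)."""
    d = np.asarray(d, dtype=float)
    return C * d ** s1 * (1.0 + (d / phi) ** gamma) ** ((s2 - s1) / gamma)


def sample_truncated_discrete_powerlaw(exponent, xmin, xmax, n, rng):
    """Inverse-CDF sampler from the normalized discrete truncated law."""
    ks = np.arange(xmin, xmax + 1, dtype=np.float64)
    pmf = ks ** (-exponent)
    cdf = np.cumsum(pmf / pmf.sum())
    return ks[np.searchsorted(cdf, rng.random(n))].astype(np.int64)


class TestMeanSizeByDuration:
    def test_grouping_example(self):
        avs = AvalancheSet(sizes=np.array([2, 4, 9]), durations=np.array([1, 1, 3]))
        c = mean_size_by_duration(avs)
        assert c.durations.tolist() == [1, 3]
        assert c.mean_sizes.tolist() == [3.0, 9.0]
        assert c.counts.tolist() == [2, 1]

    def test_single_avalanche(self):
        c = mean_size_by_duration(AvalancheSet(sizes=np.array([5.0]),
                                               durations=np.array([2])))
        assert len(c.durations) == 1

    def test_total_size_conserved(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(1, 100, 500).astype(float)
        durs = rng.integers(1, 20, 500)
        c = mean_size_by_duration(AvalancheSet(sizes=sizes, durations=durs))
        assert np.sum(c.counts * c.mean_sizes) == pytest.approx(sizes.sum())

    def test_empty_set_flagged(self):
        c = mean_size_by_duration(AvalancheSet(sizes=np.array([]),
                                               durations=np.array([])))
        assert c.empty


class TestDoublePowerLaw:
    def test_recovers_noiseless_parameters_within_one_percent(self):
        d = np.unique(np.geomspace(1, 1e4, 200).astype(int))
        curve = SizeDurationCurve(d, dpl(d, 1.0, 2.0, 1.0, 100.0),
                                  np.ones_like(d))
        fit = fit_double_powerlaw(curve)
        assert fit.converged
        assert fit.sigma1 == pytest.approx(2.0, rel=0.01)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.01)
        assert fit.phi == pytest.approx(100.0, rel=0.01)

    def test_recovers_under_multiplicative_noise_within_five_percent(self):
        rng = np.random.default_rng(5)
        d = np.unique(np.geomspace(1, 1e4, 200).astype(int))
        noisy = dpl(d, 1.0, 2.0, 1.0, 100.0) * rng.lognormal(0.0, 0.05, len(d))
        fit = fit_double_powerlaw(SizeDurationCurve(d, noisy, np.ones_like(d)))
        assert fit.sigma1 == pytest.approx(2.0, rel=0.05)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.05)
        assert fit.phi == pytest.approx(100.0, rel=0.3)

    def test_pure_power_law_flags_phi_unidentifiable(self):
        d = np.unique(np.geomspace(1, 1e3, 80).astype(int))
        fit = fit_double_powerlaw(SizeDurationCurve(d, 2.0 * d ** 1.5,
                                                    np.ones_like(d)))
        assert fit.sigma1 == pytest.approx(1.5, abs=0.02)
        assert fit.sigma2 == pytest.approx(1.5, abs=0.05)
        assert not fit.phi_identifiable

    def test_degenerate_curve_low_confidence(self):
        fit = fit_double_powerlaw(SizeDurationCurve(
            np.array([1, 2, 3]), np.array([2.0, 4.0, 6.0]), np.ones(3)))
        assert fit.low_confidence


class TestTruncatedPowerLawMLE:
    def test_recovers_exponent_from_synthetic_draws(self):
        rng = np.random.default_rng(11)
        x = sample_truncated_discrete_powerlaw(1.5, 100, 10_000, 100_000, rng)
        fit = fit_truncated_powerlaw(x, 100, 10_000)
        assert fit.exponent == pytest.approx(1.5, abs=0.05)
        assert not fit.low_confidence

    @pytest.mark.parametrize("true_exp", [1.2, 1.5, 2.0])
    def test_calibration_within_two_standard_errors(self, true_exp):
        rng = np.random.default_rng(int(true_exp * 100))
        x = sample_truncated_discrete_powerlaw(true_exp, 50, 5000, 10_000, rng)
        fit = fit_truncated_powerlaw(x, 50, 5000)
        assert abs(fit.exponent - true_exp) < 2 * fit.stderr + 1e-9

    def test_invariant_to_sample_duplication(self):
        rng = np.random.default_rng(13)
        x = sample_truncated_discrete_powerlaw(1.7, 10, 1000, 5000, rng)
        a = fit_truncated_powerlaw(x, 10, 1000).exponent
        b = fit_truncated_powerlaw(np.concatenate([x, x]), 10, 1000).exponent
        assert a == pytest.approx(b, abs=1e-6)

    def test_binned_regression_agrees_on_clean_law(self):
        rng = np.random.default_rng(17)
        x = sample_truncated_discrete_powerlaw(1.5, 100, 10_000, 200_000, rng)
        fit = fit_powerlaw_binned(x, 100, 10_000)
        assert fit.exponent == pytest.approx(1.5, abs=0.1)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            fit_truncated_powerlaw([1, 2, 3], 10, 10)

    def test_few_samples_low_confidence(self):
        fit = fit_truncated_powerlaw([5, 6, 7, 8], 1, 100)
        assert fit.low_confidence


class TestCracklingPrediction:
    @pytest.mark.parametrize("alpha, beta, expected", [
        (1.5, 2.0, 2.0),
        (2.0, 2.0, 1.0),
    ])
    def test_values(self, alpha, beta, expected):
        assert crackling_prediction(alpha, beta) == pytest.approx(expected)

    def test_singular_near_alpha_one(self):
        assert np.isnan(crackling_prediction(1.0, 2.0))
        assert np.isnan(crackling_prediction(1.015, 2.0))
        assert np.isfinite(crackling_prediction(1.05, 2.0))


class TestExponentSuite:
    def test_short_sets_are_invalid(self):
        rng = np.random.default_rng(3)
        avs = AvalancheSet(sizes=rng.integers(1, 50, 500).astype(float),
                           durations=rng.integers(1, 10, 500))  # max T < 20
        es = exponent_suite(avs)
        assert not es.valid and np.isnan(es.chi)

    def test_uncorrelated_activity_scales_linearly(self):
        """Independent Poisson bins: mean size grows linearly with duration
        (chi = 1), the hallmark of a process without avalanche structure."""
        rng = np.random.default_rng(29)
        series = rng.poisson(1.9, 400_000)
        avs = av.avalanche_pipeline(series, k=1, theta=1)
        es = exponent_suite(avs)
        assert es.valid
        assert es.chi == pytest.approx(1.0, abs=0.15)

    def test_critical_low_threshold_cell(self, critical_traces):
        """Fully sampled critical model at k=1, theta=100: chi near 2,
        alpha near 3/2, and the crackling-noise prediction consistent with
        the measured chi (DCC near 0)."""
        avs = av.avalanche_pipeline(critical_traces, k=1, theta=100)
        es = exponent_suite(avs)
        assert es.valid and es.converged
        assert 1.7 < es.chi < 2.1
        assert 1.25 < es.alpha < 1.65
        assert abs(es.dcc) < 0.25

    def test_singularity_flag_as_alpha_crosses_one(self, critical_traces):
        """Coarse-graining at high threshold pushes alpha through 1; the
        suite must flag the chi_cn singularity instead of reporting a
        diverging value."""
        seen_singular_or_crossed = False
        alphas = []
        for k in (4, 8, 12, 16):
            es = exponent_suite(av.avalanche_pipeline(critical_traces, k=k,
                                                      theta=1000))
            if not es.valid:
                continue
            alphas.append(es.alpha)
            if es.singular:
                seen_singular_or_crossed = True
                assert np.isnan(es.chi_cn) and np.isnan(es.dcc)
        crossed = any(a > 1 for a in alphas) and any(a < 1 for a in alphas)
        assert seen_singular_or_crossed or crossed


class TestRescueMap:
    def test_single_cell_equals_direct_call(self, critical_traces):
        short = [t.total[:300_000] for t in critical_traces]
        rmap = rescue_map(short, f=1.0, k_grid=[2], theta_grid=[100.0])
        direct = exponent_suite(av.avalanche_pipeline(short, k=2, theta=100.0))
        assert rmap.cells[0][0].chi == pytest.approx(direct.chi)
        assert rmap.values("chi")[0, 0] == pytest.approx(direct.chi)

    def test_fractional_thresholds_masked_unobservable(self, critical_runs):
        sub = [r.samples[0.001] for r in critical_runs]
        short = [s.counts[:200_000] for s in sub]
        rmap = rescue_map(short, f=0.001, k_grid=[1, 2], theta_grid=[0.5, 2.0])
        assert rmap.unobservable[:, 0].all()      # theta = 0.5 < 1 spike
        assert not rmap.unobservable[:, 1].any()

    def test_grids_must_increase(self, critical_traces):
        with pytest.raises(ValueError):
            rescue_map(critical_traces[0], f=1.0, k_grid=[2, 1], theta_grid=[1.0])
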