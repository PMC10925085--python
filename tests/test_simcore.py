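"""Simulation core: parameter rules, exact count dynamics, sampling coupling."""

import numpy as np
import pytest
from scipy import stats

import avascale as av
from avascale.simcore import step_counts


class TestMakeParams:
    def test_default_weight_rule_pins_criticality(self):
        p = av.make_params(3.5, N=10 ** 6)
        assert p.J == pytest.approx(1e-5)
        assert p.sigma == pytest.approx(1.0)

    def test_sigma_linear_in_g_at_fixed_J(self):
        p = av.make_params(3.75, N=10 ** 6)  # same default J as g=3.5
        assert p.J == pytest.approx(1e-5)
        assert p.sigma == pytest.approx(0.5)

    @pytest.mark.parametrize("kwargs", [
        {"g": 3.5, "N": 0},
        {"g": -1.0, "N": 1000},
        {"g": 3.5, "N": 1000, "f_E": 1.5},
        {"g": 3.5, "N": 1000, "lambda_drive": -0.1},
        {"g": 3.5, "N": 1000, "lambda_drive": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            av.make_params(**kwargs)

    def test_class_sizes_partition_network(self):
        p = av.make_params(3.5, N=999)
        assert p.N_E + p.N_I == p.N


class TestStepCounts:
    def test_absorbing_state_without_drive(self):
        p = av.make_params(3.5, N=1000, lambda_drive=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert step_counts((0, 0), p, rng) == (0, 0, 0)

    def test_drive_triggers_expected_spikes_from_quiescence(self):
        p = av.make_params(3.5, N=10 ** 6)
        rng = np.random.default_rng(1)
        draws = np.array([sum(step_counts((0, 0), p, rng)[:2]) for _ in range(3000)])
        # from quiescence the next step is purely drive: mean N*lambda = 20
        assert draws.mean() == pytest.approx(20.0, abs=3 * draws.std() / np.sqrt(len(draws)))

    def test_refractory_exhaustion(self):
        p = av.make_params(3.5, N=1000)
        rng = np.random.default_rng(2)
        nE, nI, _ = step_counts((p.N_E, p.N_I), p, rng)
        assert (nE, nI) == (0, 0)

    def test_state_bounds_checked(self):
        p = av.make_params(3.5, N=1000)
        with pytest.raises(ValueError):
            step_counts((p.N_E + 1, 0), p, np.random.default_rng(0))


def _per_neuron_one_step(nE0, nI0, params, rng):
    """Independent oracle: one update of every neuron with the full weight
    matrix, following the membrane equation and linear firing rule."""
    N, NE = params.N, params.N_E
    X = np.zeros(N, dtype=bool)
    X[:nE0] = True                    # which E neurons fired is exchangeable
    X[NE:NE + nI0] = True
    W = np.empty((N, N))
    W[:, :NE] = params.J
    W[:, NE:] = -params.g * params.J
    V = (W @ X) * (~X)
    prob = np.clip(params.Gamma * V, 0.0, 1.0)
    p_eff = 1.0 - (1.0 - prob) * (1.0 - params.lambda_drive)
    fired = (rng.random(N) < p_eff) & ~X
    return int(fired.sum())


def test_count_form_matches_per_neuron_oracle():
    """Per-step total-activity law of the O(1) count chain agrees with the
    explicit per-neuron weight-matrix simulation (KS test, 1e4 replicates)."""
    p = av.make_params(3.2, N=200, lambda_drive=1e-3)
    nE0, nI0 = 30, 10
    rng = np.random.default_rng(42)
    oracle = np.array([_per_neuron_one_step(nE0, nI0, p, rng) for _ in range(10_000)])
    rng2 = np.random.default_rng(43)
    counts = np.array([sum(step_counts((nE0, nI0), p, rng2)[:2]) for _ in range(10_000)])
    assert stats.ks_2samp(oracle, counts).pvalue > 0.01


def test_trajectory_totals_match_per_neuron_oracle():
    """Full-trajectory activity distributions agree between the two forms."""
    p = av.make_params(3.4, N=150, lambda_drive=2e-3)
    pop = av.simulate(p, steps=4000, seed=7)[0].trace.total
    oracle = av.simulate_per_neuron(p, 4000, np.random.default_rng(8)).sum(axis=1)
    assert stats.ks_2samp(pop[1:], oracle[1:]).pvalue > 0.01


def test_drive_calibration_without_coupling():
    """With J = 0 the network is a pure Poisson process: mean activity per
    step equals N*lambda within three standard errors."""
    p = av.make_params(3.5, N=10 ** 6, J=0.0)
    trace = av.simulate(p, steps=100_000, seed=11)[0].trace
    mean = trace.total[1:].mean()
    se = trace.total[1:].std() / np.sqrt(trace.steps - 1)
    assert abs(mean - 20.0) < 3 * se


def test_refractoriness_conserved_per_class(critical_traces):
    tr = critical_traces[0]
    NE, NI = 800_000, 200_000
    assert np.all(tr.nE[1:].astype(np.int64) + tr.nE[:-1] <= NE)
    assert np.all(tr.nI[1:].astype(np.int64) + tr.nI[:-1] <= NI)


def test_full_sampling_reproduces_population(critical_runs):
    run = av.simulate(av.make_params(3.5), steps=50_000,
                      sample_fractions=[1.0, 0.01], seed=19)[0]
    assert np.array_equal(run.samples[1.0].counts, run.trace.total)
    assert np.all(run.samples[0.01].counts <= run.trace.total)


def test_sampling_fraction_validation():
    p = av.make_params(3.5, N=1000)
    with pytest.raises(ValueError):
        av.simulate(p, steps=10, sample_fractions=[1.5], seed=0)
    with pytest.raises(ValueError):
        av.simulate(p, steps=10, sample_fractions=[1e-4], seed=0)  # f*N < 1


def test_runs_are_independent_and_reproducible(critical_params):
    a = av.simulate(critical_params, steps=5000, n_runs=2, seed=5)
    b = av.simulate(critical_params, steps=5000, n_runs=2, seed=5)
    assert np.array_equal(a[0].trace.total, b[0].trace.total)
    assert not np.array_equal(a[0].trace.total, a[1].trace.total)


@pytest.fixture(scope="module")
def raster_and_trace():
    return av.simulate_raster(av.make_params(3.5, N=50_000), M=60,
                              steps=5000, seed=23)


class TestTrackedRaster:
    def test_no_consecutive_spikes(self, raster_and_trace):
        X = raster_and_trace[0].to_dense()
        assert not np.any((X[:, :-1] == 1) & (X[:, 1:] == 1))

    def test_column_sums_bounded_by_population(self, raster_and_trace):
        raster, trace = raster_and_trace
        counts = raster.counts()
        assert np.all(counts <= np.minimum(raster.M, trace.total))

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError):
            av.simulate_raster(av.make_params(3.5, N=100), M=101, steps=10, seed=0)


class TestBranchingRatio:
    def test_critical_ratio_near_one(self, critical_traces, critical_params):
        r = av.branching_ratio(critical_traces[0], critical_params)
        assert r == pytest.approx(1.0, abs=0.05)

    def test_subcritical_ratio_matches_mean_field(self):
        p = av.make_params(3.75)
        r = av.ensemble_branching_ratio(p, n_runs=150, steps=40_000, seed=31)
        assert r == pytest.approx(0.5, abs=0.05)

    def test_quiescent_trace_is_undefined(self, critical_params):
        silent = av.PopulationTrace(nE=np.zeros(100, dtype=np.int64),
                                    nI=np.zeros(100, dtype=np.int64),
                                    n_drive=np.zeros(100, dtype=np.int64))
        assert np.isnan(av.branching_ratio(silent, critical_params))

    def test_monotone_in_g(self):
        ratios = [av.ensemble_branching_ratio(av.make_params(g), n_runs=30,
                                              steps=15_000, seed=37)
                  for g in (3.0, 3.5, 3.6, 3.75)]
        assert all(a > b - 0.03 for a, b in zip(ratios, ratios[1:]))
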