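"""Shared simulation fixtures.

The heavy fixtures are session-scoped: one critical-network dataset (4
runs of 2e6 steps with coupled fractional sampling) and one subcritical
dataset serve the avalanche-statistics, collapse and acceptance tests.
"""

import numpy as np
import pytest

import avascale as av


@pytest.fixture(scope="session")
def critical_params():
    return av.make_params(3.5)


@pytest.fixture(scope="session")
def critical_runs(critical_params):
    """Four independent critical runs, 2e6 steps each, with sampling at
    f = 1e-4 .. 1e-1 coupled step by step to the population counts."""
    return av.simulate(critical_params, steps=2_000_000, n_runs=4,
                       sample_fractions=[0.0001, 0.001, 0.01, 0.1], seed=101)


@pytest.fixture(scope="session")
def critical_traces(critical_runs):
    return [r.trace for r in critical_runs]


@pytest.fixture(scope="session")
def subcritical_runs():
    """Two runs of the inhibition-dominated network (g = 3.75, sigma = 0.5)."""
    return av.simulate(av.make_params(3.75), steps=1_500_000, n_runs=2,
                       sample_fractions=[0.001], seed=103)


def subsampled(runs, f):
    return [r.samples[f] for r in runs]


@pytest.fixture(scope="session")
def max_rescued_chi():
    """max over k of the fitted chi at a 1-spike threshold, per trace set."""

    def _max(traces, f, k_grid=(1, 2, 4, 8, 16, 32, 64, 128)):
        best = np.nan
        for k in k_grid:
            es = av.exponent_suite(av.avalanche_pipeline(traces, k=k, theta=1, f=f))
            if es.valid and np.isfinite(es.chi):
                best = es.chi if not np.isfinite(best) else max(best, es.chi)
        return best

    return _max
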