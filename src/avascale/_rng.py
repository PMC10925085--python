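"""Numba-compatible random variates used by the simulation kernels.

Numba's builtin ``np.random.hypergeometric`` falls back to a per-draw loop
whose cost grows with the sample size, which is prohibitive when coupling
a 10^5-neuron observation window to a 10^6-neuron network at every time
step.  We therefore carry our own port of the classic HRUA* rejection
sampler (Stadlober 1990), the same algorithm NumPy's legacy RandomState
uses, with the count-down inversion sampler for small draws.

All functions here consume the Numba-internal ``np.random`` state, so the
calling kernel must seed it (``np.random.seed``) before use.
"""

import math

import numpy as np
from numba import njit

# 2*sqrt(2/e) and 3 - 2*sqrt(3/e): HRUA* hat-function constants
_D1 = 1.7155277699214135
_D2 = 0.8989161620588988


@njit(cache=True)
def _hypergeometric_small(good, bad, sample):
    # count-down inversion; cost O(min(good, bad)), used for tiny samples
    d1 = float(bad + good - sample)
    d2 = float(min(bad, good))
    y = d2
    k = sample
    while y > 0.0:
        u = np.random.random()
        y -= math.floor(u + y / (d1 + k))
        k -= 1
        if k == 0:
            break
    z = int(d2 - y)
    if good > bad:
        z = sample - z
    return z


@njit(cache=True)
def _hypergeometric_hrua(good, bad, sample):
    popsize = good + bad
    mingoodbad = min(good, bad)
    maxgoodbad = max(good, bad)
    m = min(sample, popsize - sample)
    d4 = mingoodbad / popsize
    d5 = 1.0 - d4
    d6 = m * d4 + 0.5
    d7 = math.sqrt((popsize - m) * sample * d4 * d5 / (popsize - 1) + 0.5)
    d8 = _D1 * d7 + _D2
    d9 = int((m + 1) * (mingoodbad + 1) // (popsize + 2))
    d10 = (math.lgamma(d9 + 1) + math.lgamma(mingoodbad - d9 + 1)
           + math.lgamma(m - d9 + 1) + math.lgamma(maxgoodbad - m + d9 + 1))
    d11 = min(min(m, mingoodbad) + 1.0, math.floor(d6 + 16.0 * d7))
    z = 0
    while True:
        x = np.random.random()
        y = np.random.random()
        w = d6 + d8 * (y - 0.5) / x
        if w < 0.0 or w >= d11:
            continue
        z = int(math.floor(w))
        t = d10 - (math.lgamma(z + 1) + math.lgamma(mingoodbad - z + 1)
                   + math.lgamma(m - z + 1) + math.lgamma(maxgoodbad - m + z + 1))
        if x * (4.0 - x) - 3.0 <= t:
            break
        if x * (x - t) >= 1.0:
            continue
        if 2.0 * math.log(x) <= t:
            break
    if good > bad:
        z = m - z
    if m < sample:
        z = good - z
    return z


@njit(cache=True)
def hypergeometric(good, bad, sample):
    """Number of 'good' items in a uniform draw of `sample` without replacement.

    Degenerate cases (empty population, exhaustive sample) are resolved
    exactly; otherwise dispatches between inversion and HRUA* like the
    NumPy legacy generator.
    """
    if sample <= 0 or good <= 0:
        return 0
    if sample >= good + bad:
        return good
    if sample > 10:
        return _hypergeometric_hrua(good, bad, sample)
    return _hypergeometric_small(good, bad, sample)
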