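"""Critically balanced E/I branching network of stochastic integrate-and-fire neurons.

The model is a fully connected network of ``N`` non-leaky, stochastic
integrate-and-fire neurons, 80% excitatory and 20% inhibitory.  All
outgoing excitatory synapses carry weight ``J`` and all inhibitory ones
``-g*J``, where ``g`` is the E/I balance parameter.  With gain ``Gamma``
and leakage ``mu = 0``, a neuron's firing probability in the next step is
linear in its membrane potential, clipped to [0, 1], and every neuron is
absolutely refractory for one time step after firing.  A per-neuron
Poisson drive of rate ``lambda_drive`` per step keeps the network out of
its absorbing quiescent state.

Because weights are uniform within a class and the connectivity is
all-to-all, every non-refractory neuron sees the same field
``V = J*nE - g*J*nI`` and the per-class spike counts form an exact Markov
chain on ``(nE, nI)`` with binomial transitions.  The count-form kernel
below simulates that chain in O(1) per step, which makes runs of 10^7-10^8
steps cheap; an explicit per-neuron simulator with the full weight matrix
is provided as an independent cross-check and as the source of per-neuron
rasters.

The mean-field branching ratio is ``sigma(g) = N*Gamma*J*(f_E - g*(1-f_E))``;
with the default weight rule it equals 1 exactly at the critical balance
``g_c = 3.5``.

Observation of a random fraction ``f`` of neurons is coupled exactly to
the population chain: at every step the number of observed spikes is a
hypergeometric draw of the fired neurons within the observed,
non-refractory pool, tracked per class, so full sampling (f = 1)
reproduces the population counts identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from ._rng import hypergeometric

__all__ = [
    "G_CRITICAL",
    "ModelParams",
    "PopulationTrace",
    "SampledTrace",
    "TrackedRaster",
    "SimulationRun",
    "make_params",
    "step_counts",
    "simulate",
    "simulate_raster",
    "simulate_per_neuron",
    "branching_ratio",
    "ensemble_branching_ratio",
]

#: critical E/I balance of the default topology (4:1 E/I ratio, uniform weights)
G_CRITICAL = 3.5


@dataclass(frozen=True)
class ModelParams:
    """Network and drive constants of the balanced E/I branching model.

    Attributes
    ----------
    N : int
        Number of neurons.
    f_E : float
        Excitatory fraction (0.8 gives the 4:1 E/I ratio).
    g : float
        Inhibition balance parameter; ``g > g_c`` is subcritical
        (inhibition dominated), ``g < g_c`` supercritical.
    J : float
        Excitatory synaptic weight, in membrane-potential units per spike.
    Gamma : float
        Neuronal gain (firing probability per unit potential).
    mu : float
        Leakage; only the non-leaky case ``mu = 0`` is simulated.
    lambda_drive : float
        Per-neuron external firing probability per time step.
    seed : int | None
        Default RNG seed for simulations with these parameters.
    """

    N: int = 1_000_000
    f_E: float = 0.8
    g: float = G_CRITICAL
    J: float = 1e-5
    Gamma: float = 1.0
    mu: float = 0.0
    lambda_drive: float = 2e-5
    seed: int | None = None

    @property
    def N_E(self) -> int:
        return int(round(self.N * self.f_E))

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    @property
    def sigma(self) -> float:
        """Mean-field branching ratio N*Gamma*J*(f_E - g*(1 - f_E))."""
        return self.N * self.Gamma * self.J * (self.f_E - self.g * (1.0 - self.f_E))


def make_params(g: float = G_CRITICAL, N: int = 1_000_000, **overrides) -> ModelParams:
    """Build validated model parameters with the default synaptic-weight rule.

    Unless ``J`` is overridden it is fixed by requiring the mean-field
    branching ratio to equal 1 at the critical balance ``g_c = 3.5``:
    ``J = 1 / (N * Gamma * (f_E - g_c*(1 - f_E)))``, i.e. ``J = 1e-5`` for
    the default million-neuron network with unit gain.

    Raises
    ------
    ValueError
        On non-positive ``N``, ``f_E`` outside (0, 1), negative ``g``,
        negative drive, or drive probability above 1.
    """
    f_E = overrides.get("f_E", 0.8)
    Gamma = overrides.get("Gamma", 1.0)
    if not N >= 10:
        raise ValueError(f"N must be >= 10, got {N}")
    if not 0.0 < f_E < 1.0:
        raise ValueError(f"f_E must lie in (0, 1), got {f_E}")
    if g < 0:
        raise ValueError(f"g must be >= 0, got {g}")
    lam = overrides.get("lambda_drive", 2e-5)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda_drive must lie in [0, 1], got {lam}")
    if "J" not in overrides:
        overrides["J"] = 1.0 / (N * Gamma * (f_E - G_CRITICAL * (1.0 - f_E)))
    elif overrides["J"] < 0:
        raise ValueError(f"J must be >= 0, got {overrides['J']}")
    if overrides.get("mu", 0.0) != 0.0:
        raise ValueError("only the non-leaky case mu = 0 is supported")
    return ModelParams(N=N, g=g, **overrides)


@dataclass
class PopulationTrace:
    """Per-step spike counts of one simulation run (fully sampled activity).

    ``nE[t]``, ``nI[t]`` and ``n_drive[t]`` are the numbers of excitatory,
    inhibitory and externally triggered spikes in time bin ``t``
    (``n_drive`` counts the subset of spikes attributed to the Poisson
    drive).  Index 0 is the all-quiescent initial condition.
    """

    nE: np.ndarray
    nI: np.ndarray
    n_drive: np.ndarray
    run_id: int = 0
    seed: int | None = None

    @property
    def steps(self) -> int:
        return len(self.nE)

    @property
    def total(self) -> np.ndarray:
        """Summed population activity a(t) = nE(t) + nI(t)."""
        return self.nE.astype(np.int64) + self.nI


@dataclass
class SampledTrace:
    """Spike counts observed on a random fraction ``f`` of the network."""

    f: float
    M: int
    counts: np.ndarray
    run_id: int = 0

    @property
    def steps(self) -> int:
        return len(self.counts)


@dataclass
class TrackedRaster:
    """Sparse per-neuron spike raster of ``M`` individually tracked neurons.

    ``events`` is an (n_spikes, 2) integer array of (neuron index, time
    step) pairs; neurons ``0..M_E-1`` are excitatory, the rest inhibitory.
    """

    M: int
    M_E: int
    events: np.ndarray
    steps: int
    seed: int | None = None

    def to_dense(self) -> np.ndarray:
        """Dense (M, steps) 0/1 spike matrix."""
        X = np.zeros((self.M, self.steps), dtype=np.int8)
        if len(self.events):
            X[self.events[:, 0], self.events[:, 1]] = 1
        return X

    def counts(self) -> np.ndarray:
        """Per-step summed spike counts of the tracked subset."""
        return np.bincount(self.events[:, 1], minlength=self.steps).astype(np.int64)


@dataclass
class SimulationRun:
    """One independent run: population trace plus coupled sampled traces."""

    trace: PopulationTrace
    samples: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

@njit(cache=True)
def _population_kernel(NE, NI, J, g, gamma, lam, steps, seed, ME, MI):
    np.random.seed(seed)
    nF = ME.shape[0]
    outE = np.zeros(steps + 1, np.int32)
    outI = np.zeros(steps + 1, np.int32)
    outD = np.zeros(steps + 1, np.int32)
    outS = np.zeros((nF, steps + 1), np.int32)
    sE = np.zeros(nF, np.int64)
    sI = np.zeros(nF, np.int64)
    curE = 0
    curI = 0
    for t in range(steps):
        v = J * curE - g * J * curI
        pm = gamma * v
        if pm < 0.0:
            pm = 0.0
        elif pm > 1.0:
            pm = 1.0
        poolE = NE - curE
        poolI = NI - curI
        dE = np.random.binomial(poolE, lam) if (lam > 0.0 and poolE > 0) else 0
        dI = np.random.binomial(poolI, lam) if (lam > 0.0 and poolI > 0) else 0
        mE = np.random.binomial(poolE - dE, pm) if (pm > 0.0 and poolE - dE > 0) else 0
        mI = np.random.binomial(poolI - dI, pm) if (pm > 0.0 and poolI - dI > 0) else 0
        newE = dE + mE
        newI = dI + mI
        for q in range(nF):
            fE = hypergeometric(newE, poolE - newE, ME[q] - sE[q])
            fI = hypergeometric(newI, poolI - newI, MI[q] - sI[q])
            sE[q] = fE
            sI[q] = fI
            outS[q, t + 1] = fE + fI
        curE = newE
        curI = newI
        outE[t + 1] = curE
        outI[t + 1] = curI
        outD[t + 1] = dE + dI
    return outE, outI, outD, outS


@njit(cache=True)
def _raster_kernel(NE, NI, J, g, gamma, lam, steps, seed, ME, MI, cap0):
    # tracks ME+MI individual neurons coupled to the population chain;
    # global spikes are allocated to the tracked subset hypergeometrically,
    # then uniformly at random among its non-refractory members.
    np.random.seed(seed)
    M = ME + MI
    refr = np.zeros(M, np.bool_)
    ev_n = np.empty(cap0, np.int64)
    ev_t = np.empty(cap0, np.int64)
    nev = 0
    outE = np.zeros(steps + 1, np.int32)
    outI = np.zeros(steps + 1, np.int32)
    cand = np.empty(M, np.int64)
    curE = 0
    curI = 0
    sE = 0
    sI = 0
    for t in range(steps):
        v = J * curE - g * J * curI
        pm = gamma * v
        if pm < 0.0:
            pm = 0.0
        elif pm > 1.0:
            pm = 1.0
        poolE = NE - curE
        poolI = NI - curI
        dE = np.random.binomial(poolE, lam) if (lam > 0.0 and poolE > 0) else 0
        dI = np.random.binomial(poolI, lam) if (lam > 0.0 and poolI > 0) else 0
        mE = np.random.binomial(poolE - dE, pm) if (pm > 0.0 and poolE - dE > 0) else 0
        mI = np.random.binomial(poolI - dI, pm) if (pm > 0.0 and poolI - dI > 0) else 0
        newE = dE + mE
        newI = dI + mI
        fE = hypergeometric(newE, poolE - newE, ME - sE)
        fI = hypergeometric(newI, poolI - newI, MI - sI)
        # choose the firing tracked neurons uniformly among the
        # non-refractory members of each class (partial Fisher-Yates)
        for cls in range(2):
            if cls == 0:
                lo, hi, nf = 0, ME, fE
            else:
                lo, hi, nf = ME, M, fI
            if nf == 0:
                for i in range(lo, hi):
                    refr[i] = False
                continue
            nc = 0
            for i in range(lo, hi):
                if not refr[i]:
                    cand[nc] = i
                    nc += 1
                refr[i] = False
            for j in range(nf):
                r = j + int(np.random.random() * (nc - j))
                tmp = cand[j]
                cand[j] = cand[r]
                cand[r] = tmp
                idx = cand[j]
                refr[idx] = True
                if nev >= ev_n.shape[0]:
                    new_cap = ev_n.shape[0] * 2
                    tmp_n = np.empty(new_cap, np.int64)
                    tmp_t = np.empty(new_cap, np.int64)
                    tmp_n[:nev] = ev_n[:nev]
                    tmp_t[:nev] = ev_t[:nev]
                    ev_n = tmp_n
                    ev_t = tmp_t
                ev_n[nev] = idx
                ev_t[nev] = t + 1
                nev += 1
        sE = fE
        sI = fI
        curE = newE
        curI = newI
        outE[t + 1] = curE
        outI[t + 1] = curI
    return ev_n[:nev], ev_t[:nev], outE, outI


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def _child_seed(ss: np.random.SeedSequence) -> int:
    # numba reseeds its legacy-style stream from a 32-bit value
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def step_counts(state: tuple[int, int], params: ModelParams,
                rng: np.random.Generator) -> tuple[int, int, int]:
    """Advance the population-count Markov chain by one time step.

    Given the per-class spike counts ``(nE, nI)`` at time t, returns
    ``(nE', nI', n_drive')`` at t+1.  Neurons that fired at t are
    refractory; each remaining neuron fires with probability
    ``1 - (1 - clip(Gamma*V, 0, 1)) * (1 - lambda_drive)`` where
    ``V = J*nE - g*J*nI`` is the (class-independent) field.
    """
    nE, nI = state
    if not (0 <= nE <= params.N_E and 0 <= nI <= params.N_I):
        raise ValueError("state counts outside class bounds")
    v = params.J * nE - params.g * params.J * nI
    pm = min(max(params.Gamma * v, 0.0), 1.0)
    lam = params.lambda_drive
    poolE = params.N_E - nE
    poolI = params.N_I - nI
    dE = rng.binomial(poolE, lam)
    dI = rng.binomial(poolI, lam)
    mE = rng.binomial(poolE - dE, pm)
    mI = rng.binomial(poolI - dI, pm)
    return dE + mE, dI + mI, dE + dI


def _class_sizes(params: ModelParams, fractions: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    ME = np.empty(len(fractions), np.int64)
    MI = np.empty(len(fractions), np.int64)
    for i, f in enumerate(fractions):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"sampling fraction must lie in (0, 1], got {f}")
        M = int(round(params.N * f))
        if M < 1:
            raise ValueError(f"f*N < 1: fraction {f} observes no neuron")
        if f == 1.0:
            ME[i], MI[i] = params.N_E, params.N_I
        else:
            # stratified 80/20 composition; firing probability is
            # class-independent, so summed counts are unaffected
            ME[i] = int(round(M * params.f_E))
            MI[i] = M - ME[i]
    return ME, MI


def simulate(params: ModelParams, steps: int, n_runs: int = 1,
             sample_fractions: Sequence[float] = (),
             seed: int | None = None) -> list[SimulationRun]:
    """Run independent simulations with optional coupled fractional sampling.

    Each run starts from the all-quiescent state with its own seed stream.
    For every fraction in ``sample_fractions`` a :class:`SampledTrace` is
    produced whose counts are exact conditional hypergeometric draws from
    the run's population counts; at ``f = 1`` the sampled counts equal the
    population totals.

    Returns a list of :class:`SimulationRun`, one per run.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if seed is None:
        seed = params.seed
    ME, MI = _class_sizes(params, sample_fractions)
    ss = np.random.SeedSequence(seed)
    runs = []
    for run_id, child in enumerate(ss.spawn(n_runs)):
        kseed = _child_seed(child)
        nE, nI, nD, sC = _population_kernel(
            params.N_E, params.N_I, params.J, params.g, params.Gamma,
            params.lambda_drive, steps, kseed, ME, MI)
        trace = PopulationTrace(nE=nE, nI=nI, n_drive=nD, run_id=run_id, seed=kseed)
        samples = {
            float(f): SampledTrace(f=float(f), M=int(ME[i] + MI[i]),
                                   counts=sC[i], run_id=run_id)
            for i, f in enumerate(sample_fractions)
        }
        runs.append(SimulationRun(trace=trace, samples=samples))
    return runs


def simulate_raster(params: ModelParams, M: int, steps: int,
                    seed: int | None = None) -> tuple[TrackedRaster, PopulationTrace]:
    """Simulate with ``M`` individually tracked neurons (stratified 80/20 E/I).

    The tracked neurons keep their own refractory state; the global spike
    counts are allocated to the tracked subset by the same conditional
    hypergeometric law as :func:`simulate`, so the raster's column sums
    are distributed exactly as the corresponding sampled-trace counts.
    """
    if M > params.N:
        raise ValueError(f"M = {M} exceeds N = {params.N}")
    if M < 1:
        raise ValueError("M must be >= 1")
    if seed is None:
        seed = params.seed
    if M == params.N:
        ME, MI = params.N_E, params.N_I
    else:
        ME = int(round(M * params.f_E))
        MI = M - ME
    kseed = _child_seed(np.random.SeedSequence(seed))
    cap0 = max(4096, int(2e-4 * M * steps))
    ev_n, ev_t, nE, nI = _raster_kernel(
        params.N_E, params.N_I, params.J, params.g, params.Gamma,
        params.lambda_drive, steps, kseed, ME, MI, cap0)
    order = np.argsort(ev_t, kind="stable")
    events = np.column_stack([ev_n[order], ev_t[order]])
    raster = TrackedRaster(M=M, M_E=ME, events=events, steps=steps + 1, seed=kseed)
    trace = PopulationTrace(nE=nE, nI=nI, n_drive=np.zeros_like(nE), seed=kseed)
    return raster, trace


def simulate_per_neuron(params: ModelParams, steps: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Explicit per-neuron simulation with the full weight matrix.

    Direct implementation of the membrane update
    ``V_i(t+1) = (mu*V_i(t) + sum_j W_ij X_j(t)) * (1 - X_i(t))`` and the
    linear firing rule, neuron by neuron.  Quadratic in ``N`` per step —
    intended for small networks as an independent cross-check of the
    count-form chain.  Returns the (steps+1, 2) array of per-class spike
    counts.
    """
    N, NE = params.N, params.N_E
    w_col = np.where(np.arange(N) < NE, params.J, -params.g * params.J)
    X = np.zeros(N, dtype=bool)
    V = np.zeros(N)
    out = np.zeros((steps + 1, 2), dtype=np.int64)
    lam = params.lambda_drive
    for t in range(steps):
        drive_in = X @ w_col  # sum_j W_ij X_j, identical rows
        V = (params.mu * V + drive_in) * (~X)
        p = np.clip(params.Gamma * V, 0.0, 1.0)
        p_eff = 1.0 - (1.0 - p) * (1.0 - lam)
        X = (rng.random(N) < p_eff) & ~X
        out[t + 1, 0] = int(X[:NE].sum())
        out[t + 1, 1] = int(X[NE:].sum())
    return out


def _ratio_window(params: ModelParams, floor, ceiling) -> tuple[float, float]:
    # The conditioning window must sit well above the drive noise floor
    # (where rectification of negative fields inflates conditional growth)
    # yet well below refractory saturation; 100..1000 drive multiples keeps
    # both biases under ~1% at default parameters.
    drive = params.N * params.lambda_drive
    if floor is None:
        floor = 100.0 * drive
    if ceiling is None:
        ceiling = 1000.0 * drive
    return float(floor), float(ceiling)


def branching_ratio(trace: PopulationTrace | np.ndarray, params: ModelParams,
                    floor: float | None = None,
                    ceiling: float | None = None) -> float:
    """Drive-corrected empirical branching ratio of a run.

    Averages ``(a(t+1) - N*lambda) / a(t)`` over steps whose activity lies
    in the window ``floor < a(t) < ceiling`` (defaults ``100*N*lambda`` and
    ``1000*N*lambda``).  The floor keeps the estimate clear of the
    drive-dominated regime, where the rectification of negative membrane
    fields inflates conditional growth; the ceiling keeps it clear of
    refractory saturation.  Returns NaN when no step is eligible.
    """
    a = trace.total if isinstance(trace, PopulationTrace) else np.asarray(trace)
    floor, ceiling = _ratio_window(params, floor, ceiling)
    a = a.astype(np.float64)
    prev, nxt = a[:-1], a[1:]
    ok = (prev > floor) & (prev < ceiling)
    if not ok.any():
        return float("nan")
    drive = params.N * params.lambda_drive
    return float(np.mean((nxt[ok] - drive) / prev[ok]))


def ensemble_branching_ratio(params: ModelParams, n_runs: int = 50,
                             steps: int = 20_000, seed: int | None = None,
                             floor: float | None = None,
                             ceiling: float | None = None) -> float:
    """Branching ratio pooled over an ensemble of independent runs.

    Supercritical networks saturate at high activity and only cross the
    estimation window during their initial transient, so a single long
    run yields almost no eligible steps; pooling many short runs started
    from quiescence samples the window for any g.  Returns NaN when no
    pooled step is eligible.
    """
    floor, ceiling = _ratio_window(params, floor, ceiling)
    drive = params.N * params.lambda_drive
    num = 0.0
    n = 0
    for run in simulate(params, steps=steps, n_runs=n_runs, seed=seed):
        a = run.trace.total.astype(np.float64)
        prev, nxt = a[:-1], a[1:]
        ok = (prev > floor) & (prev < ceiling)
        if ok.any():
            num += float(np.sum((nxt[ok] - drive) / prev[ok]))
            n += int(ok.sum())
    return num / n if n else float("nan")
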