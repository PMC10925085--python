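# Methods

## The model

`avascale` simulates a fully connected network of `N` stochastic,
non-leaky integrate-and-fire neurons, a fraction `f_E = 0.8` excitatory.
Synaptic weights are uniform per presynaptic class: `+J` for excitatory,
`-g*J` for inhibitory axons, where `g` is the E/I balance parameter.  A
neuron that fired at step `t` is absolutely refractory at `t+1`; every
other neuron fires at `t+1` with probability
`1 - (1 - clip(Γ·V, 0, 1))·(1 - λ)`, where `V = J·nE(t) - g·J·nI(t)` is
the common membrane field generated by the previous step's spikes and
`λ` is a per-neuron external Poisson drive that keeps the network out of
its absorbing quiescent state.  Negative fields produce firing
probability 0 (the linear rule is rectified), and the drive acts by
directly triggering spikes in non-refractory neurons, combined with the
membrane rule as an independent OR.  A per-neuron Bernoulli(λ) draw
stands in for the per-step Poisson process; at `λ = 2e-5` the two differ
at O(λ²).

Because weights are class-uniform and connectivity is all-to-all, the
per-class spike counts `(nE, nI)` form an exact Markov chain with
binomial transitions, and the mean-field branching ratio is
`σ(g) = N·Γ·J·(f_E - g·(1 - f_E))`.  The default weight rule fixes `J`
by requiring `σ = 1` at the critical balance `g_c = 3.5`
(`J = 1e-5` for `N = 1e6`, `Γ = 1`); `σ` then falls linearly with `g`
(0.5 at `g = 3.75`).

### Exact simulation and sampling

The count chain is simulated in O(1) work per time step (two binomial
draws per class), which makes `1e7`–`1e8`-step runs a matter of seconds
to minutes on one CPU.  Observation of a random neuron subset is coupled
*exactly* to the chain: per class and step, the number of observed
spikes is a hypergeometric draw of the fired neurons within the observed
non-refractory pool.  At `f = 1` the draw is degenerate and reproduces
the population counts identically.  Observed subsets are composed 80/20
E/I (stratified rather than random composition; firing probability is
class-independent, so summed counts are unaffected and variance is
reduced).  The hypergeometric sampler is a port of the HRUA* rejection
algorithm, constant-time in the population size, validated against
`scipy.stats.hypergeom`.

An explicit per-neuron simulator with the full `N×N` weight matrix
(quadratic per step, intended for `N ≲ 200`) serves as an independent
cross-check; the test suite verifies distributional agreement of the
two forms by Kolmogorov–Smirnov tests on per-step totals.  Per-neuron
rasters of `M` tracked neurons are generated by allocating the
hypergeometrically coupled class counts uniformly at random among the
tracked non-refractory neurons, so tracked rasters are marginally
identical to sampled traces.

Runs always start from the all-quiescent state and are never
concatenated; every run draws an independent seed stream from a
`SeedSequence` spawn of the user seed.

### Branching-ratio estimation

The empirical branching ratio averages `(a(t+1) - N·λ)/a(t)` over steps
whose activity lies in the window `100·N·λ < a(t) < 1000·N·λ` (2 000 to
20 000 spikes at default parameters).  The floor matters: at low
activity the rectification of negative fields makes conditional growth
exceed `σ` substantially (measured ≈ 1.76 at criticality when
conditioning on `a < 200`), because the E/I composition of a small spike
count fluctuates strongly and negative fields are clipped to zero while
positive fluctuations are kept.  Inside the window the estimator
reproduces `σ(g)` to better than 1.5% over `g ∈ [3.5, 3.75]`.  The
ceiling keeps refractory saturation negligible.  Supercritical networks
saturate at high activity and only traverse the window during their
initial transient, so `ensemble_branching_ratio` pools eligible steps
over many short runs started from quiescence.

The same rectification raises the stationary activity of subcritical
networks above the linear-theory prediction `N·λ/(1-σ)`: at `g = 3.75`
the measured long-run mean is ≈ 130 spikes/step versus 40 predicted.
This is a property of the model (the linear prediction ignores the
`clip` at 0), not of the integrator.

## Avalanche definition

An avalanche is a maximal run of contiguous bins whose (possibly
coarse-grained) activity is at or above the coincident-firing threshold
θ; "surpassing" is inclusive, so a 1-spike threshold admits single
spikes.  Size is the summed activity over the run (subthreshold parts of
suprathreshold bins included; an exclusive convention can be obtained by
subtracting `θ·T`), duration the run length in bins.  Coarse-graining
sums non-overlapping windows of `k` bins (half-open, 0-based; a trailing
remainder is dropped).  Subsampling and coarse-graining commute for
summed counts, so their order is immaterial.  Avalanches never span run
or recording boundaries.  On integer spike data a requested threshold
`0 < θ < 1` is rejected as unobservable rather than silently rounded —
this is what produces the unobservable regions of the rescue maps under
heavy subsampling.

## Exponent estimation

The scaling exponent χ is the initial slope `σ1` of the double power law

    S(d) = C · d^σ1 · (1 + (d/Φ)^γ)^((σ2-σ1)/γ),     γ = 4 fixed,

fitted to mean size versus duration by least squares in log-log space,
one equal-weight point per observed duration.  The exponent form
`(σ2-σ1)/γ` makes the large-`d` slope equal `σ2`, as the construction
requires.  Fits are multi-started (`σ1` from the first-decade slope,
`σ2` from the last decade, `Φ` from the slope-change elbow plus fixed
quantiles of the duration range), ties broken by residual then smaller
`Φ`.  `Φ` is constrained to lie at or above the smallest observed
duration: if the optimizer pushes it to that boundary there are no data
on the initial branch, `σ1` is unconstrained, and χ is reported
undefined.  A fitted `Φ` beyond the largest duration means a pure power
law (`Φ` unidentifiable, flagged).  Curves with fewer than 4 distinct
durations or spanning less than a decade are flagged low-confidence.

The distribution exponents α (sizes) and β (durations) are measured on
truncated windows: sizes on `[max(100, θ), <S>(Φ)]` — 100 is safely
above the Poisson noise floor, θ is the smallest attainable size, and
the upper cutoff is the *fitted* curve value at Φ — durations on
`[3, Φ]`.  Two estimators are provided:

* a log-binned regression slope (default): density on logarithmic bins
  regressed against bin centers in log-log space;
* a truncated maximum-likelihood estimator, discrete (generalized
  harmonic-sum normalization) or continuous, maximized numerically with
  curvature-based standard errors.

The MLE is exactly calibrated on pure truncated power laws (verified by
simulation across exponents 1.2–2.0), but on the simulated avalanche
distributions — which are curved inside the window by the drive floor
and the finite network size — it is dominated by the lower window edge:
it under-reads the duration slope and behaves erratically near the
α → 1 crossing induced by strong coarse-graining.  The binned slope
tracks the displayed log-log slope smoothly through that crossing and is
therefore the default for the exponent suite; both remain selectable.

The crackling-noise prediction is `χ_cn = (β-1)/(α-1)`, undefined
(singularity flag) when `|α-1| ≤ 0.02`; the deviation-from-criticality
coefficient is `DCC = χ - χ_cn`.

### Validity rules

An avalanche set yields exponents only if (i) at least one avalanche
exceeds 20 coarse bins, (ii) it contains at least 50 avalanches, and
(iii) its suprathreshold occupancy is below 99%.  The occupancy rule
deserves comment: when essentially every bin is suprathreshold the
"avalanches" are complements of rare gaps, and their fitted slopes are
arbitrary (values from −9 to +3.5 were observed in such cells).  All
physically interpreted cells in the analyses here have occupancy below
0.97.

For recording-style analyses ("first-4-generations" mode) χ is the
regression slope of `log <S>` on `log T` over durations 1–4 only, while
cutoffs still come from the double fit and the size floor drops to the
spike-density scale.

## Collapse analysis

To quantify the threshold–subsampling equivalence, χ-versus-k curves at
thresholds `θ = θ100·f^ξ` (rounded to integers, minimum 1 spike, values
below 0.5 unobservable) are compared across sampling fractions for each
reference threshold `θ100 ∈ {1e2, 1e3, 1e4}` while ξ scans 0–2 in steps
of 0.1.  The collapse error — not fixed by any external convention, so
defined here — is the across-`f` population variance of χ(k), averaged
over `θ100` and the shared k grid (invalid points excluded pairwise),
normalized by the squared range of the pooled χ values.  It is zero for
identical curves, invariant under curve relabeling, and dimensionless so
that different `θ100` contribute commensurably.  On the critical model
the error profile is smooth and unimodal with its minimum at ξ = 1, two
orders of magnitude below the profile ends.

## Delayed pairwise correlations

For `M` tracked neurons over a 10⁴-step segment, each spike train is
coarse-grained by `k`, and for every ordered pair `(i, j)`, `i ≠ j`, the
product-moment correlation is taken between `series_i[0:L-1]` and
`series_j[1:L]` (lag of one coarse bin; the lag is applied to the target
neuron `j`).  Pairs in which either lagged series is constant have
undefined correlation and are excluded, with the valid-pair count
reported.  Sampling is kept at or below 1% of the network — the pair
count grows quadratically and adds nothing, since the mean curve is
independent of the sampled fraction at criticality.

## Synthetic recordings

The generator emulates two-photon population recordings: `n_rec = 17`
recordings of 30 minutes at 45.527 Hz, each with 200–400 ROIs.  Per
recording it tracks that many neurons in a critically balanced network,
sums spikes into imaging frames (2 simulation steps per frame), applies
per-ROI lognormal gains (σ = 0.25), adds a sparse truncated-normal noise
floor (`max(N(-0.04, 0.02), 0)` per ROI-frame, i.e. a small spurious
density on ~2% of frames, as appropriate for denoised and deconvolved
high-SNR data — a dense every-frame floor measurably destroys the
lognormal shape of the count curve), and scales the whole recording by
a lognormal rate multiplier (σ = 0.3) emulating across-experiment
variability.

The generator's network holds `N = 5e4` neurons, so a few hundred ROIs
correspond to an effective sampling fraction around half a percent.
This reading — a 450 µm field of view samples the *local* circuit, not
an idealized million-neuron network — is what lets the recording-style
pipeline reproduce the reference phenomenology: with `f ≈ 1e-3` of a
`1e6`-neuron network the duration-1–4 slope estimator cannot exceed
χ ≈ 1.8 on this model, while at `f ≈ 5e-3` the z-scored maps show a
contiguous band of χ between 1.8 and 2.0 across z-scored thresholds
from −1 to +0.5 whose supporting k-range shrinks as the threshold
rises, and the subcritical (g = 3.75) generator never exceeds χ ≈ 1.5.

What the generator does *not* emulate: calcium indicator dynamics and
deconvolution artifacts, spatial ROI structure and overlap, slow
non-stationarities (drift, behavioral state), and temporal correlations
between successive avalanches.  Passing the synthetic end-to-end tests
therefore shows that the analysis stack recovers the scaling of a
critical branching process under realistic sampling, gain, and noise
distortions — not that any particular real recording is critical.

### z-scoring

The avalanche count versus threshold curve of each recording is fitted,
per coarse-graining factor, with a Gaussian in `ln θ` by least squares
(grid: 41 logarithmic thresholds from the 1st percentile of positive
activity, capped at three decades below the peak, up to the maximum);
a threshold's z-score is `z = (ln θ - μ̂)/σ̂`.  The z-scored map
converts each z back to a recording-specific θ per `(recording, k)`,
estimates exponents per recording in first-4 mode, and averages valid
values per cell; cells supported by fewer than two valid recordings are
masked, since a single noisy recording can contribute an arbitrary
slope.  A pooled mode (absolute threshold, avalanches pooled across
recordings before one fit) is also provided; for identical recordings
the two agree.

## Problem sizes and determinism

Reported analyses use desk-scale runs: the acceptance script simulates
8 × 5e6 = 4e7 steps of the `N = 1e6` network (the exact O(1) count
chain makes this a ~2-minute computation), the test suite 4 × 2e6
steps; correlation segments are 10⁴ steps; synthetic-recording checks
use the full 17 × 30 min default.  All randomness flows from a single
`SeedSequence` per entry point; identical seeds give identical outputs,
and kernel seeds are recorded in the produced objects.

## Known limitations

* Leaky dynamics (μ ≠ 0), heterogeneous weights, and structured or
  sparse connectivity are out of scope; the count chain is exact only
  for the class-uniform all-to-all topology.
* Exponent estimates at desk scale sit slightly below the asymptotic
  values (e.g. α ≈ 1.4 rather than 1.5 at `k = 1, θ = 100`); they are
  stable across seeds and data volume, reflecting the drive floor and
  finite size rather than sampling noise.
* The DCC is reported as defined but is fragile by construction: it
  inherits the α → 1 singularity of the crackling-noise prediction
  under coarse-graining and is meaningful only away from it.
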