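"""Recording-style avalanche analysis and a synthetic-recording generator.

Two-photon population recordings deliver, per region of interest (ROI),
a non-negative spike-density trace sampled at the imaging frame rate.
Avalanche analysis of such data differs from the simulation pipeline in
two ways: thresholds are real-valued (spike densities are continuous),
and the number of avalanches as a function of threshold follows a
lognormal-shaped curve whose location varies across recordings and with
temporal coarse-graining.  To compare thresholds across recordings, the
count-versus-threshold curve is fitted with a Gaussian in ln(theta) and
thresholds are expressed as z-scores z = (ln theta - mu)/sigma of that
fit, inverted per recording and per k.

The synthetic generator emulates such recordings from the critical
branching network: a per-recording random subset of neurons is tracked,
spike counts are mapped to imaging frames, converted to densities with
per-ROI gains and an additive truncated-normal noise floor, and scaled
by a per-recording lognormal rate multiplier to mimic experimental
variability.  It reproduces the lognormal count-curve shape and the
coarse-graining rescue of chi ~ 2, but not calcium indicator dynamics,
deconvolution artifacts, or spatial ROI structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cascade import AvalancheSet, apply_threshold, coarse_grain, extract_avalanches
from .scalingfit import ExponentSet, exponent_suite
from .simcore import ModelParams, make_params, simulate_raster

__all__ = [
    "RecordingParams",
    "RecordingRaster",
    "ThresholdNumberCurve",
    "generate_recordings",
    "avalanche_count_vs_threshold",
    "zscored_chi_map",
    "ExperimentalMap",
]

FRAME_RATE_HZ = 45.527


@dataclass(frozen=True)
class RecordingParams:
    """Knobs of the synthetic-recording generator.

    Defaults emulate the reference acquisition conditions: ~30-minute
    recordings at 45.527 Hz with 200-400 ROIs drawn from a critically
    balanced network of 5e4 neurons -- a few hundred somata imaged in one
    plane of a local cortical circuit, i.e. an effective sampling
    fraction around half a percent.  ``steps_per_frame`` maps network time steps onto
    imaging frames (frame = sum of that many steps).  ``gain_sigma`` is
    the lognormal spread of per-ROI gains; the noise floor adds
    ``max(Normal(noise_loc, noise_scale), 0)`` per ROI-frame -- with the
    default negative location only a few percent of frames receive a
    small spurious density, mimicking residual false positives of
    high-SNR denoised-and-deconvolved traces; ``rate_sigma`` is the
    lognormal spread of the per-recording rate multiplier emulating
    across-experiment variability.
    """

    network: ModelParams = field(default_factory=lambda: make_params(N=50_000))
    frame_rate: float = FRAME_RATE_HZ
    duration_s: float = 1800.0
    steps_per_frame: int = 2
    roi_range: tuple[int, int] = (200, 400)
    gain_sigma: float = 0.25
    noise_scale: float = 0.02
    noise_loc: float = -0.04
    rate_sigma: float = 0.3

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass
class RecordingRaster:
    """ROI x frame matrix of non-negative spike densities."""

    densities: np.ndarray
    frame_rate: float = FRAME_RATE_HZ
    rec_id: int = 0
    animal_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.densities = np.asarray(self.densities)
        if not np.issubdtype(self.densities.dtype, np.floating):
            self.densities = self.densities.astype(np.float32)
        if self.densities.ndim != 2:
            raise ValueError("densities must be an (ROI, frame) matrix")
        if not np.all(np.isfinite(self.densities)):
            raise ValueError("densities must be finite")
        if self.densities.min() < 0:
            raise ValueError("densities must be non-negative")

    @property
    def n_roi(self) -> int:
        return self.densities.shape[0]

    @property
    def n_frames(self) -> int:
        return self.densities.shape[1]

    def population_activity(self) -> np.ndarray:
        """Per-frame summed spike density over ROIs."""
        return self.densities.sum(axis=0, dtype=np.float64)


def generate_recordings(params: RecordingParams | None = None, n_rec: int = 17,
                        seed: int | None = None) -> list[RecordingRaster]:
    """Generate synthetic recordings from the branching network.

    Each recording draws its own ROI count from ``roi_range``, tracks
    that many neurons through :func:`avascale.simcore.simulate_raster`,
    sums spikes into imaging frames, applies per-ROI gains and the
    additive noise floor, and scales by the per-recording rate
    multiplier.  Identical seeds give identical recordings.
    """
    if n_rec < 1:
        raise ValueError("n_rec must be >= 1")
    if params is None:
        params = RecordingParams()
    lo, hi = params.roi_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid roi_range {params.roi_range}")
    if params.n_frames < 2 or params.steps_per_frame < 1:
        raise ValueError("invalid recording dimensions")
    ss = np.random.SeedSequence(seed)
    out = []
    for rec_id, child in enumerate(ss.spawn(n_rec)):
        rng = np.random.default_rng(child)
        M = int(rng.integers(lo, hi + 1))
        steps = params.n_frames * params.steps_per_frame
        raster_seed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF) ^ 0x5A5A
        raster, _ = simulate_raster(params.network, M=M, steps=steps, seed=raster_seed)
        spikes = raster.to_dense()[:, 1:]
        frames = spikes.reshape(M, params.n_frames, params.steps_per_frame) \
            .sum(axis=2, dtype=np.int32)
        gains = rng.lognormal(mean=0.0, sigma=params.gain_sigma, size=(M, 1)) \
            if params.gain_sigma > 0 else np.ones((M, 1))
        # float32 keeps a full 17-recording session comfortably in memory
        dens = (frames * gains).astype(np.float32)
        if params.noise_scale > 0:
            noise = rng.normal(params.noise_loc, params.noise_scale,
                               size=dens.shape).astype(np.float32)
            dens += np.maximum(noise, np.float32(0.0))
        rate = rng.lognormal(mean=0.0, sigma=params.rate_sigma) \
            if params.rate_sigma > 0 else 1.0
        dens *= rate
        out.append(RecordingRaster(
            densities=dens, frame_rate=params.frame_rate, rec_id=rec_id,
            meta={"M": M, "f": M / params.network.N, "rate_multiplier": rate,
                  "seed": raster_seed, "g": params.network.g,
                  "steps_per_frame": params.steps_per_frame}))
    return out


@dataclass
class ThresholdNumberCurve:
    """Avalanche count versus threshold at one coarse-graining factor.

    ``mu`` and ``sigma`` are the location and scale (in ln theta) of the
    Gaussian fitted to the (ln theta, count) curve; the z-map
    ``z(theta) = (ln theta - mu)/sigma`` makes thresholds comparable
    across recordings and coarse-graining factors.
    """

    theta: np.ndarray
    counts: np.ndarray
    k: int
    mu: float = np.nan
    sigma: float = np.nan
    amplitude: float = np.nan
    r2: float = np.nan
    fit_ok: bool = False

    def z_of_theta(self, theta) -> np.ndarray:
        return (np.log(theta) - self.mu) / self.sigma

    def theta_of_z(self, z) -> np.ndarray:
        return np.exp(self.mu + np.asarray(z, dtype=float) * self.sigma)


def _count_avalanches(activity: np.ndarray, theta: float) -> int:
    sup = activity >= theta
    if not sup.any():
        return 0
    return int(np.count_nonzero(np.diff(np.concatenate([[False], sup]).astype(np.int8)) == 1))


def avalanche_count_vs_threshold(raster, theta_grid=None, k: int = 1) -> ThresholdNumberCurve:
    """Count avalanches per threshold and fit the lognormal-shaped curve.

    The population activity (per-frame sum over ROIs) is coarse-grained
    by ``k``; for each threshold the number of suprathreshold epochs is
    counted, and a Gaussian in ln(theta) is fitted to the counts by least
    squares.  When the fit fails the absolute-threshold counts remain
    usable but the z-map is unavailable (``fit_ok = False``).
    """
    activity = raster.population_activity() if isinstance(raster, RecordingRaster) \
        else np.asarray(raster, dtype=np.float64)
    act = coarse_grain(activity, k)
    if theta_grid is None:
        top = act.max()
        if top <= 0:
            return ThresholdNumberCurve(theta=np.array([]), counts=np.array([], dtype=int), k=k)
        # span at most ~3 decades below the peak: far smaller thresholds sit
        # below the noise dust, where counts no longer follow the lognormal bulk
        floor = max(np.percentile(act[act > 0], 1.0), top * 1e-3, 1e-9)
        theta_grid = np.geomspace(floor, top * 1.001, 41)
    theta_grid = np.asarray(theta_grid, dtype=np.float64)
    if len(theta_grid) == 0 or theta_grid.min() <= 0:
        raise ValueError("theta grid must be positive")
    counts = np.array([_count_avalanches(act, th) for th in theta_grid])
    curve = ThresholdNumberCurve(theta=theta_grid, counts=counts, k=int(k))
    ok = counts > 0
    if ok.sum() < 4:
        return curve
    lt = np.log(theta_grid[ok])
    y = counts[ok].astype(np.float64)

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = [y.max(), lt[np.argmax(y)], max((lt.max() - lt.min()) / 4.0, 0.1)]
    try:
        popt, _ = curve_fit(gauss, lt, y, p0=p0, maxfev=10_000)
    except RuntimeError:
        return curve
    a, mu, sig = popt
    sig = abs(float(sig))
    if sig <= 0 or not np.isfinite(mu):
        return curve
    resid = y - gauss(lt, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    curve.amplitude, curve.mu, curve.sigma = float(a), float(mu), sig
    curve.r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else np.nan
    curve.fit_ok = True
    return curve


@dataclass
class ExperimentalMap:
    """chi and DCC over (threshold-or-z, k) cells, aggregated over recordings."""

    rows: np.ndarray          # z values or absolute thresholds
    k_grid: np.ndarray
    chi: np.ndarray           # (len(rows), len(k_grid)); NaN = masked
    dcc: np.ndarray
    n_valid: np.ndarray
    mode: str


def _recording_avalanches(activity: np.ndarray, k: int, theta: float) -> AvalancheSet:
    cg = coarse_grain(activity, k)
    th = apply_threshold(cg, theta, integer_data=False)
    return extract_avalanches(th, k=k, theta=theta)


def zscored_chi_map(recordings, z_grid=None, k_grid=(1, 2, 4, 8, 16, 32),
                    mode: str = "zscore", theta_grid=None,
                    min_recordings: int = 2,
                    **suite_kw) -> ExperimentalMap:
    """chi and DCC maps for a set of recordings.

    ``mode="zscore"``: each z is converted, per recording and per k, to
    its recording-specific threshold via the fitted z-map; avalanches are
    extracted, exponents estimated recording-wise in duration-1-4 mode
    (with the >20-generation validity rule), and valid chi/DCC values are
    averaged across recordings per (z, k) cell.  Cells supported by fewer
    than ``min_recordings`` valid recordings (a single noisy recording
    can contribute an arbitrary slope) or with no usable z-map are NaN.

    ``mode="pooled"``: ``theta_grid`` gives absolute spike-density
    thresholds; avalanches from all recordings are pooled per (theta, k)
    before a single exponent fit.
    """
    recordings = list(recordings)
    if not recordings:
        raise ValueError("need at least one recording")
    k_grid = np.asarray(list(k_grid))
    suite_kw.setdefault("size_min", 1.0)
    activities = [r.population_activity() if isinstance(r, RecordingRaster)
                  else np.asarray(r, dtype=float) for r in recordings]
    if mode == "zscore":
        rows = np.asarray(list(z_grid if z_grid is not None
                               else np.arange(-2.0, 1.75, 0.25)), dtype=float)
        chi = np.full((len(rows), len(k_grid)), np.nan)
        dcc = np.full_like(chi, np.nan)
        n_valid = np.zeros_like(chi, dtype=int)
        per_rec: list[list[ExponentSet | None]] = []
        for act in activities:
            for kj, k in enumerate(k_grid):
                curve = avalanche_count_vs_threshold(act, k=int(k))
                for zi, z in enumerate(rows):
                    if not curve.fit_ok:
                        continue
                    theta = float(curve.theta_of_z(z))
                    es = exponent_suite(
                        _recording_avalanches(act, int(k), theta),
                        mode="first4", **suite_kw)
                    if es.valid and np.isfinite(es.chi):
                        n_valid[zi, kj] += 1
                        chi[zi, kj] = es.chi if n_valid[zi, kj] == 1 \
                            else chi[zi, kj] + (es.chi - chi[zi, kj]) / n_valid[zi, kj]
                        if np.isfinite(es.dcc):
                            dcc[zi, kj] = es.dcc if not np.isfinite(dcc[zi, kj]) \
                                else dcc[zi, kj] + (es.dcc - dcc[zi, kj]) / n_valid[zi, kj]
        thin = n_valid < min(min_recordings, len(recordings))
        chi[thin] = np.nan
        dcc[thin] = np.nan
        return ExperimentalMap(rows=rows, k_grid=k_grid, chi=chi, dcc=dcc,
                               n_valid=n_valid, mode=mode)
    if mode == "pooled":
        if theta_grid is None:
            raise ValueError("pooled mode requires an absolute theta_grid")
        rows = np.asarray(list(theta_grid), dtype=float)
        chi = np.full((len(rows), len(k_grid)), np.nan)
        dcc = np.full_like(chi, np.nan)
        n_valid = np.zeros_like(chi, dtype=int)
        for ti, theta in enumerate(rows):
            for kj, k in enumerate(k_grid):
                sets = [_recording_avalanches(act, int(k), float(theta))
                        for act in activities]
                pooled = AvalancheSet(
                    sizes=np.concatenate([s.sizes for s in sets]),
                    durations=np.concatenate([s.durations for s in sets]),
                    k=int(k), theta=float(theta))
                es = exponent_suite(pooled, mode="first4", **suite_kw)
                if es.valid:
                    chi[ti, kj] = es.chi
                    dcc[ti, kj] = es.dcc
                    n_valid[ti, kj] = len(recordings)
        return ExperimentalMap(rows=rows, k_grid=k_grid, chi=chi, dcc=dcc,
                               n_valid=n_valid, mode=mode)
    raise ValueError(f"unknown mode {mode!r}")
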