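"""From activity time series to avalanches.

An avalanche is a maximal run of contiguous time bins in which the
(possibly coarse-grained) population activity stays at or above a
coincident-firing threshold theta; its size S is the summed activity over
the run and its duration T the number of bins.  The standard pipeline is

    subsample -> coarse_grain(k) -> apply_threshold(theta) -> extract_avalanches

pooled over independent runs (avalanches never span run boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simcore import PopulationTrace, SampledTrace

__all__ = [
    "ActivitySeries",
    "AvalancheSet",
    "UnobservableThresholdError",
    "coarse_grain",
    "apply_threshold",
    "extract_avalanches",
    "avalanche_pipeline",
]


class UnobservableThresholdError(ValueError):
    """Threshold below the 1-spike resolution of integer spike data.

    On integer spike counts a fractional threshold 0 < theta < 1 cannot be
    realized (every nonzero bin already exceeds it while zero bins never
    do, making it indistinguishable from theta = 1 only after rounding);
    such requests are flagged rather than silently rounded.
    """


@dataclass
class ActivitySeries:
    """One activity series with its provenance.

    ``values`` holds non-negative activity per bin: integer spike counts
    for simulations, real spike densities for recordings.  ``k`` is the
    coarse-graining factor (bin width k * dt) and ``f`` the sampling
    fraction that produced the series.
    """

    values: np.ndarray
    k: int = 1
    f: float = 1.0
    source: str | int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("activity series must be one-dimensional")
        if len(self.values) and self.values.min() < 0:
            raise ValueError("activity values must be non-negative")
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError(f"k must be a positive integer, got {self.k}")


@dataclass
class AvalancheSet:
    """Sizes and durations of avalanches with their extraction parameters."""

    sizes: np.ndarray
    durations: np.ndarray
    k: int = 1
    theta: float = 0.0
    f: float = 1.0
    run_ids: np.ndarray | None = None
    n_bins: int = 0  # length of the thresholded series the set came from

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if len(self.sizes) != len(self.durations):
            raise ValueError("sizes and durations must have equal length")

    def __len__(self) -> int:
        return len(self.sizes)

    @property
    def max_duration(self) -> int:
        return int(self.durations.max()) if len(self.durations) else 0

    @property
    def occupancy(self) -> float:
        """Fraction of bins that are suprathreshold (NaN when unknown)."""
        if self.n_bins <= 0:
            return float("nan")
        return float(self.durations.sum() / self.n_bins)


def _as_values(series) -> np.ndarray:
    if isinstance(series, ActivitySeries):
        return series.values
    if isinstance(series, PopulationTrace):
        return series.total
    if isinstance(series, SampledTrace):
        return series.counts
    return np.asarray(series)


def coarse_grain(series, k: int):
    """Sum activity over non-overlapping windows of ``k`` bins.

    Windows are half-open ``[i*k, (i+1)*k)``; a trailing remainder shorter
    than ``k`` is dropped, so total activity is conserved up to that
    remainder.  ``k = 1`` is the identity.
    """
    if int(k) != k or k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    k = int(k)
    x = _as_values(series)
    n = (len(x) // k) * k
    out = x[:n].reshape(-1, k).sum(axis=1)
    if isinstance(series, ActivitySeries):
        return ActivitySeries(values=out, k=series.k * k, f=series.f,
                              source=series.source)
    return out


def apply_threshold(series, theta: float, *, integer_data: bool | None = None):
    """Zero all bins with activity strictly below ``theta``.

    Bins at or above theta are kept unchanged ("surpassing" is inclusive:
    a 1-spike threshold admits single spikes).  On integer spike data a
    fractional threshold 0 < theta < 1 raises
    :class:`UnobservableThresholdError`.
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    x = _as_values(series)
    if integer_data is None:
        integer_data = np.issubdtype(x.dtype, np.integer)
    if integer_data and 0 < theta < 1:
        raise UnobservableThresholdError(
            f"theta = {theta} is below the 1-spike resolution of integer data")
    out = np.where(x >= theta, x, 0)
    if isinstance(series, ActivitySeries):
        return ActivitySeries(values=out, k=series.k, f=series.f,
                              source=series.source)
    return out


def extract_avalanches(series, k: int = 1, theta: float = 0.0,
                       f: float = 1.0) -> AvalancheSet:
    """Extract maximal runs of nonzero bins from an already-thresholded series.

    Each run contributes one avalanche with size = summed bin values and
    duration = run length in bins.  An empty or all-zero series yields an
    empty set.
    """
    x = _as_values(series)
    if isinstance(series, ActivitySeries):
        k, f = series.k, series.f
    if len(x) == 0:
        return AvalancheSet(sizes=np.array([]), durations=np.array([], dtype=np.int64),
                            k=k, theta=theta, f=f, n_bins=0)
    nz = x > 0
    d = np.diff(nz.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if nz[0]:
        starts = np.concatenate([[0], starts])
    if nz[-1]:
        ends = np.concatenate([ends, [len(x)]])
    cs = np.concatenate([[0], np.cumsum(x, dtype=np.float64 if x.dtype.kind == "f"
                                        else np.int64)])
    sizes = cs[ends] - cs[starts]
    durations = ends - starts
    return AvalancheSet(sizes=sizes, durations=durations, k=k, theta=theta, f=f,
                        n_bins=len(x))


def avalanche_pipeline(traces, k: int = 1, theta: float = 0.0,
                       f: float | None = None) -> AvalancheSet:
    """Full extraction pipeline, pooled over runs.

    ``traces`` may be a single trace/series/array or an iterable of them
    (one per independent run); avalanches never span run boundaries.  The
    extraction parameters are recorded in the returned
    :class:`AvalancheSet`.
    """
    if isinstance(traces, (ActivitySeries, PopulationTrace, SampledTrace, np.ndarray)):
        traces = [traces]
    sizes, durations, run_ids = [], [], []
    n_bins = 0
    f_seen = f
    for rid, tr in enumerate(traces):
        if f_seen is None:
            if isinstance(tr, SampledTrace):
                f_seen = tr.f
            elif isinstance(tr, ActivitySeries):
                f_seen = tr.f
        cg = coarse_grain(tr, k)
        th = apply_threshold(cg, theta)
        av = extract_avalanches(th, k=k, theta=theta)
        n_bins += av.n_bins if av.n_bins else len(_as_values(th))
        sizes.append(av.sizes)
        durations.append(av.durations)
        run_ids.append(np.full(len(av), rid, dtype=np.int64))
    return AvalancheSet(
        sizes=np.concatenate(sizes) if sizes else np.array([]),
        durations=np.concatenate(durations) if durations else np.array([], dtype=np.int64),
        k=int(k), theta=theta, f=1.0 if f_seen is None else float(f_seen),
        run_ids=np.concatenate(run_ids) if run_ids else None, n_bins=n_bins)
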