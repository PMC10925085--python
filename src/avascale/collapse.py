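"""Threshold-subsampling equivalence via curve collapse.

Raising the coincident-firing threshold on a fully sampled network and
lowering the sampling fraction f at a fixed threshold bias avalanche
scaling in the same way.  To quantify the equivalence, chi-versus-k
curves measured at different f are compared after rescaling the
threshold as theta = theta100 * f**xi; the exponent xi that minimizes
the total collapse error of the curves (xi* = 1 for the all-to-all
model) measures how the threshold trades against the sampled fraction.

The collapse error of a family of curves is the across-f variance of
chi(k), averaged over the reference thresholds theta100 and the shared
k grid, normalized by the squared range of the pooled chi values; it is
zero iff all curves coincide and invariant to relabeling the curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ChiCurveFamily",
    "CollapseScan",
    "rescaled_threshold",
    "collapse_error",
    "scan_collapse",
    "chi_fn_from_traces",
]


def chi_fn_from_traces(traces_by_f: dict, **suite_kw) -> Callable[[float, int, int], float]:
    """Build a cached ``chi_fn(f, theta, k)`` from per-fraction count series.

    ``traces_by_f`` maps each sampling fraction to a list of per-run
    count arrays (or trace objects).  Coarse-grained series and fitted
    exponents are cached, since a collapse scan revisits the same
    (f, theta, k) cells for many xi values.  The returned function yields
    the double-power-law chi of the pooled avalanche set, or NaN when the
    cell fails the long-avalanche validity rule or the fit does not
    converge.
    """
    from .cascade import _as_values, apply_threshold, coarse_grain, extract_avalanches
    from .cascade import AvalancheSet
    from .scalingfit import exponent_suite

    arrays = {float(f): [np.asarray(_as_values(t)) for t in traces]
              for f, traces in traces_by_f.items()}
    coarse: dict = {}
    chi_cache: dict = {}

    def chi_fn(f: float, theta: int, k: int) -> float:
        key = (f, theta, k)
        if key in chi_cache:
            return chi_cache[key]
        ck = (f, k)
        if ck not in coarse:
            coarse[ck] = [coarse_grain(a, k) for a in arrays[f]]
        sizes, durations = [], []
        n_bins = 0
        for cg in coarse[ck]:
            av = extract_avalanches(apply_threshold(cg, theta), k=k, theta=theta)
            sizes.append(av.sizes)
            durations.append(av.durations)
            n_bins += len(cg)
        pooled = AvalancheSet(sizes=np.concatenate(sizes),
                              durations=np.concatenate(durations),
                              k=k, theta=theta, f=f, n_bins=n_bins)
        es = exponent_suite(pooled, **suite_kw)
        chi = es.chi if (es.valid and es.converged) else float("nan")
        chi_cache[key] = chi
        return chi

    return chi_fn


def rescaled_threshold(theta100: float, f: float, xi: float) -> int | None:
    """Threshold for sampling fraction ``f``: theta100 * f**xi, integerized.

    The rescaled value is rounded to the nearest integer with a minimum
    of 1 spike; values below 0.5 before rounding are unobservable on
    integer spike data and return ``None``.
    """
    if theta100 < 1:
        raise ValueError(f"theta100 must be >= 1, got {theta100}")
    if not 0.0 < f <= 1.0:
        raise ValueError(f"f must lie in (0, 1], got {f}")
    if xi < 0:
        raise ValueError(f"xi must be >= 0, got {xi}")
    theta = theta100 * f ** xi
    if theta < 0.5:
        return None
    return max(1, int(round(theta)))


@dataclass
class ChiCurveFamily:
    """chi(k) curves on a shared k grid, grouped by reference threshold.

    ``curves`` maps (theta100, f) -> array of chi over ``k_grid`` (NaN
    marks invalid points, which are excluded pairwise).
    """

    k_grid: np.ndarray
    curves: dict

    def groups(self) -> dict:
        by_theta = {}
        for (theta100, f), chi in self.curves.items():
            by_theta.setdefault(theta100, {})[f] = np.asarray(chi, dtype=float)
        return by_theta


def collapse_error(family: ChiCurveFamily) -> float:
    """Normalized total collapse error of a chi-curve family.

    For each theta100 and each k where at least two sampling fractions
    have a valid chi, the across-f population variance of chi(k) is
    computed; the error is the mean of those variances divided by the
    squared range of all pooled finite chi values.  Identical curves give
    0; fewer than two comparable curves anywhere give NaN.
    """
    pooled = np.concatenate([np.asarray(c, dtype=float).ravel()
                             for c in family.curves.values()]) \
        if family.curves else np.array([])
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        return float("nan")
    rng2 = (pooled.max() - pooled.min()) ** 2
    variances = []
    for theta100, by_f in family.groups().items():
        if len(by_f) < 2:
            continue
        mat = np.vstack(list(by_f.values()))  # (n_f, n_k)
        for j in range(mat.shape[1]):
            col = mat[:, j]
            col = col[np.isfinite(col)]
            if len(col) >= 2:
                variances.append(np.var(col))
    if not variances:
        return float("nan")
    mean_var = float(np.mean(variances))
    if rng2 == 0.0:
        return 0.0 if mean_var == 0.0 else float("inf")
    return mean_var / rng2


@dataclass
class CollapseScan:
    """Collapse error per candidate exponent xi, and its arg-min."""

    xi_grid: np.ndarray
    errors: np.ndarray
    xi_star: float


def scan_collapse(chi_fn: Callable[[float, int, int], float],
                  fractions: Sequence[float],
                  theta100s: Sequence[float],
                  xi_grid: Sequence[float] | None = None,
                  k_grid: Sequence[int] = (1, 2, 4, 8, 16, 32, 64)) -> CollapseScan:
    """Scan the collapse exponent xi and locate the minimum-error value.

    ``chi_fn(f, theta, k)`` must return the fitted scaling exponent (NaN
    when invalid) for sampling fraction f, integer threshold theta and
    coarse-graining k; callers typically wrap the avalanche pipeline with
    a cache keyed on (f, theta, k) since different xi often land on the
    same rounded threshold.  For each xi on the grid (default 0 to 2 in
    steps of 0.1) the rescaled-threshold curve family is assembled and
    its collapse error computed; xi values whose family has no
    comparable curves are excluded (NaN error).
    """
    if len(fractions) < 2:
        raise ValueError("need at least two sampling fractions to collapse")
    if xi_grid is None:
        xi_grid = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)
    xi_grid = np.asarray(list(xi_grid), dtype=float)
    k_grid = np.asarray(list(k_grid))
    errors = np.full(len(xi_grid), np.nan)
    for i, xi in enumerate(xi_grid):
        curves = {}
        for theta100 in theta100s:
            for f in fractions:
                theta = rescaled_threshold(theta100, f, xi)
                if theta is None:
                    continue
                chi = np.array([chi_fn(f, theta, int(k)) for k in k_grid])
                if np.isfinite(chi).any():
                    curves[(theta100, f)] = chi
        fam = ChiCurveFamily(k_grid=k_grid, curves=curves)
        errors[i] = collapse_error(fam)
    if not np.isfinite(errors).any():
        raise ValueError("no xi on the grid produced a comparable curve family")
    xi_star = float(xi_grid[np.nanargmin(errors)])
    return CollapseScan(xi_grid=xi_grid, errors=errors, xi_star=xi_star)
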