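"""File formats and reproducible run configurations.

Interchange defaults are plain CSV/TSV: traces as ``t,nE,nI,n_drive``,
sampled counts as ``t,count``, rasters as sparse ``neuron_id<TAB>t``
event lists with a ``#``-prefixed metadata block, avalanches as
``size,duration,k,theta,f,run_id``, and exponent maps in long format.
Every pipeline run driven by a :class:`RunConfig` writes its resolved
configuration beside its outputs so results are reproducible from the
artifacts alone.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cascade import AvalancheSet
from .simcore import PopulationTrace, SampledTrace, TrackedRaster

__all__ = [
    "FormatError",
    "RunConfig",
    "write_trace", "read_trace",
    "write_counts", "read_counts",
    "write_avalanches", "read_avalanches",
    "write_raster", "read_raster",
    "load_config", "save_config", "run_from_config",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_trace(path, trace: PopulationTrace) -> None:
    """Write a population trace as CSV with header ``t,nE,nI,n_drive``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "nE", "nI", "n_drive"])
        for t in range(trace.steps):
            w.writerow([t, int(trace.nE[t]), int(trace.nI[t]), int(trace.n_drive[t])])


def read_trace(path) -> PopulationTrace:
    """Read a ``t,nE,nI,n_drive`` CSV; empty files give an empty trace."""
    nE, nI, nD = [], [], []
    with open(path, newline="") as fh:
        rows = csv.reader(fh)
        header = next(rows, None)
        if header is None:
            return PopulationTrace(nE=np.array([], dtype=np.int64),
                                   nI=np.array([], dtype=np.int64),
                                   n_drive=np.array([], dtype=np.int64))
        if [h.strip() for h in header] != ["t", "nE", "nI", "n_drive"]:
            raise FormatError(f"{path}:1: expected header t,nE,nI,n_drive, got {header}")
        prev_t = -1
        for ln, row in enumerate(rows, start=2):
            try:
                t, e, i, d = (int(v) for v in row)
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}:{ln}: malformed row {row}") from exc
            if t <= prev_t:
                raise FormatError(f"{path}:{ln}: non-monotone time {t}")
            if e < 0 or i < 0 or d < 0:
                raise FormatError(f"{path}:{ln}: negative count")
            prev_t = t
            nE.append(e)
            nI.append(i)
            nD.append(d)
    return PopulationTrace(nE=np.array(nE, dtype=np.int64),
                           nI=np.array(nI, dtype=np.int64),
                           n_drive=np.array(nD, dtype=np.int64))


def write_counts(path, counts, f: float = 1.0) -> None:
    """Write a summed count series as ``t,count`` CSV."""
    values = counts.counts if isinstance(counts, SampledTrace) else np.asarray(counts)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "count"])
        for t, c in enumerate(values):
            w.writerow([t, c])


def read_counts(path) -> np.ndarray:
    """Read a ``t,count`` CSV into an array; empty files give an empty array."""
    out = []
    with open(path, newline="") as fh:
        rows = csv.reader(fh)
        header = next(rows, None)
        if header is None:
            return np.array([], dtype=np.int64)
        if [h.strip() for h in header] != ["t", "count"]:
            raise FormatError(f"{path}:1: expected header t,count, got {header}")
        for ln, row in enumerate(rows, start=2):
            try:
                _, c = row
                c = float(c)
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}:{ln}: malformed row {row}") from exc
            if c < 0:
                raise FormatError(f"{path}:{ln}: negative count")
            out.append(c)
    arr = np.asarray(out)
    if arr.size and np.all(np.mod(arr, 1) == 0):
        arr = arr.astype(np.int64)
    return arr


def write_avalanches(path, avset: AvalancheSet) -> None:
    """Write an avalanche set as ``size,duration,k,theta,f,run_id`` CSV."""
    rid = avset.run_ids if avset.run_ids is not None else np.zeros(len(avset), dtype=int)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["size", "duration", "k", "theta", "f", "run_id"])
        for s, d, r in zip(avset.sizes, avset.durations, rid):
            w.writerow([s, int(d), avset.k, avset.theta, avset.f, int(r)])


def read_avalanches(path) -> AvalancheSet:
    df = pd.read_csv(path)
    need = {"size", "duration"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {need - set(df.columns)}")
    k = int(df["k"].iloc[0]) if "k" in df.columns and len(df) else 1
    theta = float(df["theta"].iloc[0]) if "theta" in df.columns and len(df) else 0.0
    f = float(df["f"].iloc[0]) if "f" in df.columns and len(df) else 1.0
    return AvalancheSet(sizes=df["size"].to_numpy(),
                        durations=df["duration"].to_numpy(),
                        k=k, theta=theta, f=f,
                        run_ids=df["run_id"].to_numpy() if "run_id" in df.columns else None)


def write_raster(path, raster: TrackedRaster, params=None) -> None:
    """Write a sparse event-list TSV with a ``#`` metadata block."""
    with open(path, "w") as fh:
        fh.write(f"# M: {raster.M}\n# M_E: {raster.M_E}\n# steps: {raster.steps}\n")
        fh.write(f"# seed: {raster.seed}\n")
        if params is not None:
            fh.write(f"# params: {json.dumps(asdict(params))}\n")
        fh.write("neuron_id\tt\n")
        for n, t in raster.events:
            fh.write(f"{n}\t{t}\n")


def read_raster(path) -> TrackedRaster:
    meta = {}
    events = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("neuron_id"):
                continue
            try:
                n, t = (int(v) for v in line.split("\t"))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: malformed event {line!r}") from exc
            events.append((n, t))
    ev = np.array(events, dtype=np.int64) if events else np.empty((0, 2), dtype=np.int64)
    seed = meta.get("seed")
    return TrackedRaster(M=int(meta["M"]), M_E=int(meta["M_E"]), events=ev,
                         steps=int(meta["steps"]),
                         seed=None if seed in (None, "None") else int(seed))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One named pipeline run with all its options.

    ``pipeline`` is one of simulate | avalanches | scaling | rescue-map |
    collapse | corr | synth | exp-map; ``options`` mirrors the CLI flags
    of that pipeline; ``seed`` feeds every random draw; ``out`` is the
    output directory.  Configurations round-trip losslessly through YAML.
    """

    pipeline: str
    options: dict = field(default_factory=dict)
    seed: int | None = None
    out: str = "."

    REQUIRED = {
        "simulate": ["g", "steps"],
        "avalanches": ["input", "k", "theta"],
        "scaling": ["avalanches"],
        "rescue-map": ["trace", "k_grid", "theta_grid"],
        "collapse": ["traces", "fractions", "theta100"],
        "corr": ["raster", "k_max"],
        "synth": ["n_rec"],
        "exp-map": ["recordings"],
    }

    def validate(self) -> None:
        if self.pipeline not in self.REQUIRED:
            raise ValueError(f"unknown pipeline {self.pipeline!r}; "
                             f"known: {sorted(self.REQUIRED)}")
        missing = [k for k in self.REQUIRED[self.pipeline] if k not in self.options]
        if missing:
            raise ValueError(f"config for {self.pipeline!r} missing required "
                             f"field(s): {missing}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "pipeline" not in raw:
        raise FormatError(f"{path}: config must be a mapping with a 'pipeline' key")
    cfg = RunConfig(pipeline=raw["pipeline"], options=raw.get("options", {}),
                    seed=raw.get("seed"), out=raw.get("out", "."))
    cfg.validate()
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def run_from_config(cfg: RunConfig):
    """Execute a configured pipeline; identical config + seed => identical outputs.

    Writes the pipeline's result tables plus the resolved configuration
    into ``cfg.out`` and returns the primary in-memory result.
    """
    from . import cascade, collapse as collapse_mod, exppipe, paircorr, scalingfit, simcore

    cfg.validate()
    opts = dict(cfg.options)
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(outdir / f"{cfg.pipeline.replace('-', '_')}_config.yaml", cfg)

    if cfg.pipeline == "simulate":
        params = simcore.make_params(
            g=float(opts["g"]), N=int(opts.get("N", 1_000_000)),
            lambda_drive=float(opts.get("lambda_drive", 2e-5)))
        fractions = [float(f) for f in opts.get("fractions", [])]
        runs = simcore.simulate(params, steps=int(opts["steps"]),
                                n_runs=int(opts.get("runs", 1)),
                                sample_fractions=fractions, seed=cfg.seed)
        for run in runs:
            write_trace(outdir / f"trace_run{run.trace.run_id}.csv", run.trace)
            for f, st in run.samples.items():
                write_counts(outdir / f"counts_run{run.trace.run_id}_f{f:g}.csv", st)
        return runs

    if cfg.pipeline == "avalanches":
        try:
            counts = read_counts(opts["input"])
        except FormatError:
            counts = read_trace(opts["input"]).total  # full trace CSV
        avset = cascade.avalanche_pipeline(counts, k=int(opts["k"]),
                                           theta=float(opts["theta"]),
                                           f=float(opts.get("fraction", 1.0)))
        write_avalanches(outdir / "avalanches.csv", avset)
        return avset

    if cfg.pipeline == "scaling":
        avset = read_avalanches(opts["avalanches"])
        es = scalingfit.exponent_suite(avset, mode=opts.get("mode", "full"))
        pd.DataFrame([vars(es)]).to_csv(outdir / "exponents.csv", index=False)
        return es

    if cfg.pipeline == "rescue-map":
        counts = read_counts(opts["trace"])
        rmap = scalingfit.rescue_map(
            counts, f=float(opts.get("fraction", 1.0)),
            k_grid=[int(k) for k in opts["k_grid"]],
            theta_grid=[float(t) for t in opts["theta_grid"]],
            mode=opts.get("mode", "full"))
        pd.DataFrame(rmap.to_records()).to_csv(outdir / "map.csv", index=False)
        return rmap

    if cfg.pipeline == "collapse":
        traces = {float(f): read_counts(p) for f, p in opts["traces"].items()}
        fractions = [float(f) for f in opts["fractions"]]
        cache: dict = {}

        def chi_fn(f, theta, k):
            key = (f, theta, k)
            if key not in cache:
                avset = cascade.avalanche_pipeline(traces[f], k=k, theta=theta, f=f)
                cache[key] = scalingfit.exponent_suite(avset).chi
            return cache[key]

        scan = collapse_mod.scan_collapse(
            chi_fn, fractions, [float(t) for t in opts["theta100"]],
            k_grid=[int(k) for k in opts.get("k_grid", (1, 2, 4, 8, 16, 32, 64))])
        pd.DataFrame({"xi": scan.xi_grid, "error": scan.errors}).to_csv(
            outdir / "collapse_scan.csv", index=False)
        return scan

    if cfg.pipeline == "corr":
        raster = read_raster(opts["raster"])
        curve = paircorr.correlation_curve(raster, range(1, int(opts["k_max"]) + 1))
        pd.DataFrame({"k": curve.k, "mean_corr": curve.mean_corr,
                      "n_pairs_valid": curve.n_pairs_valid}).to_csv(
            outdir / "corr.csv", index=False)
        return curve

    if cfg.pipeline == "synth":
        gp = exppipe.RecordingParams(**opts.get("generator", {}))
        recs = exppipe.generate_recordings(gp, n_rec=int(opts["n_rec"]), seed=cfg.seed)
        for r in recs:
            np.savetxt(outdir / f"recording_{r.rec_id:02d}.csv", r.densities,
                       delimiter=",", fmt="%.6g")
        return recs

    if cfg.pipeline == "exp-map":
        rec_dir = Path(opts["recordings"])
        recs = [exppipe.RecordingRaster(densities=np.loadtxt(p, delimiter=",", ndmin=2),
                                        rec_id=i)
                for i, p in enumerate(sorted(rec_dir.glob("recording_*.csv")))]
        emap = exppipe.zscored_chi_map(
            recs, z_grid=opts.get("z_grid"),
            k_grid=[int(k) for k in opts.get("k_grid", (1, 2, 4, 8, 16, 32))],
            mode=opts.get("mode", "zscore"), theta_grid=opts.get("theta_grid"))
        rows = []
        axis = "z" if emap.mode == "zscore" else "theta"
        for i, r in enumerate(emap.rows):
            for j, k in enumerate(emap.k_grid):
                rows.append({axis: r, "k": int(k), "chi": emap.chi[i, j],
                             "dcc": emap.dcc[i, j], "n_valid": int(emap.n_valid[i, j])})
        pd.DataFrame(rows).to_csv(outdir / "exp_map.csv", index=False)
        return emap

    raise AssertionError("unreachable")
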