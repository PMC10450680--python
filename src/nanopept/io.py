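"""Plain-text readers/writers for traces, events, clusters and models.

Traces travel as ``<prefix>.csv`` (columns time_s, current_pA) with a
``<prefix>.meta.json`` sidecar carrying the simulation/acquisition metadata;
events as TSV; cluster and classifier parameters as JSON.  Negative-polarity
recordings are rectified to magnitudes at load time with the sign recorded in
metadata.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierModel
from .detect import EventRecord
from .simulate import SimConfig, Trace, TruthEvent, config_from_dict, config_to_dict
from .spectrum import ClusterFit

__all__ = [
    "SCHEMA_VERSION",
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "read_events_frame",
    "write_truth",
    "read_truth",
    "write_cluster",
    "read_cluster",
    "write_model",
    "read_model",
    "read_sim_config",
]

SCHEMA_VERSION = "1.0"

EVENT_COLUMNS = (
    "start_sample",
    "end_sample",
    "dwell_ms",
    "mean_ib_pA",
    "delta_ib_pA",
    "iex_pct",
    "sigma_b_pA",
)
TRUTH_COLUMNS = ("species", "start_sample", "end_sample", "true_iex_pct", "true_dwell_ms")

# Time column write resolution (seconds); the uniformity check below allows
# for this quantum on top of the 1 ppm contract.
_TIME_DECIMALS = 9
_TIME_QUANTUM = 10.0 ** (-_TIME_DECIMALS)


def _paths(prefix) -> tuple[Path, Path]:
    p = Path(prefix)
    if p.suffix == ".csv":
        p = p.with_suffix("")
    return p.with_suffix(".csv"), Path(str(p) + ".meta.json")


def write_trace(trace: Trace, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` + ``<prefix>.meta.json``; returns both paths."""
    csv_path, meta_path = _paths(prefix)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    # per-column formats: time needs more digits than current
    with csv_path.open("w") as fh:
        fh.write("time_s,current_pA\n")
        for ti, ci in zip(trace.times(), trace.samples):
            fh.write(f"{ti:.{_TIME_DECIMALS}f},{ci:.6f}\n")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "sample_rate_hz": trace.sample_rate,
        "n_samples": int(trace.samples.size),
        **trace.metadata,
    }
    meta_path.write_text(json.dumps(meta, indent=1, default=_jsonable) + "\n")
    return csv_path, meta_path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")


def read_trace(prefix) -> Trace:
    """Read a trace CSV and its metadata sidecar.

    A missing sidecar produces a warning and the sample rate is inferred from
    the time column.  The time column must be uniform: steps deviating from
    the median step by more than max(1 ppm, the written time quantum) raise.
    Negative-polarity recordings are rectified; the sign goes to metadata.
    """
    csv_path, meta_path = _paths(prefix)
    df = pd.read_csv(csv_path)
    for col in ("time_s", "current_pA"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["current_pA"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        step = float(np.median(dt))
        if step <= 0:
            raise ValueError("time column is not strictly increasing")
        tol = max(1e-6 * step, 2.5 * _TIME_QUANTUM)
        if np.any(np.abs(dt - step) > tol):
            worst = int(np.argmax(np.abs(dt - step)))
            raise ValueError(
                f"non-uniform time step at row {worst + 1}: "
                f"{dt[worst]:.3e} s vs median {step:.3e} s"
            )
        fs = 1.0 / step
    else:
        fs = 0.0

    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs = float(meta.get("sample_rate_hz", fs))
    else:
        warnings.warn(
            f"no metadata sidecar at {meta_path}; inferring sample rate "
            f"{fs:.6g} Hz from the time column",
            stacklevel=2,
        )
        meta = {"sample_rate_hz": fs, "schema_version": SCHEMA_VERSION}
    if fs <= 0:
        raise ValueError("cannot determine the sample rate")

    polarity = "positive"
    if np.median(x) < 0:
        polarity = "negative"
        x = np.abs(x)
    meta["polarity"] = polarity
    return Trace(samples=x, sample_rate=fs, metadata=meta)


def write_events(events, path) -> Path:
    """Write events as TSV.  Accepts a list of EventRecord or a DataFrame
    (extra columns of a DataFrame are preserved as-is)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(events, pd.DataFrame):
        df = events
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"events table is missing required column(s) {missing}")
    else:
        df = pd.DataFrame(
            [
                {
                    "start_sample": e.start,
                    "end_sample": e.end,
                    "dwell_ms": e.dwell_ms,
                    "mean_ib_pA": e.mean_ib,
                    "delta_ib_pA": e.delta_ib,
                    "iex_pct": e.iex_pct,
                    "sigma_b_pA": e.sigma_b,
                }
                for e in events
            ],
            columns=list(EVENT_COLUMNS),
        )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_events_frame(path) -> pd.DataFrame:
    """Events TSV as a DataFrame, validated; unknown columns are preserved."""
    df = pd.read_csv(path, sep="\t")
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"events file is missing required column {col!r}")
    for col in EVENT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header, 1-based
            raise ValueError(
                f"malformed value in column {col!r} at line {line} of {path}"
            )
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ValueError(f"missing value in column {col!r} at line {line} of {path}")
        df[col] = coerced
    return df


def read_events(path) -> list[EventRecord]:
    df = read_events_frame(path)
    return [
        EventRecord(
            start=int(r.start_sample),
            end=int(r.end_sample),
            dwell_ms=float(r.dwell_ms),
            mean_ib=float(r.mean_ib_pA),
            delta_ib=float(r.delta_ib_pA),
            iex_pct=float(r.iex_pct),
            sigma_b=float(r.sigma_b_pA),
        )
        for r in df.itertuples(index=False)
    ]


def write_truth(truth: list[TruthEvent], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "species": ev.species,
                "start_sample": ev.start,
                "end_sample": ev.end,
                "true_iex_pct": ev.true_iex,
                "true_dwell_ms": ev.true_dwell,
            }
            for ev in truth
        ],
        columns=list(TRUTH_COLUMNS),
    ).to_csv(path, sep="\t", index=False)
    return path


def read_truth(path) -> list[TruthEvent]:
    df = pd.read_csv(path, sep="\t")
    for col in TRUTH_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"truth file is missing required column {col!r}")
    return [
        TruthEvent(
            species=str(r.species),
            start=int(r.start_sample),
            end=int(r.end_sample),
            true_iex=float(r.true_iex_pct),
            true_dwell=float(r.true_dwell_ms),
        )
        for r in df.itertuples(index=False)
    ]


def write_cluster(cluster: ClusterFit, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "mu_pct": cluster.mu,
                "sigma_pct": cluster.sigma,
                "amplitude": cluster.amplitude,
                "n_events": cluster.n_events,
                "window": list(cluster.window) if cluster.window else None,
            },
            indent=1,
        )
        + "\n"
    )
    return path


def read_cluster(path) -> ClusterFit:
    d = json.loads(Path(path).read_text())
    return ClusterFit(
        mu=float(d["mu_pct"]),
        sigma=float(d["sigma_pct"]),
        amplitude=float(d.get("amplitude", float("nan"))),
        n_events=int(d.get("n_events", 0)),
        window=tuple(d["window"]) if d.get("window") else None,
    )


def write_model(model: ClassifierModel, path, extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = {
        "schema_version": SCHEMA_VERSION,
        "classes": list(model.classes),
        "weights": model.weights.tolist(),
        "feature_means": model.feature_means.tolist(),
        "feature_scales": model.feature_scales.tolist(),
        "feature_names": list(model.feature_names),
        "separation_flag": model.separation_flag,
    }
    if extra:
        d.update(extra)
    path.write_text(json.dumps(d, indent=1) + "\n")
    return path


def read_model(path) -> ClassifierModel:
    d = json.loads(Path(path).read_text())
    return ClassifierModel(
        classes=tuple(d["classes"]),
        weights=np.asarray(d["weights"], dtype=float),
        feature_means=np.asarray(d["feature_means"], dtype=float),
        feature_scales=np.asarray(d["feature_scales"], dtype=float),
        feature_names=tuple(d["feature_names"]),
        separation_flag=bool(d.get("separation_flag", False)),
    )


def read_sim_config(path) -> SimConfig:
    return config_from_dict(json.loads(Path(path).read_text()))


def write_sim_config(config: SimConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(config_to_dict(config), indent=1) + "\n")
    return path
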