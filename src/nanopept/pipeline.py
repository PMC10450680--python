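"""End-to-end pipeline: simulate -> detect -> spectrum -> classify/quantify.

A run is described by a plain dict (usually loaded from JSON):

    {
      "seed": 1,                      # optional; auto-drawn and logged if absent
      "task": "quantify",             # or "classify", or null (stop after spectra)
      "simulate": {                   # one SimConfig dict per trace role
        "sample":  {...}, "mixture": {...}        # quantify
        # or "train_a": {...}, "train_b": {...}, "mixture": {...}   # classify
      },
      "detect": {"threshold_k": 5, "min_duration_us": 50},
      "clusters": {"A": [lo, hi], "B": [lo, hi]},   # I_ex% windows
      "classify_filter": [50, 90]     # classify task only
    }

Every output JSON embeds the seed and a hash of the configuration; a
structured log records event counts and fit diagnostics per stage.  Re-running
with the same config and seed reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import secrets
from pathlib import Path

from . import io as npio
from .classify import evaluate, filter_events, predict, train_classifier
from .detect import analyze_trace
from .quantify import quantify
from .simulate import config_from_dict, label_events_by_truth, simulate
from .spectrum import fit_cluster

logger = logging.getLogger("nanopept.pipeline")

__all__ = ["run_pipeline", "config_hash"]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, err) from err
        return wrapper
    return deco


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured pipeline; returns a summary dict (also written
    to ``summary.json`` in ``out_dir``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.get("seed")
    if seed is None:
        seed = secrets.randbelow(2**31)
        logger.info("no seed supplied; drew seed %d", seed)
    chash = config_hash(config)
    logger.info("pipeline start: hash=%s seed=%d task=%s",
                chash, seed, config.get("task"))

    det_cfg = config.get("detect", {})
    thr_k = float(det_cfg.get("threshold_k", 5.0))
    min_us = float(det_cfg.get("min_duration_us", 50.0))
    if "threshold_k" not in det_cfg or "min_duration_us" not in det_cfg:
        logger.info("detection defaults in use: threshold 5*sigma, 50 us minimum")

    @_stage("simulate+detect")
    def _sim_detect(role: str, sim_dict: dict, role_seed: int):
        sim = config_from_dict({**sim_dict, "seed": role_seed})
        trace, truth = simulate(sim)
        fit, events = analyze_trace(trace, threshold_k=thr_k, min_duration_us=min_us)
        logger.info(
            "[%s] i0=%.2f pA sigma0=%.3f pA; %d truth events, %d detected",
            role, fit.i0, fit.sigma0, len(truth), len(events),
        )
        npio.write_events(events, out / f"{role}.events.tsv")
        npio.write_truth(truth, out / f"{role}.truth.tsv")
        return trace, truth, fit, events

    roles = config.get("simulate", {})
    artifacts: dict = {}
    for i, (role, sim_dict) in enumerate(sorted(roles.items())):
        artifacts[role] = _sim_detect(role, sim_dict, seed + 7919 * (i + 1))

    summary: dict = {
        "schema_version": npio.SCHEMA_VERSION,
        "config_hash": chash,
        "seed": seed,
        "task": config.get("task"),
        "n_events": {r: len(a[3]) for r, a in artifacts.items()},
    }

    task = config.get("task")
    windows = {k: tuple(v) for k, v in config.get("clusters", {}).items()}

    if task == "quantify":
        @_stage("spectrum")
        def _clusters():
            # cluster parameters come from individual peptide measurements
            # (calib_a / calib_b roles) when provided; otherwise they are fit
            # on the mixture spectrum, which is less accurate for
            # overlapping clusters
            calib_roles = {"A": "calib_a", "B": "calib_b"}
            fits = {}
            for name, win in windows.items():
                role = calib_roles.get(name, "mixture")
                if role not in artifacts:
                    role = "mixture"
                cf = fit_cluster(artifacts[role][3], win)
                logger.info("[%s] cluster %s: mu=%.2f sigma=%.2f n=%d",
                            role, name, cf.mu, cf.sigma, cf.n_events)
                npio.write_cluster(cf, out / f"cluster_{name}.json")
                fits[name] = cf
            return fits

        fits = _clusters()

        @_stage("quantify")
        def _quant():
            res = quantify(
                artifacts["sample"][3],
                artifacts["mixture"][3],
                fits["A"],
                fits["B"],
                n_boot=int(config.get("bootstrap", 0)),
                seed=seed,
            )
            logger.info("conversion=%.2f%% (F=%.3f, E_sample=%.2f, E_mix=%.2f)",
                        res.conversion, res.detection_factor, res.e_sample, res.e_mix)
            payload = {
                "schema_version": npio.SCHEMA_VERSION,
                "config_hash": chash,
                "seed": seed,
                "counts": res.counts,
                "e_sample_pct": res.e_sample,
                "e_mix_pct": res.e_mix,
                "detection_factor": res.detection_factor,
                "conversion_pct": res.conversion,
                "ci_pct": list(res.ci) if res.ci else None,
                "n_boot": res.n_boot,
            }
            (out / "quant.json").write_text(json.dumps(payload, indent=1) + "\n")
            return payload

        summary["quantification"] = _quant()

    elif task == "classify":
        @_stage("classify")
        def _classify():
            lo, hi = config.get("classify_filter", (50.0, 90.0))
            labeled = []
            for role in ("train_a", "train_b"):
                trace, truth, fit, events = artifacts[role]
                species = truth[0].species if truth else role
                labeled += [(e, species) for e in filter_events(events, lo, hi)]
            model = train_classifier(labeled)
            npio.write_model(model, out / "model.json",
                            extra={"filter": [lo, hi], "seed": seed,
                                   "config_hash": chash})
            trace, truth, fit, events = artifacts["mixture"]
            mix_events = filter_events(events, lo, hi)
            truth_labels = label_events_by_truth(
                truth, [(e.start, e.end) for e in mix_events]
            )
            keep = [i for i, t in enumerate(truth_labels) if t is not None]
            mix_events = [mix_events[i] for i in keep]
            truth_labels = [truth_labels[i] for i in keep]
            pred, _ = predict(model, mix_events)
            summ = evaluate(pred, truth_labels)
            logger.info("mixture TPR: %s",
                        {c: round(v, 1) for c, v in summ.tpr_pct.items()})
            payload = {
                "schema_version": npio.SCHEMA_VERSION,
                "config_hash": chash,
                "seed": seed,
                "classes": list(summ.classes),
                "confusion": summ.counts.tolist(),
                "tpr_pct": {c: summ.tpr_pct[c] for c in summ.classes},
                "n": summ.n,
            }
            (out / "classification.json").write_text(json.dumps(payload, indent=1) + "\n")
            return payload

        summary["classification"] = _classify()

    elif task not in (None, "detect"):
        raise PipelineError("config", ValueError(f"unknown task {task!r}"))

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary
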