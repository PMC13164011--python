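"""End-to-end workflow: simulate -> preprocess -> evaluate -> attribute.

Ties the stages into a reproducible run directory with a hashed config
echo, per-run JSON results, an aggregate report shaped like the
protocol's summary tables, attribution outputs, and a dataset format
validator for external recordings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribution import AttributionConfig, attribute_dataset, save_attributions
from .evaluate import TrainingConfig, repeat_protocol
from .models import NetworkConfig
from .preprocess import PreprocessConfig, build_model_inputs, save_model_inputs
from .simulate import (PRESSURE_COLUMNS, SimulationConfig, generate_dataset,
                       save_dataset)

__all__ = ["WorkbenchConfig", "run_pipeline", "validate_dataset",
           "config_hash"]

log = logging.getLogger("frostgrip")


@dataclass
class WorkbenchConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    run_dir: str = "runs"
    repeats: int = 10
    model_kinds: tuple = ("fusion", "pressure_only", "vibration_only")
    base_seed: int = 0

    @staticmethod
    def from_file(path) -> "WorkbenchConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sections = {
            "simulation": SimulationConfig,
            "preprocess": PreprocessConfig,
            "network": NetworkConfig,
            "training": TrainingConfig,
            "attribution": AttributionConfig,
        }
        kwargs = {}
        for name, cls in sections.items():
            section = raw.pop(name, {}) or {}
            if name == "network" and "head_units" in section:
                section["head_units"] = tuple(section["head_units"])
            kwargs[name] = cls(**section)
        for key in ("run_dir", "repeats", "base_seed"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "model_kinds" in raw:
            kwargs["model_kinds"] = tuple(raw.pop("model_kinds"))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return WorkbenchConfig(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_kinds"] = list(self.model_kinds)
        d["network"]["head_units"] = list(self.network.head_units)
        return d


def config_hash(cfg: WorkbenchConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stamp(cfg: WorkbenchConfig) -> dict:
    return {"config_hash": config_hash(cfg), "base_seed": cfg.base_seed}


def run_pipeline(cfg: WorkbenchConfig) -> dict:
    """Full run; returns a summary dict and writes every artifact under
    ``cfg.run_dir``. Aborts naming the failing stage."""
    if cfg.repeats < 2:
        raise ValueError("repeats must be >= 2 (sample SD undefined otherwise)")
    out = Path(cfg.run_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        trials, manifest = generate_dataset(cfg.simulation)
        manifest["provenance"] = _stamp(cfg)
        save_dataset(trials, manifest, out / "dataset")
        timings[stage] = time.perf_counter() - t0
        log.info("simulate: %d trials in %.1fs", len(trials), timings[stage])

        stage = "preprocess"
        t0 = time.perf_counter()
        inputs = build_model_inputs(trials, cfg.preprocess)
        save_model_inputs(inputs, cfg.preprocess, out / "inputs")
        timings[stage] = time.perf_counter() - t0
        log.info("preprocess: %d inputs in %.1fs", len(inputs), timings[stage])

        stage = "evaluate"
        t0 = time.perf_counter()
        results, report, models = repeat_protocol(
            cfg.model_kinds, inputs, n_repeats=cfg.repeats,
            base_seed=cfg.base_seed, tcfg=cfg.training, ncfg=cfg.network,
            keep_models=True)
        for kind, runs in results.items():
            for res, model in zip(runs, models[kind]):
                rdir = out / "runs" / kind / f"seed{res.seed}"
                rdir.mkdir(parents=True, exist_ok=True)
                payload = res.to_dict()
                payload["provenance"] = _stamp(cfg)
                payload["network"] = asdict(cfg.network)  # reload validation
                with open(rdir / "result.json", "w") as fh:
                    json.dump(payload, fh, indent=2)
                np.savez(rdir / "params.npz",
                         **{f"p{i}": arr
                            for i, arr in enumerate(model.get_state())})
                log.info("%s seed %d: stopped at epoch %d (best %d)",
                         kind, res.seed, res.stopped_epoch, res.best_epoch)
        report_payload = report.to_dict()
        report_payload["provenance"] = _stamp(cfg)
        with open(out / "report.json", "w") as fh:
            json.dump(report_payload, fh, indent=2)
        timings[stage] = time.perf_counter() - t0
        log.info("evaluate: %d kinds x %d repeats in %.1fs",
                 len(cfg.model_kinds), cfg.repeats, timings[stage])

        stage = "attribute"
        t0 = time.perf_counter()
        attr_kind = ("fusion" if "fusion" in cfg.model_kinds
                     else cfg.model_kinds[0])
        profiles, hist = attribute_dataset(models[attr_kind][0], inputs,
                                           cfg.attribution)
        save_attributions(profiles, hist, out / "attributions")
        timings[stage] = time.perf_counter() - t0
        log.info("attribute: %d profiles in %.1fs",
                 len(profiles), timings[stage])
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    summary = {"provenance": _stamp(cfg), "timings_s": timings,
               "report": report.to_dict(),
               "histogram": {"edges": hist.edges.tolist(),
                             "counts": hist.counts.tolist()}}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def validate_dataset(dataset_dir) -> dict:
    """Schema / range / monotonicity checks on a dataset directory.

    Returns ``{"ok": bool, "trials": {trial_id: {"ok": bool,
    "issues": [...]}}}``.
    """
    src = Path(dataset_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    adc_max = manifest.get("config", {}).get("adc_max", 1023)
    report = {"ok": True, "trials": {}}
    for entry in manifest["trials"]:
        issues = []
        for stream, cols in (("pressure", PRESSURE_COLUMNS),
                             ("vibration", ["timestamp_s", "v"])):
            path = src / entry["files"][stream]
            if not path.exists():
                issues.append(f"missing file {path.name}")
                continue
            df = pd.read_csv(path)
            if list(df.columns) != cols:
                issues.append(f"{stream}: unexpected columns")
                continue
            ts = df["timestamp_s"].to_numpy()
            if not np.all(np.diff(ts) > 0):
                issues.append(f"{stream}: timestamps not strictly increasing")
            counts = df[cols[1:]].to_numpy()
            if counts.min() < 0 or counts.max() > adc_max:
                issues.append(f"{stream}: counts outside [0, {adc_max}]")
            if not np.allclose(counts, np.rint(counts)):
                issues.append(f"{stream}: non-integer counts")
        ok = not issues
        report["trials"][entry["trial_id"]] = {"ok": ok, "issues": issues}
        report["ok"] = report["ok"] and ok
    return report
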