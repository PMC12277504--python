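"""One-command orchestration: simulate -> preprocess -> train -> evaluate.

A run is fully described by a :class:`RunConfig` (YAML-loadable). Every
stage draws its seed deterministically from the global seed, so a full run
is byte-reproducible and individual stages can be re-run standalone. The
run directory collects the raw tables, the interaction table, split
assignments, training curves, the evaluation report, a model checkpoint and
a manifest with content hashes and headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, model as model_mod, preprocessing as prep, synthetic_data as sim

logger = logging.getLogger("cdld.pipeline")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing (global seed, stage)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    augment_magnitude: float = 0.1
    augment_factor: int = 5
    seed: int = 0
    train_baseline: bool = False

    def validate(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        self.sim.validate()
        self.model.validate()

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one global seed into every stage deterministically."""
        return dataclasses.replace(
            self,
            seed=seed,
            sim=dataclasses.replace(self.sim, seed=stage_seed(seed, "simulate")),
            model=dataclasses.replace(self.model, seed=stage_seed(seed, "train")),
        )


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    tuple_fields = {"measurements_per_stay_range", "hidden_widths", "head_hidden", "fractions"}
    clean = {k: tuple(v) if k in tuple_fields and v is not None else v for k, v in data.items()}
    return cls(**clean)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; absent fields take defaults, unknown keys fail."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    sim_cfg = _build(sim.SimConfig, data.pop("sim", {}) or {}, "sim")
    model_cfg = _build(model_mod.ModelConfig, data.pop("model", {}) or {}, "model")
    config = _build(RunConfig, {**data, "sim": sim_cfg, "model": model_cfg}, "run")
    config.validate()
    return config


def dump_config(config: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written).

    Identical configs produce byte-identical artifacts: no wall-clock data
    enters any output file (timings go to the log only).
    """
    config.validate()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_probe").write_text("")
        (out / ".write_probe").unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": {
            "simulate": config.sim.seed,
            "split": stage_seed(config.seed, "split"),
            "augment": stage_seed(config.seed, "augment"),
            "train": config.model.seed,
        },
        "counts": {},
        "rmse": {},
        "files": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        return lambda: logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)

    try:
        done = stage("simulate")
        tables, truth = sim.generate(config.sim)
        sim.write_raw_tables(tables, out / "raw")
        truth.provider_latents.to_csv(out / "truth_provider_latents.csv")
        done()

        done = stage("preprocess")
        table, provider_map = prep.build_interaction_table(tables)
        table.to_csv(out / "interactions.csv", index=False)
        pd.DataFrame(
            {"provider_id": list(provider_map), "provider_code": list(provider_map.values())}
        ).to_csv(out / "provider_map.csv", index=False)
        splits = prep.split_data(len(table), config.fractions, stage_seed(config.seed, "split"))
        splits.as_frame().to_csv(out / "splits.csv", index=False)
        augmented = prep.augment_training(
            table.iloc[splits.train_rows].reset_index(drop=True),
            magnitude=config.augment_magnitude,
            factor=config.augment_factor,
            seed=stage_seed(config.seed, "augment"),
        )
        manifest["counts"] = {
            "n_patients": int(tables.patients.shape[0]),
            "n_admissions": int(tables.admissions.shape[0]),
            "n_interactions": int(len(table)),
            "n_dropped": int(tables.admissions.shape[0] - len(table)),
            "n_train": int(len(splits.train_rows)),
            "n_valid": int(len(splits.valid_rows)),
            "n_test": int(len(splits.test_rows)),
            "n_train_augmented": int(len(augmented.frame)),
            "n_providers_observed": int(len(provider_map)),
        }
        done()

        done = stage("train")
        valid_table = table.iloc[splits.valid_rows]
        cdld = model_mod.init_model(config.model, n_providers=len(provider_map))
        cdld, curve1 = model_mod.cyclic_train(cdld, augmented.frame, valid_table)
        cdld, curve2 = model_mod.synthesize_predictor(cdld, augmented.frame, valid_table)
        curves = pd.concat([curve1, curve2], ignore_index=True)
        curves.to_csv(out / "curves.csv", index=False)
        model_mod.save_model(cdld, out / "model.npz")
        done()

        done = stage("evaluate")
        report = evaluation.evaluate_model(cdld, table, splits)
        report.table.to_csv(out / "report.csv", index=False)
        report_json = {
            f"{r.phase}/{r.split}": {"rmse_unit": r.rmse_unit, "rmse_mgdl": r.rmse_mgdl, "n": int(r.n)}
            for r in report.table.itertuples()
        }
        if config.train_baseline:
            baseline, _ = model_mod.train_patient_only_baseline(
                augmented.frame, valid_table, config.model
            )
            base_report = evaluation.evaluate_baseline(baseline, table, splits)
            comparison = evaluation.compare_models(report, base_report)
            comparison.to_csv(out / "comparison.csv", index=False)
            report_json["baseline"] = {
                f"patient_only/{r.split}": {"rmse_unit": r.rmse_unit} for r in base_report.table.itertuples()
            }
        (out / "report.json").write_text(json.dumps(report_json, indent=2, sort_keys=True))
        manifest["rmse"] = {
            f"{r.phase}/{r.split}": round(float(r.rmse_unit), 6) for r in report.table.itertuples()
        }
        done()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
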