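"""End-to-end study orchestration.

``run_study`` executes the whole reproduction in order — retention factors,
HC50 estimation, descriptor clustering, exhaustive MLR search per endpoint,
cross-validation and applicability-domain reports — from a single YAML
config, and writes a manifest (config hash, input digests, seed, per-stage
output paths, version) sufficient to re-execute any stage in isolation.
Outputs are pure functions of (inputs, config, seed); floats are serialized
at 12 significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import admissible_sets, variable_cluster
from .errors import SchemaError, StageError
from .hemolysis import probit_fit
from .io_tables import (
    CompoundPanel,
    DatasetBundle,
    attach_logk,
    read_hemolysis,
    read_panel,
    read_retention,
    write_model_report,
)
from .mlr import search_models
from .synthetic import SimulationSpec, gen_bundle
from .validation import LMO, LOO, cross_validate, williams_report

log = logging.getLogger("biomimqsar")

__all__ = ["RunManifest", "run_study", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "endpoints": ["logP_wpc", "logKp", "logP_wHSA", "logBB", "HC50"],
    "lipophilicity": ["logk_BMC", "logk_IAM"],
    "structural_vars": ["MW", "TPSA", "alpha", "HBD_HBA", "NRB"],
    "cluster_threshold": 50.0,
    "max_predictors": 3,
    "lmo": {"fraction": 1.0 / 3.0, "repeats": 100, "seed": 20250204},
}


def _sig12(obj):
    """Round all floats to 12 significant digits, recursively."""
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _sig12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sig12(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    input_digests: dict[str, str]
    outputs: dict[str, list[str]]  # stage -> paths
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "input_digests": self.input_digests,
            "outputs": self.outputs,
            "skipped": self.skipped,
        }


class _StageWriter:
    """Tracks files written by the current stage; renames to .partial on failure."""

    def __init__(self):
        self.current: list[Path] = []
        self.by_stage: dict[str, list[str]] = {}

    def start(self, stage: str):
        self.stage = stage
        self.current = []

    def record(self, path: Path):
        self.current.append(path)
        self.by_stage.setdefault(self.stage, []).append(str(path))

    def fail(self):
        for p in self.current:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_sig12(obj), indent=1, sort_keys=True))


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def _load_inputs(cfg: dict, base: Path) -> tuple[DatasetBundle, dict, dict[str, str]]:
    digests: dict[str, str] = {}
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        if "seed" in cfg and "seed" not in sim:
            sim["seed"] = cfg["seed"]
        spec = SimulationSpec(**sim)
        bundle, truth = gen_bundle(spec)
        return bundle, truth, digests
    inputs = cfg.get("inputs")
    if not inputs or "panel" not in inputs:
        raise SchemaError("config needs either a 'simulate' block or inputs.panel")
    panel_path = base / inputs["panel"]
    panel = read_panel(panel_path)
    digests["panel"] = _digest(panel_path)
    retention = []
    if inputs.get("retention"):
        rp = base / inputs["retention"]
        retention = read_retention(rp)
        digests["retention"] = _digest(rp)
    hemolysis = []
    if inputs.get("hemolysis"):
        hp = base / inputs["hemolysis"]
        hemolysis = read_hemolysis(hp)
        digests["hemolysis"] = _digest(hp)
    return DatasetBundle(panel=panel, retention=retention, hemolysis=hemolysis), {}, digests


def run_study(config, base_dir=None) -> RunManifest:
    """Run every stage of the study described by ``config`` (path or dict)."""
    if isinstance(config, (str, Path)):
        base = Path(config).parent if base_dir is None else Path(base_dir)
        cfg_text = Path(config).read_text()
        cfg = yaml.safe_load(cfg_text)
    else:
        base = Path(".") if base_dir is None else Path(base_dir)
        cfg = dict(config)
        cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    merged = {**DEFAULT_CONFIG, **cfg}
    out_dir = Path(merged.get("out_dir", "study_out"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        yaml.safe_dump(_sig12(merged), sort_keys=True).encode()
    ).hexdigest()

    writer = _StageWriter()
    skipped: list[str] = []

    def stage(name):
        writer.start(name)
        log.info("stage %s", name)

    try:
        stage("inputs")
        bundle, truth, digests = _load_inputs(merged, base)
        panel = bundle.panel
        if truth:
            p = out_dir / "truth.json"
            _write_json(p, truth)
            writer.record(p)
    except StageError:
        raise
    except Exception as exc:
        writer.fail()
        raise StageError("inputs", exc) from exc

    try:
        stage("retention")
        if bundle.retention:
            panel = attach_logk(panel, bundle.retention)
            rows = [
                {"compound_id": r.compound_id, "system": r.system, "log_k": r.log_k}
                for r in bundle.retention
            ]
            p = out_dir / "logk.csv"
            _write_csv(p, pd.DataFrame(rows).round(12))
            writer.record(p)
        else:
            skipped.append("retention: no retention records")
    except Exception as exc:
        writer.fail()
        raise StageError("retention", exc) from exc

    endpoints = list(merged["endpoints"])
    try:
        stage("hemolysis")
        if bundle.hemolysis:
            rows = []
            hc50_map = {}
            for curve in bundle.hemolysis:
                fit = probit_fit(curve.concentrations, curve.pct)
                hc50_map[curve.compound_id] = fit.hc50
                rows.append(
                    {
                        "compound_id": curve.compound_id,
                        "HC50_uM": round(fit.hc50),
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "n_points": fit.n_points,
                    }
                )
            frame = panel.frame.copy()
            frame["HC50"] = frame["compound_id"].map(hc50_map)
            panel = CompoundPanel(frame)
            p = out_dir / "hc50.csv"
            _write_csv(p, pd.DataFrame(rows))
            writer.record(p)
        elif "HC50" in endpoints and "HC50" not in panel.frame.columns:
            skipped.append("hemolysis: no data; HC50 endpoint disabled")
            endpoints = [e for e in endpoints if e != "HC50"]
            log.info("HC50 endpoint skipped: no hemolysis data")
        else:
            skipped.append("hemolysis: no data")
    except Exception as exc:
        writer.fail()
        raise StageError("hemolysis", exc) from exc

    try:
        stage("clustering")
        tree = variable_cluster(panel, merged["structural_vars"])
        p = out_dir / "clusters.json"
        _write_json(
            p,
            {
                **tree.to_json_dict(),
                "flat_clusters": tree.flat_clusters(merged["cluster_threshold"]),
                "threshold": merged["cluster_threshold"],
            },
        )
        writer.record(p)
        pn = out_dir / "clusters.nwk"
        pn.write_text(tree.to_newick() + "\n")
        writer.record(pn)
        candidates = admissible_sets(
            tree,
            merged["cluster_threshold"],
            merged["lipophilicity"],
            merged["max_predictors"],
        )
    except Exception as exc:
        writer.fail()
        raise StageError("clustering", exc) from exc

    panel_path = out_dir / "panel_final.csv"
    panel.to_csv(panel_path)

    lmo_cfg = merged["lmo"]
    for endpoint in endpoints:
        try:
            stage(f"search:{endpoint}")
            if endpoint not in panel.frame.columns:
                skipped.append(f"search:{endpoint}: column absent")
                continue
            result = search_models(panel, endpoint, candidates)
            p = out_dir / f"models_{endpoint}.json"
            write_model_report(result.models, p)
            writer.record(p)

            best = result.best
            sub = panel.frame.dropna(subset=list(best.predictors) + [endpoint])
            X = sub.loc[:, list(best.predictors)]
            y = sub[endpoint].to_numpy(dtype=float)

            ad = williams_report(best, X, y)
            pw = out_dir / f"williams_{endpoint}.csv"
            _write_csv(pw, ad.table.round(12))
            writer.record(pw)
            pj = out_dir / f"williams_{endpoint}.json"
            _write_json(
                pj,
                {
                    "response": ad.response,
                    "predictors": ad.predictors,
                    "h_star": ad.h_star,
                    "sd_band": ad.sd_band,
                    "outside": ad.outside,
                },
            )
            writer.record(pj)

            loo = cross_validate(X, y, LOO())
            lmo = cross_validate(X, y, LMO(**lmo_cfg))
            pc = out_dir / f"cv_{endpoint}.json"
            _write_json(
                pc,
                {
                    "response": endpoint,
                    "predictors": list(best.predictors),
                    "LOO": {"Q2": loo.q2, "RMSE": loo.rmse, "n_folds": loo.n_folds},
                    "LMO": {
                        "Q2": lmo.q2,
                        "RMSE": lmo.rmse,
                        "n_folds": lmo.n_folds,
                        **lmo.params,
                    },
                },
            )
            writer.record(pc)
        except Exception as exc:
            writer.fail()
            raise StageError(f"search:{endpoint}", exc) from exc

    manifest = RunManifest(
        config_hash=config_hash,
        seed=merged.get("seed"),
        version=__version__,
        input_digests=digests,
        outputs=writer.by_stage,
        skipped=skipped,
    )
    _write_json(out_dir / "manifest.json", manifest.to_dict())
    return manifest
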