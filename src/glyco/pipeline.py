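"""End-to-end orchestration: ingest/simulate -> reconcile -> impute ->
denoise -> physiological state estimation -> features -> labels ->
selection -> detector training -> evaluation.

A pipeline run is driven by a plain config dict (YAML on disk), writes
every stage artifact into a run directory together with a manifest
(config hash, seed, stage order), and fans the global seed out to
per-stage seeds by stable hashing so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import detect, features, impute, io_grid, label, physio, reconcile, synthdata

log = logging.getLogger("glyco")

STAGE_ORDER = ("ingest", "reconcile", "impute", "physio", "features",
               "label", "select", "train")


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def preprocess(series: io_grid.GriddedSeries, seed: int = 0,
               ppca_q: int = 10, ppca_tol: float = 1e-5,
               ppca_max_iter: int = 75) -> tuple[io_grid.GriddedSeries, dict]:
    """Reconciliation + imputation + denoising, in the order the stages
    depend on each other: outlier rejection first (it creates gaps),
    rule-based and PPCA imputation next, SSA denoising on the
    reconciled CGM last."""
    reports = {}
    series, reports["outliers"] = reconcile.reject_outliers(series)
    series = impute.impute_rule_based(series)
    series, model = impute.impute_cgm_ppca(series, q=ppca_q, tol=ppca_tol,
                                           max_iter=ppca_max_iter, seed=seed)
    reports["ppca"] = {"converged": bool(model.converged),
                       "n_iter": int(model.n_iter),
                       "sigma2": float(model.sigma2)} if model else None
    series, reports["denoise"] = reconcile.denoise_cgm(series)
    return series, reports


def extract_features(series: io_grid.GriddedSeries,
                     params: physio.HovorkaParams | None = None,
                     pf_cfg: physio.PFConfig | None = None):
    """Particle-filter PIC/U_G estimation plus the full feature table."""
    params = params or physio.HovorkaParams()
    try:
        params.body_weight = physio.estimate_body_weight(series)
    except ValueError:
        log.warning("extract_features: body-weight estimate unavailable; "
                    "using default %.0f kg", params.body_weight)
    pf = physio.pf_estimate(series, params, pf_cfg or physio.PFConfig(n_particles=300))
    table = features.assemble_features(series, pf.pic, pf.ug)
    return table, pf, params


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages; returns the result summary.

    Artifacts (gridded CSVs, JSON reports, metrics) land in ``out_dir``
    with a manifest carrying the config hash and per-stage seeds.
    """
    t_start = time.time()
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "glyco_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(config), "seed": seed, "stages": []}
    stages_cfg = config.get("stages", {})

    def enabled(name):
        return stages_cfg.get(name, True)

    # ---- ingest or simulate
    if "input" in config:
        inp = config["input"]
        schema = io_grid.load_schema(inp["schema"]) if isinstance(
            inp.get("schema"), str) else inp["schema"]
        records = io_grid.parse_dataset(inp["path"], schema,
                                        glucose_unit=inp.get("units", "mgdl"))
        series = io_grid.to_uniform_grid(io_grid.to_unix_sorted(records))
        truth = None
    else:
        syn = config.get("synthetic", {})
        scenario = synthdata.Scenario(**{k: v for k, v in syn.items()
                                         if k in synthdata.Scenario.__dataclass_fields__})
        series, rendered, ledger = synthdata.generate_dataset(
            scenario, seed=stage_seed(seed, "ingest"))
        truth = rendered.truth
        (out / "corruption_ledger.json").write_text(
            json.dumps({k: len(v) for k, v in ledger.items()}))
    io_grid.write_gridded(series, out / "ingested.csv")
    manifest["stages"].append("ingest")

    if not enabled("reconcile"):
        manifest["elapsed_s"] = time.time() - t_start
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"manifest": manifest}

    # ---- preprocessing
    series, reports = preprocess(series, seed=stage_seed(seed, "impute"),
                                 **config.get("preprocess", {}))
    io_grid.write_gridded(series, out / "reconciled.csv")
    (out / "preprocess_report.json").write_text(json.dumps(reports, default=str))
    manifest["stages"] += ["reconcile", "impute"]

    # ---- physiology + features
    pf_cfg = physio.PFConfig(seed=stage_seed(seed, "physio"),
                             **config.get("physio", {}))
    table, pf, params = extract_features(series, pf_cfg=pf_cfg)
    manifest["stages"] += ["physio", "features"]

    # ---- labels
    labels = label.label_events(series)
    manifest["stages"].append("label")

    result = {"manifest": manifest, "label_counts": labels.counts(),
              "preprocess": reports}

    # ---- selection
    if enabled("select"):
        sel_cfg = config.get("select", {})
        kept = features.deviance_filter(table, labels.classes,
                                        alpha=sel_cfg.get("alpha", 0.05))
        filtered = table.select(kept)
        names, trace = features.sffs_select(
            filtered, labels.classes, k_out=sel_cfg.get("k_out", 20),
            seed=stage_seed(seed, "select"), folds=sel_cfg.get("folds", 3),
            max_rows=sel_cfg.get("max_rows", 2000))
        (out / "selected_features.json").write_text(json.dumps(
            {"deviance_survivors": kept, "selected": names}))
        result["selected_features"] = names
        manifest["stages"].append("select")
    else:
        names = table.names
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return result

    # ---- training + evaluation
    if enabled("train"):
        tr_cfg = config.get("train", {})
        arch = tr_cfg.get("architecture", "conv1d_bilstm")
        dcfg = detect.DetectorConfig(**{k: v for k, v in tr_cfg.items()
                                        if k in detect.DetectorConfig.__dataclass_fields__})
        batch = build_training_batch(table, names, labels)
        detectors, report = detect.train_detector(
            batch, arch, dcfg, seed=stage_seed(seed, "train"))
        (out / "metrics.json").write_text(json.dumps(report))
        result["train_report"] = report
        manifest["stages"].append("train")

    manifest["elapsed_s"] = time.time() - t_start
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def build_training_batch(table: features.FeatureTable, selected_names,
                         labels: label.EventLabels,
                         train_frac: float = 0.875) -> detect.SequenceBatch:
    """Standardize on the chronological training split, restrict to the
    selected features and build the window tensors."""
    n = len(table.values)
    train_rows = np.zeros(n, dtype=bool)
    train_rows[: int(round(train_frac * n))] = True
    std = table.standardize(train_rows).select(selected_names)
    return detect.build_sequences(std, labels.classes)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
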