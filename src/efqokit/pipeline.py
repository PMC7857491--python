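"""Staged pipeline: simulate → quantify → fit → report, with a manifest.

A run is driven by a single config mapping (usually loaded from YAML) and
a master seed.  Exactly one input source is allowed: either a
``simulation`` block (design + base parameters) or ``kinetics``/``layout``
file paths.  Every output table is written deterministically, the manifest
records the config hash and seed, and a failing stage aborts the run with
the stage named while retaining partial outputs under a ``failed`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import compare, fitting, plateio, quantify
from .errors import PipelineError
from .simulate import simulate_plate
from .types import CalibrationModel, PlateDataset, SimulationConfig, WellRole

__all__ = ["run", "load_config", "config_hash", "build_design", "build_base_config"]

log = logging.getLogger("efqokit.pipeline")

_FIT_X_COLUMNS = {
    "mm": "substrate_conc_M",
    "ic50": "inhibitor_conc_M",
    "ph": "pH",
    "thermal": "temp_C",
}


def load_config(path) -> dict:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_base_config(block: dict | None) -> SimulationConfig:
    return SimulationConfig().with_(**(block or {}))


def build_design(entries: list) -> list[tuple]:
    """Convert config design entries to (well, role, overrides) tuples.

    Each entry is a mapping with ``well`` and ``role``; all remaining keys
    (including the layout-only ``condition``/``enzyme``/``replicate``) are
    treated as overrides.
    """
    design = []
    for e in entries:
        e = dict(e)
        well = e.pop("well")
        role = e.pop("role", "sample")
        overrides = e.pop("overrides", {})
        overrides.update(e)
        design.append((well, role, overrides))
    return design


def _calibration_from_config(block: dict | None, out_dir: Path) -> CalibrationModel:
    from .errors import CalibrationError

    if not block:
        raise CalibrationError(
            "no calibration given: supply {'k': value} or {'file': path}"
        )
    if "k" in block:
        k = float(block["k"])
        return CalibrationModel(k=k, intercept=0.0, r_squared=1.0,
                                substrate_amounts=np.array([]),
                                imax_values=np.array([]), n_points=0)
    if "file" in block:
        df = pd.read_csv(block["file"])
        if {"amount_mol", "imax_AU"}.issubset(df.columns):
            return quantify.fit_calibration(df["amount_mol"], df["imax_AU"])
        if "k_AU_per_mol" in df.columns:
            row = df.iloc[0]
            return CalibrationModel(
                k=float(row["k_AU_per_mol"]),
                intercept=float(row.get("intercept_AU", 0.0)),
                r_squared=float(row.get("r_squared", 1.0)),
                substrate_amounts=np.array([]), imax_values=np.array([]),
                n_points=int(row.get("n_points", 0)),
            )
        raise CalibrationError(
            f"{block['file']}: expected columns amount_mol,imax_AU or k_AU_per_mol"
        )
    raise CalibrationError("calibration block must contain 'k' or 'file'")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                log.error("stage %s: FAILED (%s)", name, exc)
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(config: dict, seed: int, out_dir: Path, outputs: list) -> PlateDataset:
    sim = config["simulation"]
    base = build_base_config(sim.get("base"))
    design = build_design(sim["design"])
    dataset = simulate_plate(design, base, seed=seed)
    dialect = sim.get("dialect", "long")
    kin_path = out_dir / "kinetics.csv"
    lay_path = out_dir / "layout.csv"
    plateio.write_kinetics(dataset.traces, kin_path, dialect=dialect)
    plateio.write_layout(dataset.layout, lay_path)
    outputs += [str(kin_path), str(lay_path)]
    return dataset


@_stage("load")
def _run_load(config: dict) -> PlateDataset:
    traces = plateio.read_kinetics(config["kinetics"],
                                   dialect=config.get("dialect", "long"))
    layout = plateio.read_layout(config["layout"])
    return plateio.assemble_dataset(traces, layout,
                                    metadata={"source": str(config["kinetics"])})


@_stage("quantify")
def _run_quantify(dataset: PlateDataset, config: dict, out_dir: Path, outputs: list):
    qc = config.get("quantify", {})
    calib = _calibration_from_config(config.get("calibration"), out_dir)
    results = quantify.quantify_plate(
        dataset, calib,
        policy=qc.get("policy", "initial_window"),
        window=int(qc.get("window", 12)),
        baseline_m=int(qc.get("baseline_m", 1)),
    )
    path = out_dir / "activities.csv"
    plateio.write_results(results, path)
    outputs.append(str(path))
    return results, calib


@_stage("fit")
def _run_fit(results, dataset: PlateDataset, config: dict, out_dir: Path, outputs: list):
    specs = config.get("fits", [])
    if not specs:
        return {}
    layout = dataset.layout.table
    fits: dict[str, Any] = {}
    for spec in specs:
        model = spec["model"]
        xcol = spec.get("x_column", _FIT_X_COLUMNS.get(model))
        if xcol is None:
            raise ValueError(f"fit spec for {model!r} needs x_column")
        x, y = [], []
        for r in results:
            x.append(float(layout.loc[r.well_id, xcol]))
            y.append(r.activity)
        name = spec.get("name", model)
        if model == "mm":
            fits[name] = fitting.fit_mm(x, y).__dict__
        elif model == "ic50":
            fits[name] = fitting.fit_4pl(x, y).__dict__
        elif model == "ph":
            fits[name] = fitting.estimate_ph_optimum(x, y).__dict__
        elif model == "thermal":
            fits[name] = fitting.estimate_thermal_midpoint(x, y).__dict__
        else:
            raise ValueError(f"unknown fit model {model!r}")
    path = out_dir / "fits.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True, default=str)
    outputs.append(str(path))
    return fits


@_stage("report")
def _run_report(results, dataset: PlateDataset, config: dict, seed: int,
                out_dir: Path, outputs: list):
    sc = config.get("stats", {})
    agg = quantify.aggregate_replicates(results, dataset.layout)
    rows = [{
        "condition": a.condition, "n": a.n,
        "mean_activity_mol_per_min": a.mean,
        "sem_activity_mol_per_min": a.sem,
        "mean_specific_activity_mol_per_min_per_mg": a.mean_specific,
        "sem_specific_activity_mol_per_min_per_mg": a.sem_specific,
        "mean_integrated_activity_mol_min": a.mean_integrated,
    } for a in agg]
    control = sc.get("control")
    if control is not None:
        by_cond: dict[str, list[float]] = {}
        for r in results:
            if r.condition is not None:
                by_cond.setdefault(str(r.condition), []).append(r.activity)
        if control not in by_cond:
            raise ValueError(f"control condition {control!r} not found in results")
        n_boot = int(sc.get("bootstrap", 2000))
        alpha = float(sc.get("alpha", 0.05))
        fold = {}
        for cond, vals in by_cond.items():
            if cond == control:
                continue
            fc = compare.fold_change(vals, by_cond[control], cond, control,
                                     n_boot=n_boot, seed=seed)
            fold[cond] = fc
        testable = {c: v for c, v in by_cond.items() if len(v) >= 2}
        dunnett = None
        if control in testable and len(testable) >= 2:
            dunnett = compare.dunnett_vs_control(testable, control, alpha=alpha)
        for row in rows:
            cond = row["condition"]
            if cond in fold:
                row["fold_change_vs_control"] = fold[cond].fold_change
                row["fold_ci_low"] = fold[cond].ci_low
                row["fold_ci_high"] = fold[cond].ci_high
            if dunnett is not None and cond in dunnett.labels:
                i = dunnett.labels.index(cond)
                row["dunnett_p_adjusted"] = float(dunnett.p_adjusted[i])
                row["significance"] = dunnett.stars[i]
    df = pd.DataFrame(rows).sort_values("condition").reset_index(drop=True)
    path = out_dir / "report.csv"
    plateio.write_results(df, path)
    outputs.append(str(path))
    return df


def run(config: dict, seed: int = 0, out_dir=None, log_level: str = "INFO") -> dict:
    """Execute the configured pipeline and return the run manifest."""
    out_dir = Path(out_dir if out_dir is not None else config.get("out_dir", "efqo_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    has_sim = "simulation" in config
    has_files = "kinetics" in config or "layout" in config
    outputs: list[str] = []
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "outputs": outputs,
        "status": "running",
    }
    try:
        if has_sim == has_files:
            raise PipelineError(
                "validate",
                "exactly one of a 'simulation' block or 'kinetics'+'layout' "
                "paths must be supplied",
            )
        if has_sim:
            dataset = _run_simulate(config, seed, out_dir, outputs)
        else:
            dataset = _run_load(config)
        results, _calib = _run_quantify(dataset, config, out_dir, outputs)
        _run_fit(results, dataset, config, out_dir, outputs)
        _run_report(results, dataset, config, seed, out_dir, outputs)
        manifest["status"] = "ok"
    except PipelineError as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = exc.stage
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.removeHandler(handler)
        handler.close()
        raise
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.removeHandler(handler)
    handler.close()
    manifest["out_dir"] = str(out_dir)
    return manifest
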