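"""End-to-end pipeline: simulate femora → fit nails → cohort summary.

A single YAML/dict config drives all stages; one explicit master seed makes
every artifact reproducible. Each run writes a manifest (config snapshot,
seed, package version, SHA-256 of every emitted file, timestamps) from which
the output directory can be regenerated exactly (summaries to 1e-9;
simulated inputs byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .femur import FemurModel, load_femur, save_femur
from .metrics import FitnessOptions, FitnessReport, compute_fitness
from .nails import (NailSpec, build_nail_mesh, make_generic_spec,
                    make_intertan_spec, make_pfna2_spec, make_pfna_legacy_spec)
from .placement import PlacementOptions, place_nail
from .stats import CohortTable, build_summary
from .synthetic import PopulationSpec, build_femur, sample_population

log = logging.getLogger(__name__)

NAIL_FACTORIES = {"pfna2": make_pfna2_spec, "pfna": make_pfna_legacy_spec,
                  "intertan": make_intertan_spec, "generic": make_generic_spec}

DEFAULT_CONFIG = {
    "seed": None,                  # must be given explicitly
    "n": 10,
    "nails": ["pfna2", "intertan"],
    "nail_length": 170.0,          # standard short nail for the population
    "distal_diameter": 10.0,
    "population": {},              # overrides of synthetic.DEFAULT_POPULATION
    "fitness": {"density": 2.0},   # cohort default scaled down for runtime
    "placement": {},
    "mesh": {"n_circ": 40, "axial_step": 2.5},
    "write_meshes": True,
}


def validate_config(config: dict) -> dict:
    """Merge with defaults and validate; raises ConfigError with the
    offending key path."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **config}
    if cfg["seed"] is None:
        raise ConfigError("seed: an explicit integer seed is required")
    if not isinstance(cfg["seed"], int) or isinstance(cfg["seed"], bool):
        raise ConfigError("seed: must be an integer")
    if not isinstance(cfg["n"], int) or cfg["n"] < 1:
        raise ConfigError(f"n: need a positive integer, got {cfg['n']!r}")
    if not cfg["nails"]:
        raise ConfigError("nails: need at least one nail design")
    for name in cfg["nails"]:
        if name not in NAIL_FACTORIES:
            raise ConfigError(
                f"nails: unknown design {name!r}; choose from "
                f"{sorted(NAIL_FACTORIES)}")
    if cfg["nail_length"] <= 0 or cfg["distal_diameter"] <= 0:
        raise ConfigError("nail_length / distal_diameter must be positive")
    for section, cls in (("fitness", FitnessOptions),
                         ("placement", PlacementOptions)):
        try:
            cls(**cfg[section])
        except TypeError as exc:
            raise ConfigError(f"{section}: {exc}") from None
    return cfg


def load_config(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    return validate_config(data or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def nail_spec_for(name: str, cfg: dict) -> NailSpec:
    return NAIL_FACTORIES[name](cfg["nail_length"], cfg["distal_diameter"])


def simulate_cohort(cfg: dict, out_dir: Path) -> list[FemurModel]:
    """Sample and build the synthetic cohort; write STL + landmark JSON and
    a manifest CSV of the true generator parameters."""
    out_dir.mkdir(parents=True, exist_ok=True)
    pop_spec = PopulationSpec(n=cfg["n"], seed=cfg["seed"],
                              distributions=cfg["population"] or None)
    params = sample_population(pop_spec)
    models = []
    rows = []
    for i, p in enumerate(params):
        fid = f"femur_{i:03d}"
        model = build_femur(p, fid, **cfg["mesh"])
        models.append(model)
        rows.append({"id": fid, **asdict(p)})
        if cfg["write_meshes"]:
            save_femur(model, out_dir / f"{fid}.stl", out_dir / f"{fid}.json")
        log.info("simulate: %s built (%d faces)", fid,
                 model.endosteal_mesh.n_faces)
    import pandas as pd
    pd.DataFrame(rows).to_csv(out_dir / "true_parameters.csv", index=False)
    return models


def fit_one(femur: FemurModel, nail_name: str, cfg: dict) -> FitnessReport:
    """Place one nail in one femur and measure the fitness parameters."""
    spec = nail_spec_for(nail_name, cfg)
    nail = build_nail_mesh(spec)
    popts = PlacementOptions(**cfg["placement"])
    fopts = FitnessOptions(**{"allow_unconverged": True, **cfg["fitness"]})
    placement = place_nail(femur, nail, popts)
    report = compute_fitness(femur, nail, placement, fopts)
    report.nail_id = nail_name.upper()
    return report


def run_pipeline(config: dict, out_dir) -> dict:
    """simulate → fit (every nail × every femur) → cohort summary.

    Returns a dict of output paths. Per-case failures are logged, tallied in
    the manifest, and do not abort the run.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    models = simulate_cohort(cfg, out / "femurs")

    reports_dir = out / "reports"
    reports_dir.mkdir(exist_ok=True)
    reports: list[FitnessReport] = []
    failures: list[dict] = []
    for model in models:
        for nail_name in cfg["nails"]:
            try:
                rep = fit_one(model, nail_name, cfg)
            except Exception as exc:  # logged, tallied, run continues
                log.error("fit failed: %s/%s: %s", model.id, nail_name, exc)
                failures.append({"femur": model.id, "nail": nail_name,
                                 "error": str(exc)})
                continue
            reports.append(rep)
            (reports_dir / f"{model.id}_{nail_name}.json").write_text(
                rep.to_json())
            log.info("fit: %s/%s converged=%s", model.id, nail_name,
                     rep.converged)

    table = CohortTable.from_reports(reports)
    summary = build_summary(table)
    (out / "summary.json").write_text(summary.to_json())
    summary.to_csv(out / "summary.csv")

    manifest = {
        "config": cfg,
        "seed": cfg["seed"],
        "version": __version__,
        "n_reports": len(reports),
        "failures": failures,
        "elapsed_s": round(time.time() - t_start, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {str(p.relative_to(out)): _sha256(p)
                  for p in sorted(out.rglob("*")) if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"out": out, "summary_json": out / "summary.json",
            "summary_csv": out / "summary.csv",
            "manifest": out / "manifest.json", "n_failures": len(failures)}


def cohort_from_report_dir(reports_dir) -> CohortTable:
    """Rebuild a cohort table from per-case JSON reports on disk."""
    reports = []
    for p in sorted(Path(reports_dir).glob("*.json")):
        reports.append(FitnessReport.from_json(p.read_text()))
    if not reports:
        raise ConfigError(f"no reports found in {reports_dir}")
    return CohortTable.from_reports(reports)
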