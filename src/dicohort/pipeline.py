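"""End-to-end workflow: encode -> QC -> association -> DCA/DI -> tree -> LOOCV.

Every stage writes plain TSV/JSON into the run directory so it can be
inspected or re-run independently; a provenance record captures the config
hash, seed, and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import GENETIC_MODELS, association_scan
from .cohort import (
    DiscreteCohort,
    read_cohort,
    summarize_phenotypes,
    summarize_treatment_lines,
)
from .dca import DEFAULT_PSEUDOCOUNT, di_matrix
from .network import chow_liu_tree, export_network, rank_response_couplings
from .predict import loocv
from .qc import QCThresholds, apply_qc
from .simulate import SimulationConfig, assemble_cohort

log = logging.getLogger("dicohort")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "write_cohort_tsv"]


@dataclass
class PipelineConfig:
    """Normalized configuration of a full pipeline run."""

    outdir: str = "dicohort_run"
    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    schema_config: str | dict | None = None
    lam: float = DEFAULT_PSEUDOCOUNT
    qc: QCThresholds = field(default_factory=QCThresholds)
    models: tuple[str, ...] = GENETIC_MODELS
    bonferroni_m: int | None = None
    response_cutoff: float = 7.0
    run_loocv: bool = True
    tree_formats: tuple[str, ...] = ("tsv", "graphml", "dot")


_KNOWN_KEYS = {
    "outdir", "seed", "simulate", "simulation", "cohort_path", "schema_config",
    "lam", "qc", "models", "bonferroni_m", "response_cutoff", "run_loocv",
    "tree_formats",
}


def validate_config(raw) -> tuple[PipelineConfig, list[str]]:
    """Normalize a config mapping (or YAML path): defaults, errors, warnings.

    Returns the filled config and a list of warnings; contradictions raise
    ``ValueError`` listing every offending field.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("pipeline config must be a mapping")
    warnings = [f"unknown config key {k!r} ignored" for k in raw if k not in _KNOWN_KEYS]
    errors: list[str] = []

    cfg = PipelineConfig()
    cfg.outdir = str(raw.get("outdir", cfg.outdir))
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.simulate = bool(raw.get("simulate", "cohort_path" not in raw))
    cfg.cohort_path = raw.get("cohort_path")
    cfg.schema_config = raw.get("schema_config")
    cfg.lam = float(raw.get("lam", cfg.lam))
    if not 0.0 <= cfg.lam <= 1.0:
        errors.append(f"lam must be in [0, 1], got {cfg.lam}")
    qc_raw = raw.get("qc", {})
    thresholds = QCThresholds(
        min_call_rate=float(qc_raw.get("min_call_rate", 0.90)),
        min_hwe_p=float(qc_raw.get("min_hwe_p", 0.05)),
        min_maf=float(qc_raw.get("min_maf", 0.01)),
    )
    if not 0.0 <= thresholds.min_call_rate <= 1.0:
        errors.append(f"qc.min_call_rate must be in [0, 1], got {thresholds.min_call_rate}")
    if not 0.0 <= thresholds.min_hwe_p < 1.0:
        errors.append(f"qc.min_hwe_p must be in [0, 1), got {thresholds.min_hwe_p}")
    if not 0.0 <= thresholds.min_maf < 0.5:
        errors.append(f"qc.min_maf must be in [0, 0.5), got {thresholds.min_maf}")
    cfg.qc = thresholds
    models = tuple(raw.get("models", GENETIC_MODELS))
    bad = [m for m in models if m not in GENETIC_MODELS]
    if bad:
        errors.append(f"unknown genetic models {bad}; choose from {GENETIC_MODELS}")
    cfg.models = models
    if raw.get("bonferroni_m") is not None:
        cfg.bonferroni_m = int(raw["bonferroni_m"])
        if cfg.bonferroni_m < 1:
            errors.append("bonferroni_m must be >= 1")
    cfg.response_cutoff = float(raw.get("response_cutoff", 7.0))
    if cfg.response_cutoff <= 0:
        errors.append("response_cutoff must be positive")
    cfg.run_loocv = bool(raw.get("run_loocv", True))
    if "simulation" in raw and raw["simulation"]:
        cfg.simulation = SimulationConfig.from_dict(raw["simulation"])
    if not cfg.simulate and not cfg.cohort_path:
        errors.append("either simulate: true or a cohort_path is required")
    if errors:
        raise ValueError("invalid pipeline config:\n- " + "\n- ".join(errors))
    return cfg, warnings


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    blob = json.dumps(asdict_safe(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(cfg: PipelineConfig) -> dict:
    d = {}
    for k, v in vars(cfg).items():
        if isinstance(v, QCThresholds):
            d[k] = asdict(v)
        elif isinstance(v, SimulationConfig):
            d[k] = "custom-simulation"
        else:
            d[k] = v if isinstance(v, (int, float, str, bool, type(None))) else list(v) if isinstance(v, tuple) else str(v)
    return d


def write_cohort_tsv(cohort: DiscreteCohort, path) -> None:
    cohort.data.to_csv(path, sep="\t", index_label="patient_id")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write its outputs under the run directory.

    A stage failure raises with the stage name in the message.  If QC leaves
    no SNP columns, the association stage is skipped (with a logged reason)
    and the coupling analysis proceeds on the remaining variables.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "input"
        if config.simulate:
            log.info("simulating cohort (seed=%d)", config.seed)
            cohort, truth = assemble_cohort(config.simulation, seed=config.seed)
            write_cohort_tsv(cohort, outdir / "cohort.tsv")
            truth.to_json(outdir / "truth.json")
        else:
            log.info("reading cohort from %s", config.cohort_path)
            cohort = read_cohort(config.cohort_path, config.schema_config)

        stage = "summaries"
        try:
            summarize_treatment_lines(cohort).to_csv(
                outdir / "summary_treatment_lines.tsv", sep="\t", index=False
            )
        except ValueError:
            log.info("no drug columns; skipping treatment-line summary")
        resp_name = cohort.response_variable.name
        summarize_phenotypes(cohort, resp_name).to_csv(
            outdir / "summary_phenotypes.tsv", sep="\t", index=False
        )

        stage = "qc"
        log.info("running genotype QC")
        report, cohort_qc = apply_qc(cohort, config.qc)
        report.to_tsv(outdir / "qc_report.tsv")
        report.to_json(outdir / "qc_report.json")
        log.info("QC kept %d/%d SNPs", len(report.surviving), len(report.table))

        stage = "association"
        if report.surviving:
            scan = association_scan(
                cohort_qc, models=config.models, bonferroni_m=config.bonferroni_m
            )
            scan.to_csv(outdir / "association.tsv", sep="\t", index=False)
        else:
            log.info("association skipped: no SNP columns survived QC")
            (outdir / "association.SKIPPED").write_text(
                "no SNP columns survived QC\n"
            )

        stage = "dca"
        log.info("computing direct information (lam=%.3g)", config.lam)
        di = di_matrix(cohort_qc, lam=config.lam)
        di.to_long_frame().to_csv(outdir / "di_long.tsv", sep="\t", index=False)
        di.to_frame().to_csv(outdir / "di_matrix.tsv", sep="\t")

        stage = "network"
        kinds = {v.name: v.kind for v in cohort_qc.schema}
        tree = chow_liu_tree(di, node_kinds=kinds)
        for fmt in config.tree_formats:
            export_network(tree, outdir / f"tree.{fmt if fmt != 'tsv' else 'tsv'}", fmt)
        ranking = rank_response_couplings(di, resp_name)
        ranking.table.to_csv(outdir / "response_ranking.tsv", sep="\t", index=False)

        stage = "loocv"
        cv_summary = None
        if config.run_loocv:
            log.info("leave-one-out cross-validation (%d folds)", cohort_qc.n_patients)
            cv = loocv(cohort_qc, lam=config.lam)
            cv.folds.to_csv(outdir / "cv_folds.tsv", sep="\t", index=False)
            cv_summary = cv.to_json_dict()
            with open(outdir / "cv_report.json", "w") as fh:
                json.dump(cv_summary, fh, indent=2)

        stage = "provenance"
        prov = {
            "config": asdict_safe(config),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "dicohort_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "stages": {
                "qc_surviving": report.surviving,
                "loocv": cv_summary,
            },
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
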