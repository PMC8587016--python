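"""End-to-end pipeline: chemicals -> QSAR -> ICE pool -> SSD -> PNEC -> RQ.

Each stage writes its intermediate table under the run directory
(qsar_predictions.csv, species_pool.csv, ssd_fit.json, pnec.csv,
risk_report.csv/.json) and appends stage-tagged lines to pipeline.log, so
every number in the final report is traceable to a logged intermediate.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import core, ice, qsar, risk, ssd
from ._utils import round_sig
from .errors import ConfigError, PipelineError


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run; file paths may be None to skip stages."""

    chemicals: Optional[str] = None
    toxicity: Optional[str] = None
    ice_models: Optional[str] = None
    monitoring: Optional[str] = None
    output_dir: str = "pfasrisk_run"
    af: float = 5.0
    alpha: float = 0.05
    min_species: int = 6
    p_enter: float = 0.05
    p_remove: float = 0.10
    seed: int = 0
    include_out_of_domain: bool = False

    def __post_init__(self) -> None:
        problems = []
        if self.af <= 0:
            problems.append(f"af must be positive, got {self.af}")
        if not 0 < self.alpha < 1:
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_species < 2:
            problems.append(f"min_species must be >= 2, got {self.min_species}")
        if not 0 < self.p_enter < 1 or not 0 < self.p_remove <= 1:
            problems.append("p_enter/p_remove must be probabilities")
        if problems:
            raise ConfigError("; ".join(problems))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; report all problems at once.

    Unknown keys are rejected with a did-you-mean suggestion; defaults are
    applied for everything not given (af = 5, alpha = 0.05, ...).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw: dict[str, Any] = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    problems = []
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            problems.append(f"unknown key {key!r}{suffix}")
    for key in ("chemicals", "toxicity", "ice_models", "monitoring"):
        p = raw.get(key)
        if p is not None and not Path(p).exists():
            problems.append(f"{key} file not found: {p}")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    try:
        return PipelineConfig(**raw)
    except (ConfigError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunReport:
    """Outcome of run_full_pipeline: per-chemical fits plus the risk table."""

    ssd_fits: dict[str, ssd.SsdFit]
    pnecs: dict[str, float]  # mg/L
    risk: Optional[risk.RiskReport]
    log_lines: list[str] = field(default_factory=list)
    output_dir: Optional[Path] = None


def _stage(log: list[str], stage: str, msg: str) -> None:
    log.append(f"[{stage}] {msg}")


def run_full_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every configured stage; any stage error aborts, naming the stage."""
    log: list[str] = []
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ingest ---------------------------------------------------------
    try:
        chemicals = core.load_chemical_table(config.chemicals) if config.chemicals else []
        tox_records = core.load_toxicity_table(config.toxicity) if config.toxicity else []
        ice_models = ice.load_ice_models(config.ice_models) if config.ice_models else []
    except Exception as exc:
        raise PipelineError(f"stage=ingest: {exc}") from exc
    _stage(log, "ingest", f"chemicals={len(chemicals)} toxicity_records={len(tox_records)} "
                          f"ice_models={len(ice_models)}")

    # --- QSAR predictions (published per-species equations) -------------
    predictions: list[qsar.PredictionResult] = []
    if chemicals:
        try:
            predictions = qsar.predict_toxicity_matrix(qsar.PUBLISHED_MODELS, chemicals)
        except Exception as exc:
            raise PipelineError(f"stage=qsar: {exc}") from exc
        pd.DataFrame(
            [
                {
                    "chem_id": p.chem_id,
                    "species": p.species,
                    "endpoint": p.endpoint.value,
                    "duration_h": p.duration_h,
                    "log10_mg_L": p.log10_value,
                    "mg_L": p.value,
                    "in_training_domain": p.in_training_domain,
                }
                for p in predictions
            ]
        ).to_csv(out / "qsar_predictions.csv", index=False)
        _stage(log, "qsar", f"predictions={len(predictions)}")

    # --- species pools, SSD fits, PNECs ---------------------------------
    chem_ids = sorted(
        {c.chem_id for c in chemicals} | {r.chem_id for r in tox_records}
    )
    fits: dict[str, ssd.SsdFit] = {}
    pnecs: dict[str, float] = {}
    pool_rows = []
    for cid in chem_ids:
        try:
            measured_recs = core.select_preferred_records(
                [r for r in tox_records if r.chem_id == cid]
            )
            measured = core.aggregate_species_toxicity(measured_recs)
            qsar_recs = qsar.prediction_records(
                [p for p in predictions if p.chem_id == cid]
            )
            pool = ice.build_species_pool(
                measured, qsar_recs, ice_models, cid,
                include_out_of_domain=config.include_out_of_domain,
            )
        except Exception as exc:
            raise PipelineError(f"stage=pool chemical={cid!r}: {exc}") from exc
        for st in pool:
            pool_rows.append(
                {"chem_id": cid, "species": st.species, "mg_L": st.value,
                 "n_source_records": st.n_source_records,
                 "provenance": st.provenance.value}
            )
        _stage(log, "pool", f"chemical={cid} n_species={len(pool)}")
        try:
            fit = ssd.fit_ssd_pipeline(
                pool, af=config.af, alpha=config.alpha, min_n=config.min_species
            )
        except Exception as exc:
            raise PipelineError(f"stage=ssd chemical={cid!r}: {exc}") from exc
        fits[cid] = fit
        pnecs[cid] = fit.pnec
        for w in fit.warnings:
            _stage(log, "ssd", f"chemical={cid} warning: {w}")
        _stage(
            log, "ssd",
            f"chemical={cid} mu={fit.mu:.4f} sigma={fit.sigma:.4f} "
            f"hc5={fit.hc5:.6g} pnec={fit.pnec:.6g} "
            f"gof={{{', '.join(f'{k}: {v.passed}' for k, v in fit.gof.items())}}}",
        )

    if pool_rows:
        pd.DataFrame(pool_rows).to_csv(out / "species_pool.csv", index=False)
    if fits:
        (out / "ssd_fit.json").write_text(
            json.dumps(
                {
                    cid: {
                        "mu": f.mu,
                        "sigma": f.sigma,
                        "n_species": f.n_species,
                        "hc5_mg_L": f.hc5,
                        "af": f.af,
                        "pnec_mg_L": f.pnec,
                        "hc5_mg_L_3sf": round_sig(f.hc5, 3),
                        "pnec_mg_L_3sf": round_sig(f.pnec, 3),
                        "gof": {
                            k: {"statistic": g.statistic, "passed": g.passed,
                                "critical": g.critical, "p_value": g.p_value}
                            for k, g in f.gof.items()
                        },
                        "warnings": f.warnings,
                    }
                    for cid, f in fits.items()
                },
                indent=2,
            )
        )
        pd.DataFrame(
            [{"chem_id": cid, "pnec_mg_per_L": f.pnec} for cid, f in fits.items()]
        ).to_csv(out / "pnec.csv", index=False)

    # --- risk ------------------------------------------------------------
    report: Optional[risk.RiskReport] = None
    if config.monitoring:
        try:
            monitoring = risk.load_monitoring_table(config.monitoring)
            report = risk.risk_report(monitoring, pnecs)
            risk.write_risk_report(report, out)
        except Exception as exc:
            raise PipelineError(f"stage=risk: {exc}") from exc
        _stage(log, "risk", f"sites={report.per_site_sum_mec.size} "
                            f"chemicals={len(report.per_chemical)}")

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return RunReport(ssd_fits=fits, pnecs=pnecs, risk=report, log_lines=log, output_dir=out)
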