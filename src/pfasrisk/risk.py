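"""Risk quotients from measured environmental concentrations and PNECs.

The screening-level risk quotient is RQ = MEC/PNEC with both sides in the
same units; monitoring data arrive in ng/L and PNECs in mg/L, so the ratio
carries a fixed 1e6 bridge.  Grades follow the conventional screening
bands: high (RQ ≥ 1), medium (1 > RQ ≥ 0.1), low (0.1 > RQ ≥ 0.01), none
(RQ < 0.01), each boundary belonging to the higher grade.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import geometric_mean, round_sig
from .errors import DomainError, FormatError, ValidationError
from .core import convert_concentration


class RiskGrade(enum.IntEnum):
    """Ordered so that comparisons follow severity."""

    none = 0
    low = 1
    medium = 2
    high = 3


def compute_rq(mec_ng_L: float, pnec_mg_L: float) -> float:
    """RQ = MEC / PNEC with MEC in ng/L and PNEC in mg/L (dimensionless)."""
    if pnec_mg_L <= 0:
        raise DomainError(f"PNEC must be positive, got {pnec_mg_L}")
    if mec_ng_L < 0:
        raise DomainError(f"MEC must be non-negative, got {mec_ng_L}")
    return convert_concentration(mec_ng_L, "ng/L", "mg/L") / pnec_mg_L


def classify_risk(rq: float) -> RiskGrade:
    """Half-open screening bands; boundaries belong to the higher grade."""
    if rq < 0:
        raise DomainError(f"RQ must be non-negative, got {rq}")
    if rq >= 1:
        return RiskGrade.high
    if rq >= 0.1:
        return RiskGrade.medium
    if rq >= 0.01:
        return RiskGrade.low
    return RiskGrade.none


@dataclass(frozen=True)
class RiskResult:
    site: str
    chem_id: str
    mec: float      # ng/L
    pnec: float     # mg/L
    rq: float
    grade: RiskGrade


@dataclass
class RiskReport:
    """Per-(site, chemical) RQs plus chemical-level and site-level summaries."""

    results: list[RiskResult]
    per_chemical: pd.DataFrame  # rq_min/mean/max (x1e-6, 3 s.f.), grade of mean
    per_site_sum_mec: pd.Series  # sum of MECs per site, ng/L


def risk_report(
    monitoring: pd.DataFrame,
    pnecs: Mapping[str, float],
    *,
    mean_kind: str = "arithmetic",
    nondetect_value: float = 0.0,
) -> RiskReport:
    """Build a site x chemical risk table from monitoring MECs and PNECs.

    ``monitoring`` needs columns (site, chem_id, mec[, unit]); MECs default
    to ng/L.  Every monitored chemical must have a PNEC (mg/L).  Per
    chemical the report carries the per-site RQ range and mean (arithmetic
    by default, geometric behind ``mean_kind="geometric"``) scaled by 1e6
    and rounded to 3 significant figures, plus the grade of the mean; per
    site, the summed MEC.  Non-detects (missing MEC) enter at
    ``nondetect_value`` (default 0, i.e. RQ 0; pass LOD/2 to substitute).
    """
    required = {"site", "chem_id", "mec"}
    missing_cols = required - set(monitoring.columns)
    if missing_cols:
        raise FormatError(f"monitoring table missing column(s): {sorted(missing_cols)}")
    if mean_kind not in ("arithmetic", "geometric"):
        raise ValidationError(f"mean_kind must be arithmetic|geometric, got {mean_kind!r}")

    df = monitoring.copy()
    if "unit" in df.columns:
        df["mec"] = [
            convert_concentration(float(v), u, "ng/L")
            for v, u in zip(df["mec"].fillna(nondetect_value), df["unit"])
        ]
    else:
        df["mec"] = df["mec"].fillna(nondetect_value).astype(float)

    monitored = sorted(set(df["chem_id"]))
    no_pnec = [c for c in monitored if c not in pnecs]
    if no_pnec:
        raise ValidationError(f"no PNEC for monitored chemical(s): {no_pnec}")

    results = [
        RiskResult(
            site=str(row.site),
            chem_id=str(row.chem_id),
            mec=float(row.mec),
            pnec=float(pnecs[row.chem_id]),
            rq=(rq := compute_rq(float(row.mec), float(pnecs[row.chem_id]))),
            grade=classify_risk(rq),
        )
        for row in df.itertuples()
    ]

    rows = []
    for chem in monitored:
        rqs = np.array([r.rq for r in results if r.chem_id == chem])
        if mean_kind == "arithmetic":
            mean_rq = float(rqs.mean())
        else:
            mean_rq = geometric_mean(rqs) if np.all(rqs > 0) else float("nan")
        rows.append(
            {
                "chem_id": chem,
                "rq_min_1e6": round_sig(rqs.min() * 1e6, 3),
                "rq_max_1e6": round_sig(rqs.max() * 1e6, 3),
                "rq_mean_1e6": round_sig(mean_rq * 1e6, 3),
                "rq_mean_raw": mean_rq,
                "grade_of_mean": classify_risk(mean_rq).name,
            }
        )
    per_chemical = pd.DataFrame(rows).set_index("chem_id")
    per_site = df.groupby("site")["mec"].sum().rename("sum_mec_ng_L")
    return RiskReport(results=results, per_chemical=per_chemical, per_site_sum_mec=per_site)


def load_monitoring_table(path: str | Path) -> pd.DataFrame:
    """Read monitoring.csv with columns (site, chem_id, mec[, unit])."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"monitoring table not found: {path}")
    df = pd.read_csv(path)
    missing = {"site", "chem_id", "mec"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s): {sorted(missing)}")
    return df


def write_risk_report(report: RiskReport, out_dir: str | Path) -> None:
    """Emit risk_report.csv (per-chemical summary, x1e-6) and .json (full)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_chemical.to_csv(out_dir / "risk_report.csv")
    payload = {
        "note": "rq columns scaled by 1e6; mec ng/L; pnec mg/L",
        "per_chemical": report.per_chemical.reset_index().to_dict(orient="records"),
        "per_site_sum_mec_ng_L": report.per_site_sum_mec.to_dict(),
        "results": [
            {
                "site": r.site,
                "chem_id": r.chem_id,
                "mec_ng_L": r.mec,
                "pnec_mg_L": r.pnec,
                "rq": r.rq,
                "grade": r.grade.name,
            }
            for r in report.results
        ],
    }
    (out_dir / "risk_report.json").write_text(json.dumps(payload, indent=2))
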