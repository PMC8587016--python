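"""Interspecies correlation estimation (ICE) models and species-pool assembly.

An ICE model is an ordinary least-squares line in log10-log10 space mapping
the acute toxicity of a well-tested surrogate species to that of a predicted
species.  Applying a battery of ICE models to the species for which measured
or QSAR-predicted values exist expands a handful of toxicity values into a
species pool large enough to support an SSD fit.  Model applicability is
guarded by the surrogate's training concentration range (the applicability
domain) plus a quality gate on fit statistics.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from ._utils import geometric_mean, normalize_species
from .core import Provenance, SpeciesToxicity, ToxicityRecord
from .errors import DomainError, FitError, FormatError, ValidationError


@dataclass(frozen=True)
class IceModel:
    """log10(predicted mg/L) = intercept + slope * log10(surrogate mg/L)."""

    surrogate_species: str
    predicted_species: str
    intercept: float
    slope: float
    n: int
    R2: float
    p: float
    surrogate_domain: tuple[float, float]  # (min, max) mg/L of training surrogates

    def __post_init__(self) -> None:
        lo, hi = self.surrogate_domain
        if not (0 < lo <= hi):
            raise ValidationError("surrogate_domain must satisfy 0 < min <= max")
        if self.n < 3:
            raise ValidationError("ICE model needs n >= 3")


def fit_ice_model(
    pairs: Sequence[tuple[float, float]],
    *,
    surrogate_species: str = "surrogate",
    predicted_species: str = "predicted",
) -> IceModel:
    """OLS of log10(predicted) on log10(surrogate) toxicity (mg/L)."""
    if len(pairs) < 3:
        raise FitError(f"ICE fit needs at least 3 pairs, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    if np.any(arr <= 0):
        raise FitError("all toxicity values must be positive")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    if np.ptp(x) == 0:
        raise FitError("zero variance in surrogate values")
    res = sps.linregress(x, y)
    return IceModel(
        surrogate_species=surrogate_species,
        predicted_species=predicted_species,
        intercept=float(res.intercept),
        slope=float(res.slope),
        n=len(pairs),
        R2=float(res.rvalue**2),
        p=float(res.pvalue),
        surrogate_domain=(float(arr[:, 0].min()), float(arr[:, 0].max())),
    )


def apply_ice(model: IceModel, surrogate_value: float) -> tuple[float, bool]:
    """Extrapolate one surrogate toxicity; returns (mg/L, in_domain).

    The prediction is always computed; ``in_domain`` is False when the
    surrogate value falls outside the model's training range (inclusive).
    """
    if surrogate_value <= 0:
        raise DomainError(f"surrogate_value must be positive, got {surrogate_value}")
    predicted = 10.0 ** (model.intercept + model.slope * math.log10(surrogate_value))
    lo, hi = model.surrogate_domain
    return predicted, lo <= surrogate_value <= hi


def passes_quality_gate(
    model: IceModel, min_r2: float = 0.6, max_p: float = 0.05, min_n: int = 3
) -> bool:
    """Minimum-quality screen applied before using an ICE model."""
    return model.R2 >= min_r2 and model.p < max_p and model.n >= min_n


def build_species_pool(
    measured: Sequence[SpeciesToxicity],
    qsar_preds: Sequence[ToxicityRecord],
    ice_models: Sequence[IceModel],
    chemical: str,
    *,
    surrogate_map: Optional[Mapping[str, str]] = None,
    include_out_of_domain: bool = False,
    apply_quality_gate: bool = True,
) -> list[SpeciesToxicity]:
    """Assemble the species pool feeding the SSD for one chemical.

    The pool is the union of measured species values, QSAR predictions, and
    ICE extrapolations, with per-species precedence measured > qsar > ice so
    observations always dominate.  Each ICE model consumes the pooled value
    of its own surrogate species unless ``surrogate_map`` routes a predicted
    species to a different surrogate.  Several ICE routes to one predicted
    species are combined by geometric mean.  Out-of-domain extrapolations
    are dropped unless explicitly included.
    """
    pool: dict[str, SpeciesToxicity] = {}
    for st in measured:
        pool[normalize_species(st.species)] = st

    qsar_groups: dict[str, list[ToxicityRecord]] = {}
    for rec in qsar_preds:
        if rec.chem_id != chemical:
            continue
        qsar_groups.setdefault(normalize_species(rec.species), []).append(rec)
    for key, grp in qsar_groups.items():
        if key in pool:  # measured wins
            continue
        pool[key] = SpeciesToxicity(
            species=grp[0].species,
            value=geometric_mean(r.concentration for r in grp),
            n_source_records=len(grp),
            provenance=Provenance.qsar,
            endpoint=grp[0].endpoint,
        )

    ice_outputs: dict[str, list[tuple[str, float]]] = {}
    for model in ice_models:
        if apply_quality_gate and not passes_quality_gate(model):
            continue
        pred_key = normalize_species(model.predicted_species)
        surrogate = (
            surrogate_map.get(model.predicted_species, model.surrogate_species)
            if surrogate_map
            else model.surrogate_species
        )
        source = pool.get(normalize_species(surrogate))
        if source is None:
            continue
        value, in_domain = apply_ice(model, source.value)
        if not in_domain and not include_out_of_domain:
            continue
        ice_outputs.setdefault(pred_key, []).append((model.predicted_species, value))

    for key, preds in ice_outputs.items():
        if key in pool:  # measured or qsar wins
            continue
        pool[key] = SpeciesToxicity(
            species=preds[0][0],
            value=geometric_mean(v for _, v in preds),
            n_source_records=len(preds),
            provenance=Provenance.ice,
        )

    if not pool:
        raise FitError(f"empty species pool for chemical {chemical!r}")
    return list(pool.values())


_ICE_COLUMNS = (
    "surrogate_species",
    "predicted_species",
    "intercept",
    "slope",
    "n",
    "R2",
    "p",
    "domain_min",
    "domain_max",
)


def load_ice_models(path: str | Path) -> list[IceModel]:
    """Read user-supplied ICE parameters from ice_models.csv."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"ICE model table not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _ICE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        models = []
        for i, row in enumerate(reader, start=1):
            try:
                models.append(
                    IceModel(
                        surrogate_species=row["surrogate_species"].strip(),
                        predicted_species=row["predicted_species"].strip(),
                        intercept=float(row["intercept"]),
                        slope=float(row["slope"]),
                        n=int(row["n"]),
                        R2=float(row["R2"]),
                        p=float(row["p"]),
                        surrogate_domain=(float(row["domain_min"]), float(row["domain_max"])),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}, data row {i}: {exc}") from exc
    return models


def write_ice_models(models: Iterable[IceModel], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_ICE_COLUMNS)
        for m in models:
            w.writerow(
                [m.surrogate_species, m.predicted_species, repr(float(m.intercept)),
                 repr(float(m.slope)), m.n, repr(float(m.R2)), repr(float(m.p)),
                 repr(float(m.surrogate_domain[0])), repr(float(m.surrogate_domain[1]))]
            )
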