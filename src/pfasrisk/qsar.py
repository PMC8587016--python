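"""Stepwise multiple-linear-regression QSAR models of acute aquatic toxicity.

A QSAR model here is a linear map from molecular descriptors (optionally
log10-transformed) to log10 LC50/EC50 in mg/L for one test species.  Models
are built by forward selection with backward elimination on partial-F
p-values — the classic stepwise procedure with default entry/removal
thresholds 0.05/0.10 — and validated by the non-cross-validated r² and the
leave-one-out Q² (1 − PRESS/TSS).  Four published per-species equations are
shipped ready to evaluate; their printed coefficients are applied literally,
with no rescaling of descriptor values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import published
from .core import ChemicalRecord, Endpoint, Provenance, SpeciesClass, ToxicityRecord
from .errors import DomainError, FitError, ValidationError

Transform = str  # "identity" | "log10"


@dataclass(frozen=True)
class Term:
    """One regression term: a descriptor, its transform, and its coefficient."""

    symbol: str
    transform: Transform
    coefficient: float

    def design_value(self, raw: float) -> float:
        if self.transform == "identity":
            return raw
        if self.transform == "log10":
            if raw <= 0:
                raise DomainError(
                    f"descriptor {self.symbol!r} must be positive under log10, got {raw}"
                )
            return math.log10(raw)
        raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ModelStats:
    n: int
    R2: float          # coefficient of determination of the multiple regression
    p: float           # overall-F significance
    r2: float = float("nan")   # squared Pearson corr of fitted vs observed
    q2: float = float("nan")   # leave-one-out 1 - PRESS/TSS


@dataclass
class QsarModel:
    """A fitted or published linear QSAR for one species."""

    species: str
    terms: list[Term]
    intercept: float
    stats: ModelStats
    endpoint: Endpoint = Endpoint.LC50
    species_class: SpeciesClass = SpeciesClass.other
    #: min-max box of the raw training descriptor values, per term symbol;
    #: None for published models whose training data are not available.
    training_ranges: Optional[dict[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        symbols = [t.symbol for t in self.terms]
        if len(symbols) != len(set(symbols)):
            raise ValidationError("each descriptor may appear in at most one term")

    @property
    def required_symbols(self) -> list[str]:
        return [t.symbol for t in self.terms]

    def predict_log10(self, descriptors: Mapping[str, float]) -> float:
        """Evaluate the linear combination in log10 space."""
        total = self.intercept
        for t in self.terms:
            if t.symbol not in descriptors:
                raise ValidationError(
                    f"model for {self.species!r} requires descriptor {t.symbol!r}"
                )
            total += t.coefficient * t.design_value(descriptors[t.symbol])
        return total

    def in_training_domain(self, descriptors: Mapping[str, float]) -> Optional[bool]:
        """Min-max box check on raw descriptors; None when no box is known."""
        if self.training_ranges is None:
            return None
        for sym, (lo, hi) in self.training_ranges.items():
            v = descriptors.get(sym)
            if v is None or not lo <= v <= hi:
                return False
        return True


@dataclass(frozen=True)
class PredictionResult:
    """One QSAR prediction: log10 value, back-transformed value, domain flag."""

    chem_id: str
    species: str
    log10_value: float
    value: float  # mg/L, equals 10**log10_value
    in_training_domain: Optional[bool]
    endpoint: Endpoint = Endpoint.LC50
    species_class: SpeciesClass = SpeciesClass.other
    duration_h: float = 96.0

    def to_record(self) -> ToxicityRecord:
        return ToxicityRecord(
            chem_id=self.chem_id,
            species=self.species,
            species_class=self.species_class,
            endpoint=self.endpoint,
            duration_h=self.duration_h,
            concentration=self.value,
            provenance=Provenance.qsar,
        )


def _published_model(equation_id: str) -> QsarModel:
    try:
        spec = published.QSAR_EQUATIONS[equation_id]
    except KeyError:
        raise KeyError(
            f"unknown equation id {equation_id!r}; "
            f"known: {sorted(published.QSAR_EQUATIONS)}"
        )
    s = spec["stats"]
    return QsarModel(
        species=spec["species"],
        terms=[Term(sym, tr, coef) for sym, tr, coef in spec["terms"]],
        intercept=spec["intercept"],
        stats=ModelStats(n=s["n"], R2=s["R2"], p=s["p"], r2=s["r2"], q2=s["q2"]),
        endpoint=Endpoint(spec["endpoint"]),
        species_class=SpeciesClass(spec["species_class"]),
        training_ranges=None,
    )


#: The four published per-species equations, keyed by equation id.
PUBLISHED_MODELS: dict[str, QsarModel] = {
    eq_id: _published_model(eq_id) for eq_id in published.QSAR_EQUATIONS
}


def evaluate_published_equation(
    equation_id: str, descriptors: Mapping[str, float], chem_id: str = ""
) -> PredictionResult:
    """Evaluate one published equation literally as printed.

    The linear combination is computed in log10 space and back-transformed
    to mg/L.  Missing descriptors raise naming the symbol; a non-positive
    value under a log10 term raises a domain error.
    """
    model = PUBLISHED_MODELS[equation_id]
    log10_value = model.predict_log10(descriptors)
    return PredictionResult(
        chem_id=chem_id,
        species=model.species,
        log10_value=log10_value,
        value=10.0 ** log10_value,
        in_training_domain=model.in_training_domain(descriptors),
        endpoint=model.endpoint,
        species_class=model.species_class,
        duration_h=48.0 if model.species_class is SpeciesClass.invertebrate else 96.0,
    )


# ---------------------------------------------------------------------------
# stepwise fitting
# ---------------------------------------------------------------------------

def _candidate_columns(X: pd.DataFrame, add_log_transforms: bool) -> list[tuple[str, Transform, np.ndarray]]:
    cands: list[tuple[str, Transform, np.ndarray]] = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            raise FitError(f"descriptor {col!r} contains missing/non-finite values")
        cands.append((str(col), "identity", v))
        if add_log_transforms and np.all(v > 0):
            cands.append((str(col), "log10", np.log10(v)))
    return cands


def _ols(y: np.ndarray, cols: Sequence[np.ndarray]):
    design = sm.add_constant(np.column_stack(cols) if cols else np.empty((len(y), 0)),
                             has_constant="add")
    return sm.OLS(y, design).fit()


def fit_stepwise_mlr(
    X: pd.DataFrame,
    y: Sequence[float],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    *,
    species: str = "",
    endpoint: Endpoint = Endpoint.LC50,
    species_class: SpeciesClass = SpeciesClass.other,
    add_log_transforms: bool = True,
) -> QsarModel:
    """Forward-selection / backward-elimination OLS on partial-F p-values.

    At each step the candidate with the smallest partial-F p-value enters if
    it is <= ``p_enter`` (the partial F for a single added regressor equals
    its squared t, so the coefficient's t-test p-value is used); any included
    term whose p-value rises to >= ``p_remove`` is then dropped.  Iteration
    stops when neither move applies.  Each descriptor competes both raw and
    (when strictly positive) log10-transformed, but may appear in at most one
    term.  Ties on p-value resolve toward the larger |t|, then the
    lexicographically smaller symbol.

    Returns an intercept-only model (R² = 0) when no candidate passes
    ``p_enter``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise FitError(f"need at least 4 observations, got {n}")
    if len(X) != n:
        raise FitError("X and y have different lengths")
    if np.ptp(y) == 0:
        raise FitError("response is constant; nothing to fit")

    candidates = _candidate_columns(X, add_log_transforms)
    included: list[tuple[str, Transform, np.ndarray]] = []

    tss = float(np.sum((y - y.mean()) ** 2))
    for _ in range(10 * (len(candidates) + 1)):  # hard stop against cycling
        changed = False
        # forward: best candidate among descriptors not yet in the model;
        # skip when the current model already fits to machine precision —
        # p-values on a zero residual are numerical noise
        if included and float(_ols(y, [c for _, _, c in included]).ssr) <= 1e-12 * tss:
            break
        in_symbols = {sym for sym, _, _ in included}
        best = None  # (p, -|t|, symbol, transform, column)
        for sym, tr, col in candidates:
            if sym in in_symbols:
                continue
            if len(included) + 2 >= n:  # keep residual df >= 1
                break
            try:
                res = _ols(y, [c for _, _, c in included] + [col])
            except Exception:
                continue
            pval = float(res.pvalues[-1])
            tval = float(res.tvalues[-1])
            if not np.isfinite(pval):
                continue
            key = (pval, -abs(tval), sym, tr)
            if best is None or key < best[0]:
                best = (key, sym, tr, col)
        if best is not None and best[0][0] <= p_enter:
            included.append((best[1], best[2], best[3]))
            changed = True
        # backward: drop included terms that lost significance
        while included:
            res = _ols(y, [c for _, _, c in included])
            pvals = res.pvalues[1:]  # skip intercept
            worst = int(np.argmax(pvals))
            if float(pvals[worst]) >= p_remove:
                del included[worst]
                changed = True
            else:
                break
        if not changed:
            break

    res = _ols(y, [c for _, _, c in included])
    if included:
        stats = ModelStats(n=n, R2=float(res.rsquared), p=float(res.f_pvalue))
        terms = [
            Term(sym, tr, float(coef))
            for (sym, tr, _), coef in zip(included, res.params[1:])
        ]
    else:
        stats = ModelStats(n=n, R2=0.0, p=1.0)
        terms = []
    ranges = {
        sym: (float(X[sym].min()), float(X[sym].max()))
        for sym in {s for s, _, _ in included}
    }
    return QsarModel(
        species=species,
        terms=terms,
        intercept=float(res.params[0]),
        stats=stats,
        endpoint=endpoint,
        species_class=species_class,
        training_ranges=ranges if included else {},
    )


def _design_from_terms(model: QsarModel, X: pd.DataFrame) -> np.ndarray:
    cols = []
    for t in model.terms:
        if t.symbol not in X.columns:
            raise ValidationError(f"validation data lack descriptor {t.symbol!r}")
        v = X[t.symbol].to_numpy(dtype=float)
        if t.transform == "log10":
            if np.any(v <= 0):
                raise DomainError(f"descriptor {t.symbol!r} must be positive under log10")
            v = np.log10(v)
        cols.append(v)
    return sm.add_constant(
        np.column_stack(cols) if cols else np.empty((len(X), 0)), has_constant="add"
    )


@dataclass(frozen=True)
class QsarValidation:
    r2: float
    q2: float
    passes_quality: bool  # r2 > 0.6 and q2 > 0.5


def quality_flag(r2: float, q2: float) -> bool:
    """Predictive-ability rule of thumb: r² > 0.6 and Q² > 0.5."""
    return r2 > 0.6 and q2 > 0.5


def validate_qsar(model: QsarModel, X: pd.DataFrame, y: Sequence[float]) -> QsarValidation:
    """Compute r² (fitted vs observed) and leave-one-out Q² for a term set.

    Coefficients are re-estimated on (X, y) with the model's term set held
    fixed.  Q² = 1 − PRESS/TSS, where PRESS sums squared LOO prediction
    errors; for OLS these equal e_i/(1 − h_ii), so the hat matrix gives the
    exact LOO result without literal refitting.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = len(model.terms)
    if n <= k + 1:
        raise FitError(f"LOO refit singular: n={n} too small for {k} terms")
    design = _design_from_terms(model, X)
    res = sm.OLS(y, design).fit()
    fitted = np.asarray(res.fittedvalues)

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise FitError("response is constant; r2/q2 undefined")
    if np.ptp(fitted) == 0:  # intercept-only model
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    h = np.asarray(res.get_influence().hat_matrix_diag)
    loo_resid = np.asarray(res.resid) / (1.0 - h)
    press = float(np.sum(loo_resid**2))
    q2 = 1.0 - press / tss
    return QsarValidation(r2=r2, q2=q2, passes_quality=quality_flag(r2, q2))


def predict_toxicity_matrix(
    models: Mapping[str, QsarModel], chemicals: Sequence[ChemicalRecord]
) -> list[PredictionResult]:
    """Predict toxicity for every (chemical, model-species) combination.

    Exposure durations follow the species-class preference (48 h for
    invertebrates, 96 h otherwise).  Predictions outside a fitted model's
    training min-max box are flagged, not suppressed.  Convert to
    :class:`~pfasrisk.core.ToxicityRecord` via ``PredictionResult.to_record``.
    """
    out: list[PredictionResult] = []
    for chem in chemicals:
        for model in models.values():
            log10_value = model.predict_log10(chem.descriptors)
            out.append(
                PredictionResult(
                    chem_id=chem.chem_id,
                    species=model.species,
                    log10_value=log10_value,
                    value=10.0 ** log10_value,
                    in_training_domain=model.in_training_domain(chem.descriptors),
                    endpoint=model.endpoint,
                    species_class=model.species_class,
                    duration_h=48.0
                    if model.species_class is SpeciesClass.invertebrate
                    else 96.0,
                )
            )
    return out


def prediction_records(
    predictions: Sequence[PredictionResult], include_out_of_domain: bool = True
) -> list[ToxicityRecord]:
    """Convert predictions to toxicity records (provenance = qsar)."""
    return [
        p.to_record()
        for p in predictions
        if include_out_of_domain or p.in_training_domain is not False
    ]
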