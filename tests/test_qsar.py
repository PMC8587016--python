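"""Stepwise MLR fitting, LOO validation, and published-equation evaluation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from itertools import combinations

from pfasrisk.core import SpeciesClass
from pfasrisk.errors import DomainError, FitError, ValidationError
from pfasrisk.qsar import (
    PUBLISHED_MODELS,
    evaluate_published_equation,
    fit_stepwise_mlr,
    predict_toxicity_matrix,
    prediction_records,
    quality_flag,
    validate_qsar,
)
from pfasrisk.simulate import SimulationConfig, generate_qsar_dataset


def _independent_candidates(seed, n=50, k=10):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(-2, 2, size=(n, k)), columns=[f"d{i}" for i in range(1, k + 1)])


def _ols_pvalue(y, cols):
    """Direct OLS oracle: p-value of the last column's coefficient."""
    design = sm.add_constant(np.column_stack(cols))
    return sm.OLS(y, design).fit().pvalues[-1]


class TestPublishedEquations:
    def test_intercept_only_cases(self):
        # zeroed slopes leave only the printed intercepts
        r5 = evaluate_published_equation("eq5_cvulgaris", {"Kow": 0.0, "ECCR": 0.0})
        assert r5.log10_value == pytest.approx(-4.29)
        assert r5.value == pytest.approx(10 ** -4.29)
        r7 = evaluate_published_equation("eq7_drerio", {"Kow": 0.0, "ECCR": 0.0, "ELUMO": 0.0})
        assert r7.value == pytest.approx(10 ** 2.94)

    def test_hand_summed_linear_combination(self):
        r = evaluate_published_equation("eq7_drerio", {"Kow": 1.0, "ECCR": 1.0, "ELUMO": 1.0})
        assert r.log10_value == pytest.approx(-1.03 - 1.04 + 0.318 + 2.94, abs=1e-12)
        assert r.log10_value == pytest.approx(1.188, abs=1e-12)

    @pytest.mark.parametrize("eq_id", sorted(PUBLISHED_MODELS))
    def test_matches_manual_term_by_term_evaluation(self, eq_id):
        """Arithmetic oracle: literal re-evaluation of the printed equation."""
        desc = {"Kow": 2.5, "TE": 3.0, "ECCR": 1.7, "ELUMO": 0.9}
        model = PUBLISHED_MODELS[eq_id]
        expected = model.intercept
        for t in model.terms:
            v = desc[t.symbol]
            expected += t.coefficient * (np.log10(v) if t.transform == "log10" else v)
        r = evaluate_published_equation(eq_id, desc)
        assert r.log10_value == pytest.approx(expected, abs=1e-12)
        assert r.value == pytest.approx(10.0 ** expected, rel=1e-12)

    def test_missing_descriptor_named(self):
        with pytest.raises(ValidationError, match="ECCR"):
            evaluate_published_equation("eq5_cvulgaris", {"Kow": 1.0})

    def test_nonpositive_under_log10_rejected(self):
        with pytest.raises(DomainError, match="ELUMO"):
            evaluate_published_equation(
                "eq4_psubcapitata", {"Kow": 1.0, "TE": 1.0, "ELUMO": -0.5, "ECCR": 1.0}
            )

    def test_affine_in_identity_terms(self):
        base = {"Kow": 1.0, "ECCR": 1.0, "ELUMO": 1.0}
        bumped = dict(base, Kow=3.0)
        a = evaluate_published_equation("eq7_drerio", base).log10_value
        b = evaluate_published_equation("eq7_drerio", bumped).log10_value
        assert b - a == pytest.approx(-1.03 * 2.0, abs=1e-12)


class TestStepwise:
    def test_exact_linear_dependence(self):
        X = _independent_candidates(seed=3)
        y = X["d2"].to_numpy()
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        assert [t.symbol for t in m.terms] == ["d2"]
        assert m.terms[0].coefficient == pytest.approx(1.0, abs=1e-10)
        assert m.intercept == pytest.approx(0.0, abs=1e-10)
        assert m.stats.R2 == pytest.approx(1.0, abs=1e-12)

    def test_recovers_sparse_signal_consistent_with_oracles(self):
        """True terms found; any extra term must itself pass the entry oracle,
        and exhaustive best-subset-of-2 agrees on the true support."""
        X = _independent_candidates(seed=11)
        rng = np.random.default_rng(12)
        y = 2.0 * X["d1"].to_numpy() - 3.0 * X["d4"].to_numpy() + rng.normal(0, 0.1, len(X))
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        selected = {t.symbol for t in m.terms}
        assert {"d1", "d4"} <= selected
        coefs = {t.symbol: t.coefficient for t in m.terms}
        assert coefs["d1"] == pytest.approx(2.0, rel=0.05)
        assert coefs["d4"] == pytest.approx(-3.0, rel=0.05)
        # best subset of size 2 by residual sum of squares
        best = min(
            combinations(X.columns, 2),
            key=lambda pair: float(
                sm.OLS(y, sm.add_constant(X[list(pair)].to_numpy())).fit().ssr
            ),
        )
        assert set(best) == {"d1", "d4"}
        # extras (if any) entered legitimately at p <= 0.05 given the true terms
        for sym in selected - {"d1", "d4"}:
            p = _ols_pvalue(y, [X["d1"], X["d4"], X[sym]])
            assert p <= 0.05

    def test_pure_noise_consistent_with_entry_oracle(self):
        """Intercept-only exactly when no candidate's partial-F p-value <= 0.05."""
        X = _independent_candidates(seed=21)
        rng = np.random.default_rng(22)
        y = rng.normal(size=len(X))
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        min_p = min(_ols_pvalue(y, [X[c]]) for c in X.columns)
        if min_p > 0.05:
            assert m.terms == [] and m.stats.R2 == 0.0
        else:
            assert len(m.terms) >= 1

    def test_column_order_invariance(self):
        X = _independent_candidates(seed=31)
        rng = np.random.default_rng(32)
        y = 1.5 * X["d3"].to_numpy() + rng.normal(0, 0.2, len(X))
        m1 = fit_stepwise_mlr(X, y, add_log_transforms=False)
        m2 = fit_stepwise_mlr(X[list(reversed(X.columns))], y, add_log_transforms=False)
        assert [(t.symbol, t.transform) for t in m1.terms] == [
            (t.symbol, t.transform) for t in m2.terms
        ]

    def test_too_few_observations_rejected(self):
        X = _independent_candidates(seed=1, n=3)
        with pytest.raises(FitError):
            fit_stepwise_mlr(X, [1.0, 2.0, 3.0])

    def test_constant_response_rejected(self):
        X = _independent_candidates(seed=1)
        with pytest.raises(FitError, match="constant"):
            fit_stepwise_mlr(X, np.ones(len(X)))


class TestValidation:
    def test_perfect_fit_gives_unit_scores(self):
        X = _independent_candidates(seed=41)
        y = 0.5 + 2.0 * X["d1"].to_numpy() - 1.0 * X["d2"].to_numpy()
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        v = validate_qsar(m, X, y)
        assert v.r2 == pytest.approx(1.0, abs=1e-9)
        assert v.q2 == pytest.approx(1.0, abs=1e-9)
        assert v.passes_quality

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_q2_equals_literal_row_deletion_loop(self, seed):
        X = _independent_candidates(seed=seed, n=30, k=5)
        rng = np.random.default_rng(seed + 100)
        y = X["d1"].to_numpy() - 2.0 * X["d3"].to_numpy() + rng.normal(0, 0.5, len(X))
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        if not m.terms:  # ensure a non-trivial model for the oracle
            pytest.skip("no terms selected at this seed")
        v = validate_qsar(m, X, y)
        # brute-force LOO: literally delete row i, refit the same term set, predict i
        cols = [t.symbol for t in m.terms]
        press = 0.0
        for i in range(len(X)):
            mask = np.arange(len(X)) != i
            fit_i = sm.OLS(
                y[mask], sm.add_constant(X.loc[mask, cols].to_numpy())
            ).fit()
            pred_i = fit_i.predict(np.concatenate([[1.0], X.loc[~mask, cols].to_numpy()[0]]))[0]
            press += (y[i] - pred_i) ** 2
        q2_loop = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert v.q2 == pytest.approx(q2_loop, rel=1e-10)
        assert v.q2 <= 1.0

    def test_published_stats_pass_quality_rule(self):
        for m in PUBLISHED_MODELS.values():
            assert quality_flag(m.stats.r2, m.stats.q2)
        assert quality_flag(0.742, 0.701)
        assert not quality_flag(0.55, 0.701)
        assert not quality_flag(0.742, 0.45)

    def test_loo_singular_when_n_too_small(self):
        X = _independent_candidates(seed=51, n=50, k=3)
        y = X["d1"].to_numpy() + 0.1
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        with pytest.raises(FitError, match="singular"):
            validate_qsar(m, X.iloc[: len(m.terms) + 1], y[: len(m.terms) + 1])


def _toy_chemicals(n):
    """Small positive descriptor vectors every published equation can evaluate."""
    from pfasrisk.core import ChemicalRecord

    return [
        ChemicalRecord(
            chem_id=f"C{i}",
            descriptors={"Kow": 1.0 + 0.1 * i, "TE": 2.0 + 0.05 * i,
                         "ELUMO": 0.8 + 0.02 * i, "ECCR": 1.1 + 0.1 * i},
        )
        for i in range(n)
    ]


class TestPredictionMatrix:
    def test_cardinality_six_chemicals_four_models(self):
        preds = predict_toxicity_matrix(PUBLISHED_MODELS, _toy_chemicals(6))
        assert len(preds) == 24
        assert len({(p.chem_id, p.species) for p in preds}) == 24

    def test_durations_follow_species_class(self):
        preds = predict_toxicity_matrix(PUBLISHED_MODELS, _toy_chemicals(1))
        by_species = {p.species: p for p in preds}
        assert by_species["Daphnia magna"].duration_h == 48.0
        assert by_species["Danio rerio"].duration_h == 96.0

    def test_out_of_domain_flagged_but_computed(self):
        X = _independent_candidates(seed=61)
        y = 2.0 * X["d1"].to_numpy()
        m = fit_stepwise_mlr(X, y, add_log_transforms=False)
        lo, hi = m.training_ranges["d1"]
        inside = (lo + hi) / 2
        assert m.in_training_domain({"d1": inside}) is True
        assert m.in_training_domain({"d1": hi + 1.0}) is False

    def test_prediction_records_have_qsar_provenance(self):
        recs = prediction_records(predict_toxicity_matrix(PUBLISHED_MODELS, _toy_chemicals(1)))
        assert len(recs) == 4
        assert all(r.provenance.value == "qsar" for r in recs)
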