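"""Pattern submodels, CCS, complete-case, hybrid, MIMI, relaxed lasso."""

import numpy as np
import pytest

from patternsub import (
    DataTable,
    BaseLearner,
    PatternModelSet,
    build_mimi_design,
    compute_indicator_matrix,
    fit_ccs,
    fit_complete_case,
    fit_engine,
    fit_hybrid,
    fit_mimi,
    fit_ps,
    predict_record,
)
from patternsub.models import fit_relaxed_lasso_submodel

NA = np.nan


def _ols_oracle(Xc, y):
    Z = np.column_stack([np.ones(len(y)), Xc]) if Xc.size else np.ones((len(y), 1))
    return np.linalg.solve(Z.T @ Z, Z.T @ y)


def test_ps_without_missingness_is_full_table_ols():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(25, 2))
    y = 1 + X @ [2.0, -1.0] + rng.normal(size=25)
    ps = fit_ps(DataTable(y=y, X=X))
    assert list(ps.models) == [(0, 0)]
    assert np.allclose(ps.models[(0, 0)].coef, _ols_oracle(X, y), atol=1e-10)


def test_ps_per_pattern_coefficients_match_ols_oracle(two_pattern_table):
    tab, _ = two_pattern_table
    ps = fit_ps(tab)
    # complete pattern: OLS of y on (x1, x2) over its own four rows
    assert np.allclose(
        ps.models[(0, 0)].coef, _ols_oracle(tab.X[:4], tab.y[:4]), atol=1e-10
    )
    # x1-missing pattern: OLS of y on x2 over its four rows only
    assert np.allclose(
        ps.models[(1, 0)].coef, _ols_oracle(tab.X[4:, 1:], tab.y[4:]), atol=1e-10
    )
    assert ps.models[(1, 0)].columns == (1,)
    assert ps.models[(1, 0)].n_fit == 4
    assert ps.models[(1, 0)].resid_var is not None


def test_ps_all_missing_pattern_is_that_patterns_mean(three_pattern_table):
    tab, _ = three_pattern_table
    ps = fit_ps(tab)
    model = ps.models[(1, 1)]
    assert model.columns == ()
    assert model.coef[0] == pytest.approx(tab.y[20:].mean())


def test_ps_sparse_pattern_raises():
    X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [NA, 1.0]])
    tab = DataTable(y=np.arange(4.0), X=X)
    with pytest.raises(ValueError, match="fit_hybrid"):
        fit_ps(tab)


def test_ccs_reuses_all_rows_observing_the_columns(three_pattern_table):
    tab, _ = three_pattern_table
    ccs = fit_ccs(tab)
    # x1-missing pattern: regress y on x2 using ALL rows that observe x2 (rows 0..19)
    assert np.allclose(
        ccs.models[(1, 0)].coef, _ols_oracle(tab.X[:20, 1:], tab.y[:20]), atol=1e-10
    )
    assert ccs.models[(1, 0)].n_fit == 20
    # all-missing pattern: grand mean over every record
    assert ccs.models[(1, 1)].coef[0] == pytest.approx(tab.y.mean())


def test_ps_and_ccs_coincide_without_missingness():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(15, 2))
    y = X @ [1.0, 1.0] + rng.normal(size=15)
    tab = DataTable(y=y, X=X)
    a, b = fit_ps(tab), fit_ccs(tab)
    assert np.allclose(a.models[(0, 0)].coef, b.models[(0, 0)].coef)


def test_complete_case_fit_and_forecast_contract(two_pattern_table):
    tab, _ = two_pattern_table
    cc = fit_complete_case(tab)
    assert np.allclose(
        cc.models[(0, 0)].coef, _ols_oracle(tab.X[:4], tab.y[:4]), atol=1e-10
    )
    with pytest.raises(ValueError, match="imputation engine"):
        cc.predict(np.array([[NA, 2.0]]))
    eng = fit_engine(tab, method="unconditional_mean")
    pred = cc.predict(np.array([[NA, 2.0]]), engine=eng)
    c = cc.models[(0, 0)].coef
    assert pred[0] == pytest.approx(c[0] + c[1] * eng.column_means[0] + c[2] * 2.0)


def test_complete_case_needs_a_complete_row():
    X = np.array([[NA, 1.0], [2.0, NA]])
    with pytest.raises(ValueError, match="complete"):
        fit_complete_case(DataTable(y=np.zeros(2), X=X))


def test_hybrid_threshold_extremes_and_sources(three_pattern_table):
    tab, _ = three_pattern_table
    ps, ccs = fit_ps(tab), fit_ccs(tab)
    zero_thr = fit_hybrid(tab, threshold=0)
    for key in ps.models:
        assert np.allclose(zero_thr.models[key].coef, ps.models[key].coef)
        assert zero_thr.models[key].fit_source == "PS"
    huge_thr = fit_hybrid(tab, threshold=np.inf)
    for key in ccs.models:
        assert np.allclose(huge_thr.models[key].coef, ccs.models[key].coef)
        assert huge_thr.models[key].fit_source == "CCS"
    # default threshold is 2p = 4: every pattern here holds 10 rows -> PS
    default = fit_hybrid(tab)
    assert all(m.fit_source == "PS" for m in default.models.values())


def test_hybrid_sparse_pattern_gets_ccs():
    rng = np.random.default_rng(3)
    X = rng.normal(3, 1, (30, 2))
    y = X @ [1.0, 2.0] + rng.normal(size=30)
    Xobs = X.copy()
    Xobs[:3, 0] = NA  # sparse pattern: 3 records <= threshold 4
    hyb = fit_hybrid(DataTable(y=y, X=Xobs))
    assert hyb.models[(1, 0)].fit_source == "CCS"
    assert hyb.models[(0, 0)].fit_source == "PS"


def test_mimi_design_term_counts():
    rng = np.random.default_rng(4)
    for p, scope, expected in [(2, "full", 9), (3, "own", 10), (3, "full", 16)]:
        X = rng.normal(size=(40, p))
        M = (rng.random((40, p)) < 0.5).astype(int)
        Z, design = build_mimi_design(X, M, scope=scope)
        # enumeration oracle: 1 + p mains + p indicators + interactions
        n_inter = p if scope == "own" else p * p
        assert expected == 1 + p + p + n_inter
        assert Z.shape[1] == expected
        assert not design.dropped_names


def test_mimi_design_reduces_without_missingness():
    X = np.random.default_rng(5).normal(size=(10, 2))
    Z, design = build_mimi_design(X, np.zeros((10, 2), dtype=int), scope="full")
    assert Z.shape[1] == 3  # intercept + x1 + x2
    assert set(design.dropped_names) == {"m1", "m2", "x1:m1", "x2:m2", "x1:m2", "x2:m1"}


def test_mimi_without_missingness_equals_plain_ols():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 2))
    y = 1 + X @ [3.0, 1.0] + rng.normal(size=30)
    tab = DataTable(y=y, X=X)
    eng = fit_engine(tab, method="conditional_mean_freq")
    mm = fit_mimi(tab, engine=eng)
    assert np.allclose(mm.mimi.fits[0].coef, _ols_oracle(X, y), atol=1e-10)


def test_predict_dispatches_on_pattern(two_pattern_table):
    tab, _ = two_pattern_table
    ps = fit_ps(tab)
    g = ps.models[(1, 0)].coef
    assert predict_record(ps, [NA, 2.5]) == pytest.approx(g[0] + g[1] * 2.5)
    f = ps.models[(0, 0)].coef
    assert predict_record(ps, [1.0, 2.0]) == pytest.approx(f[0] + f[1] + 2 * f[2])


def test_unseen_pattern_fallback_matches_fresh_ccs(two_pattern_table):
    tab, _ = two_pattern_table
    ps = fit_ps(tab)
    # pattern (0,1) never occurs in training; fallback fits a CCS on demand
    pred = predict_record(ps, [2.0, NA])
    oracle = _ols_oracle(tab.X[:4, :1], tab.y[:4])  # rows observing x1, y ~ x1
    assert pred == pytest.approx(oracle[0] + oracle[1] * 2.0)
    assert ps.models[(0, 1)].fit_source == "CCS(fallback)"
    strict = fit_ps(tab)
    strict.fallback = "error"
    with pytest.raises(ValueError, match="not seen"):
        predict_record(strict, [2.0, NA])


def test_relaxed_lasso_penalty_extremes():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 3))
    y = 2 + X @ [1.0, -2.0, 0.5] + 0.1 * rng.normal(size=60)
    plain = _ols_oracle(X, y)
    near_zero = fit_relaxed_lasso_submodel(
        X, y, BaseLearner(variant="relaxed_lasso", lasso_alpha=1e-10)
    )
    assert np.allclose(near_zero.coef, plain, atol=1e-4)
    huge = fit_relaxed_lasso_submodel(
        X, y, BaseLearner(variant="relaxed_lasso", lasso_alpha=1e6)
    )
    assert np.allclose(huge.coef[1:], 0.0)
    assert huge.coef[0] == pytest.approx(y.mean())


def test_relaxed_lasso_selects_the_active_column():
    """One real signal among five noise columns is recovered almost always."""
    hits = 0
    reps = 100
    for s in range(reps):
        rng = np.random.default_rng(s)
        X = rng.normal(size=(200, 6))
        y = 3.0 * X[:, 2] + rng.normal(size=200)
        fit = fit_relaxed_lasso_submodel(
            X, y, BaseLearner(variant="relaxed_lasso"), seed=s
        )
        if abs(fit.coef[3]) > 1e-8:  # column 2 -> coef index 3
            hits += 1
    assert hits >= 95


def test_logistic_family_produces_probabilities(three_pattern_table):
    tab, _ = three_pattern_table
    y01 = (tab.y > np.median(tab.y)).astype(float)
    binary = DataTable(y=y01, X=tab.X)
    ps = fit_ps(binary, learner=BaseLearner(family="logistic"))
    preds = ps.predict(tab.X)
    assert np.all((preds >= 0) & (preds <= 1))
    assert ps.learner.family == "logistic"
    for m in ps.models.values():  # one class per model set: family never mixes
        assert m.fit_source == "PS"


def test_model_set_json_roundtrip(two_pattern_table):
    tab, _ = two_pattern_table
    ps = fit_ps(tab)
    restored = PatternModelSet.from_json(ps.to_json())
    X_new = np.array([[2.0, 3.0], [NA, 1.5]])
    assert np.allclose(ps.predict(X_new), restored.predict(X_new))
    # MIMI round-trips with its engine embedded
    eng = fit_engine(tab, method="conditional_mean_freq")
    mm = fit_mimi(tab, engine=eng)
    mm2 = PatternModelSet.from_json(mm.to_json())
    assert np.allclose(mm.predict(X_new, engine=eng), mm2.predict(X_new))


def test_aliased_columns_dropped_and_recorded():
    """A duplicated predictor is aliased, not fatal; its coefficient is 0."""
    rng = np.random.default_rng(8)
    x = rng.normal(size=20)
    X = np.column_stack([x, x])
    y = 1 + 2 * x + rng.normal(size=20)
    ps = fit_ps(DataTable(y=y, X=X))
    model = ps.models[(0, 0)]
    assert len(model.dropped) == 1
    assert model.coef[1 + model.dropped[0]] == 0.0
    pred = ps.predict(X)
    assert np.allclose(pred, model.coef[0] + X @ model.coef[1:])
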