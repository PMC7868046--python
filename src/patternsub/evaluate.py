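"""Pattern-decomposed losses, proper scoring rules, cross-validation,
and the end-to-end simulation study driver.

The central object is the loss decomposition: overall expected
prediction error is the pattern-probability-weighted sum of
pattern-specific expected losses, so the empirical total equals

    sum_m  (n_m / n) * mean squared error within pattern m

which is identically the pooled mean squared error.  Only
pattern-restricted metrics are produced here; cross-pattern ranking
metrics such as AUC do not decompose this way and are deliberately
absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .impute import fit_engine, impute_matrix
from .models import BaseLearner, PatternModelSet
from .patterns import (
    DataTable,
    PatternKey,
    PatternTable,
    compute_indicator_matrix,
    enumerate_patterns,
    key_to_string,
)
from .simulate import MechanismSpec, OutcomeSpec, PredictorSpec, simulate_dataset

logger = logging.getLogger("patternsub")

LOG_EPS = 1e-15

#: study strategy name -> imputation-engine method needed at deployment
STRATEGY_ENGINES = {
    "ps": None,
    "ccs": None,
    "hybrid": None,
    "mimi": "pmm_mice",
    "mi_pmm": "pmm_mice",
    "cc_zero": "zero",
    "cc_mean": "unconditional_mean",
    "cc_cond_mean": "conditional_mean_freq",
    "cc_cond_mean_bayes": "conditional_mean_bayes",
}

__all__ = [
    "LossDecomposition",
    "CvReport",
    "Scenario",
    "STRATEGY_ENGINES",
    "squared_error_decomposition",
    "binary_scores",
    "cross_validate",
    "run_simulation_study",
    "summarize_study",
    "plot_pattern_losses",
]


@dataclass
class LossDecomposition:
    """Per-pattern mean losses, empirical pattern weights, weighted total."""

    per_pattern: dict[PatternKey, tuple[int, float]]  # key -> (n_m, mean loss)
    weights: dict[PatternKey, float]
    total: float

    def loss(self, key: PatternKey) -> float:
        return self.per_pattern[tuple(key)][1]


def _as_pattern_table(patterns) -> PatternTable:
    if isinstance(patterns, PatternTable):
        return patterns
    return enumerate_patterns(np.asarray(patterns))


def _decompose(values: np.ndarray, table: PatternTable) -> LossDecomposition:
    per, weights = {}, {}
    total = 0.0
    for info in table:
        mean_loss = float(values[info.rows].mean())
        w = info.count / table.n
        per[info.key] = (info.count, mean_loss)
        weights[info.key] = w
        total += w * mean_loss
    return LossDecomposition(per_pattern=per, weights=weights, total=total)


def squared_error_decomposition(
    y: np.ndarray, yhat: np.ndarray, patterns
) -> LossDecomposition:
    """Per-pattern mean squared error and its pattern-weighted total.

    The total equals the pooled MSE exactly (weights are the empirical
    pattern proportions).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    table = _as_pattern_table(patterns)
    if table.n != y.size:
        raise ValueError("pattern table size != number of observations")
    return _decompose((y - yhat) ** 2, table)


def binary_scores(
    y01: np.ndarray, prob: np.ndarray, patterns
) -> dict[str, LossDecomposition]:
    """Pattern-decomposed Brier score and logarithmic score.

    The log score is reported as the *negative* mean Bernoulli
    log-likelihood, so smaller is better for both scores.  Probabilities
    are clipped to [1e-15, 1 - 1e-15] inside the log, keeping a
    confident wrong prediction finite but enormous.
    """
    y01 = np.asarray(y01, dtype=float).ravel()
    prob = np.asarray(prob, dtype=float).ravel()
    if y01.shape != prob.shape:
        raise ValueError("y01 and prob must have equal length")
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.isin(y01, (0.0, 1.0)).all():
        raise ValueError("y01 must be binary 0/1")
    table = _as_pattern_table(patterns)
    brier = (y01 - prob) ** 2
    pc = np.clip(prob, LOG_EPS, 1.0 - LOG_EPS)
    logloss = -(y01 * np.log(pc) + (1.0 - y01) * np.log(1.0 - pc))
    return {"brier": _decompose(brier, table), "log_score": _decompose(logloss, table)}


# ---------------- strategy fitting shared by CV and the study ----------------


def _fit_strategy(
    name: str,
    train: DataTable,
    M: np.ndarray,
    learner: BaseLearner,
    *,
    threshold: float | None,
    m: int,
    cycles: int,
    k_donors: int,
    engine_seed: int,
    scope: str | None = None,
    mi_include_response: bool = False,
) -> tuple[PatternModelSet, object]:
    """Fit one named strategy; returns (model set, deployment engine or None)."""
    if name not in STRATEGY_ENGINES:
        raise ValueError(f"unknown strategy {name!r}; choose from {sorted(STRATEGY_ENGINES)}")
    method = STRATEGY_ENGINES[name]
    engine = None
    if method is not None:
        engine = fit_engine(
            train, M, method, seed=engine_seed, m=m, k_donors=k_donors,
            include_response=mi_include_response if method == "pmm_mice" else False,
        )
    if name == "ps":
        return _models.fit_ps(train, M, learner), None
    if name == "ccs":
        return _models.fit_ccs(train, M, learner), None
    if name == "hybrid":
        return _models.fit_hybrid(train, M, learner, threshold=threshold), None
    if name == "mimi":
        return _models.fit_mimi(train, M, engine, learner, scope=scope, cycles=cycles), engine
    if name == "mi_pmm":
        return _models.fit_mimi(train, M, engine, learner, scope="none", cycles=cycles), engine
    # complete-case model + deployment imputation
    return _models.fit_complete_case(train, M, learner), engine


@dataclass
class CvReport:
    """k-fold cross-validation result, pattern-stratified."""

    strategy: str
    k: int
    seed: int
    fold_assignment: np.ndarray
    per_fold: list
    pooled: object  # LossDecomposition, or dict of them for binary scores


def _stratified_folds(table: PatternTable, k: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(table.n, dtype=int)
    start = 0
    for info in table:
        if info.count < k:
            logger.info(
                "pattern %s has %d records (< k=%d): fold balance is approximate",
                info.key, info.count, k,
            )
        perm = rng.permutation(info.rows)
        fold[perm] = (start + np.arange(info.count)) % k
        start += info.count
    return fold


def cross_validate(
    data: DataTable,
    *,
    strategy: str = "ps",
    learner: BaseLearner | None = None,
    k: int = 10,
    seed: int = 0,
    threshold: float | None = None,
    m: int = 10,
    cycles: int = 10,
    k_donors: int = 5,
    scope: str | None = None,
    binary: bool = False,
) -> CvReport:
    """Pattern-stratified k-fold cross-validation of one strategy.

    Each fold sees approximately each pattern's proportion.  Any
    submodel tuning (the relaxed lasso's penalty) happens inside the
    training folds only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if learner is None:
        learner = BaseLearner(family="logistic" if binary else "linear")
    M = compute_indicator_matrix(data)
    table = enumerate_patterns(M)
    rng = np.random.default_rng(seed)
    fold = _stratified_folds(table, k, rng)

    yhat = np.empty(data.n)
    per_fold = []
    for f in range(k):
        tr = fold != f
        te = ~tr
        train = DataTable(y=data.y[tr], X=data.X[tr], columns=data.columns)
        Mtr = M[tr]
        fitted, engine = _fit_strategy(
            strategy, train, Mtr, learner, threshold=threshold, m=m, cycles=cycles,
            k_donors=k_donors, engine_seed=(seed * 1009 + f) & 0x7FFFFFFF, scope=scope,
        )
        pred = fitted.predict(data.X[te], engine=engine)
        yhat[te] = pred
        sub_patterns = enumerate_patterns(M[te])
        if binary:
            per_fold.append(binary_scores(data.y[te], pred, sub_patterns))
        else:
            per_fold.append(squared_error_decomposition(data.y[te], pred, sub_patterns))
    pooled = (
        binary_scores(data.y, yhat, table)
        if binary
        else squared_error_decomposition(data.y, yhat, table)
    )
    return CvReport(
        strategy=strategy, k=k, seed=seed, fold_assignment=fold,
        per_fold=per_fold, pooled=pooled,
    )


# ---------------- the simulation study ----------------


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: a mechanism paired with an outcome model."""

    name: str
    mechanism: MechanismSpec
    outcome: OutcomeSpec


def run_simulation_study(
    scenarios: Sequence[Scenario],
    predictor_spec: PredictorSpec,
    strategies: Sequence[str],
    reps: int = 1000,
    seed: int = 0,
    *,
    n_out: int | None = None,
    learner: BaseLearner | None = None,
    m: int = 10,
    cycles: int = 10,
    k_donors: int = 5,
    threshold: float | None = None,
) -> pd.DataFrame:
    """In-sample fit, frozen-engine out-of-sample forecasting, repeated.

    Each repetition: simulate an in-sample population, freeze the
    imputation engines and fit every strategy on it, simulate an
    out-of-sample population under the *same* calibrated mechanism,
    impute and predict its records one by one with the frozen engines,
    and score with the pattern-decomposed squared-error loss.  Alongside
    each strategy's loss, the mean squared imputation error for the
    mechanism's missing column is recorded for engine-based strategies
    (separating imputation bias from prediction bias).

    Returns a long-format frame with per-pattern rows and an
    ``is_total`` row per (scenario, rep, strategy).  A failed repetition
    is logged and skipped, not fatal.
    """
    if learner is None:
        learner = BaseLearner()
    unknown = [s for s in strategies if s not in STRATEGY_ENGINES]
    if unknown:
        raise ValueError(
            f"unknown strategy {unknown[0]!r}; choose from {sorted(STRATEGY_ENGINES)}"
        )
    n_out = n_out or predictor_spec.n
    base = int(seed) & 0x7FFFFFFF
    rows = []
    for si, sc in enumerate(scenarios):
        for r in range(reps):
            try:
                rows.extend(
                    _run_one_rep(
                        sc, si, r, predictor_spec, strategies, learner, base,
                        n_out=n_out, m=m, cycles=cycles, k_donors=k_donors,
                        threshold=threshold,
                    )
                )
            except Exception:
                logger.exception("rep %d of scenario %s failed; skipping", r, sc.name)
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "mechanism", "formulation", "rep", "strategy",
            "pattern", "n", "loss", "weight", "is_total", "imputation_mse",
        ],
    )


def _run_one_rep(
    sc: Scenario, si: int, r: int, pspec: PredictorSpec, strategies, learner, base,
    *, n_out: int, m: int, cycles: int, k_donors: int, threshold,
):
    ss = np.random.SeedSequence([base, si, r])
    s_in, s_out, s_eng = ss.spawn(3)
    ds_in = simulate_dataset(pspec, sc.outcome, sc.mechanism, seed=s_in)
    # reuse the calibrated intercept: mechanism consistent in/out of sample
    ds_out = simulate_dataset(pspec.with_n(n_out), sc.outcome, ds_in.mechanism, seed=s_out)
    engine_seed = int(s_eng.generate_state(1)[0]) & 0x7FFFFFFF
    Min, Mout = ds_in.M, ds_out.M
    out_patterns = enumerate_patterns(Mout)
    mcol = sc.mechanism.missing_col
    miss_rows = Mout[:, mcol].astype(bool)

    rows = []
    imp_err_cache: dict[str, float] = {}
    for name in strategies:
        fitted, engine = _fit_strategy(
            name, ds_in.table, Min, learner, threshold=threshold, m=m,
            cycles=cycles, k_donors=k_donors, engine_seed=engine_seed,
        )
        pred = fitted.predict(ds_out.table.X, engine=engine)
        decomp = squared_error_decomposition(ds_out.table.y, pred, out_patterns)
        imp_err = float("nan")
        method = STRATEGY_ENGINES[name]
        if method is not None and miss_rows.any():
            if method not in imp_err_cache:
                completed = impute_matrix(engine, ds_out.table.X)
                errs = [
                    np.mean((Xs[miss_rows, mcol] - ds_out.truth[miss_rows, mcol]) ** 2)
                    for Xs in completed.sets
                ]
                imp_err_cache[method] = float(np.mean(errs))
            imp_err = imp_err_cache[method]
        common = (sc.name, sc.mechanism.kind, sc.mechanism.formulation, r, name)
        for key, (n_m, loss) in decomp.per_pattern.items():
            rows.append(
                common + (key_to_string(key), n_m, loss, decomp.weights[key], False, float("nan"))
            )
        rows.append(common + ("TOTAL", out_patterns.n, decomp.total, 1.0, True, imp_err))
    return rows


def summarize_study(df: pd.DataFrame) -> pd.DataFrame:
    """Mean total loss and its Monte-Carlo standard error per strategy."""
    tot = df[df["is_total"]]
    g = tot.groupby(["scenario", "strategy"], sort=False)["loss"]
    out = g.agg(reps="count", mean_total="mean", sd="std").reset_index()
    out["mc_se"] = out["sd"] / np.sqrt(out["reps"])
    imp = (
        df[df["is_total"]]
        .groupby(["scenario", "strategy"], sort=False)["imputation_mse"]
        .mean()
        .reset_index(name="mean_imputation_mse")
    )
    return out.merge(imp, on=["scenario", "strategy"])


def plot_pattern_losses(df: pd.DataFrame, path: str | None = None):
    """Per-pattern mean prediction error by strategy, one panel per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[~df["is_total"]]
    scenarios = sub["scenario"].unique()
    fig, axes = plt.subplots(
        1, max(len(scenarios), 1), figsize=(4 * max(len(scenarios), 1), 3.5),
        squeeze=False,
    )
    for ax, scn in zip(axes[0], scenarios):
        d = sub[sub["scenario"] == scn]
        means = d.groupby(["pattern", "strategy"])["loss"].mean().unstack()
        means.plot(kind="bar", ax=ax, legend=False)
        ax.set_title(str(scn))
        ax.set_ylabel("mean squared error")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
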