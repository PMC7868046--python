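"""Pattern-dispatched prediction models.

Strategies
----------
PS (pattern submodels)
    One submodel per observed missingness pattern, fit *only* on the
    records in that pattern, using only its observed columns.  The
    all-missing pattern gets an intercept-only model (that pattern's
    mean response).  Residual variance is stored per pattern.
CCS (complete-case submodels)
    Same per-pattern model forms, but each pattern's model is fit on
    *all* records that observe that pattern's columns (records from
    richer patterns are re-used with their extra columns ignored).
complete_case
    A single full-column model fit on the fully observed records only;
    forecasting for an incomplete record requires an imputation engine.
hybrid
    Per pattern: PS when the pattern has more than ``threshold`` records
    (default 2p), CCS otherwise.  Which source was used is recorded.
MIMI (multiple imputation with missingness indicators)
    The indicator-augmented mean model -- intercept, X main effects,
    missing-data indicator main effects and indicator-by-covariate
    interactions -- fit on each completed data set produced by an
    imputation engine; forecasts are averaged over sets.  With a single
    conditional-mean completion its predictions coincide with PS.

All strategies in one model set share one learner class (same family,
same variant); mixing classes across patterns is not possible by
construction, which is what makes per-pattern loss minimization imply
overall loss minimization within the class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.special import expit, logit

from . import _design
from .impute import CompletedData, ImputationEngine, impute_matrix, multiply_impute_insample
from .patterns import (
    DataTable,
    PatternKey,
    compute_indicator_matrix,
    enumerate_patterns,
    key_to_string,
    string_to_key,
)

logger = logging.getLogger("patternsub")

__all__ = [
    "BaseLearner",
    "PatternModel",
    "PatternModelSet",
    "MimiDesign",
    "MimiFit",
    "fit_ps",
    "fit_ccs",
    "fit_complete_case",
    "fit_hybrid",
    "build_mimi_design",
    "fit_mimi",
    "predict_record",
    "fit_relaxed_lasso_submodel",
]


@dataclass(frozen=True)
class BaseLearner:
    """The model class shared by every pattern in one model set."""

    family: str = "linear"        # "linear" | "logistic"
    variant: str = "plain"        # "plain" | "relaxed_lasso"
    cv_folds: int = 5             # lasso-stage CV folds
    lasso_alpha: float | None = None  # fixed lasso penalty; None = choose by CV
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if self.variant not in ("plain", "relaxed_lasso"):
            raise ValueError("variant must be 'plain' or 'relaxed_lasso'")


@dataclass
class LinearFitInfo:
    coef: np.ndarray              # full length, aliased entries 0
    se: np.ndarray | None         # same layout (linear fits only)
    resid_var: float | None
    dropped: tuple[int, ...]      # aliased column indices (into the design)
    n: int


def _ols_fit(Z: np.ndarray, y: np.ndarray) -> LinearFitInfo:
    """OLS with pivoted-QR detection of aliased columns (coef set to 0)."""
    n, k = Z.shape
    _, R, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
    dia = np.abs(np.diag(R))
    tol = dia[0] * 1e-8 if dia.size and dia[0] > 0 else 0.0
    rank = int(np.sum(dia > tol))
    rank = min(rank, n)
    kept = np.sort(piv[:rank])
    dropped = tuple(int(c) for c in np.sort(piv[rank:]))
    coef = np.zeros(k)
    se = np.full(k, np.nan)
    Zk = Z[:, kept]
    sol, _, _, _ = np.linalg.lstsq(Zk, y, rcond=None)
    coef[kept] = sol
    resid = y - Zk @ sol
    resid_var = float(resid @ resid) / (n - rank) if n > rank else float("nan")
    if n > rank:
        cov = resid_var * np.linalg.inv(Zk.T @ Zk)
        se[kept] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return LinearFitInfo(coef=coef, se=se, resid_var=resid_var, dropped=dropped, n=n)


def _logistic_fit(Xcols: np.ndarray, y: np.ndarray, max_iter: int) -> LinearFitInfo:
    from sklearn.linear_model import LogisticRegression

    n = Xcols.shape[0]
    classes = np.unique(y)
    if classes.size < 2 or Xcols.shape[1] == 0:
        # degenerate: intercept-only model at the empirical class rate
        p = float(np.clip(np.mean(y), 1e-10, 1 - 1e-10))
        coef = np.zeros(Xcols.shape[1] + 1)
        coef[0] = float(logit(p))
        return LinearFitInfo(coef=coef, se=None, resid_var=None, dropped=(), n=n)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter, tol=1e-8)
    clf.fit(Xcols, y)
    coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return LinearFitInfo(coef=coef, se=None, resid_var=None, dropped=(), n=n)


def fit_relaxed_lasso_submodel(
    Xcols: np.ndarray,
    y: np.ndarray,
    learner: BaseLearner,
    seed: int = 0,
) -> LinearFitInfo:
    """Cross-validated lasso selection, then an unpenalized refit.

    Covariates are standardized inside the lasso stage; the refit (and
    the returned coefficients) are on the original scale.  The penalty
    is chosen by cross-validation unless ``learner.lasso_alpha`` fixes
    it.  An empty selected support gives an intercept-only model.
    """
    n, k = Xcols.shape
    if k == 0 or n < 3:
        return _plain_fit(Xcols, y, learner)
    sd = Xcols.std(axis=0)
    usable = sd > 0
    if not usable.any():
        return _plain_fit(np.empty((n, 0)), y, learner)  # intercept only
    Xs = (Xcols[:, usable] - Xcols[:, usable].mean(axis=0)) / sd[usable]
    folds = max(2, min(learner.cv_folds, n))
    from sklearn.model_selection import KFold

    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    alpha = learner.lasso_alpha
    if learner.family == "linear":
        from sklearn.linear_model import Lasso, LassoCV

        if alpha is not None:
            las = Lasso(alpha=max(alpha, 1e-12), max_iter=5000)
        else:
            las = LassoCV(cv=cv, random_state=seed, max_iter=5000)
        las.fit(Xs, y)
        sel = np.abs(las.coef_) > 1e-10
    else:
        from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

        if alpha is not None:
            las = LogisticRegression(
                penalty="l1", solver="liblinear", C=1.0 / max(alpha, 1e-12),
                max_iter=learner.max_iter,
            )
        else:
            las = LogisticRegressionCV(
                penalty="l1", solver="liblinear", cv=cv, Cs=10, random_state=seed,
                max_iter=learner.max_iter,
            )
        las.fit(Xs, y)
        sel = np.abs(las.coef_.ravel()) > 1e-10
    support = np.flatnonzero(usable)[sel]
    fit = _plain_fit(Xcols[:, support], y, learner)
    coef = np.zeros(k + 1)
    coef[0] = fit.coef[0]
    coef[1 + support] = fit.coef[1:]
    se = None
    if fit.se is not None:
        se = np.full(k + 1, np.nan)
        se[0] = fit.se[0]
        se[1 + support] = fit.se[1:]
    return LinearFitInfo(coef=coef, se=se, resid_var=fit.resid_var, dropped=(), n=n)


def _plain_fit(Xcols: np.ndarray, y: np.ndarray, learner: BaseLearner) -> LinearFitInfo:
    if learner.family == "linear":
        Z = np.column_stack([np.ones(Xcols.shape[0]), Xcols])
        return _ols_fit(Z, y)
    return _logistic_fit(Xcols, y, learner.max_iter)


def _fit_submodel(
    Xcols: np.ndarray, y: np.ndarray, learner: BaseLearner, seed: int = 0
) -> LinearFitInfo:
    if learner.variant == "relaxed_lasso":
        return fit_relaxed_lasso_submodel(Xcols, y, learner, seed=seed)
    return _plain_fit(Xcols, y, learner)


@dataclass
class PatternModel:
    """One pattern's fitted submodel on its observed columns."""

    key: PatternKey
    columns: tuple[int, ...]      # observed column indices, in table order
    coef: np.ndarray              # intercept first, then slopes on `columns`
    n_fit: int
    resid_var: float | None
    fit_source: str               # "PS" | "CCS" | "CC" | "CCS(fallback)"
    dropped: tuple[int, ...] = () # aliased columns (indices into `columns`)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        vals = X[:, list(self.columns)] if self.columns else np.empty((X.shape[0], 0))
        return self.coef[0] + vals @ self.coef[1:]


@dataclass
class MimiDesign:
    """Layout of the indicator-augmented design (intercept implicit)."""

    names: list[str]              # full term layout, before constant-dropping
    kept: np.ndarray              # boolean mask over `names`
    p: int
    scope: str

    @property
    def kept_names(self) -> list[str]:
        return ["const"] + [nm for nm, k in zip(self.names, self.kept) if k]

    @property
    def dropped_names(self) -> list[str]:
        return [nm for nm, k in zip(self.names, self.kept) if not k]


@dataclass
class MimiFit:
    """Per-imputation-set fits of the indicator-augmented model."""

    design: MimiDesign
    fits: list[LinearFitInfo]
    engine: ImputationEngine | None

    def pooled_coef(self) -> np.ndarray:
        return np.mean([f.coef for f in self.fits], axis=0)

    def rubin_se(self) -> np.ndarray:
        """Total-variance standard errors (within + between-imputation)."""
        m = len(self.fits)
        coefs = np.stack([f.coef for f in self.fits])
        within = np.mean(np.stack([f.se**2 for f in self.fits]), axis=0)
        between = coefs.var(axis=0, ddof=1) if m > 1 else np.zeros(coefs.shape[1])
        return np.sqrt(within + (1.0 + 1.0 / m) * between)

    def coef_names(self) -> list[str]:
        return self.design.kept_names


@dataclass
class PatternModelSet:
    """A fitted strategy: pattern-keyed submodels or a MIMI fit."""

    strategy: str                 # "PS" | "CCS" | "hybrid" | "complete_case" | "MIMI"
    learner: BaseLearner
    column_names: list[str]
    p: int
    models: dict[PatternKey, PatternModel] = field(default_factory=dict)
    mimi: MimiFit | None = None
    fallback: str = "ccs_on_demand"   # or "error"
    _train: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # (X, M, y)

    # ---------------- prediction ----------------

    def predict(
        self,
        X: np.ndarray,
        engine: ImputationEngine | None = None,
        y: np.ndarray | None = None,
    ) -> np.ndarray:
        """Predict each record of ``X`` (NaN cells mark its pattern).

        Records are independent: predicting them together or one at a
        time gives identical results.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"records have {X.shape[1]} cells, expected {self.p}")
        if self.strategy == "MIMI":
            return self._predict_mimi(X, engine, y)
        if self.strategy == "complete_case":
            return self._predict_complete_case(X, engine, y)
        out = np.empty(X.shape[0])
        table = enumerate_patterns(np.isnan(X).astype(np.int8))
        for info in table:
            model = self.models.get(info.key)
            if model is None:
                model = self._fallback_model(info.key)
            eta = model.linear_predictor(X[info.rows])
            out[info.rows] = expit(eta) if self.learner.family == "logistic" else eta
        return out

    def _fallback_model(self, key: PatternKey) -> PatternModel:
        if self.fallback != "ccs_on_demand":
            raise ValueError(f"pattern {key} was not seen in training")
        if self._train is None:
            raise ValueError(
                f"pattern {key} unseen and no training data retained for a "
                "CCS fallback fit"
            )
        logger.warning("unseen pattern %s: fitting a CCS submodel on demand", key)
        Xtr, Mtr, ytr = self._train
        model = _fit_pattern(
            Xtr, Mtr, ytr, key, rows=None, learner=self.learner, source="CCS(fallback)"
        )
        self.models[key] = model
        return model

    def _predict_complete_case(self, X, engine, y):
        model = self.models[(0,) * self.p]
        incomplete = np.isnan(X).any(axis=1)
        if incomplete.any() and engine is None:
            raise ValueError(
                "complete-case model cannot forecast incomplete records "
                "without an imputation engine"
            )
        out = np.empty(X.shape[0])
        ok = ~incomplete
        if ok.any():
            eta = model.linear_predictor(X[ok])
            out[ok] = expit(eta) if self.learner.family == "logistic" else eta
        if incomplete.any():
            completed = impute_matrix(engine, X[incomplete], None if y is None else y[incomplete])
            preds = []
            for Xs in completed.sets:
                eta = model.linear_predictor(Xs)
                preds.append(expit(eta) if self.learner.family == "logistic" else eta)
            out[incomplete] = np.mean(preds, axis=0)
        return out

    def _predict_mimi(self, X, engine, y):
        mimi = self.mimi
        engine = engine if engine is not None else mimi.engine
        if engine is None:
            raise ValueError("MIMI prediction requires an imputation engine")
        Mrec = np.isnan(X).astype(float)
        completed = impute_matrix(engine, X, y)
        preds = []
        for Xs in completed.sets:
            Z = _design_matrix(mimi.design, Xs, Mrec)
            for fit in mimi.fits:
                eta = Z @ fit.coef
                preds.append(expit(eta) if self.learner.family == "logistic" else eta)
        return np.mean(preds, axis=0)

    # ---------------- serialization ----------------

    def to_json(self) -> str:
        doc: dict = {
            "strategy": self.strategy,
            "family": self.learner.family,
            "variant": self.learner.variant,
            "columns": self.column_names,
            "p": self.p,
            "fallback": self.fallback,
            "models": {
                key_to_string(k): {
                    "columns": list(m.columns),
                    "coef": m.coef.tolist(),
                    "n_fit": m.n_fit,
                    "residual_variance": m.resid_var,
                    "fit_source": m.fit_source,
                    "dropped": list(m.dropped),
                }
                for k, m in self.models.items()
            },
        }
        if self.mimi is not None:
            doc["mimi"] = {
                "scope": self.mimi.design.scope,
                "names": self.mimi.design.names,
                "kept": self.mimi.design.kept.astype(int).tolist(),
                "coefs": [f.coef.tolist() for f in self.mimi.fits],
                "engine": None if self.mimi.engine is None else json.loads(self.mimi.engine.to_json()),
            }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "PatternModelSet":
        d = json.loads(doc)
        learner = BaseLearner(family=d["family"], variant=d["variant"])
        models = {
            string_to_key(ks): PatternModel(
                key=string_to_key(ks),
                columns=tuple(v["columns"]),
                coef=np.asarray(v["coef"], dtype=float),
                n_fit=int(v["n_fit"]),
                resid_var=v["residual_variance"],
                fit_source=v["fit_source"],
                dropped=tuple(v["dropped"]),
            )
            for ks, v in d["models"].items()
        }
        mimi = None
        if d.get("mimi") is not None:
            md = d["mimi"]
            design = MimiDesign(
                names=list(md["names"]),
                kept=np.asarray(md["kept"], dtype=bool),
                p=d["p"],
                scope=md["scope"],
            )
            fits = [
                LinearFitInfo(
                    coef=np.asarray(c, dtype=float), se=None, resid_var=None,
                    dropped=(), n=0,
                )
                for c in md["coefs"]
            ]
            engine = (
                None
                if md["engine"] is None
                else ImputationEngine.from_json(json.dumps(md["engine"]))
            )
            mimi = MimiFit(design=design, fits=fits, engine=engine)
        return cls(
            strategy=d["strategy"],
            learner=learner,
            column_names=list(d["columns"]),
            p=int(d["p"]),
            models=models,
            mimi=mimi,
            fallback=d.get("fallback", "ccs_on_demand"),
        )


# ---------------- fitting ----------------


def _pattern_seed(base: int, key: PatternKey) -> int:
    return (int(base) + int("0" + key_to_string(key), 2)) & 0x7FFFFFFF


def _fit_pattern(
    X: np.ndarray,
    M: np.ndarray,
    y: np.ndarray,
    key: PatternKey,
    rows: np.ndarray | None,
    learner: BaseLearner,
    source: str,
) -> PatternModel:
    """Fit one pattern's submodel.

    ``rows=None`` selects the CCS training set: every record observing
    the pattern's columns.  Otherwise ``rows`` is the PS training set
    (the pattern's own records).
    """
    cols = tuple(j for j, b in enumerate(key) if not b)
    if rows is None:
        if cols:
            rows = np.flatnonzero((M[:, list(cols)] == 0).all(axis=1))
        else:
            rows = np.arange(X.shape[0])
    need = len(cols) + 1
    if rows.size < need:
        raise ValueError(
            f"pattern {key} submodel ({source}) has {rows.size} records for "
            f"{need} coefficients; consider fit_hybrid"
        )
    Xc = X[np.ix_(rows, list(cols))] if cols else np.empty((rows.size, 0))
    fit = _fit_submodel(Xc, y[rows], learner, seed=_pattern_seed(learner.seed, key))
    dropped = tuple(cols[i - 1] for i in fit.dropped if i > 0)
    return PatternModel(
        key=key,
        columns=cols,
        coef=fit.coef,
        n_fit=int(rows.size),
        resid_var=fit.resid_var,
        fit_source=source,
        dropped=dropped,
    )


def _prep(data: DataTable, M: np.ndarray | None, learner: BaseLearner | None):
    if M is None:
        M = compute_indicator_matrix(data)
    if learner is None:
        learner = BaseLearner()
    return data.X, M, data.y, learner


def fit_ps(
    data: DataTable, M: np.ndarray | None = None, learner: BaseLearner | None = None
) -> PatternModelSet:
    """Fit a pattern submodel on each observed pattern's own records."""
    X, M, y, learner = _prep(data, M, learner)
    models = {}
    for info in enumerate_patterns(M):
        models[info.key] = _fit_pattern(X, M, y, info.key, info.rows, learner, "PS")
    return PatternModelSet(
        strategy="PS", learner=learner, column_names=list(data.columns), p=data.p,
        models=models, _train=(X, M, y),
    )


def fit_ccs(
    data: DataTable, M: np.ndarray | None = None, learner: BaseLearner | None = None
) -> PatternModelSet:
    """Fit complete-case submodels: each pattern's columns, all observing rows."""
    X, M, y, learner = _prep(data, M, learner)
    models = {}
    for info in enumerate_patterns(M):
        models[info.key] = _fit_pattern(X, M, y, info.key, None, learner, "CCS")
    return PatternModelSet(
        strategy="CCS", learner=learner, column_names=list(data.columns), p=data.p,
        models=models, _train=(X, M, y),
    )


def fit_complete_case(
    data: DataTable, M: np.ndarray | None = None, learner: BaseLearner | None = None
) -> PatternModelSet:
    """Single full-column model on the fully observed records."""
    X, M, y, learner = _prep(data, M, learner)
    complete = np.flatnonzero((M == 0).all(axis=1))
    if complete.size == 0:
        raise ValueError("no complete records: complete-case model cannot be fit")
    key = (0,) * data.p
    model = _fit_pattern(X, M, y, key, complete, learner, "CC")
    return PatternModelSet(
        strategy="complete_case", learner=learner, column_names=list(data.columns),
        p=data.p, models={key: model}, _train=(X, M, y),
    )


def fit_hybrid(
    data: DataTable,
    M: np.ndarray | None = None,
    learner: BaseLearner | None = None,
    threshold: float | None = None,
) -> PatternModelSet:
    """PS for well-populated patterns, CCS for sparse ones.

    A pattern gets its own PS fit when it holds more than ``threshold``
    records (default 2p, the rule of thumb; (p+1)*2 is another common
    convention) and a CCS fit otherwise.
    """
    X, M, y, learner = _prep(data, M, learner)
    if threshold is None:
        threshold = 2 * data.p
    models = {}
    for info in enumerate_patterns(M):
        use_ps = info.count > threshold
        rows = info.rows if use_ps else None
        source = "PS" if use_ps else "CCS"
        models[info.key] = _fit_pattern(X, M, y, info.key, rows, learner, source)
    return PatternModelSet(
        strategy="hybrid", learner=learner, column_names=list(data.columns), p=data.p,
        models=models, _train=(X, M, y),
    )


# ---------------- MIMI ----------------


def build_mimi_design(
    X_completed: np.ndarray,
    M: np.ndarray,
    scope: str | None = None,
    column_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, MimiDesign]:
    """Indicator-augmented design matrix (with intercept) and its layout.

    ``scope`` controls the interaction set: "full" includes every
    X_j x M_k pair (the two-covariate canonical form), "own" only
    X_j x M_j, "none" drops all indicator terms (a plain MI design).
    Default: "full" for p <= 2, "own" above (the full set grows
    quadratically).  Constant columns -- indicators that never vary and
    their interactions -- are dropped and recorded.
    """
    X_completed = np.asarray(X_completed, dtype=float)
    M = np.asarray(M, dtype=float)
    p = X_completed.shape[1]
    if np.isnan(X_completed).any():
        raise ValueError("X_completed must have no missing cells (impute first)")
    if scope is None:
        scope = "full" if p <= 2 else "own"
    names = _design.term_names(
        list(column_names) if column_names is not None else [f"x{j+1}" for j in range(p)],
        scope,
    )
    terms = _design.term_matrix(X_completed, M, scope)
    kept = np.ptp(terms, axis=0) > 0
    kept[:p] = True  # predictor main effects always stay
    design = MimiDesign(names=names, kept=kept, p=p, scope=scope)
    if design.dropped_names:
        logger.info("MIMI design: dropped constant terms %s", design.dropped_names)
    Z = np.column_stack([np.ones(X_completed.shape[0]), terms[:, kept]])
    return Z, design


def _design_matrix(design: MimiDesign, X: np.ndarray, M: np.ndarray) -> np.ndarray:
    terms = _design.term_matrix(X, M, design.scope)
    return np.column_stack([np.ones(X.shape[0]), terms[:, design.kept]])


def fit_mimi(
    data: DataTable,
    M: np.ndarray | None = None,
    engine: ImputationEngine | None = None,
    learner: BaseLearner | None = None,
    scope: str | None = None,
    completed: CompletedData | None = None,
    cycles: int = 10,
) -> PatternModelSet:
    """Fit the indicator-augmented model on engine-completed data.

    With a PMM engine the training table is completed by chained
    equations (``engine.m`` sets); deterministic engines give a single
    completed set.  One fit is stored per set; forecasts average the
    per-set predictions.  Aliased design columns (exact in the
    conditional-mean case, where the imputed column is a linear function
    of the others within a pattern) are dropped with coefficient 0 and
    recorded on each fit.
    """
    X, M, y, learner = _prep(data, M, learner)
    if completed is None:
        if engine is None:
            raise ValueError("fit_mimi needs an imputation engine or completed data")
        if engine.method == "pmm_mice":
            completed = multiply_impute_insample(
                data, M, m=engine.m, cycles=cycles, k_donors=engine.k_donors,
                seed=engine.seed, include_response=engine.include_response,
            )
        else:
            completed = impute_matrix(engine, X, y if engine.include_response else None)
    _, design = build_mimi_design(completed.sets[0], M, scope, data.columns)
    fits = []
    for Xs in completed.sets:
        Z = _design_matrix(design, Xs, M.astype(float))
        if learner.family == "linear":
            fits.append(_ols_fit(Z, y))
        else:
            fit = _logistic_fit(Z[:, 1:], y, learner.max_iter)
            fits.append(fit)
    return PatternModelSet(
        strategy="MIMI", learner=learner, column_names=list(data.columns), p=data.p,
        mimi=MimiFit(design=design, fits=fits, engine=engine), _train=(X, M, y),
    )


def predict_record(
    models: PatternModelSet,
    record: Sequence[float] | np.ndarray,
    engine: ImputationEngine | None = None,
    y: float | None = None,
) -> float:
    """Forecast one partially observed record from its matching submodel."""
    rec = np.asarray(record, dtype=float).ravel()
    yv = None if y is None else np.asarray([y], dtype=float)
    return float(models.predict(rec[None, :], engine=engine, y=yv)[0])
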