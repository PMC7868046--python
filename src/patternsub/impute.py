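"""Imputation strategies with a frozen in-sample engine.

The engine captures, at fit time, everything needed to impute a single
out-of-sample record: column means, per-pattern conditional regressions
(the record's observed columns predict each of its missing columns), and
predictive-mean-matching (PMM) donor pools.  The engine is immutable
after fitting, so imputing a thousand new records one by one -- in any
order -- gives each record exactly the result it would get alone.  For
PMM this is enforced by deriving each record's random stream from the
engine seed plus a hash of the record's own cells.

Methods
-------
zero                 missing cells become 0
unconditional_mean   missing cells become the training column mean
conditional_mean_freq
                     OLS regression of each missing column on the
                     record's observed columns (model keyed by pattern)
conditional_mean_bayes
                     as above, but the coefficient vector is a single
                     posterior draw (flat prior) taken at fit time
pmm_mice             the frozen conditional model supplies a predicted
                     mean; the imputed value is drawn uniformly from the
                     k observed donor values with nearest fitted means,
                     independently for each of m imputation sets

:func:`multiply_impute_insample` is the separate in-sample procedure:
multiple imputation by chained equations with PMM, used to build the
completed training sets for MI and MIMI fits.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .patterns import DataTable, assign_pattern, compute_indicator_matrix, enumerate_patterns

logger = logging.getLogger("patternsub")

METHODS = (
    "zero",
    "unconditional_mean",
    "conditional_mean_freq",
    "conditional_mean_bayes",
    "pmm_mice",
)

__all__ = [
    "METHODS",
    "CondModel",
    "ImputationEngine",
    "CompletedData",
    "fit_engine",
    "impute_record",
    "impute_matrix",
    "multiply_impute_insample",
]


@dataclass(frozen=True)
class CondModel:
    """One frozen conditional regression: target column on observed columns."""

    target: int
    predictors: tuple[int, ...]
    alpha: np.ndarray  # intercept first, then slopes on `predictors` (+ y last if used)
    n_fit: int
    donors: np.ndarray | None = None      # observed target values, sorted by fitted mean
    donor_fit: np.ndarray | None = None   # their fitted means, ascending


@dataclass
class CompletedData:
    """m completed copies of a predictor matrix plus imputation provenance."""

    sets: list[np.ndarray]
    M: np.ndarray  # 1 marks the cells that were imputed

    @property
    def m(self) -> int:
        return len(self.sets)

    def stacked(self) -> np.ndarray:
        return np.stack(self.sets)


@dataclass
class ImputationEngine:
    """Frozen in-sample imputation state (treat as immutable after fit)."""

    method: str
    columns: tuple[str, ...]
    column_means: np.ndarray
    cond_models: dict[tuple[int, tuple[int, ...]], CondModel] = field(default_factory=dict)
    m: int = 1
    k_donors: int = 5
    include_response: bool = False
    seed: int = 0

    @property
    def p(self) -> int:
        return len(self.columns)

    def to_json(self) -> str:
        models = {}
        for (j, obs), cm in self.cond_models.items():
            key = f"{j}|{','.join(map(str, obs))}"
            models[key] = {
                "alpha": cm.alpha.tolist(),
                "n_fit": cm.n_fit,
                "donors": None if cm.donors is None else cm.donors.tolist(),
                "donor_fit": None if cm.donor_fit is None else cm.donor_fit.tolist(),
            }
        return json.dumps(
            {
                "method": self.method,
                "columns": list(self.columns),
                "column_means": self.column_means.tolist(),
                "m": self.m,
                "k_donors": self.k_donors,
                "include_response": self.include_response,
                "seed": self.seed,
                "cond_models": models,
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "ImputationEngine":
        d = json.loads(doc)
        models: dict[tuple[int, tuple[int, ...]], CondModel] = {}
        for key, v in d["cond_models"].items():
            j_s, obs_s = key.split("|")
            obs = tuple(int(t) for t in obs_s.split(",")) if obs_s else ()
            models[(int(j_s), obs)] = CondModel(
                target=int(j_s),
                predictors=obs,
                alpha=np.asarray(v["alpha"], dtype=float),
                n_fit=int(v["n_fit"]),
                donors=None if v["donors"] is None else np.asarray(v["donors"], float),
                donor_fit=None
                if v["donor_fit"] is None
                else np.asarray(v["donor_fit"], float),
            )
        return cls(
            method=d["method"],
            columns=tuple(d["columns"]),
            column_means=np.asarray(d["column_means"], dtype=float),
            cond_models=models,
            m=int(d["m"]),
            k_donors=int(d["k_donors"]),
            include_response=bool(d["include_response"]),
            seed=int(d["seed"]),
        )


def _ols_alpha(design: np.ndarray, target: np.ndarray, colname: str) -> tuple[np.ndarray, float, np.ndarray]:
    """Least-squares fit; returns (alpha, resid_var, XtX_inv). Errors if singular."""
    ncol = design.shape[1]
    if design.shape[0] < ncol:
        raise ValueError(
            f"cannot fit conditional model for column {colname!r}: "
            f"{design.shape[0]} complete records for {ncol} coefficients"
        )
    alpha, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < ncol:
        raise ValueError(
            f"singular conditional model for column {colname!r} (rank {rank} < {ncol})"
        )
    resid = target - design @ alpha
    dof = max(design.shape[0] - ncol, 1)
    resid_var = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    return alpha, resid_var, xtx_inv


def fit_engine(
    train: DataTable,
    M: np.ndarray | None = None,
    method: str = "unconditional_mean",
    *,
    seed: int = 0,
    m: int | None = None,
    k_donors: int = 5,
    include_response: bool = False,
) -> ImputationEngine:
    """Freeze all state needed for later single-record imputation.

    Conditional models are fit, for every missingness pattern observed in
    training and every column missing in that pattern, on the rows where
    the target and the pattern's observed columns are all present.
    ``include_response`` adds Y as an extra regressor (only usable when Y
    is known at imputation time, i.e. in-sample).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if M is None:
        M = compute_indicator_matrix(train)
    X = train.X
    n, p = X.shape
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column -> NaN mean
        means = np.nanmean(np.where(M.astype(bool), np.nan, X), axis=0)
    if method != "zero" and np.isnan(means).any():
        bad = [train.columns[j] for j in np.flatnonzero(np.isnan(means))]
        raise ValueError(f"columns never observed in training: {bad}")
    if m is None:
        m = 10 if method == "pmm_mice" else 1

    engine = ImputationEngine(
        method=method,
        columns=tuple(train.columns),
        column_means=means,
        m=m,
        k_donors=k_donors,
        include_response=include_response,
        seed=seed,
    )
    if method in ("zero", "unconditional_mean"):
        return engine

    rng = np.random.default_rng(np.random.SeedSequence([_nonneg(seed), 0]))
    observed = ~M.astype(bool)
    for info in enumerate_patterns(M):
        miss = [j for j, b in enumerate(info.key) if b]
        if not miss:
            continue
        obs = tuple(j for j, b in enumerate(info.key) if not b)
        for j in miss:
            if (j, obs) in engine.cond_models:
                continue
            fit_rows = observed[:, j].copy()
            for c in obs:
                fit_rows &= observed[:, c]
            idx = np.flatnonzero(fit_rows)
            if idx.size == 0:
                logger.warning(
                    "no complete records to fit E[%s | pattern]; will fall back "
                    "to the unconditional mean",
                    train.columns[j],
                )
                continue
            design = np.column_stack(
                [np.ones(idx.size), X[np.ix_(idx, list(obs))]]
                + ([train.y[idx][:, None]] if include_response else [])
            )
            alpha, resid_var, xtx_inv = _ols_alpha(design, X[idx, j], train.columns[j])
            if method == "conditional_mean_bayes":
                # one posterior draw under a flat prior, frozen into the engine
                cov = resid_var * xtx_inv
                alpha = rng.multivariate_normal(alpha, cov)
            donors = donor_fit = None
            if method == "pmm_mice":
                fit_vals = design @ alpha
                order = np.argsort(fit_vals, kind="stable")
                donors = X[idx, j][order]
                donor_fit = fit_vals[order]
            engine.cond_models[(j, obs)] = CondModel(
                target=j,
                predictors=obs,
                alpha=alpha,
                n_fit=idx.size,
                donors=donors,
                donor_fit=donor_fit,
            )
    return engine


def _nonneg(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def _record_rng(engine: ImputationEngine, record: np.ndarray) -> np.random.Generator:
    """Per-record stream: depends only on the engine seed and the record itself."""
    miss = np.isnan(record)
    payload = np.where(miss, 0.0, record).astype(np.float64).tobytes() + miss.tobytes()
    h = zlib.crc32(payload) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([_nonneg(engine.seed), 1, h]))


def _knn_window(sorted_vals: np.ndarray, preds: np.ndarray, k: int) -> np.ndarray:
    """Indices (into ascending `sorted_vals`) of the k values nearest each pred."""
    n = sorted_vals.size
    k = min(k, n)
    w = min(2 * k, n)
    pos = np.searchsorted(sorted_vals, preds)
    lo = np.clip(pos - k, 0, n - w)
    idx = lo[:, None] + np.arange(w)[None, :]
    d = np.abs(sorted_vals[idx] - preds[:, None])
    sel = np.argpartition(d, k - 1, axis=1)[:, :k]
    return np.take_along_axis(idx, sel, axis=1)


def impute_record(
    engine: ImputationEngine, record: Sequence[float] | np.ndarray, y: float | None = None
) -> np.ndarray:
    """Impute one predictor row; returns an (m, p) array of completed copies.

    Observed cells are returned untouched in every copy.  m is 1 for the
    deterministic methods and ``engine.m`` for PMM.
    """
    record = np.asarray(record, dtype=float).ravel()
    if record.size != engine.p:
        raise ValueError(f"record has {record.size} cells, expected {engine.p}")
    key = assign_pattern(record)
    miss = [j for j, b in enumerate(key) if b]
    n_sets = engine.m if engine.method == "pmm_mice" else 1
    out = np.tile(record, (n_sets, 1))
    if not miss:
        return out
    if engine.include_response and y is None and engine.method not in (
        "zero",
        "unconditional_mean",
    ):
        raise ValueError("engine was fit with the response as a predictor; pass y")

    if engine.method == "zero":
        out[:, miss] = 0.0
        return out
    if engine.method == "unconditional_mean":
        out[:, miss] = engine.column_means[miss]
        return out

    obs = tuple(j for j, b in enumerate(key) if not b)
    rng = _record_rng(engine, record) if engine.method == "pmm_mice" else None
    for j in miss:
        cm = engine.cond_models.get((j, obs))
        if cm is None:
            logger.warning(
                "no conditional model for column %s in pattern %s; "
                "falling back to the unconditional mean",
                engine.columns[j],
                key,
            )
            out[:, j] = engine.column_means[j]
            continue
        x_obs = np.concatenate(
            [[1.0], record[list(obs)]] + ([[float(y)]] if engine.include_response else [])
        )
        pred = float(x_obs @ cm.alpha)
        if engine.method in ("conditional_mean_freq", "conditional_mean_bayes"):
            out[:, j] = pred
        else:  # pmm_mice
            cand = _knn_window(cm.donor_fit, np.array([pred]), engine.k_donors)[0]
            picks = rng.integers(0, cand.size, size=n_sets)
            out[:, j] = cm.donors[cand[picks]]
    return out


def impute_matrix(
    engine: ImputationEngine, X: np.ndarray, y: np.ndarray | None = None
) -> CompletedData:
    """Impute each row independently (one-by-one semantics, vector output)."""
    X = np.asarray(X, dtype=float)
    n_sets = engine.m if engine.method == "pmm_mice" else 1
    sets = [X.copy() for _ in range(n_sets)]
    for i in range(X.shape[0]):
        if not np.isnan(X[i]).any():
            continue
        filled = impute_record(engine, X[i], None if y is None else float(y[i]))
        for s in range(n_sets):
            sets[s][i] = filled[s]
    return CompletedData(sets=sets, M=np.isnan(X).astype(np.int8))


def multiply_impute_insample(
    train: DataTable,
    M: np.ndarray | None = None,
    *,
    m: int = 10,
    cycles: int = 10,
    k_donors: int = 5,
    seed: int = 0,
    include_response: bool = False,
) -> CompletedData:
    """MICE with predictive mean matching on the training table.

    Columns are visited in order of increasing missingness; each chained
    regression uses all other columns (and optionally Y) at their current
    completed values.  Every imputed value is an observed donor value, so
    imputations stay inside the empirical support.
    """
    if M is None:
        M = compute_indicator_matrix(train)
    X = train.X
    n, p = X.shape
    miss_counts = M.sum(axis=0)
    if np.any(miss_counts == n):
        bad = [train.columns[j] for j in np.flatnonzero(miss_counts == n)]
        raise ValueError(f"cannot impute columns with no observed values: {bad}")
    chain = [j for j in np.argsort(miss_counts, kind="stable") if miss_counts[j] > 0]
    obs_mask = ~M.astype(bool)

    sets: list[np.ndarray] = []
    for s in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([_nonneg(seed), 2, s]))
        work = X.copy()
        for j in chain:
            pool = X[obs_mask[:, j], j]
            work[~obs_mask[:, j], j] = rng.choice(pool, size=int(miss_counts[j]))
        for _ in range(cycles):
            for j in chain:
                others = [c for c in range(p) if c != j]
                cols = [np.ones(n), work[:, others].reshape(n, -1)]
                if include_response:
                    cols.append(train.y[:, None])
                design = np.column_stack(cols)
                rows_obs = obs_mask[:, j]
                alpha, _, _, _ = np.linalg.lstsq(design[rows_obs], X[rows_obs, j], rcond=None)
                fit_obs = design[rows_obs] @ alpha
                order = np.argsort(fit_obs, kind="stable")
                donors = X[rows_obs, j][order]
                donor_fit = fit_obs[order]
                preds = design[~rows_obs] @ alpha
                cand = _knn_window(donor_fit, preds, k_donors)
                picks = rng.integers(0, cand.shape[1], size=cand.shape[0])
                work[~rows_obs, j] = donors[cand[np.arange(cand.shape[0]), picks]]
        sets.append(work)
    return CompletedData(sets=sets, M=M.copy())
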