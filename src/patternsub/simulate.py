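"""Synthetic data under selection-model and pattern-mixture formulations.

The generator draws correlated Gaussian predictors, induces missingness
in one designated column under one of five mechanisms, and generates the
response either from a marginal linear model (selection formulation) or
from the indicator-dependent mean model (pattern-mixture formulation).

Mechanisms
----------
MCAR   missingness probability is a constant ``c``
MAR    logistic in the *observed* predictors (all columns except the one
       going missing)
MNAR   logistic in the predictor that goes missing itself
MARY   MAR drivers plus the response Y
MNARY  MNAR drivers plus the response Y

MARY and MNARY can only be simulated in the selection formulation: under
the pattern-mixture factorization Y is generated *after* M, so M cannot
depend on it.

The logistic intercept ``nu0`` is calibrated empirically by root-finding
so that the mean missingness probability over the realized driver values
equals ``target_prob``.  Calibration uses the in-sample drivers; reusing
the calibrated intercept for an out-of-sample population keeps the
mechanism consistent between the two, which is how the simulation study
uses it.

Randomness is split into three child streams (predictors, missingness,
noise) spawned from one seed, so changing the mechanism never perturbs
the predictor draw.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import _design
from .patterns import DataTable

MECHANISMS = ("MCAR", "MAR", "MNAR", "MARY", "MNARY")
FORMULATIONS = ("selection", "pattern_mixture")

__all__ = [
    "PredictorSpec",
    "OutcomeSpec",
    "MechanismSpec",
    "SimulatedDataset",
    "simulate_predictors",
    "linear_predictor",
    "calibrate_intercept",
    "induce_missingness",
    "mimi_mean",
    "generate_outcome",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PredictorSpec:
    """n draws from N(mu, sigma)."""

    mu: Sequence[float]
    sigma: Sequence[Sequence[float]]
    n: int

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if mu.ndim != 1 or sigma.shape != (mu.size, mu.size):
            raise ValueError("mu must be length-p and sigma p x p")
        if not np.allclose(sigma, sigma.T):
            raise ValueError("sigma must be symmetric")
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError("sigma must be positive definite") from exc
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def p(self) -> int:
        return len(self.mu)

    def with_n(self, n: int) -> "PredictorSpec":
        return dataclasses.replace(self, n=n)


@dataclass(frozen=True)
class OutcomeSpec:
    """Linear response model.

    ``beta`` has the intercept first.  Under the selection formulation
    the mean is ``beta0 + X @ beta[1:]`` and ``delta`` is ignored (a
    nonzero delta triggers a warning).  Under the pattern-mixture
    formulation the mean is the full indicator-augmented model evaluated
    at the *true* X and the simulated M; ``delta`` follows the term
    layout of :mod:`patternsub._design` (indicator mains, own
    interactions, cross interactions) and may be given short and is then
    zero-padded.
    """

    formulation: str
    beta: Sequence[float]
    delta: Sequence[float] = ()
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"formulation must be one of {FORMULATIONS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def p(self) -> int:
        return len(self.beta) - 1

    def padded_delta(self) -> np.ndarray:
        full = np.zeros(_design.n_delta_terms(self.p, "full"))
        d = np.asarray(self.delta, dtype=float).ravel()
        if d.size > full.size:
            raise ValueError(f"delta has {d.size} entries, at most {full.size} allowed")
        full[: d.size] = d
        return full


@dataclass
class MechanismSpec:
    """One missingness mechanism acting on a single predictor column.

    ``nu_x`` holds per-column coefficients on X (defaults to all ones);
    the mechanism selects which of them are active.  ``nu_y`` is the
    coefficient on Y for MARY/MNARY.  ``nu0`` is the calibrated
    intercept, filled in by :func:`calibrate_intercept` /
    :func:`simulate_dataset`.
    """

    kind: str
    formulation: str = "selection"
    target_prob: float = 0.5
    nu_x: Sequence[float] | None = None
    nu_y: float = 1.0
    missing_col: int = 0
    nu0: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MECHANISMS:
            raise ValueError(f"kind must be one of {MECHANISMS}")
        if self.formulation not in FORMULATIONS:
            raise ValueError(f"formulation must be one of {FORMULATIONS}")
        if not 0.0 < self.target_prob < 1.0:
            raise ValueError("target_prob must be in (0, 1)")
        if self.kind in ("MARY", "MNARY") and self.formulation != "selection":
            raise ValueError(
                f"{self.kind} depends on Y and can only be simulated under the "
                "selection formulation (Y is generated after M in the "
                "pattern-mixture formulation)"
            )

    def resolved_nu_x(self, p: int) -> np.ndarray:
        if self.nu_x is None:
            return np.ones(p)
        nu = np.asarray(self.nu_x, dtype=float).ravel()
        if nu.size != p:
            raise ValueError(f"nu_x must have length p={p}")
        return nu


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_predictors(spec: PredictorSpec, seed=0) -> np.ndarray:
    """Draw the complete (pre-deletion) n x p predictor matrix."""
    rng = _rng(seed)
    L = np.linalg.cholesky(np.asarray(spec.sigma, dtype=float))
    Z = rng.standard_normal((spec.n, spec.p))
    return np.asarray(spec.mu, dtype=float) + Z @ L.T


def linear_predictor(
    mech: MechanismSpec, X: np.ndarray, y: np.ndarray | None = None
) -> np.ndarray:
    """Driver part of the logistic linear predictor (without nu0)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if mech.kind == "MCAR":
        return np.zeros(n)
    nu = mech.resolved_nu_x(p)
    j = mech.missing_col
    if mech.kind in ("MAR", "MARY"):
        mask = np.ones(p, dtype=bool)
        mask[j] = False
        eta = X[:, mask] @ nu[mask]
    else:  # MNAR, MNARY
        eta = nu[j] * X[:, j]
    if mech.kind in ("MARY", "MNARY"):
        if y is None:
            raise ValueError(f"{mech.kind} requires the response vector")
        eta = eta + mech.nu_y * np.asarray(y, dtype=float)
    return eta


def calibrate_intercept(
    mech: MechanismSpec,
    X: np.ndarray,
    y: np.ndarray | None = None,
    tol: float = 1e-10,
) -> float:
    """Find nu0 with mean(expit(nu0 + eta)) = target_prob over realized drivers.

    The map nu0 -> mean probability is strictly increasing, so a
    bracketing root-finder always converges.  With no active drivers the
    closed form logit(target_prob) is returned.
    """
    if mech.kind == "MCAR":
        raise ValueError("MCAR uses target_prob directly; nothing to calibrate")
    eta = linear_predictor(mech, X, y)
    target = mech.target_prob
    if np.all(eta == 0.0):
        return float(logit(target))

    def f(nu0: float) -> float:
        return float(np.mean(expit(nu0 + eta))) - target

    span = float(np.max(np.abs(eta)))
    lo = logit(target) - span - 40.0
    hi = logit(target) + span + 40.0
    try:
        root = brentq(f, lo, hi, xtol=tol)
    except ValueError as exc:  # pragma: no cover - bracket is constructed to hold
        raise RuntimeError(
            f"intercept calibration failed for {mech.kind}: f({lo})={f(lo):.3g}, "
            f"f({hi})={f(hi):.3g}"
        ) from exc
    return float(root)


def induce_missingness(
    truth: np.ndarray,
    y: np.ndarray | None,
    mech: MechanismSpec,
    seed=0,
) -> np.ndarray:
    """Bernoulli-draw the indicator matrix for the mechanism's column.

    Only ``mech.missing_col`` is subject to missingness; every other
    column of the returned matrix is zero.  For non-MCAR mechanisms the
    calibrated ``mech.nu0`` must be present.
    """
    rng = _rng(seed)
    truth = np.asarray(truth, dtype=float)
    n, p = truth.shape
    if mech.kind == "MCAR":
        prob = np.full(n, mech.target_prob)
    else:
        if mech.nu0 is None:
            raise ValueError("nu0 not calibrated; call calibrate_intercept first")
        prob = expit(mech.nu0 + linear_predictor(mech, truth, y))
    M = np.zeros((n, p), dtype=np.int8)
    M[:, mech.missing_col] = (rng.random(n) < prob).astype(np.int8)
    return M


def mimi_mean(
    X: np.ndarray, M: np.ndarray, beta: Sequence[float], delta: Sequence[float]
) -> np.ndarray:
    """Indicator-augmented mean b0 + X b + [M, XM] d with the full term layout."""
    beta = np.asarray(beta, dtype=float).ravel()
    p = beta.size - 1
    terms = _design.term_matrix(np.asarray(X, float), np.asarray(M, float), "full")
    coef = np.concatenate([beta[1:], np.asarray(delta, dtype=float).ravel()])
    if coef.size != terms.shape[1]:
        raise ValueError("delta length inconsistent with p (use OutcomeSpec.padded_delta)")
    return beta[0] + terms @ coef


def generate_outcome(
    truth: np.ndarray,
    M: np.ndarray | None,
    spec: OutcomeSpec,
    seed=0,
) -> np.ndarray:
    """Draw Y = mean(formulation) + N(0, noise_sd^2) noise."""
    rng = _rng(seed)
    truth = np.asarray(truth, dtype=float)
    beta = np.asarray(spec.beta, dtype=float)
    if spec.formulation == "selection":
        if np.any(np.asarray(spec.delta, dtype=float) != 0):
            import warnings

            warnings.warn(
                "delta is ignored under the selection formulation", stacklevel=2
            )
        mean = beta[0] + truth @ beta[1:]
    else:
        if M is None:
            raise ValueError("pattern_mixture outcome requires the indicator matrix")
        mean = mimi_mean(truth, M, beta, spec.padded_delta())
    return mean + spec.noise_sd * rng.standard_normal(truth.shape[0])


@dataclass
class SimulatedDataset:
    """One simulated population: observed table, indicators, and the truth."""

    table: DataTable
    M: np.ndarray
    truth: np.ndarray
    predictor_spec: PredictorSpec
    outcome_spec: OutcomeSpec
    mechanism: MechanismSpec  # with nu0 filled in (non-MCAR)
    seed: object = None


def simulate_dataset(
    predictor_spec: PredictorSpec,
    outcome_spec: OutcomeSpec,
    mechanism: MechanismSpec,
    seed=0,
    columns: Sequence[str] | None = None,
) -> SimulatedDataset:
    """Compose the three generators under a single seed.

    Selection formulation: X, then Y, then M (M may depend on Y).
    Pattern mixture: X, then M, then Y (the mean depends on M).
    If ``mechanism.nu0`` is already set it is reused unchanged, which is
    how an out-of-sample population shares the in-sample mechanism.
    """
    if outcome_spec.formulation != mechanism.formulation:
        raise ValueError(
            "outcome and mechanism formulations disagree: "
            f"{outcome_spec.formulation!r} vs {mechanism.formulation!r}"
        )
    if outcome_spec.p != predictor_spec.p:
        raise ValueError("beta length inconsistent with predictor dimension")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pred, s_miss, s_noise = ss.spawn(3)
    truth = simulate_predictors(predictor_spec, np.random.default_rng(s_pred))

    mech = dataclasses.replace(mechanism)
    if mechanism.formulation == "selection":
        y = generate_outcome(truth, None, outcome_spec, np.random.default_rng(s_noise))
        if mech.kind != "MCAR" and mech.nu0 is None:
            mech.nu0 = calibrate_intercept(mech, truth, y)
        M = induce_missingness(truth, y, mech, np.random.default_rng(s_miss))
    else:
        if mech.kind != "MCAR" and mech.nu0 is None:
            mech.nu0 = calibrate_intercept(mech, truth, None)
        M = induce_missingness(truth, None, mech, np.random.default_rng(s_miss))
        y = generate_outcome(truth, M, outcome_spec, np.random.default_rng(s_noise))

    X_obs = truth.copy()
    X_obs[M.astype(bool)] = np.nan
    table = DataTable(y=y, X=X_obs, columns=columns)
    return SimulatedDataset(
        table=table,
        M=M,
        truth=truth,
        predictor_spec=predictor_spec,
        outcome_spec=outcome_spec,
        mechanism=mech,
        seed=seed,
    )
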