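"""Synthetic predictors, outcomes, and the five missingness mechanisms."""

import numpy as np
import pytest
from scipy.special import expit

from patternsub import (
    MechanismSpec,
    OutcomeSpec,
    PredictorSpec,
    calibrate_intercept,
    generate_outcome,
    induce_missingness,
    simulate_dataset,
    simulate_predictors,
)
from patternsub.simulate import linear_predictor, mimi_mean

PSPEC = PredictorSpec(mu=[3.0, 3.0], sigma=[[1.0, 0.5], [0.5, 1.0]], n=100_000)


def test_predictor_moments_match_spec():
    X = simulate_predictors(PSPEC, seed=1)
    assert np.allclose(X.mean(axis=0), [3.0, 3.0], atol=0.02)
    assert abs(np.corrcoef(X.T)[0, 1] - 0.5) < 0.02


def test_predictor_draw_is_deterministic_and_validates_sigma():
    spec = PredictorSpec(mu=[0.0, 0.0], sigma=np.eye(2), n=3)
    assert np.array_equal(simulate_predictors(spec, seed=5), simulate_predictors(spec, seed=5))
    with pytest.raises(ValueError, match="positive definite"):
        PredictorSpec(mu=[0.0, 0.0], sigma=[[1.0, 2.0], [2.0, 1.0]], n=3)


@pytest.mark.parametrize("target, expected", [(0.2, np.log(0.2 / 0.8)), (0.5, 0.0)])
def test_calibration_closed_form_without_drivers(target, expected):
    mech = MechanismSpec("MAR", "selection", target, nu_x=[0.0, 0.0])
    nu0 = calibrate_intercept(mech, np.zeros((100, 2)))
    assert abs(nu0 - expected) < 1e-9


def test_calibration_matches_grid_search_oracle():
    """Root-found intercept agrees with a brute-force grid over nu0."""
    rng = np.random.default_rng(3)
    X = np.column_stack([rng.normal(3, 1, 20_000), rng.normal(3, 1, 20_000)])
    mech = MechanismSpec("MAR", "selection", 0.5, nu_x=[1.0, 1.0])
    eta = linear_predictor(mech, X)
    nu0 = calibrate_intercept(mech, X)
    grid = np.arange(-8.0, 0.0, 1e-4)
    frac = np.array([expit(g + eta).mean() for g in grid[:: 100]])  # coarse bracket
    coarse = grid[::100][np.argmin(np.abs(frac - 0.5))]
    fine = np.arange(coarse - 0.02, coarse + 0.02, 1e-4)
    best = fine[np.argmin([abs(expit(g + eta).mean() - 0.5) for g in fine])]
    assert abs(nu0 - best) < 1e-3
    assert abs(expit(nu0 + eta).mean() - 0.5) < 1e-9


def test_mcar_fraction_and_degenerate_limit():
    truth = simulate_predictors(PSPEC, seed=2)
    M = induce_missingness(truth, None, MechanismSpec("MCAR", "selection", 0.5), seed=0)
    assert abs(M[:, 0].mean() - 0.5) < 0.01
    tiny = MechanismSpec("MCAR", "selection", 1e-9)
    M0 = induce_missingness(truth[:100], None, tiny, seed=0)
    assert not M0.any()


def test_mar_equal_drivers_give_equal_probability():
    mech = MechanismSpec("MAR", "selection", 0.4)
    mech.nu0 = -3.0
    X = np.array([[1.0, 2.0], [99.0, 2.0], [5.0, 7.0]])  # rows 0,1 share x2
    eta = linear_predictor(mech, X)
    assert eta[0] == eta[1] != eta[2]


def test_mary_requires_selection_formulation():
    with pytest.raises(ValueError, match="selection"):
        MechanismSpec("MARY", "pattern_mixture", 0.5)
    with pytest.raises(ValueError, match="selection"):
        MechanismSpec("MNARY", "pattern_mixture", 0.5)


def test_uncalibrated_mechanism_refuses_to_draw():
    mech = MechanismSpec("MNAR", "selection", 0.5)
    with pytest.raises(ValueError, match="calibrate"):
        induce_missingness(np.ones((5, 2)), np.ones(5), mech, seed=0)


def test_selection_outcome_deterministic_mean():
    spec = OutcomeSpec("selection", beta=[1.0, 3.0, 1.0], noise_sd=0.0)
    y = generate_outcome(np.array([[1.0, 1.0]]), None, spec, seed=0)
    assert y[0] == pytest.approx(5.0)


def test_pattern_mixture_mean_with_indicator_shift():
    """delta1 = delta3 = 1 shifts intercept and x1 slope in the missing pattern."""
    spec = OutcomeSpec(
        "pattern_mixture", beta=[1.0, 3.0, 1.0], delta=[1.0, 0.0, 1.0], noise_sd=0.0
    )
    y = generate_outcome(np.array([[1.0, 1.0]]), np.array([[1, 0]]), spec, seed=0)
    assert y[0] == pytest.approx(7.0)  # (1+1) + (3+1)*1 + 1*1
    y0 = generate_outcome(np.array([[1.0, 1.0]]), np.array([[0, 0]]), spec, seed=0)
    assert y0[0] == pytest.approx(5.0)  # observed pattern: plain mean


def test_zero_delta_reduces_to_selection_mean():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(50, 2))
    M = (rng.random((50, 2)) < 0.5).astype(int)
    assert np.allclose(
        mimi_mean(X, M, [1.0, 3.0, 1.0], np.zeros(6)), 1.0 + X @ [3.0, 1.0]
    )


def test_dataset_determinism_and_truth_consistency():
    pspec = PredictorSpec(mu=[3, 3], sigma=[[1, 0.5], [0.5, 1]], n=500)
    ospec = OutcomeSpec("pattern_mixture", [1, 3, 1], delta=[1, 0, 1])
    mech = MechanismSpec("MNAR", "pattern_mixture", 0.5)
    a = simulate_dataset(pspec, ospec, mech, seed=11)
    b = simulate_dataset(pspec, ospec, mech, seed=11)
    assert np.array_equal(a.truth, b.truth) and np.array_equal(a.M, b.M)
    assert np.array_equal(a.table.y, b.table.y)
    masked = a.truth.copy()
    masked[a.M.astype(bool)] = np.nan
    assert np.array_equal(np.isnan(a.table.X), np.isnan(masked))
    assert np.array_equal(a.table.X[~np.isnan(masked)], masked[~np.isnan(masked)])


def test_headline_configuration_missing_half():
    pspec = PredictorSpec(mu=[3, 3], sigma=[[1, 0.5], [0.5, 1]], n=1000)
    ds = simulate_dataset(
        pspec,
        OutcomeSpec("selection", [1, 3, 1]),
        MechanismSpec("MNAR", "selection", 0.5),
        seed=4,
    )
    assert abs(int(ds.M[:, 0].sum()) - 500) < 60  # about half the rows miss x1
    assert ds.M[:, 1].sum() == 0


def test_formulation_mismatch_rejected():
    pspec = PredictorSpec(mu=[3, 3], sigma=np.eye(2), n=10)
    with pytest.raises(ValueError, match="disagree"):
        simulate_dataset(
            pspec,
            OutcomeSpec("selection", [1, 3, 1]),
            MechanismSpec("MNAR", "pattern_mixture", 0.5),
            seed=0,
        )
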