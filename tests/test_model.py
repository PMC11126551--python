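"""Multinomial transition model: MLE correctness against analytic and
independent (statsmodels) oracles, prediction properties, stratification."""

import numpy as np
import pandas as pd
import pytest

import worklife as wl
from worklife.design import design_matrix, term_names
from worklife.model import (
    MultinomialTransitionModel,
    _newton_fit,
    _stable_probs,
    multinomial_loglik,
)
from worklife.states import STATES, TRANSIENT_STATES

SPEC = wl.ModelSpec(age_knots=(42.0, 48.0, 57.0, 66.0, 73.0))
SIMPLE = wl.ModelSpec(age_knots=(45.0, 57.0, 70.0), main_effects=("education",),
                      interaction=False)


def test_intercept_only_mle_equals_observed_proportions():
    """Saturated multinomial MLE reproduces the cell frequencies."""
    X = np.ones((1, 1))
    Y = np.array([[1000.0, 600.0, 300.0, 100.0]])
    B, ll, converged, _, _ = _newton_fit(X, Y, ridge=0.0, tol=1e-10, max_iter=100)
    probs = _stable_probs(X @ B)[0]
    assert converged
    assert np.allclose(probs, [0.5, 0.3, 0.15, 0.05], atol=1e-6)


def test_softmax_shift_invariance(rng):
    """Adding a constant to every destination's linear predictor leaves
    the probabilities unchanged (softmax identifiability)."""
    eta = rng.normal(size=(50, 3))
    base = _stable_probs(eta)
    # shifting all four predictors by c == subtracting c from the three
    # non-reference ones with the reference pinned at zero
    full = np.concatenate([np.zeros((50, 1)), eta], axis=1) + 7.3
    direct = np.exp(full) / np.exp(full).sum(axis=1, keepdims=True)
    assert np.allclose(base, direct, atol=1e-12)


def test_fit_matches_statsmodels_oracle(annual_records):
    sm = pytest.importorskip("statsmodels.api")
    df = annual_records.data
    sub = df[df["gender"] == "women"].reset_index(drop=True)
    model = MultinomialTransitionModel(spec=SIMPLE).fit(sub, sub["destination"])
    X = design_matrix(sub, SIMPLE, np.asarray(SIMPLE.age_knots))
    codes = np.array([
        {"employed": 0, "jobless": 1, "retired": 2, "dead": 3}[d]
        for d in sub["destination"]
    ])
    ref = sm.MNLogit(codes, X).fit(method="newton", disp=0, maxiter=200)
    assert model.loglik_ == pytest.approx(ref.llf, abs=1e-4)
    ours = model.coef_.to_numpy()
    theirs = ref.params.to_numpy() if hasattr(ref.params, "to_numpy") else ref.params
    assert np.allclose(ours, theirs, atol=1e-4)


def test_absent_destination_has_zero_probability(annual_records):
    df = annual_records.data
    sub = df[(df["gender"] == "men") & (df["destination"] != "retired")]
    sub = sub.reset_index(drop=True)
    model = MultinomialTransitionModel(spec=SIMPLE).fit(sub, sub["destination"])
    assert model.absent_destinations_ == ("retired",)
    probs = model.predict_proba(sub.head(50))
    assert np.all(probs[:, STATES.index("retired")] == 0.0)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


def test_predicted_rows_sum_to_one_for_random_coefficients(rng):
    names = term_names(SPEC, SPEC.age_knots)
    for _ in range(5):
        coef = pd.DataFrame(
            rng.normal(scale=0.3, size=(len(names), 3)),
            index=names, columns=["jobless", "retired", "dead"],
        )
        prof = wl.CovariateProfile(blocks={
            "education": {"low": 0.3, "medium": 0.4, "high": 0.3},
            "parity": {"0": 0.2, "1": 0.2, "2": 0.35, "3+": 0.25},
            "marital": {"married": 0.6, "single": 0.2, "divorced": 0.15,
                        "widowed": 0.05},
            "extra": {"native": 0.95, "foreign": 0.05},
        })
        tp = wl.probabilities_from_coefficients(
            coef, SPEC, SPEC.age_knots, prof, np.arange(40.0, 75.0), 1
        )
        assert np.allclose(tp.probs.sum(axis=2), 1.0, atol=1e-10)


def test_all_zero_coefficients_give_uniform_quarter():
    names = term_names(SPEC, SPEC.age_knots)
    coef = pd.DataFrame(0.0, index=names, columns=["jobless", "retired", "dead"])
    prof = wl.CovariateProfile(blocks={
        "education": {"low": 1.0, "medium": 0.0, "high": 0.0},
        "parity": {"0": 1.0, "1": 0.0, "2": 0.0, "3+": 0.0},
        "marital": {"married": 1.0, "single": 0.0, "divorced": 0.0, "widowed": 0.0},
        "extra": {"native": 1.0, "foreign": 0.0},
    })
    tp = wl.probabilities_from_coefficients(
        coef, SPEC, SPEC.age_knots, prof, np.arange(40.0, 75.0), 1
    )
    assert np.allclose(tp.probs, 0.25, atol=1e-12)


def test_loglik_at_mle_dominates_truth(annual_config, annual_records):
    """The maximised likelihood is at least the likelihood at the true
    generating coefficients."""
    df = annual_records.data
    sub = df[df["gender"] == "women"].reset_index(drop=True)
    spec = annual_config.truth_spec()
    model = MultinomialTransitionModel(spec=spec).fit(sub, sub["destination"])
    truth = annual_config.truth_coef_table("women").to_numpy()
    X = design_matrix(sub, spec, np.asarray(spec.age_knots))
    codes = np.array([
        {"employed": 0, "jobless": 1, "retired": 2, "dead": 3}[d]
        for d in sub["destination"]
    ])
    ll_truth = multinomial_loglik(X, codes, truth)
    assert model.loglik_ >= ll_truth - 1e-6


def test_gender_stratification_equals_fully_interacted_pooled_fit(annual_records):
    """Separate per-gender fits coincide with one pooled fit in which
    every term is interacted with gender (block-diagonal design)."""
    df = annual_records.data.reset_index(drop=True)
    strata = wl.fit_transition_models(df, SIMPLE)
    knots = np.asarray(SIMPLE.age_knots)
    Xw = design_matrix(df[df["gender"] == "women"], SIMPLE, knots)
    Xm = design_matrix(df[df["gender"] == "men"], SIMPLE, knots)
    pooled = np.zeros((len(df), Xw.shape[1] * 2))
    wmask = (df["gender"] == "women").to_numpy()
    pooled[wmask, : Xw.shape[1]] = Xw
    pooled[~wmask, Xw.shape[1]:] = Xm
    codes = np.array([
        {"employed": 0, "jobless": 1, "retired": 2, "dead": 3}[d]
        for d in df["destination"]
    ])
    Y = np.zeros((len(df), 4))
    Y[np.arange(len(df)), codes] = 1.0
    B, _, converged, _, _ = _newton_fit(pooled, Y, ridge=0.0, tol=1e-9,
                                        max_iter=200)
    assert converged
    p = Xw.shape[1]
    assert np.allclose(B[:p], strata["women"].coef_.to_numpy(), atol=1e-4)
    assert np.allclose(B[p:], strata["men"].coef_.to_numpy(), atol=1e-4)


def test_predicted_matrix_recovers_truth_probabilities():
    """Fitted transition matrices at the truth profile approach the truth
    cell-wise on a large simulated sample."""
    cfg = wl.default_config(4000, seed=31)
    records = wl.build_transition_records(wl.generate_panel(cfg))
    spec = cfg.truth_spec()
    models = wl.fit_transition_models(records.data, spec)
    ages = cfg.origin_ages()
    radix = np.array([0.75, 0.20, 0.05])
    for gender, model in models.items():
        prof = wl.marginal_profile(cfg)
        est = model.transition_probabilities(prof, ages, 1)
        truth = wl.truth_transition_probabilities(cfg, prof, gender)
        err = np.abs(est.probs - truth.probs)
        # cells are recovered in proportion to their data support: tight on
        # the well-populated employed rows, and on average when weighting
        # each origin row by its occupancy under the truth chain
        assert err[:, 0, :].max() < 0.03
        occ = wl.occupancy_forward(truth, radix)
        weighted = (err.max(axis=2) * occ).sum() / occ.sum()
        assert weighted < 0.01


def test_sklearn_estimator_interface(annual_records):
    model = MultinomialTransitionModel(spec=SIMPLE)
    params = model.get_params()
    assert params["spec"] is SIMPLE
    clone = MultinomialTransitionModel(**params)
    df = annual_records.data
    sub = df[df["gender"] == "women"].reset_index(drop=True)
    clone.fit(sub, sub["destination"])
    assert clone.converged_
    assert clone.coef_.shape[0] == len(clone.terms_)
    assert set(clone.coef_.columns) <= set(STATES)
    assert clone.bse_.shape == clone.coef_.shape
    assert np.all(clone.bse_.to_numpy() >= 0)
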