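"""Synthetic-panel generator: reproducibility, validity, convergence to
the ground truth, and closed-form truth expectancies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import worklife as wl
from worklife.errors import ConfigurationError
from worklife.states import DEAD, STATES, TRANSIENT_STATES


def zero_coefficient_config(n, censor_age=42, seed=0):
    """Truth with all coefficients zero: every destination equally likely."""
    zeros = {g: {d: {} for d in ("jobless", "retired", "dead")}
             for g in ("women", "men")}
    return wl.default_config(n, seed=seed, censor_age=censor_age,
                             truth_coefficients=zeros)


def test_same_seed_gives_byte_identical_panels():
    cfg = wl.default_config(400, seed=77)
    a = wl.generate_panel(cfg).data
    b = wl.generate_panel(cfg).data
    pd.testing.assert_frame_equal(a, b)
    c = wl.generate_panel(wl.default_config(400, seed=78)).data
    assert not a.equals(c)


def test_zero_coefficients_give_uniform_destinations():
    """With all coefficients at zero every one-step destination has
    probability 1/4; empirical frequencies stay within 3 binomial SE."""
    n = 50_000
    panel = wl.generate_panel(zero_coefficient_config(n, seed=5))
    rec = wl.build_transition_records(panel).data
    first = rec[rec["age"] == 40]
    assert len(first) == n
    se = np.sqrt(0.25 * 0.75 / n)
    for s in STATES:
        freq = (first["destination"] == s).mean()
        assert abs(freq - 0.25) < 3 * se


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError, match="state_labels"):
        wl.GeneratorConfig(n_persons=10, state_labels=("employed", "jobless", "dead"))
    with pytest.raises(ConfigurationError, match="step"):
        wl.GeneratorConfig(n_persons=10, step=3)
    with pytest.raises(ConfigurationError, match="censor_age"):
        wl.GeneratorConfig(n_persons=10, censor_age=40)
    from worklife.simulate import DEFAULT_COVARIATE_DISTRIBUTIONS
    dists = {k: dict(v) for k, v in DEFAULT_COVARIATE_DISTRIBUTIONS.items()}
    dists["education"] = {"low": 0.5, "medium": 0.4, "high": 0.2}
    with pytest.raises(ConfigurationError, match="education"):
        wl.GeneratorConfig(n_persons=10, covariate_distributions=dists)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n=st.integers(1, 25),
    step=st.sampled_from([1, 2]),
    span=st.integers(2, 10),
    seed=st.integers(0, 2**31 - 1),
)
def test_generated_panels_satisfy_invariants(n, step, span, seed):
    cfg = wl.default_config(
        n, step=step, seed=seed, censor_age=40 + step * span
    )
    panel = wl.generate_panel(cfg)
    panel.validate(strict=True)
    df = panel.data
    assert df["age"].between(cfg.baseline_age, cfg.censor_age).all()
    # death terminal: the dead never reappear
    last_states = df.sort_values(["person_id", "age"]).groupby("person_id")["state"]
    for _, states in last_states:
        vals = states.to_numpy()
        dead_at = np.flatnonzero(vals == DEAD)
        if dead_at.size:
            assert dead_at[0] == len(vals) - 1


def test_empirical_frequencies_converge_to_truth():
    """Destination frequencies from age 40, by origin state, match the
    covariate-averaged truth probabilities within 3 binomial SE."""
    cfg = wl.default_config(50_000, seed=9, censor_age=42)
    panel = wl.generate_panel(cfg)
    rec = wl.build_transition_records(panel).data
    first = rec[rec["age"] == 40]
    for gender in ("women", "men"):
        sub = first[first["gender"] == gender]
        for origin in TRANSIENT_STATES:
            grp = sub[sub["origin"] == origin]
            if len(grp) < 200:
                continue
            # truth probability averaged over this group's covariates
            probs = np.zeros(len(STATES))
            frame = grp.groupby(
                ["parity", "education", "marital", "extra"], observed=True
            ).size()
            for key, count in frame.items():
                group = dict(zip(["parity", "education", "marital", "extra"], key))
                prof = wl.marginal_profile(cfg, group)
                tp = wl.truth_transition_probabilities(
                    cfg, prof, gender, ages=[40.0]
                )
                probs += count * tp.probs[0, TRANSIENT_STATES.index(origin)]
            probs /= len(grp)
            emp = np.array([(grp["destination"] == s).mean() for s in STATES])
            se = np.sqrt(probs * (1 - probs) / len(grp))
            assert np.all(np.abs(emp - probs) <= 3 * se + 1e-12)


def test_truth_expectancy_closed_forms():
    # everyone stays employed, no mortality: 35 years employed
    stay = {g: {"jobless": {"intercept": -40.0}, "retired": {"intercept": -40.0},
                "dead": {"intercept": -40.0}} for g in ("women", "men")}
    cfg = wl.default_config(10, truth_coefficients=stay,
                            initial_state_probs={"employed": 1.0})
    exp = wl.truth_expectancies(cfg, wl.marginal_profile(cfg), "women")
    assert exp.employment == pytest.approx(35.0, abs=1e-9)
    assert exp.joblessness == pytest.approx(0.0, abs=1e-9)
    assert exp.retirement == pytest.approx(0.0, abs=1e-9)

    # stay employed w.p. 0.9, else die: geometric series sum_{k<35} 0.9^k
    p_die = np.log(0.1 / 0.9)
    geom = {g: {"jobless": {"intercept": -40.0}, "retired": {"intercept": -40.0},
                "dead": {"intercept": p_die}} for g in ("women", "men")}
    cfg = wl.default_config(10, truth_coefficients=geom,
                            initial_state_probs={"employed": 1.0})
    expected = sum(0.9**k for k in range(35))
    exp = wl.truth_expectancies(cfg, wl.marginal_profile(cfg), "women")
    assert exp.employment == pytest.approx(expected, abs=1e-9)

    # biennial, zero mortality: 18 occupancy points x 2 years
    cfg = wl.default_config(10, step=2, truth_coefficients=stay,
                            initial_state_probs={"employed": 1.0})
    exp = wl.truth_expectancies(cfg, wl.marginal_profile(cfg), "women")
    assert exp.total == pytest.approx(36.0, abs=1e-9)


def test_truth_expectancies_match_monte_carlo():
    cfg = wl.default_config(10, seed=1)
    prof = wl.marginal_profile(cfg)
    tp = wl.truth_transition_probabilities(cfg, prof, "women")
    radix = np.array([0.75, 0.20, 0.05])
    exact = wl.fundamental_expectancies(tp, radix)
    means, ses = wl.monte_carlo_expectancies(
        tp, radix, 100_000, np.random.default_rng(42)
    )
    for q in ("employment", "joblessness", "retirement", "total"):
        assert abs(means[q] - exact[q]) <= 3 * ses[q]


def test_thinned_panel_is_valid_biennial_panel():
    cfg = wl.default_config(400, seed=21)
    panel = wl.generate_panel(cfg)
    thinned = wl.thin_panel(panel)
    thinned.validate(strict=True)
    assert thinned.step == 2
    # deaths between waves land on the next coarse wave
    assert set(thinned.data["age"] % 2) == {0}
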