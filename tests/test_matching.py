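"""Life-table mortality matching: fixed points, survival reproduction,
structure preservation, error handling."""

import numpy as np
import pytest

import worklife as wl
from worklife.errors import MatchingError
from worklife.matching import implied_death_probabilities

RADIX = np.array([0.7, 0.2, 0.1])


def lifetable_for(tp, qx):
    return wl.LifeTable(ages=tp.ages, qx=np.broadcast_to(qx, tp.ages.shape),
                        step=tp.step)


def single_state_chain(q=0.02, n_ages=35):
    probs = np.zeros((n_ages, 3, 4))
    probs[:, :, 0] = 1 - q
    probs[:, :, 3] = q
    return wl.TransitionProbabilities(
        ages=np.arange(40.0, 40.0 + n_ages), step=1, probs=probs
    )


def test_matching_to_own_mortality_is_identity(rng):
    tp = wl.random_transition_probabilities(rng, max_death=0.05)
    own = implied_death_probabilities(tp, RADIX)
    lt = wl.LifeTable(ages=tp.ages, qx=own, step=1)
    matched, factors = wl.match_mortality(tp, lt, RADIX)
    assert np.allclose(factors, 1.0, atol=1e-9)
    assert np.allclose(matched.probs, tp.probs, atol=1e-12)


def test_zero_target_removes_all_mortality(rng):
    tp = wl.random_transition_probabilities(rng, max_death=0.05)
    matched, factors = wl.match_mortality(tp, lifetable_for(tp, 0.0), RADIX)
    assert np.all(matched.probs[:, :, 3] == 0.0)
    assert np.allclose(matched.probs.sum(axis=2), 1.0, atol=1e-10)
    assert np.all(factors == 0.0)


def test_single_state_halving():
    """Model q = 0.02 everywhere, target 0.01: the factor is exactly 1/2
    and survival follows the life table."""
    tp = single_state_chain(0.02)
    matched, factors = wl.match_mortality(
        tp, lifetable_for(tp, 0.01), np.array([1.0, 0.0, 0.0])
    )
    assert np.allclose(factors, 0.5, atol=1e-9)
    implied = implied_death_probabilities(matched, np.array([1.0, 0.0, 0.0]))
    assert np.allclose(implied, 0.01, atol=1e-10)
    occ = wl.occupancy_forward(matched, np.array([1.0, 0.0, 0.0]))
    assert np.allclose(occ.sum(axis=1), 0.99 ** np.arange(35), atol=1e-10)


def test_survival_matches_life_table_on_random_chains(rng):
    for _ in range(10):
        tp = wl.random_transition_probabilities(rng, max_death=0.08)
        target = implied_death_probabilities(tp, RADIX) * rng.uniform(0.6, 1.5)
        target = np.clip(target, 0.0, 0.5)
        lt = wl.LifeTable(ages=tp.ages, qx=target, step=1)
        matched, _ = wl.match_mortality(tp, lt, RADIX)
        achieved = implied_death_probabilities(matched, RADIX)
        assert np.abs(achieved - target).max() < 1e-8
        # survival curves agree at every age
        occ = wl.occupancy_forward(matched, RADIX).sum(axis=1)
        expected = np.concatenate([[1.0], np.cumprod(1 - target)])[:-1]
        assert np.abs(occ - expected).max() < 1e-8


def test_total_le_equals_life_table_temporary_expectancy(rng):
    tp = wl.random_transition_probabilities(rng, max_death=0.08)
    target = np.clip(implied_death_probabilities(tp, RADIX) * 0.8, 0, 0.5)
    lt = wl.LifeTable(ages=tp.ages, qx=target, step=1)
    matched, _ = wl.match_mortality(tp, lt, RADIX)
    exp = wl.fundamental_expectancies(matched, RADIX)
    assert exp.total == pytest.approx(lt.temporary_life_expectancy(), abs=1e-8)


def test_state_specific_mortality_ordering_preserved(rng):
    tp = wl.random_transition_probabilities(rng, max_death=0.08)
    target = np.clip(implied_death_probabilities(tp, RADIX) * 1.3, 0, 0.5)
    matched, _ = wl.match_mortality(
        tp, wl.LifeTable(ages=tp.ages, qx=target, step=1), RADIX
    )
    q_old = tp.probs[:, :, 3]
    q_new = matched.probs[:, :, 3]
    for a in range(tp.n_ages):
        order_old = np.argsort(q_old[a], kind="stable")
        assert np.all(np.diff(q_new[a][order_old]) >= -1e-12)


def test_uniform_scaling_changes_expectancy_ratios_by_under_one_percent(rng):
    """When every state shares the same death probability the matching
    factor is constant across states and the status-expectancy ratios
    barely move (the preservation property of proportional matching)."""
    trans = np.array([
        [0.70, 0.20, 0.10],
        [0.30, 0.50, 0.20],
        [0.25, 0.25, 0.50],
    ])
    q = 0.02
    probs = np.zeros((35, 3, 4))
    probs[:, :, :3] = trans * (1 - q)
    probs[:, :, 3] = q
    tp = wl.TransitionProbabilities(np.arange(40.0, 75.0), 1, probs)
    # start near the stationary composition so the state mix is stable in
    # age and the single-factor scaling leaves it untouched
    vals, vecs = np.linalg.eig(trans.T)
    stat = np.real(vecs[:, np.argmax(np.real(vals))])
    radix = stat / stat.sum()
    matched, _ = wl.match_mortality(tp, lifetable_for(tp, 0.01), radix)
    before = wl.fundamental_expectancies(tp, radix)
    after = wl.fundamental_expectancies(matched, radix)
    for a, b in (("employment", "joblessness"), ("employment", "retirement")):
        r0 = before[a] / before[b]
        r1 = after[a] / after[b]
        assert abs(r1 / r0 - 1) < 0.01


def test_rank_order_of_status_expectancies_preserved(rng):
    for _ in range(10):
        tp = wl.random_transition_probabilities(rng, max_death=0.06)
        target = np.clip(
            implied_death_probabilities(tp, RADIX) * rng.uniform(0.7, 1.4), 0, 0.5
        )
        matched, _ = wl.match_mortality(
            tp, wl.LifeTable(ages=tp.ages, qx=target, step=1), RADIX
        )
        before = wl.fundamental_expectancies(tp, RADIX)
        after = wl.fundamental_expectancies(matched, RADIX)
        quantities = ("employment", "joblessness", "retirement")
        assert np.argsort([before[q] for q in quantities]).tolist() == \
            np.argsort([after[q] for q in quantities]).tolist()


def test_unattainable_target_reports_age():
    """If the states carrying mortality cannot supply the target rate the
    algorithm refuses, naming the age."""
    probs = np.zeros((2, 3, 4))
    # only the jobless (rare) state carries any mortality
    probs[:, 0, 0] = 1.0
    probs[:, 1, 1] = 0.5
    probs[:, 1, 3] = 0.5
    probs[:, 2, 2] = 1.0
    tp = wl.TransitionProbabilities(np.array([40.0, 41.0]), 1, probs)
    lt = wl.LifeTable(ages=tp.ages, qx=np.array([0.4, 0.4]), step=1)
    with pytest.raises(MatchingError, match="40"):
        wl.match_mortality(tp, lt, np.array([0.9, 0.1, 0.0]))


def test_zero_model_mortality_requires_additive_fallback():
    tp = single_state_chain(0.0)
    lt = lifetable_for(tp, 0.01)
    with pytest.raises(MatchingError, match="zero"):
        wl.match_mortality(tp, lt, np.array([1.0, 0.0, 0.0]))
    matched, factors = wl.match_mortality(
        tp, lt, np.array([1.0, 0.0, 0.0]), additive_fallback=True
    )
    implied = implied_death_probabilities(matched, np.array([1.0, 0.0, 0.0]))
    assert np.allclose(implied, 0.01, atol=1e-10)
    assert np.all(np.isnan(factors))
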