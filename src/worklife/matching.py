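"""Match chain-implied mortality to an external period life table.

Estimated transition models can misstate overall mortality (sparse death
follow-up in survey panels); matching rescales the state-specific death
probabilities so that the chain's population survival reproduces an
official life table, while preserving the relative mortality structure
across labor-force states and hence the relationship between the status
expectancies.

The scheme is proportional and sequential in age: at each origin age a,
given the occupancy distribution pi(a) implied by the already-adjusted
younger ages, a single factor c(a) >= 0 solves

    sum_i pi_i(a) * min(1, c(a) q_i(a)) = q_lt(a)

(monotone in c; solved by bisection to 1e-12), death probabilities are
capped at 1, and each row's transient probabilities are rescaled by
(1 - q'_i) / (1 - q_i) so rows still sum to one.
"""

from __future__ import annotations

import numpy as np

from .errors import MatchingError
from .expectancy import TransitionProbabilities, _radix_vector
from .io import LifeTable
from .states import STATES, TRANSIENT_STATES

_DEAD_COL = STATES.index("dead")
_NT = len(TRANSIENT_STATES)


def _solve_factor(pi: np.ndarray, q: np.ndarray, target: float,
                  tol: float = 1e-12) -> float:
    """Smallest c >= 0 with sum_i pi_i min(1, c q_i) = target."""
    if target <= 0:
        return 0.0
    attainable = float(pi[q > 0].sum())
    if target > attainable + 1e-12:
        raise MatchingError(
            f"target death probability {target:.6g} unattainable: only "
            f"{attainable:.6g} of occupancy has positive model mortality"
        )

    def f(c):
        return float(pi @ np.minimum(1.0, c * q)) - target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise MatchingError("no finite scaling factor reaches the target")
    lo = 0.0
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _rescale_rows(rows: np.ndarray, q_old: np.ndarray,
                  q_new: np.ndarray) -> np.ndarray:
    """Replace death probabilities and rescale transient mass to keep row
    sums at one."""
    out = rows.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q_old < 1.0, (1.0 - q_new) / (1.0 - q_old), 0.0)
    out[:, :_NT] = rows[:, :_NT] * ratio[:, None]
    out[:, _DEAD_COL] = q_new
    return out


def match_mortality(
    tp: TransitionProbabilities,
    lifetable: LifeTable,
    radix,
    additive_fallback: bool = False,
):
    """Adjust ``tp`` so its population survival equals the life table's.

    Parameters
    ----------
    tp : TransitionProbabilities
        Model-implied chain.
    lifetable : LifeTable
        Target one-step death probabilities; must cover every origin age
        of ``tp`` at the same step.
    radix : dict or array
        Initial state distribution at the baseline age.
    additive_fallback : bool
        If the model mortality is identically zero at an age with a
        positive target, add the target uniformly instead of failing.

    Returns
    -------
    (TransitionProbabilities, ndarray)
        The matched chain and the per-age scaling factors c(a)
        (``nan`` where the additive fallback was used).
    """
    if lifetable.step != tp.step:
        raise MatchingError(
            f"life table step {lifetable.step} != chain step {tp.step}"
        )
    q_target = lifetable.q_at(tp.ages)
    if np.any(q_target > 1):
        raise MatchingError("life table death probability exceeds 1")

    occ = _radix_vector(radix)
    probs = tp.probs.copy()
    factors = np.empty(tp.n_ages)
    for k in range(tp.n_ages):
        alive = occ.sum()
        if alive <= 0:
            raise MatchingError(f"no surviving occupancy at age {tp.ages[k]:g}")
        pi = occ / alive
        q = probs[k, :, _DEAD_COL].copy()
        tgt = float(q_target[k])
        if tgt == 0.0:
            q_new = np.zeros(_NT)
            factors[k] = 0.0
        elif np.all(q[pi > 0] == 0):
            if not additive_fallback:
                raise MatchingError(
                    f"model mortality is zero at age {tp.ages[k]:g} but the "
                    f"life table target is {tgt:.6g}; no direction to scale "
                    "(enable additive_fallback to add it uniformly)"
                )
            q_new = np.minimum(1.0, q + tgt)
            factors[k] = np.nan
        else:
            try:
                c = _solve_factor(pi, q, tgt)
            except MatchingError as exc:
                raise MatchingError(f"at age {tp.ages[k]:g}: {exc}") from None
            q_new = np.minimum(1.0, c * q)
            factors[k] = c
        probs[k] = _rescale_rows(probs[k], q, q_new)
        occ = occ @ probs[k, :, :_NT]
    return (
        TransitionProbabilities(ages=tp.ages.copy(), step=tp.step, probs=probs),
        factors,
    )


def apply_mortality_factors(
    tp: TransitionProbabilities, factors: np.ndarray
) -> TransitionProbabilities:
    """Apply per-age scaling factors (estimated at the population level)
    to another chain, e.g. a group-specific one, preserving the relative
    mortality structure across groups."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (tp.n_ages,):
        raise MatchingError("one factor per origin age is required")
    probs = tp.probs.copy()
    for k in range(tp.n_ages):
        q = probs[k, :, _DEAD_COL].copy()
        c = factors[k]
        q_new = np.minimum(1.0, c * q) if np.isfinite(c) else q
        probs[k] = _rescale_rows(probs[k], q, q_new)
    return TransitionProbabilities(ages=tp.ages.copy(), step=tp.step, probs=probs)


def implied_death_probabilities(tp: TransitionProbabilities, radix) -> np.ndarray:
    """Population one-step death probability at each origin age under the
    chain, conditional on being alive."""
    occ = _radix_vector(radix)
    out = np.empty(tp.n_ages)
    for k in range(tp.n_ages):
        pi = occ / occ.sum()
        out[k] = float(pi @ tp.probs[k, :, _DEAD_COL])
        occ = occ @ tp.probs[k, :, :_NT]
    return out
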