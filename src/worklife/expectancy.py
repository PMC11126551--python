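"""Absorbing-chain expectancies between a baseline and a censoring age.

The age-expanded state space combines each origin age with each transient
labor-force state ("aged 68 and employed", ...).  Stacking the
age-specific transition matrices into the block-superdiagonal
transient-to-transient matrix U gives an absorbing Markov chain whose
fundamental matrix N = (I - U)^-1 yields the expected occupancy of each
composite state; summing within a labor-force state across ages and
multiplying by the step length gives the state expectancies.  A person
occupying state s at exact age a contributes `step` years in s for
[a, a+step); no half-interval correction is applied, which makes the
conservation identity (employment + joblessness + retirement = residual
life expectancy) and the zero-mortality bounds exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .states import DEAD, STATES, TRANSIENT_STATES

_N_TRANSIENT = len(TRANSIENT_STATES)
_N_STATES = len(STATES)


@dataclass
class TransitionProbabilities:
    """Age-specific transition matrices P[a, i, j].

    ``ages`` are the origin ages (baseline .. censor - step, spaced by
    ``step``); axis 1 indexes transient origin states, axis 2 destination
    states including dead.  Every row must sum to 1.
    """

    ages: np.ndarray
    step: int
    probs: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.ages.size, _N_TRANSIENT, _N_STATES):
            raise DataError(
                f"probability array shape {self.probs.shape} does not match "
                f"{self.ages.size} ages x {_N_TRANSIENT} origins x {_N_STATES} states"
            )
        if self.ages.size == 0:
            raise DataError("at least one origin age is required")
        if self.ages.size > 1 and not np.allclose(np.diff(self.ages), self.step):
            raise DataError("origin ages must be contiguous at the given step")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise DataError("transition probabilities outside [0, 1]")
        rowsums = self.probs.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-10):
            worst = float(np.abs(rowsums - 1).max())
            raise DataError(f"transition rows must sum to 1 (max deviation {worst:.2e})")

    @property
    def n_ages(self) -> int:
        return int(self.ages.size)

    @property
    def baseline_age(self) -> float:
        return float(self.ages[0])

    @property
    def censor_age(self) -> float:
        return float(self.ages[-1] + self.step)

    def death_probabilities(self) -> np.ndarray:
        """State-specific one-step death probabilities, shape (A, 3)."""
        return self.probs[:, :, STATES.index(DEAD)].copy()


@dataclass
class StateExpectancies:
    """Expected years in each transient state between baseline and censoring."""

    employment: float
    joblessness: float
    retirement: float
    total: float
    baseline_age: float
    step: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "employment": self.employment,
            "joblessness": self.joblessness,
            "retirement": self.retirement,
            "total": self.total,
        }

    def __getitem__(self, key: str) -> float:
        return self.as_dict()[key]


def _radix_vector(radix) -> np.ndarray:
    if isinstance(radix, dict):
        vec = np.array([radix.get(s, 0.0) for s in TRANSIENT_STATES], dtype=float)
    else:
        vec = np.asarray(radix, dtype=float)
    if vec.shape != (_N_TRANSIENT,):
        raise ConfigurationError("radix must give one value per transient state")
    if np.any(vec < 0) or not np.isclose(vec.sum(), 1.0, atol=1e-8):
        raise ConfigurationError("radix must be a distribution over transient states")
    return vec


def build_chain(tp: TransitionProbabilities) -> np.ndarray:
    """Transient-to-transient matrix U of the age-expanded chain.

    Composite states are ordered age-major: (age_0, employed), (age_0,
    jobless), (age_0, retired), (age_1, employed), ...  Rows of the final
    age block are zero: surviving past the last occupancy interval is
    treated as absorption (censoring).
    """
    A = tp.n_ages
    m = A * _N_TRANSIENT
    U = np.zeros((m, m))
    for k in range(A - 1):
        r, c = k * _N_TRANSIENT, (k + 1) * _N_TRANSIENT
        U[r : r + _N_TRANSIENT, c : c + _N_TRANSIENT] = tp.probs[k, :, :_N_TRANSIENT]
    return U


def occupancy_forward(tp: TransitionProbabilities, radix) -> np.ndarray:
    """Alive-state occupancies by forward iteration, shape (A, 3).

    Row 0 equals the radix; pi(a + step) = pi(a) P(a) restricted to the
    transient destinations.  This is the direct oracle for the
    fundamental-matrix computation.
    """
    vec = _radix_vector(radix)
    A = tp.n_ages
    occ = np.empty((A, _N_TRANSIENT))
    occ[0] = vec
    for k in range(A - 1):
        occ[k + 1] = occ[k] @ tp.probs[k, :, :_N_TRANSIENT]
    return occ


def fundamental_expectancies(tp: TransitionProbabilities, radix) -> StateExpectancies:
    """State expectancies via the fundamental matrix N = (I - U)^-1.

    The radix-weighted row of N gives the expected occupancy of every
    composite (age, state) cell; each cell contributes ``step`` years.
    """
    vec = _radix_vector(radix)
    U = build_chain(tp)
    m = U.shape[0]
    start = np.zeros(m)
    start[:_N_TRANSIENT] = vec
    occ_flat = np.linalg.solve((np.eye(m) - U).T, start)
    occ = occ_flat.reshape(tp.n_ages, _N_TRANSIENT)
    years = tp.step * occ.sum(axis=0)
    return StateExpectancies(
        employment=float(years[0]),
        joblessness=float(years[1]),
        retirement=float(years[2]),
        total=float(years.sum()),
        baseline_age=tp.baseline_age,
        step=tp.step,
    )


def monte_carlo_expectancies(
    tp: TransitionProbabilities, radix, n_trajectories: int, rng: np.random.Generator
):
    """Trajectory-simulation estimate of the state expectancies.

    Simulates ``n_trajectories`` independent paths through the chain and
    returns (mean years per state incl. total, standard errors), each as
    a dict keyed like :meth:`StateExpectancies.as_dict`.
    """
    vec = _radix_vector(radix)
    n = int(n_trajectories)
    cur = rng.choice(_N_TRANSIENT, size=n, p=vec)
    years = np.zeros((n, _N_TRANSIENT))
    alive = np.ones(n, dtype=bool)
    for k in range(tp.n_ages):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        states_now = cur[idx]
        for s in range(_N_TRANSIENT):
            years[idx[states_now == s], s] += tp.step
        # transition (the final interval ends in censoring; no draw needed)
        if k < tp.n_ages - 1:
            p = tp.probs[k][states_now]
            u = rng.random(idx.size)
            nxt = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
            cur[idx] = nxt
            died = nxt == _N_TRANSIENT
            alive[idx[died]] = False
    totals = years.sum(axis=1)
    cols = {"employment": years[:, 0], "joblessness": years[:, 1],
            "retirement": years[:, 2], "total": totals}
    means = {k: float(v.mean()) for k, v in cols.items()}
    ses = {k: float(v.std(ddof=1) / np.sqrt(n)) for k, v in cols.items()}
    return means, ses


def random_transition_probabilities(
    rng: np.random.Generator,
    baseline_age: int = 40,
    censor_age: int = 75,
    step: int = 1,
    max_death: float = 0.1,
) -> TransitionProbabilities:
    """Random valid chain for property tests: Dirichlet transient rows with
    a uniform death probability capped at ``max_death`` per age/origin."""
    ages = np.arange(baseline_age, censor_age, step, dtype=float)
    A = ages.size
    q = rng.uniform(0.0, max_death, size=(A, _N_TRANSIENT))
    trans = rng.dirichlet(np.ones(_N_TRANSIENT), size=(A, _N_TRANSIENT))
    probs = np.empty((A, _N_TRANSIENT, _N_STATES))
    probs[:, :, :_N_TRANSIENT] = trans * (1 - q)[:, :, None]
    probs[:, :, _N_TRANSIENT] = q
    return TransitionProbabilities(ages=ages, step=step, probs=probs)
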