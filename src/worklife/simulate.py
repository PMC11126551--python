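"""Synthetic longitudinal panels from a known ground-truth transition model.

The generator emulates the two study designs the pipeline targets: an
annual register-style panel (observations every year from the baseline
age 40 up to a censoring age of 75) and a biennial survey-style panel
(every second year, censored at 76).  Each synthetic person draws fixed
covariates from configurable marginals, an initial labor-force state at
the baseline age, and then advances through the four-state space
(employed, jobless, retired, dead; death absorbing) by sampling from a
known multinomial-logit transition model — the same parameterization the
estimation stage fits, so the ground truth is exactly recoverable.

The default truth coefficients describe a stylized Nordic-like regime:
jobless spells are persistent, retirement hazards rise steeply from the
late fifties, mortality rises log-linearly with age and is higher for
men, parents of two children are the most firmly attached to employment,
and higher education lowers both joblessness and mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .design import CovariateProfile, ModelSpec, population_profile, term_names
from .errors import ConfigurationError
from .expectancy import (
    StateExpectancies,
    TransitionProbabilities,
    fundamental_expectancies,
)
from .model import probabilities_from_coefficients
from .splines import rcs_basis
from .states import (
    DEAD,
    DEAD_CODE,
    GENDERS,
    PANEL_COLUMNS,
    STATES,
    TRANSIENT_STATES,
)

_DEFAULT_TRUTH_KNOTS = (42.0, 48.0, 57.0, 66.0, 73.0)

#: Covariate marginals of the order of register/survey samples:
#: balanced genders, parity concentrated at two children, a broad
#: education mix, a married majority, and a small foreign-born share.
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "gender": {"women": 0.53, "men": 0.47},
    "parity": {"0": 0.16, "1": 0.18, "2": 0.36, "3+": 0.30},
    "education": {"low": 0.31, "medium": 0.38, "high": 0.31},
    "marital": {"married": 0.60, "single": 0.17, "divorced": 0.17, "widowed": 0.06},
    "extra": {"native": 0.965, "foreign": 0.035},
}

DEFAULT_INITIAL_STATE = {"employed": 0.75, "jobless": 0.20, "retired": 0.05}


def default_truth_coefficients(step: int = 1) -> dict[str, dict[str, dict[str, float]]]:
    """Ground-truth coefficients per gender, destination and term.

    Terms not listed are zero.  For the biennial design the intercepts of
    the three exit destinations are shifted by log(2), roughly doubling
    the small one-year hazards over the two-year interval.
    """
    shift = float(np.log(step))

    def eqs(mortality_intercept: float, parity_jobless: dict[str, float]):
        return {
            "jobless": {
                "intercept": -3.3 + shift,
                "age_rcs1": 0.01,
                "age_rcs2": 0.015,
                "origin[jobless]": 4.0,
                "origin[retired]": -1.0,
                "education[medium]": -0.20,
                "education[high]": -0.45,
                "marital[single]": 0.25,
                "marital[divorced]": 0.15,
                "marital[widowed]": 0.10,
                "extra[foreign]": 0.40,
                **parity_jobless,
                "education[medium]:parity[3+]": -0.10,
                "education[high]:parity[2]": -0.10,
                "education[high]:parity[3+]": -0.20,
            },
            "retired": {
                "intercept": -30.0 + shift,
                "age_rcs1": 0.45,
                "origin[jobless]": 0.8,
                "origin[retired]": 6.0,
                "education[high]": -0.15,
            },
            "dead": {
                "intercept": mortality_intercept + shift,
                "age_rcs1": 0.085,
                "origin[jobless]": 0.40,
                "origin[retired]": 0.30,
                "education[medium]": -0.10,
                "education[high]": -0.25,
                "marital[single]": 0.30,
                "marital[divorced]": 0.20,
                "marital[widowed]": 0.35,
                "extra[foreign]": 0.10,
                "parity[1]": -0.05,
                "parity[2]": -0.05,
                "parity[3+]": -0.05,
            },
        }

    return {
        "women": eqs(
            -10.2,
            {"parity[1]": -0.15, "parity[2]": -0.30, "parity[3+]": 0.15},
        ),
        "men": eqs(
            -9.7,
            {"parity[1]": -0.20, "parity[2]": -0.35, "parity[3+]": -0.35},
        ),
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-panel generator.

    ``censor_age`` is the last observation age: 75 with annual steps, 76
    with biennial steps, so the last modelled origin age is 74 in both
    designs.  ``truth_coefficients`` maps gender -> destination -> term
    -> value in the estimation parameterization (reference destination
    employed); ``truth_knots`` fixes the age-spline knots of the truth.
    """

    n_persons: int
    baseline_age: int = 40
    censor_age: int = 75
    step: int = 1
    state_labels: tuple[str, ...] = STATES
    covariate_distributions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_DISTRIBUTIONS.items()
        }
    )
    initial_state_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_STATE)
    )
    truth_coefficients: dict = field(default_factory=default_truth_coefficients)
    truth_knots: tuple[float, ...] = _DEFAULT_TRUTH_KNOTS
    extra_levels: tuple[str, ...] = ("native", "foreign")
    entry_years: tuple[int, int] = (2000, 2005)
    seed: int = 0

    def __post_init__(self):
        if self.step not in (1, 2):
            raise ConfigurationError(f"step must be 1 or 2, got {self.step}")
        if self.censor_age <= self.baseline_age:
            raise ConfigurationError("censor_age must exceed baseline_age")
        if (self.censor_age - self.baseline_age) % self.step != 0:
            raise ConfigurationError(
                "censor_age - baseline_age must be a multiple of step"
            )
        if tuple(self.state_labels) != STATES:
            raise ConfigurationError(
                f"state_labels must be exactly {STATES}, got {tuple(self.state_labels)}"
            )
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be positive")
        self.extra_levels = tuple(self.covariate_distributions["extra"])
        for block, dist in {
            **self.covariate_distributions,
            "initial_state_probs": self.initial_state_probs,
        }.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"distribution {block!r} sums to {total!r}, expected 1"
                )
            if any(p < 0 for p in dist.values()):
                raise ConfigurationError(f"distribution {block!r} has negative mass")
        for s in self.initial_state_probs:
            if s not in TRANSIENT_STATES:
                raise ConfigurationError(
                    f"initial_state_probs keys must be transient states, got {s!r}"
                )

    # -- truth model -------------------------------------------------------

    def truth_spec(self) -> ModelSpec:
        return ModelSpec(age_knots=tuple(self.truth_knots),
                         extra_levels=self.extra_levels)

    def truth_coef_table(self, gender: str) -> pd.DataFrame:
        """Truth coefficients as a terms x destinations table (zeros filled)."""
        spec = self.truth_spec()
        names = term_names(spec, np.asarray(self.truth_knots))
        dests = [s for s in STATES if s != spec.reference_destination]
        table = pd.DataFrame(0.0, index=names, columns=dests)
        coeffs = self.truth_coefficients.get(gender)
        if coeffs is None:
            raise ConfigurationError(f"no truth coefficients for gender {gender!r}")
        for dest, terms in coeffs.items():
            if dest not in dests:
                raise ConfigurationError(f"unknown truth destination {dest!r}")
            for term, value in terms.items():
                if term not in table.index:
                    raise ConfigurationError(f"unknown truth term {term!r}")
                table.loc[term, dest] = float(value)
        return table

    def origin_ages(self) -> np.ndarray:
        return np.arange(self.baseline_age, self.censor_age, self.step, dtype=float)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("state_labels", "truth_knots", "entry_years", "extra_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def default_config(n_persons: int, step: int = 1, seed: int = 0,
                   **overrides) -> GeneratorConfig:
    """Annual (step 1, censor 75) or biennial (step 2, censor 76) default
    study conditions."""
    censor = overrides.pop("censor_age", 75 if step == 1 else 76)
    truth = overrides.pop("truth_coefficients", default_truth_coefficients(step))
    return GeneratorConfig(
        n_persons=n_persons, step=step, censor_age=censor, seed=seed,
        truth_coefficients=truth, **overrides,
    )


@dataclass
class Panel:
    """Long-format synthetic or observed panel plus its design metadata."""

    data: pd.DataFrame
    step: int
    baseline_age: int
    censor_age: int

    def validate(self, strict: bool = True) -> None:
        df = self.data
        if df["age"].min() < self.baseline_age or df["age"].max() > self.censor_age:
            raise ConfigurationError("panel ages outside [baseline_age, censor_age]")
        by_person = df.sort_values(["person_id", "age"]).groupby("person_id")
        diffs = by_person["age"].diff().dropna()
        if strict and not (diffs == self.step).all():
            raise ConfigurationError("ages must increase by exactly `step`")
        if not strict and not (diffs > 0).all():
            raise ConfigurationError("ages must strictly increase within persons")
        dead_seen = by_person["state"].apply(
            lambda s: (s.to_numpy()[:-1] == DEAD).any() if len(s) > 1 else False
        )
        if dead_seen.any():
            raise ConfigurationError("death must be terminal within each person")


def _sample_levels(rng, dist: dict[str, float], n: int) -> np.ndarray:
    levels = np.array(list(dist), dtype=object)
    p = np.array([dist[lv] for lv in levels], dtype=float)
    return levels[rng.choice(len(levels), size=n, p=p / p.sum())]


def generate_panel(config: GeneratorConfig) -> Panel:
    """Simulate a panel under the ground-truth transition model.

    Deterministic given ``config.seed``: one master generator drives the
    covariate draws and the vectorised state stepping in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    obs_ages = np.arange(config.baseline_age, config.censor_age + 1, config.step)
    n_obs = obs_ages.size

    cov = {
        block: _sample_levels(rng, dist, n)
        for block, dist in config.covariate_distributions.items()
    }
    init_p = np.array(
        [config.initial_state_probs.get(s, 0.0) for s in TRANSIENT_STATES]
    )
    states = np.empty((n, n_obs), dtype=np.int8)
    states[:, 0] = rng.choice(len(TRANSIENT_STATES), size=n, p=init_p)
    entry = rng.integers(config.entry_years[0], config.entry_years[1] + 1, size=n)

    spec = config.truth_spec()
    knots = np.asarray(config.truth_knots, dtype=float)
    n_age = spec.n_age_cols(knots)
    age_basis = rcs_basis(obs_ages[:-1].astype(float), knots)

    # Decompose the linear predictor into person (covariate), age and
    # origin-state contributions; exact because the design has no
    # origin x covariate terms and origin x age enters only via the
    # optional interaction (off in the truth spec).
    for gender in GENDERS:
        g_idx = np.flatnonzero(cov["gender"] == gender)
        if g_idx.size == 0:
            continue
        B = config.truth_coef_table(gender).to_numpy()  # p x 3
        names = term_names(spec, knots)
        pos = {t: i for i, t in enumerate(names)}
        cov_terms = [
            t for t in names
            if not t.startswith(("origin[", "age_rcs")) and t != "intercept"
        ]
        frame = pd.DataFrame({b: cov[b][g_idx] for b in spec.blocks()})
        cov_lp = np.zeros((g_idx.size, B.shape[1]))
        for t in cov_terms:
            # term "block[lv]" or "education[e]:parity[k]"
            parts = t.split(":")
            col = np.ones(g_idx.size)
            for part in parts:
                block, lv = part[:-1].split("[")
                col = col * (frame[block].to_numpy() == lv)
            cov_lp += col[:, None] * B[pos[t]]
        cov_lp += B[pos["intercept"]]
        age_lp = age_basis @ B[[pos[f"age_rcs{j + 1}"] for j in range(n_age)]]
        origin_lp = np.zeros((len(TRANSIENT_STATES), B.shape[1]))
        for i, s in enumerate(TRANSIENT_STATES[1:], start=1):
            origin_lp[i] = B[pos[f"origin[{s}]"]]

        for k in range(n_obs - 1):
            cur = states[g_idx, k]
            alive = cur != DEAD_CODE
            idx = g_idx[alive]
            if idx.size == 0:
                states[g_idx[~alive], k + 1] = DEAD_CODE
                continue
            eta = cov_lp[alive] + age_lp[k] + origin_lp[cur[alive]]
            ex = np.exp(eta - np.clip(eta.max(axis=1, keepdims=True), 0, None))
            ref = np.exp(-np.clip(eta.max(axis=1), 0, None))
            denom = ref + ex.sum(axis=1)
            probs = np.column_stack([ref, ex[:, 0], ex[:, 1], ex[:, 2]]) / denom[:, None]
            # destination columns in order employed, jobless, retired, dead
            u = rng.random(idx.size)
            nxt = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
            states[idx, k + 1] = nxt
            states[g_idx[~alive], k + 1] = DEAD_CODE

    # flatten, keeping one observation of the death and dropping the rest
    keep = np.ones((n, n_obs), dtype=bool)
    keep[:, 1:] = states[:, :-1] != DEAD_CODE
    pid, wave = np.nonzero(keep)
    df = pd.DataFrame(
        {
            "person_id": pid,
            "time": entry[pid] + wave * config.step,
            "age": obs_ages[wave],
            "state": np.array(STATES, dtype=object)[states[pid, wave]],
            "gender": cov["gender"][pid],
            "parity": cov["parity"][pid],
            "education": cov["education"][pid],
            "marital": cov["marital"][pid],
            "extra": cov["extra"][pid],
        },
        columns=list(PANEL_COLUMNS),
    )
    return Panel(
        data=df, step=config.step,
        baseline_age=config.baseline_age, censor_age=config.censor_age,
    )


def thin_panel(panel: Panel, every: int = 2) -> Panel:
    """Observe an annual panel only every ``every``-th wave.

    Emulates a biennial survey run over annual underlying dynamics (the
    thinning study mode).  A death occurring between observed waves is
    assigned to the next wave on the coarse grid, i.e. to the destination
    of the pair whose origin is the last alive observation.
    """
    if every < 2:
        raise ConfigurationError("thinning requires every >= 2")
    g = panel.step * every
    base = panel.baseline_age
    censor = base + ((panel.censor_age - base) // g) * g
    df = panel.data
    on_grid = ((df["age"] - base) % g == 0) & (df["age"] <= censor)
    kept = df.loc[on_grid]
    skipped_deaths = df.loc[(df["state"] == DEAD) & ~on_grid].copy()
    if len(skipped_deaths):
        new_age = base + np.ceil((skipped_deaths["age"] - base) / g).astype(int) * g
        keep = new_age <= censor
        skipped_deaths = skipped_deaths.loc[keep]
        shift = (new_age[keep] - skipped_deaths["age"]).to_numpy()
        skipped_deaths["time"] = skipped_deaths["time"] + shift
        skipped_deaths["age"] = new_age[keep]
    out = pd.concat([kept, skipped_deaths], ignore_index=True)
    out = out.sort_values(["person_id", "age"], kind="mergesort").reset_index(drop=True)
    return Panel(data=out, step=g, baseline_age=base, censor_age=censor)


def truth_transition_probabilities(
    config: GeneratorConfig,
    profile: CovariateProfile,
    gender: str = "women",
    ages=None,
) -> TransitionProbabilities:
    """Exact transition matrices of the ground-truth model at a profile."""
    if ages is None:
        ages = config.origin_ages()
    return probabilities_from_coefficients(
        config.truth_coef_table(gender), config.truth_spec(), config.truth_knots,
        profile, ages, config.step,
    )


def truth_expectancies(
    config: GeneratorConfig,
    profile: CovariateProfile,
    gender: str = "women",
    radix=None,
) -> StateExpectancies:
    """Ground-truth state expectancies, computed without any data or
    fitting: truth matrices -> fundamental matrix.  The recovery target
    for the full estimation pipeline."""
    if radix is None:
        radix = {s: config.initial_state_probs.get(s, 0.0) for s in TRANSIENT_STATES}
    tp = truth_transition_probabilities(config, profile, gender)
    return fundamental_expectancies(tp, radix)


def marginal_profile(config: GeneratorConfig,
                     group: dict[str, str] | None = None) -> CovariateProfile:
    """Profile built from the generator marginals (indicators for ``group``
    blocks, marginal proportions elsewhere; independent joint cells)."""
    group = group or {}
    spec = config.truth_spec()
    blocks = {}
    for block, levels in spec.blocks().items():
        dist = config.covariate_distributions[block]
        if block in group:
            blocks[block] = {lv: 1.0 if lv == group[block] else 0.0 for lv in levels}
        else:
            blocks[block] = {lv: dist[lv] for lv in levels}
    return CovariateProfile(blocks=blocks)
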