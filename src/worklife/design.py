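"""Model specification, design matrices, and covariate profiles.

The discrete-time transition model regresses the state at t+step on the
state at t (lagged-state indicators), a restricted cubic spline in age,
main effects of education, parity, marital status and one extra
country-style categorical, and an education x parity interaction.  The
sample is stratified by gender, so gender never appears as a column.

A :class:`CovariateProfile` holds, for every categorical block, either
the sample proportions of its levels (population-level prediction) or an
indicator vector (group-specific prediction); the same design machinery
evaluates the linear predictor in both cases because dummy columns set
to fractional proportions are exactly the profile-averaged predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyGroupError
from .splines import default_knots, rcs_basis, validate_knots
from .states import (
    EDUCATION_LEVELS,
    EMPLOYED,
    MARITAL_LEVELS,
    PARITY_LEVELS,
    TRANSIENT_STATES,
)

_FIXED_BLOCKS = {
    "education": EDUCATION_LEVELS,
    "parity": PARITY_LEVELS,
    "marital": MARITAL_LEVELS,
}

#: Reference categories (first level of each block): education=low, parity=0,
#: marital=married, origin=employed, destination=employed.
_INTERACTION_EDU = EDUCATION_LEVELS[1:]
_INTERACTION_PARITY = PARITY_LEVELS[1:]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the transition regression within a gender stratum.

    Parameters
    ----------
    age_knots : tuple of float, optional
        Explicit spline knot locations (years).  When ``None`` the knots
        are placed at conventional quantiles of the observed origin ages
        at fit time.
    n_knots : int
        Number of knots when ``age_knots`` is ``None``.
    main_effects : tuple of str
        Categorical blocks entering as main effects, drawn from
        {"education", "parity", "marital", "extra"}.
    interaction : bool
        Include the education x parity interaction (requires both blocks
        among the main effects).
    extra_levels : tuple of str
        Levels of the extra country-specific categorical; first level is
        the reference.
    origin_age_interaction : bool
        Interact the lagged-state indicators with the age spline
        (off by default).
    reference_destination : str
        Destination whose linear predictor is pinned at zero.
    """

    age_knots: tuple[float, ...] | None = None
    n_knots: int = 5
    main_effects: tuple[str, ...] = ("education", "parity", "marital", "extra")
    interaction: bool = True
    extra_levels: tuple[str, ...] = ("native", "foreign")
    origin_age_interaction: bool = False
    reference_destination: str = EMPLOYED

    def __post_init__(self):
        for block in self.main_effects:
            if block not in ("education", "parity", "marital", "extra"):
                raise ConfigurationError(f"unknown main effect block {block!r}")
        if self.interaction and not (
            "education" in self.main_effects and "parity" in self.main_effects
        ):
            raise ConfigurationError(
                "education x parity interaction requires both main effects"
            )
        if self.age_knots is not None:
            validate_knots(self.age_knots)
        if len(self.extra_levels) < 1:
            raise ConfigurationError("extra_levels must list at least one level")
        if self.reference_destination not in TRANSIENT_STATES:
            raise ConfigurationError(
                f"reference destination must be transient, got "
                f"{self.reference_destination!r}"
            )

    def blocks(self) -> dict[str, tuple[str, ...]]:
        """Categorical blocks and their level orderings (reference first)."""
        out: dict[str, tuple[str, ...]] = {}
        for b in self.main_effects:
            out[b] = self.extra_levels if b == "extra" else _FIXED_BLOCKS[b]
        return out

    def resolve_knots(self, ages) -> np.ndarray:
        if self.age_knots is not None:
            return np.asarray(self.age_knots, dtype=float)
        return default_knots(ages, self.n_knots)

    def n_age_cols(self, knots) -> int:
        return len(knots) - 1


def term_names(spec: ModelSpec, knots) -> list[str]:
    """Names of the design columns, in design-matrix order."""
    n_age = spec.n_age_cols(knots)
    names = ["intercept"]
    names += [f"origin[{s}]" for s in TRANSIENT_STATES[1:]]
    names += [f"age_rcs{j + 1}" for j in range(n_age)]
    if spec.origin_age_interaction:
        names += [
            f"origin[{s}]:age_rcs{j + 1}"
            for s in TRANSIENT_STATES[1:]
            for j in range(n_age)
        ]
    for block, levels in spec.blocks().items():
        names += [f"{block}[{lv}]" for lv in levels[1:]]
    if spec.interaction:
        names += [
            f"education[{e}]:parity[{k}]"
            for e in _INTERACTION_EDU
            for k in _INTERACTION_PARITY
        ]
    return names


def _level_codes(values, levels, block) -> np.ndarray:
    lut = {lv: i for i, lv in enumerate(levels)}
    try:
        return np.asarray([lut[v] for v in values], dtype=np.int64)
    except KeyError:
        bad = sorted(set(values) - set(levels))
        raise ConfigurationError(f"unknown {block} level(s): {bad}") from None


def design_matrix(frame: pd.DataFrame, spec: ModelSpec, knots) -> np.ndarray:
    """Build the design matrix for person-period records.

    ``frame`` must carry ``origin`` and ``age`` columns plus one column
    per main-effect block.
    """
    n = len(frame)
    age_basis = rcs_basis(frame["age"].to_numpy(dtype=float), knots)
    origin_codes = _level_codes(frame["origin"], TRANSIENT_STATES, "origin")

    cols: list[np.ndarray] = [np.ones(n)]
    origin_dummies = [(origin_codes == i).astype(float) for i in (1, 2)]
    cols += origin_dummies
    cols += [age_basis[:, j] for j in range(age_basis.shape[1])]
    if spec.origin_age_interaction:
        for d in origin_dummies:
            cols += [d * age_basis[:, j] for j in range(age_basis.shape[1])]
    block_dummies: dict[str, dict[str, np.ndarray]] = {}
    for block, levels in spec.blocks().items():
        codes = _level_codes(frame[block], levels, block)
        block_dummies[block] = {
            lv: (codes == i).astype(float) for i, lv in enumerate(levels)
        }
        cols += [block_dummies[block][lv] for lv in levels[1:]]
    if spec.interaction:
        for e in _INTERACTION_EDU:
            for k in _INTERACTION_PARITY:
                cols.append(block_dummies["education"][e] * block_dummies["parity"][k])
    return np.column_stack(cols)


@dataclass
class CovariateProfile:
    """Values at which the linear predictor is evaluated.

    ``blocks`` maps each categorical block to a level -> value mapping;
    values are level proportions (population profile) or a one-hot
    indicator (group profile).  ``joint_education_parity`` optionally
    sets the interaction cells; when absent the product of the margins
    is used.
    """

    blocks: dict[str, dict[str, float]]
    joint_education_parity: dict[tuple[str, str], float] | None = None

    def validate(self, spec: ModelSpec) -> None:
        for block, levels in spec.blocks().items():
            if block not in self.blocks:
                raise ConfigurationError(f"profile missing block {block!r}")
            vals = self.blocks[block]
            missing = set(levels) - set(vals)
            if missing:
                raise ConfigurationError(
                    f"profile block {block!r} missing level(s) {sorted(missing)}"
                )
            total = sum(vals[lv] for lv in levels)
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ConfigurationError(
                    f"profile block {block!r} sums to {total}, expected 1"
                )
            if any(vals[lv] < -1e-12 or vals[lv] > 1 + 1e-12 for lv in levels):
                raise ConfigurationError(f"profile block {block!r} outside [0, 1]")

    def value(self, block: str, level: str) -> float:
        return float(self.blocks[block][level])

    def interaction_value(self, edu: str, parity: str) -> float:
        if self.joint_education_parity is not None:
            return float(self.joint_education_parity.get((edu, parity), 0.0))
        return self.value("education", edu) * self.value("parity", parity)


def profile_design(
    profile: CovariateProfile,
    origin: str,
    ages,
    spec: ModelSpec,
    knots,
) -> np.ndarray:
    """Design rows for one origin state across ``ages`` at a profile."""
    profile.validate(spec)
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    age_basis = rcs_basis(ages, knots)
    origin_idx = TRANSIENT_STATES.index(origin)

    cols: list[np.ndarray] = [np.ones(n)]
    for i in (1, 2):
        cols.append(np.full(n, 1.0 if origin_idx == i else 0.0))
    cols += [age_basis[:, j] for j in range(age_basis.shape[1])]
    if spec.origin_age_interaction:
        for i in (1, 2):
            flag = 1.0 if origin_idx == i else 0.0
            cols += [flag * age_basis[:, j] for j in range(age_basis.shape[1])]
    for block, levels in spec.blocks().items():
        for lv in levels[1:]:
            cols.append(np.full(n, profile.value(block, lv)))
    if spec.interaction:
        for e in _INTERACTION_EDU:
            for k in _INTERACTION_PARITY:
                cols.append(np.full(n, profile.interaction_value(e, k)))
    return np.column_stack(cols)


def population_profile(
    records: pd.DataFrame,
    spec: ModelSpec,
    group: dict[str, str] | None = None,
    weights: np.ndarray | None = None,
) -> CovariateProfile:
    """Covariate profile from person-period records.

    Without ``group`` each block carries the (weighted) sample proportion
    of its levels.  With ``group`` (block -> level), the named blocks are
    set to indicators and the remaining blocks to within-group
    proportions; the education x parity interaction cells are always the
    joint (weighted) proportions over the selected records, which keeps
    them consistent with the margins.
    """
    group = group or {}
    mask = np.ones(len(records), dtype=bool)
    for block, level in group.items():
        mask &= (records[block] == level).to_numpy()
    if weights is not None:
        w = np.asarray(weights, dtype=float)[mask]
        if w.sum() <= 0:
            raise EmptyGroupError(f"no records with positive weight for {group}")
    else:
        w = None
    sub = records.loc[mask]
    if len(sub) == 0:
        raise EmptyGroupError(f"no records match group filter {group}")

    blocks: dict[str, dict[str, float]] = {}
    for block, levels in spec.blocks().items():
        if block in group:
            blocks[block] = {lv: 1.0 if lv == group[block] else 0.0 for lv in levels}
            continue
        codes = _level_codes(sub[block], levels, block)
        counts = np.bincount(codes, weights=w, minlength=len(levels)).astype(float)
        blocks[block] = dict(zip(levels, counts / counts.sum()))

    joint = None
    if spec.interaction:
        edu_codes = _level_codes(sub["education"], EDUCATION_LEVELS, "education")
        par_codes = _level_codes(sub["parity"], PARITY_LEVELS, "parity")
        cell = edu_codes * len(PARITY_LEVELS) + par_codes
        counts = np.bincount(
            cell, weights=w, minlength=len(EDUCATION_LEVELS) * len(PARITY_LEVELS)
        ).astype(float)
        counts /= counts.sum()
        joint = {
            (e, k): counts[i * len(PARITY_LEVELS) + j]
            for i, e in enumerate(EDUCATION_LEVELS)
            for j, k in enumerate(PARITY_LEVELS)
        }
        # When a block is pinned by the group filter the joint computed on the
        # filtered records is automatically consistent with the indicator.
        if "education" in group or "parity" in group:
            pass
    return CovariateProfile(blocks=blocks, joint_education_parity=joint)
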