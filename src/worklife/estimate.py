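"""Single pass of the estimation pipeline: records -> models -> matrices
-> expectancies, for the population and for covariate-defined groups.

The pass is the unit of work the bootstrap replays on resampled data, so
it is split into a *compile* step (all label decoding, grouping and
design construction, done once) and a *run* step (numpy-only: weighted
counts, Newton refit, prediction, expectancies) that accepts per-record
frequency weights.  Resampling persons with replacement is exactly a
frequency-weighting of their records, so a weighted run reproduces the
estimate on the materialised resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CovariateProfile, ModelSpec, design_matrix
from .errors import ConfigurationError, EmptyGroupError, FitError
from .expectancy import fundamental_expectancies
from .io import LifeTable, TransitionRecords
from .matching import apply_mortality_factors, match_mortality
from .model import _newton_fit, destination_order, matrices_at_profile
from .states import (
    EDUCATION_LEVELS,
    GENDERS,
    MARITAL_LEVELS,
    PARITY_LEVELS,
    TRANSIENT_STATES,
)

QUANTITIES = ("employment", "joblessness", "retirement", "total")

_LEVEL_ORDER = {
    "parity": PARITY_LEVELS,
    "education": EDUCATION_LEVELS,
    "marital": MARITAL_LEVELS,
}


@dataclass
class EstimationSettings:
    """What one pipeline pass estimates and how.

    ``groupby`` lists covariate blocks (beyond the gender strata) whose
    level combinations define the reported groups; empty means
    population-level rows only.  ``radix`` is either the string
    ``"observed"`` (state distribution at the baseline age within each
    group) or an explicit distribution over the transient states.
    ``age_window`` restricts the analysis to occupancy ages
    [window[0], window[1]]; records are refiltered and the models refit.
    """

    spec: ModelSpec = field(default_factory=ModelSpec)
    groupby: tuple[str, ...] = ("parity",)
    lifetable: LifeTable | None = None
    match: bool = False
    radix: object = "observed"
    age_window: tuple[int, int] | None = None
    zero_cells: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self):
        for block in self.groupby:
            if block not in ("parity", "education", "marital", "extra"):
                raise ConfigurationError(f"cannot group by unknown block {block!r}")
            if block not in self.spec.main_effects:
                raise ConfigurationError(
                    f"cannot group by {block!r}: not among the model main effects"
                )
        if self.match and self.lifetable is None:
            raise ConfigurationError("matching requested but no life table supplied")
        if isinstance(self.radix, str) and self.radix != "observed":
            raise ConfigurationError(f"unknown radix mode {self.radix!r}")


def _codes(values: np.ndarray, levels) -> np.ndarray:
    lut = {lv: i for i, lv in enumerate(levels)}
    try:
        return np.fromiter((lut[v] for v in values), dtype=np.int64, count=len(values))
    except KeyError:
        bad = sorted(set(values) - set(levels))
        raise ConfigurationError(f"unknown level(s): {bad}") from None


class _Stratum:
    """Precompiled per-gender slice of the records."""

    def __init__(self, gender, frame, settings, knots, dests, baseline):
        self.gender = gender
        spec = settings.spec
        self.n = len(frame)
        self.y = _codes(frame["destination"].to_numpy(), dests)
        self.origin = _codes(frame["origin"].to_numpy(), TRANSIENT_STATES)
        self.n_dest = len(dests)

        code_cols = ["age", "origin", *spec.blocks()]
        codes, dims = [], []
        for col in code_cols:
            u, inv = np.unique(frame[col].to_numpy(), return_inverse=True)
            codes.append(inv.ravel())
            dims.append(len(u))
        cell = np.ravel_multi_index(codes, dims)
        _, first, inv = np.unique(cell, return_index=True, return_inverse=True)
        self.cell_inv = inv.ravel()
        self.design = design_matrix(frame.iloc[first], spec, knots)

        self.block_codes = {
            b: _codes(frame[b].to_numpy(), levels)
            for b, levels in spec.blocks().items()
        }
        self.baseline_mask = frame["age"].to_numpy() == baseline

        # observed group cells, in canonical level order
        cells = [{}]
        for block in settings.groupby:
            order = _LEVEL_ORDER.get(block, tuple(sorted(set(frame[block]))))
            present = [
                lv for lv in order
                if (self.block_codes[block] == list(spec.blocks()[block]).index(lv)).any()
            ]
            cells = [{**c, block: lv} for c in cells for lv in present]
        self.cells = cells
        self.cell_masks = []
        for cell_def in cells:
            mask = np.ones(self.n, dtype=bool)
            for block, lv in cell_def.items():
                lv_idx = list(spec.blocks()[block]).index(lv)
                mask &= self.block_codes[block] == lv_idx
            self.cell_masks.append(mask)
        self.origins_present = np.flatnonzero(
            np.bincount(self.origin, minlength=len(TRANSIENT_STATES)) > 0
        )
        self.warm_start = None
        self.warm_pattern = None


class CompiledEstimator:
    """One estimation pass, compiled for cheap weighted re-runs."""

    def __init__(self, records: TransitionRecords, settings: EstimationSettings):
        spec = settings.spec
        df = records.data
        step = records.step

        if settings.age_window is not None:
            lo, hi = settings.age_window
            if lo < records.baseline_age or hi + step > records.censor_age + 1e-9:
                raise ConfigurationError(
                    f"age window [{lo}, {hi}] outside the panel span "
                    f"[{records.baseline_age}, {records.censor_age - step}]"
                )
            keep = (df["age"].to_numpy() >= lo) & (df["age"].to_numpy() <= hi)
            df = df.loc[keep].reset_index(drop=True)
            self._keep = keep
            self.baseline = lo
            self.ages = np.arange(lo, hi + step, step, dtype=float)
        else:
            self._keep = None
            self.baseline = records.baseline_age
            self.ages = np.arange(self.baseline, records.censor_age, step, dtype=float)
        if len(df) == 0:
            raise EmptyGroupError("no transition records in the analysis window")

        if spec.age_knots is None:
            knots = spec.resolve_knots(df["age"].to_numpy(dtype=float))
            spec = replace(spec, age_knots=tuple(knots))
        self.knots = np.asarray(spec.age_knots, dtype=float)
        self.settings = replace(settings, spec=spec)
        self.step = step
        self.dests = destination_order(spec)

        if settings.match and settings.lifetable is not None:
            if settings.lifetable.step != step:
                raise ConfigurationError(
                    f"life table step {settings.lifetable.step} != panel step {step}"
                )

        self.strata: list[_Stratum] = []
        for g in GENDERS:
            mask = (df["gender"] == g).to_numpy()
            if not mask.any():
                continue
            self.strata.append(
                _Stratum(g, df.loc[mask].reset_index(drop=True), self.settings,
                         self.knots, self.dests, self.baseline)
            )
        if not self.strata:
            raise EmptyGroupError("no recognised gender stratum in records")
        self._strata_masks = [
            (df["gender"] == s.gender).to_numpy() for s in self.strata
        ]
        self.row_keys = [
            (s.gender, *(cell[b] for b in self.settings.groupby))
            for s in self.strata
            for cell in s.cells
        ]

    # -- per-replicate work ------------------------------------------------

    def _fit_stratum(self, st: _Stratum, w: np.ndarray):
        Y = np.bincount(
            st.cell_inv * st.n_dest + st.y, weights=w,
            minlength=st.design.shape[0] * st.n_dest,
        ).reshape((st.design.shape[0], st.n_dest))
        present = Y.sum(axis=0) > 0
        if not present[0]:
            raise EmptyGroupError(
                f"reference destination empty in stratum {st.gender!r}"
            )
        keep_eq = np.flatnonzero(present[1:])
        Yk = Y[:, np.concatenate([[0], keep_eq + 1])]
        pattern = tuple(keep_eq)
        warm = st.warm_start if st.warm_pattern == pattern else None
        try:
            B, _, conv, _, _ = _newton_fit(
                st.design, Yk, 0.0, 1e-8, 200, start=warm, need_info=False
            )
            if not conv:
                raise FitError("no convergence")
        except FitError:
            B, _, conv, _, _ = _newton_fit(
                st.design, Yk, 1e-6, 1e-8, 200, need_info=False
            )
            if not conv:
                raise FitError(f"stratum {st.gender!r} refit failed to converge")
        if st.warm_start is None:
            st.warm_start, st.warm_pattern = B.copy(), pattern
        coef_dests = [self.dests[1:][i] for i in keep_eq]
        return B, coef_dests

    def _profile(self, st: _Stratum, mask: np.ndarray, w: np.ndarray,
                 group: dict[str, str]) -> CovariateProfile:
        spec = self.settings.spec
        wm = w * mask
        total = wm.sum()
        if total <= 0:
            raise EmptyGroupError(f"no records with positive weight for {group}")
        blocks = {}
        for block, levels in spec.blocks().items():
            if block in group:
                blocks[block] = {
                    lv: 1.0 if lv == group[block] else 0.0 for lv in levels
                }
                continue
            counts = np.bincount(st.block_codes[block], weights=wm,
                                 minlength=len(levels))
            blocks[block] = dict(zip(levels, counts / counts.sum()))
        joint = None
        if spec.interaction:
            cell = (st.block_codes["education"] * len(PARITY_LEVELS)
                    + st.block_codes["parity"])
            counts = np.bincount(
                cell, weights=wm,
                minlength=len(EDUCATION_LEVELS) * len(PARITY_LEVELS),
            )
            counts = counts / counts.sum()
            joint = {
                (e, k): counts[i * len(PARITY_LEVELS) + j]
                for i, e in enumerate(EDUCATION_LEVELS)
                for j, k in enumerate(PARITY_LEVELS)
            }
        return CovariateProfile(blocks=blocks, joint_education_parity=joint)

    def _radix(self, st: _Stratum, mask: np.ndarray, w: np.ndarray) -> np.ndarray:
        if not isinstance(self.settings.radix, str):
            vec = self.settings.radix
            if isinstance(vec, dict):
                return np.array(
                    [vec.get(s, 0.0) for s in TRANSIENT_STATES], dtype=float
                )
            return np.asarray(vec, dtype=float)
        sel = mask & st.baseline_mask
        counts = np.bincount(st.origin[sel], weights=w[sel],
                             minlength=len(TRANSIENT_STATES))
        if counts.sum() <= 0:
            raise EmptyGroupError(
                f"no records at baseline age {self.baseline:g} for radix"
            )
        return counts / counts.sum()

    def run_values(self, person_weights: np.ndarray | None = None) -> np.ndarray:
        """Expectancies for every row key, shape (n_rows, 4)."""
        settings = self.settings
        if person_weights is None:
            w_all = None
        else:
            w_all = np.asarray(person_weights, dtype=float)
            if self._keep is not None:
                w_all = w_all[self._keep]
        out = np.empty((len(self.row_keys), len(QUANTITIES)))
        row = 0
        for st, gmask in zip(self.strata, self._strata_masks):
            w = np.ones(st.n) if w_all is None else w_all[gmask]
            if w.sum() <= 0:
                raise EmptyGroupError(f"stratum {st.gender!r} empty in resample")
            by_origin = np.bincount(st.origin, weights=w,
                                    minlength=len(TRANSIENT_STATES))
            lost = by_origin[st.origins_present] <= 0
            if lost.any():
                empty = TRANSIENT_STATES[int(st.origins_present[lost][0])]
                raise EmptyGroupError(
                    f"origin state {empty!r} empty in stratum {st.gender!r}"
                )
            B, coef_dests = self._fit_stratum(st, w)

            factors = None
            if settings.match:
                pop_profile = self._profile(st, np.ones(st.n, dtype=bool), w, {})
                pop_tp = matrices_at_profile(
                    B, coef_dests, self.dests, settings.spec, self.knots,
                    pop_profile, self.ages, self.step, settings.zero_cells,
                )
                pop_radix = self._radix(st, np.ones(st.n, dtype=bool), w)
                _, factors = match_mortality(
                    pop_tp, settings.lifetable, pop_radix
                )

            for cell_def, cmask in zip(st.cells, st.cell_masks):
                if (w * cmask).sum() <= 0:
                    raise EmptyGroupError(
                        f"group {cell_def} empty in stratum {st.gender!r}"
                    )
                profile = self._profile(st, cmask, w, cell_def)
                tp = matrices_at_profile(
                    B, coef_dests, self.dests, settings.spec, self.knots,
                    profile, self.ages, self.step, settings.zero_cells,
                )
                if factors is not None:
                    tp = apply_mortality_factors(tp, factors)
                exp = fundamental_expectancies(tp, self._radix(st, cmask, w))
                out[row] = [exp[q] for q in QUANTITIES]
                row += 1
        return out

    def run(self, person_weights: np.ndarray | None = None) -> pd.DataFrame:
        values = self.run_values(person_weights)
        keys = pd.DataFrame(
            self.row_keys, columns=["gender", *self.settings.groupby]
        )
        vals = pd.DataFrame(values, columns=list(QUANTITIES))
        return pd.concat([keys, vals], axis=1)


def estimate_expectancies(
    records: TransitionRecords,
    settings: EstimationSettings,
    person_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run one full estimation pass and return the expectancy table.

    Parameters
    ----------
    records : TransitionRecords
        Person-period transition records.
    settings : EstimationSettings
    person_weights : array of shape (len(records),), optional
        Frequency weight per record (a person's resampling multiplicity
        replicated over their records).

    Returns
    -------
    pandas.DataFrame
        One row per gender x group cell with columns ``gender``, the
        grouping blocks, ``employment``, ``joblessness``, ``retirement``
        and ``total`` (years).
    """
    return CompiledEstimator(records, settings).run(person_weights)


def freeze_knots(records: TransitionRecords,
                 settings: EstimationSettings) -> EstimationSettings:
    """Resolve data-driven spline knots once and pin them in the spec, so
    repeated passes (bootstrap replicates) share the same basis."""
    if settings.spec.age_knots is not None:
        return settings
    df = records.data
    if settings.age_window is not None:
        lo, hi = settings.age_window
        df = df.loc[(df["age"] >= lo) & (df["age"] <= hi)]
    knots = settings.spec.resolve_knots(df["age"].to_numpy(dtype=float))
    return replace(settings, spec=replace(settings.spec, age_knots=tuple(knots)))
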