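"""Panel and life-table input/output, state recoding, person-period records.

Panels travel as long-format CSV with the fixed header
``person_id,time,age,state,gender,parity,education,marital,extra``.
Life tables are CSV with ``age`` and either ``qx`` (one-year death
probability) or ``lx`` (survivors) columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, EmptyGroupError
from .simulate import Panel
from .states import (
    DEAD,
    DEFAULT_STATE_MAPPING,
    GENDERS,
    PANEL_COLUMNS,
    STATES,
)

_COVARIATE_BLOCKS = ("parity", "education", "marital", "extra")


def recode_states(raw_labels, mapping: dict[str, str] | None = None) -> list[str]:
    """Map raw activity labels onto the four analysis states.

    The default mapping aggregates unemployed, inactive, students, the
    permanently disabled, housekeepers and other residual categories into
    the jobless state; the retired state contains only the retired.
    Unmapped labels raise a :class:`DataError` listing every offender.
    """
    mapping = DEFAULT_STATE_MAPPING if mapping is None else mapping
    out = []
    unmapped = set()
    for label in raw_labels:
        key = label.strip().lower() if isinstance(label, str) else label
        state = mapping.get(key)
        if state is None:
            unmapped.add(label)
        else:
            out.append(state)
    if unmapped:
        raise DataError(f"unmapped activity label(s): {sorted(map(str, unmapped))}")
    bad = set(out) - set(STATES)
    if bad:
        raise DataError(f"mapping produced non-state label(s): {sorted(bad)}")
    return out


def write_panel(panel: Panel, path) -> None:
    panel.data.to_csv(path, index=False, columns=list(PANEL_COLUMNS))


def read_panel(path, step: int | None = None, baseline_age: int | None = None,
               censor_age: int | None = None) -> Panel:
    """Read a panel CSV; metadata not supplied is inferred from the data
    (step = modal within-person age difference)."""
    df = pd.read_csv(path, dtype={"person_id": np.int64, "age": np.int64,
                                  "time": np.int64},
                     converters=None)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"panel file missing column(s): {sorted(missing)}")
    for col in ("state", "gender", "parity", "education", "marital", "extra"):
        df[col] = df[col].astype(str)
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise DataError(f"unknown state label(s) in panel: {sorted(bad)}")
    if step is None:
        diffs = df.sort_values(["person_id", "age"]).groupby("person_id")["age"].diff()
        diffs = diffs.dropna()
        step = int(diffs.mode().iloc[0]) if len(diffs) else 1
    return Panel(
        data=df[list(PANEL_COLUMNS)],
        step=step,
        baseline_age=int(df["age"].min()) if baseline_age is None else baseline_age,
        censor_age=int(df["age"].max()) if censor_age is None else censor_age,
    )


@dataclass
class TransitionRecords:
    """Person-period pairs: one row per observed (t, t+step) transition.

    Columns: person_id, age (origin age), origin, destination, gender,
    parity, education, marital, extra.  Covariates are taken at t.
    """

    data: pd.DataFrame
    step: int
    baseline_age: int
    censor_age: int

    def __len__(self) -> int:
        return len(self.data)


def build_transition_records(panel: Panel) -> TransitionRecords:
    """Pair adjacent observations within persons into transition records.

    Pairs spanning a gap (age difference != step) are dropped rather than
    bridged; no row originates from the dead state.  Non-monotone ages
    raise a :class:`DataError` naming the person.
    """
    df = panel.data.sort_values(["person_id", "age"], kind="mergesort")
    ages = df["age"].to_numpy()
    pids = df["person_id"].to_numpy()
    same = pids[1:] == pids[:-1]
    nonmono = same & (ages[1:] <= ages[:-1])
    if nonmono.any():
        culprit = pids[1:][nonmono][0]
        raise DataError(f"non-increasing ages for person_id {culprit!r}")
    adjacent = same & (ages[1:] - ages[:-1] == panel.step)
    states = df["state"].to_numpy()
    keep = adjacent & (states[:-1] != DEAD)
    idx = np.flatnonzero(keep)
    origin_rows = df.iloc[idx]
    records = pd.DataFrame(
        {
            "person_id": origin_rows["person_id"].to_numpy(),
            "age": origin_rows["age"].to_numpy(),
            "origin": origin_rows["state"].to_numpy(),
            "destination": states[idx + 1],
            "gender": origin_rows["gender"].to_numpy(),
            "parity": origin_rows["parity"].to_numpy(),
            "education": origin_rows["education"].to_numpy(),
            "marital": origin_rows["marital"].to_numpy(),
            "extra": origin_rows["extra"].to_numpy(),
        }
    )
    return TransitionRecords(
        data=records, step=panel.step,
        baseline_age=panel.baseline_age, censor_age=panel.censor_age,
    )


def frequency_transition_probabilities(records: TransitionRecords):
    """Regression-free chain estimate: raw destination frequencies per
    (origin age, origin state) cell.

    Serves as an independent oracle for the model-based chain.  Cells
    with no observed records are set to immediate absorption; their
    occupancy under the empirical radix is zero, so the choice does not
    affect expectancies.
    """
    from .expectancy import TransitionProbabilities
    from .states import TRANSIENT_STATES

    df = records.data
    ages = np.arange(records.baseline_age, records.censor_age, records.step,
                     dtype=float)
    probs = np.zeros((ages.size, len(TRANSIENT_STATES), len(STATES)))
    age_idx = ((df["age"].to_numpy() - records.baseline_age) // records.step).astype(int)
    origin_idx = np.asarray(
        [TRANSIENT_STATES.index(s) for s in df["origin"]], dtype=int
    )
    dest_idx = np.asarray([STATES.index(s) for s in df["destination"]], dtype=int)
    flat = (age_idx * len(TRANSIENT_STATES) + origin_idx) * len(STATES) + dest_idx
    counts = np.bincount(
        flat, minlength=ages.size * len(TRANSIENT_STATES) * len(STATES)
    ).reshape(probs.shape)
    totals = counts.sum(axis=2)
    nonzero = totals > 0
    probs[nonzero] = counts[nonzero] / totals[nonzero][:, None]
    probs[~nonzero, STATES.index(DEAD)] = 1.0
    return TransitionProbabilities(ages=ages, step=records.step, probs=probs)


@dataclass
class LifeTable:
    """External period life table: one-step death probabilities by age."""

    ages: np.ndarray
    qx: np.ndarray
    step: int = 1

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.shape != self.qx.shape or self.ages.ndim != 1:
            raise DataError("life table ages and qx must be 1-d and aligned")
        if self.ages.size > 1 and not np.allclose(np.diff(self.ages), self.step):
            raise DataError("life table ages must be contiguous at the given step")
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            bad = self.ages[(self.qx < 0) | (self.qx > 1)]
            raise DataError(f"qx outside [0, 1] at age(s) {bad.tolist()}")

    def q_at(self, ages) -> np.ndarray:
        """Death probabilities at the requested origin ages."""
        ages = np.asarray(ages, dtype=float)
        idx = np.clip(np.searchsorted(self.ages, ages), 0, self.ages.size - 1)
        ok = np.isclose(self.ages[idx], ages)
        if not ok.all():
            raise DataError(f"life table missing age(s) {ages[~ok].tolist()}")
        return self.qx[idx]

    def survival(self) -> np.ndarray:
        """l(x)/l(x0) at each table age (1 at the first age)."""
        return np.concatenate([[1.0], np.cumprod(1 - self.qx)])[:-1]

    def temporary_life_expectancy(self) -> float:
        """Residual life expectancy over the table span under the discrete
        occupancy convention: step x sum of survivorship at origin ages."""
        return float(self.step * self.survival().sum())


def read_lifetable(path, step: int = 1) -> LifeTable:
    """Read a life table CSV (columns ``age`` and ``qx`` or ``lx``).

    With ``step=2`` the two-year probability is the survival product
    1 - (1-qx(x))(1-qx(x+1)) at every second age.
    """
    df = pd.read_csv(path)
    if "age" not in df.columns:
        raise DataError("life table file must have an 'age' column")
    df = df.sort_values("age").reset_index(drop=True)
    ages = df["age"].to_numpy(dtype=float)
    if "qx" in df.columns:
        qx = df["qx"].to_numpy(dtype=float)
    elif "lx" in df.columns:
        lx = df["lx"].to_numpy(dtype=float)
        if np.any(lx <= 0):
            raise DataError("lx must be positive")
        qx = 1.0 - lx[1:] / lx[:-1]
        ages = ages[:-1]
    else:
        raise DataError("life table file must have a 'qx' or 'lx' column")
    table = LifeTable(ages=ages, qx=qx, step=1)
    if np.any(np.diff(ages) != 1):
        raise DataError("life table must tabulate consecutive single ages")
    if step == 1:
        return table
    if step != 2:
        raise ConfigurationError(f"step must be 1 or 2, got {step}")
    if ages.size % 2 == 1:
        ages = ages[:-1]
    even = np.arange(0, ages.size, 2)
    q2 = 1.0 - (1.0 - qx[even]) * (1.0 - qx[even + 1])
    return LifeTable(ages=ages[even], qx=q2, step=2)


def summarize_panel(panel: Panel) -> pd.DataFrame:
    """Descriptive table: percentages by gender within each covariate
    block, computed over person-records (person-years/waves), plus the
    record count per gender."""
    df = panel.data
    if len(df) == 0:
        raise EmptyGroupError("cannot summarize an empty panel")
    genders = [g for g in GENDERS if (df["gender"] == g).any()]
    rows = []
    counts = {g: int((df["gender"] == g).sum()) for g in genders}
    rows.append({"block": "n_records", "level": "", **counts})
    for block in _COVARIATE_BLOCKS:
        levels = list(dict.fromkeys(df[block]))
        for lv in sorted(levels):
            row = {"block": block, "level": lv}
            for g in genders:
                sub = df.loc[df["gender"] == g, block]
                row[g] = round(100.0 * float((sub == lv).mean()), 4)
            rows.append(row)
    return pd.DataFrame(rows)
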