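"""State space and covariate codings for the multistate working-life table.

The model distinguishes three transient labor-force states (employed,
jobless, retired) and one absorbing state (dead).  "Jobless" aggregates
unemployed, inactive, students, the permanently disabled, housekeepers
and other non-employed, non-retired activity categories; "retired"
contains only the retired.
"""

from __future__ import annotations

EMPLOYED = "employed"
JOBLESS = "jobless"
RETIRED = "retired"
DEAD = "dead"

#: Full state space, in canonical order.  Dead is absorbing and always last.
STATES: tuple[str, ...] = (EMPLOYED, JOBLESS, RETIRED, DEAD)

#: The three transient labor-force states.
TRANSIENT_STATES: tuple[str, ...] = (EMPLOYED, JOBLESS, RETIRED)

STATE_CODES: dict[str, int] = {s: i for i, s in enumerate(STATES)}
DEAD_CODE: int = STATE_CODES[DEAD]

GENDERS: tuple[str, ...] = ("women", "men")

EDUCATION_LEVELS: tuple[str, ...] = ("low", "medium", "high")
PARITY_LEVELS: tuple[str, ...] = ("0", "1", "2", "3+")
MARITAL_LEVELS: tuple[str, ...] = ("married", "single", "divorced", "widowed")

#: Raw activity labels folded into the jobless state by the default recoding.
DEFAULT_STATE_MAPPING: dict[str, str] = {
    "employed": EMPLOYED,
    "working": EMPLOYED,
    "unemployed": JOBLESS,
    "inactive": JOBLESS,
    "student": JOBLESS,
    "permanently disabled": JOBLESS,
    "disabled": JOBLESS,
    "housekeeper": JOBLESS,
    "other": JOBLESS,
    "others": JOBLESS,
    "retired": RETIRED,
    "dead": DEAD,
}

#: Column order of the panel CSV interchange format.
PANEL_COLUMNS: tuple[str, ...] = (
    "person_id",
    "time",
    "age",
    "state",
    "gender",
    "parity",
    "education",
    "marital",
    "extra",
)
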