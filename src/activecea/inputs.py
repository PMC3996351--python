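"""Model-input containers and their CSV round-trip.

All stratified tables share one coordinate system: sex ``male``/``female``
and seven 10-year age bands partitioning ages 30-100 (30-39 ... 90-100,
with the last band covering eleven single years).  Rate tables are stored
as event counts with person-year denominators — the inputs to
beta-binomial transition-probability sampling — in dense numpy arrays
whose axes follow the canonical orders of :mod:`activecea.state_space`.

On disk each table is one UTF-8 CSV with a header row (see ``FILE_NAMES``);
``read_inputs`` validates complete stratum coverage and raises a
:class:`InputError` naming the offending table and key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from activecea import state_space as ss

__all__ = [
    "SEXES",
    "AGE_BANDS",
    "AGES",
    "BAND_OF_AGE",
    "band_of_age",
    "ACTIVITY_CATEGORIES",
    "InputError",
    "TrialEffect",
    "UnitCosts",
    "UtilityCatalogue",
    "ModelInputs",
    "write_inputs",
    "read_inputs",
]

SEXES: tuple[str, str] = ("male", "female")
#: Inclusive 10-year bands partitioning ages 30-100.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 89), (90, 100),
)
AGES: np.ndarray = np.arange(30, 101)
N_AGES = AGES.size
N_BANDS = len(AGE_BANDS)
#: Exposure categories, least to most active; 'active' is the risk reference.
ACTIVITY_CATEGORIES: tuple[str, str, str] = ("inactive", "insufficiently_active", "active")


def band_of_age(age: int) -> int:
    """Index of the 10-year band containing ``age`` (30-100)."""
    if not 30 <= age <= 100:
        raise ValueError(f"age {age} outside the modelled range 30-100")
    return min((int(age) - 30) // 10, N_BANDS - 1)


BAND_OF_AGE: np.ndarray = np.array([band_of_age(a) for a in AGES])


def band_label(b: int) -> str:
    lo, hi = AGE_BANDS[b]
    return f"{lo}-{hi}"


_BAND_BY_LABEL = {band_label(b): b for b in range(N_BANDS)}


class InputError(ValueError):
    """A model-input table is missing, malformed or incomplete."""


@dataclass(frozen=True)
class TrialEffect:
    """Meta-analytic effect of brief primary-care advice on activity.

    Odds ratio (with 95 % CI) for a sedentary participant becoming active,
    together with the control-arm event rate it applies to.
    """

    odds_ratio: float = 1.42
    ci_low: float = 1.17
    ci_high: float = 1.73
    control_events: int = 507
    control_n: int = 1924

    def __post_init__(self) -> None:
        if not 0 < self.ci_low <= self.odds_ratio <= self.ci_high:
            raise InputError("trial-effect CI must satisfy ci_low <= OR <= ci_high > 0")
        if not 0 < self.control_events <= self.control_n:
            raise InputError("control events must be in (0, control_n]")

    @property
    def control_event_rate(self) -> float:
        return self.control_events / self.control_n


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs of health-care contacts, GBP at 2010 prices."""

    consultation: float = 35.0
    emergency_consultation: float = 35.0
    home_visit: float = 117.0
    telephone: float = 21.0
    inpatient: float = 493.0
    outpatient: float = 189.0
    day_case: float = 143.0
    emergency_visit: float = 110.0

    def __post_init__(self) -> None:
        for k, v in self.__dict__.items():
            if v <= 0:
                raise InputError(f"unit cost {k} must be positive")


@dataclass(frozen=True)
class UtilityCatalogue:
    """Additive EQ-5D utility catalogue (Sullivan-style regression decrements).

    Mean utility for a state at a given age is the baseline at age 43 plus
    a linear age slope, plus one decrement per condition present
    (depression included) and an extra decrement by the total number of
    chronic conditions when two or more are present.
    """

    baseline_at_43: float = 0.828
    age_slope_per_year: float = -0.00029
    decrement: dict[str, float] = field(
        default_factory=lambda: {
            "DM": -0.0621,
            "CHD": -0.0557,
            "STROKE": -0.1009,
            "CRC": -0.0378,
            "DEPRESSION": -0.1302,
        }
    )
    count_decrement: dict[int, float] = field(
        default_factory=lambda: {2: -0.0615, 3: -0.0667, 4: -0.0433, 5: -0.0287}
    )

    def __post_init__(self) -> None:
        if not 0 < self.baseline_at_43 <= 1:
            raise InputError("baseline utility must be in (0, 1]")
        if any(v > 0 for v in self.decrement.values()) or any(
            v > 0 for v in self.count_decrement.values()
        ):
            raise InputError("utility decrements must be <= 0")


@dataclass
class ModelInputs:
    """Every stratified table the simulation consumes.

    Array axes (canonical orders):

    - ``incidence_*``: (32 incidence transitions, 2 sexes, 7 bands)
    - ``mortality_*`` and ``depression_*``: (16 disease combos, 2, 7)
    - ``cost_mean`` / ``cost_sd``: (16 combos, 2 depressed, 2 sexes, 7 bands)
    - ``activity``: (2 sexes, 7 bands, 3 categories) proportions summing to 1
    - ``rr``: (4 diseases, 2) relative risks for (inactive, insufficiently
      active) vs the active reference
    - ``initial_cohort``: (2 sexes, 71 single years of age 30-100) counts
    """

    incidence_events: np.ndarray
    incidence_py: np.ndarray
    mortality_events: np.ndarray
    mortality_py: np.ndarray
    depression_events: np.ndarray
    depression_py: np.ndarray
    cost_mean: np.ndarray
    cost_sd: np.ndarray
    activity: np.ndarray
    rr: np.ndarray
    trial: TrialEffect
    unit_costs: UnitCosts
    utilities: UtilityCatalogue
    initial_cohort: np.ndarray

    def validate(self) -> None:
        shapes = {
            "incidence_events": (len(ss.INCIDENCE_TRANSITIONS), 2, N_BANDS),
            "incidence_py": (len(ss.INCIDENCE_TRANSITIONS), 2, N_BANDS),
            "mortality_events": (ss.N_COMBOS, 2, N_BANDS),
            "mortality_py": (ss.N_COMBOS, 2, N_BANDS),
            "depression_events": (ss.N_COMBOS, 2, N_BANDS),
            "depression_py": (ss.N_COMBOS, 2, N_BANDS),
            "cost_mean": (ss.N_COMBOS, 2, 2, N_BANDS),
            "cost_sd": (ss.N_COMBOS, 2, 2, N_BANDS),
            "activity": (2, N_BANDS, 3),
            "rr": (len(ss.DISEASES), 2),
            "initial_cohort": (2, N_AGES),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if tuple(arr.shape) != shape:
                raise InputError(f"table {name}: expected shape {shape}, got {tuple(arr.shape)}")
        for name in ("incidence", "mortality", "depression"):
            ev, py = getattr(self, f"{name}_events"), getattr(self, f"{name}_py")
            if np.any(py <= 0):
                raise InputError(f"table {name}: person-years must be positive")
            if np.any(ev < 0) or np.any(ev > py):
                raise InputError(f"table {name}: events must satisfy 0 <= events <= person_years")
        if np.any(self.cost_mean < 0) or np.any(self.cost_sd < 0):
            raise InputError("table costs: means and SDs must be non-negative")
        if np.any(self.activity < 0) or np.any(
            np.abs(self.activity.sum(axis=2) - 1.0) > 1e-9
        ):
            raise InputError("table activity: category shares must be >= 0 and sum to 1")
        if np.any(self.rr <= 0):
            raise InputError("table relative_risks: relative risks must be positive")
        if np.any(self.initial_cohort < 0):
            raise InputError("table initial_cohort: counts must be non-negative")

    def copy(self) -> "ModelInputs":
        kw = {
            name: (getattr(self, name).copy() if isinstance(getattr(self, name), np.ndarray) else getattr(self, name))
            for name in self.__dataclass_fields__
        }
        return ModelInputs(**kw)

    def equals(self, other: "ModelInputs") -> bool:
        for name in self.__dataclass_fields__:
            a, b = getattr(self, name), getattr(other, name)
            if isinstance(a, np.ndarray):
                if not np.array_equal(a, b):
                    return False
            elif a != b:
                return False
        return True


FILE_NAMES = (
    "incidence.csv",
    "mortality.csv",
    "depression_prevalence.csv",
    "costs.csv",
    "activity.csv",
    "relative_risks.csv",
    "trial_effect.csv",
    "unit_costs.csv",
    "utilities.csv",
    "initial_cohort.csv",
)


def _combo_frame(events: np.ndarray, py: np.ndarray) -> pd.DataFrame:
    rows = []
    for ci, combo in enumerate(ss.ALL_COMBOS):
        for si, sex in enumerate(SEXES):
            for b in range(N_BANDS):
                rows.append(
                    (ss.combo_name(combo), sex, band_label(b), int(events[ci, si, b]), py[ci, si, b])
                )
    return pd.DataFrame(rows, columns=["combo", "sex", "age_band", "events", "person_years"])


def write_inputs(inp: ModelInputs, directory: str | Path) -> None:
    """Write every table as a plain CSV under ``directory``."""
    inp.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for ti, tr in enumerate(ss.INCIDENCE_TRANSITIONS):
        for si, sex in enumerate(SEXES):
            for b in range(N_BANDS):
                rows.append(
                    (
                        ss.combo_name(tr.from_combo),
                        ss.combo_name(tr.to_combo),
                        sex,
                        band_label(b),
                        int(inp.incidence_events[ti, si, b]),
                        inp.incidence_py[ti, si, b],
                    )
                )
    pd.DataFrame(
        rows, columns=["from_state", "to_state", "sex", "age_band", "events", "person_years"]
    ).to_csv(d / "incidence.csv", index=False)

    _combo_frame(inp.mortality_events, inp.mortality_py).to_csv(d / "mortality.csv", index=False)
    _combo_frame(inp.depression_events, inp.depression_py).to_csv(
        d / "depression_prevalence.csv", index=False
    )

    rows = []
    for ci, combo in enumerate(ss.ALL_COMBOS):
        for dep in (0, 1):
            for si, sex in enumerate(SEXES):
                for b in range(N_BANDS):
                    rows.append(
                        (
                            ss.combo_name(combo),
                            dep,
                            sex,
                            band_label(b),
                            inp.cost_mean[ci, dep, si, b],
                            inp.cost_sd[ci, dep, si, b],
                        )
                    )
    pd.DataFrame(rows, columns=["combo", "depressed", "sex", "age_band", "mean", "sd"]).to_csv(
        d / "costs.csv", index=False
    )

    rows = []
    for si, sex in enumerate(SEXES):
        for b in range(N_BANDS):
            rows.append((sex, band_label(b), *inp.activity[si, b]))
    pd.DataFrame(
        rows, columns=["sex", "age_band", *ACTIVITY_CATEGORIES]
    ).to_csv(d / "activity.csv", index=False)

    rows = [
        (disease, cat, inp.rr[di, k])
        for di, disease in enumerate(ss.DISEASES)
        for k, cat in enumerate(ACTIVITY_CATEGORIES[:2])
    ]
    pd.DataFrame(rows, columns=["disease", "category", "relative_risk"]).to_csv(
        d / "relative_risks.csv", index=False
    )

    t = inp.trial
    pd.DataFrame(
        [
            {
                "odds_ratio": t.odds_ratio,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "control_events": t.control_events,
                "control_n": t.control_n,
            }
        ]
    ).to_csv(d / "trial_effect.csv", index=False)

    pd.DataFrame(
        sorted(inp.unit_costs.__dict__.items()), columns=["item", "cost"]
    ).to_csv(d / "unit_costs.csv", index=False)

    u = inp.utilities
    rows = [("baseline_at_43", u.baseline_at_43), ("age_slope_per_year", u.age_slope_per_year)]
    rows += [(f"decrement_{k}", v) for k, v in u.decrement.items()]
    rows += [(f"count_decrement_{k}", v) for k, v in u.count_decrement.items()]
    pd.DataFrame(rows, columns=["parameter", "value"]).to_csv(d / "utilities.csv", index=False)

    rows = [
        (sex, int(age), int(inp.initial_cohort[si, ai]))
        for si, sex in enumerate(SEXES)
        for ai, age in enumerate(AGES)
    ]
    pd.DataFrame(rows, columns=["sex", "age", "count"]).to_csv(
        d / "initial_cohort.csv", index=False
    )


def _read_csv(d: Path, name: str, columns: list[str]) -> pd.DataFrame:
    path = d / name
    if not path.exists():
        raise InputError(f"table {name.removesuffix('.csv')}: file {path} not found")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(
            f"table {name.removesuffix('.csv')}: missing columns {missing} in {path}"
        )
    return df


def _parse_band(label: str, table: str) -> int:
    try:
        return _BAND_BY_LABEL[str(label)]
    except KeyError:
        raise InputError(f"table {table}: unknown age band {label!r}") from None


def _fill_combo_table(df: pd.DataFrame, table: str) -> tuple[np.ndarray, np.ndarray]:
    events = np.full((ss.N_COMBOS, 2, N_BANDS), np.nan)
    py = np.full_like(events, np.nan)
    sex_index = {s: i for i, s in enumerate(SEXES)}
    for row in df.itertuples(index=False):
        ci = ss.COMBO_INDEX[ss.parse_combo_name(row.combo)]
        si = sex_index[row.sex]
        b = _parse_band(row.age_band, table)
        events[ci, si, b] = row.events
        py[ci, si, b] = row.person_years
    if np.isnan(events).any():
        ci, si, b = np.argwhere(np.isnan(events))[0]
        raise InputError(
            f"table {table}: missing stratum ({ss.combo_name(ss.ALL_COMBOS[ci])}, "
            f"{SEXES[si]}, {band_label(b)})"
        )
    return events, py


def read_inputs(directory: str | Path) -> ModelInputs:
    """Load and validate a complete input set previously written by :func:`write_inputs`."""
    d = Path(directory)
    sex_index = {s: i for i, s in enumerate(SEXES)}

    df = _read_csv(d, "incidence.csv", ["from_state", "to_state", "sex", "age_band", "events", "person_years"])
    tr_index = {
        (ss.combo_name(t.from_combo), ss.combo_name(t.to_combo)): i
        for i, t in enumerate(ss.INCIDENCE_TRANSITIONS)
    }
    inc_events = np.full((len(tr_index), 2, N_BANDS), np.nan)
    inc_py = np.full_like(inc_events, np.nan)
    for row in df.itertuples(index=False):
        key = (row.from_state, row.to_state)
        if key not in tr_index:
            raise InputError(f"table incidence: illegal transition {key[0]} -> {key[1]}")
        inc_events[tr_index[key], sex_index[row.sex], _parse_band(row.age_band, "incidence")] = row.events
        inc_py[tr_index[key], sex_index[row.sex], _parse_band(row.age_band, "incidence")] = row.person_years
    if np.isnan(inc_events).any():
        ti, si, b = np.argwhere(np.isnan(inc_events))[0]
        t = ss.INCIDENCE_TRANSITIONS[ti]
        raise InputError(
            f"table incidence: missing stratum ({ss.combo_name(t.from_combo)} -> "
            f"{ss.combo_name(t.to_combo)}, {SEXES[si]}, {band_label(b)})"
        )

    mort_events, mort_py = _fill_combo_table(
        _read_csv(d, "mortality.csv", ["combo", "sex", "age_band", "events", "person_years"]),
        "mortality",
    )
    dep_events, dep_py = _fill_combo_table(
        _read_csv(
            d, "depression_prevalence.csv", ["combo", "sex", "age_band", "events", "person_years"]
        ),
        "depression_prevalence",
    )

    df = _read_csv(d, "costs.csv", ["combo", "depressed", "sex", "age_band", "mean", "sd"])
    cost_mean = np.full((ss.N_COMBOS, 2, 2, N_BANDS), np.nan)
    cost_sd = np.full_like(cost_mean, np.nan)
    for row in df.itertuples(index=False):
        ci = ss.COMBO_INDEX[ss.parse_combo_name(row.combo)]
        cost_mean[ci, int(row.depressed), sex_index[row.sex], _parse_band(row.age_band, "costs")] = row.mean
        cost_sd[ci, int(row.depressed), sex_index[row.sex], _parse_band(row.age_band, "costs")] = row.sd
    if np.isnan(cost_mean).any():
        ci, dep, si, b = np.argwhere(np.isnan(cost_mean))[0]
        raise InputError(
            f"table costs: missing stratum ({ss.combo_name(ss.ALL_COMBOS[ci])}, depressed={dep}, "
            f"{SEXES[si]}, {band_label(b)})"
        )

    df = _read_csv(d, "activity.csv", ["sex", "age_band", *ACTIVITY_CATEGORIES])
    activity = np.full((2, N_BANDS, 3), np.nan)
    for row in df.itertuples(index=False):
        b = _parse_band(row.age_band, "activity")
        activity[sex_index[row.sex], b] = [getattr(row, c) for c in ACTIVITY_CATEGORIES]
    if np.isnan(activity).any():
        si, b, _ = np.argwhere(np.isnan(activity))[0]
        raise InputError(f"table activity: missing stratum ({SEXES[si]}, {band_label(b)})")

    df = _read_csv(d, "relative_risks.csv", ["disease", "category", "relative_risk"])
    rr = np.full((len(ss.DISEASES), 2), np.nan)
    cat_index = {c: k for k, c in enumerate(ACTIVITY_CATEGORIES[:2])}
    for row in df.itertuples(index=False):
        if row.disease not in ss.DISEASES or row.category not in cat_index:
            raise InputError(
                f"table relative_risks: unknown key ({row.disease}, {row.category})"
            )
        rr[ss.DISEASES.index(row.disease), cat_index[row.category]] = row.relative_risk
    if np.isnan(rr).any():
        di, k = np.argwhere(np.isnan(rr))[0]
        raise InputError(
            f"table relative_risks: missing ({ss.DISEASES[di]}, {ACTIVITY_CATEGORIES[k]})"
        )

    df = _read_csv(
        d, "trial_effect.csv", ["odds_ratio", "ci_low", "ci_high", "control_events", "control_n"]
    )
    r = df.iloc[0]
    trial = TrialEffect(
        odds_ratio=float(r.odds_ratio),
        ci_low=float(r.ci_low),
        ci_high=float(r.ci_high),
        control_events=int(r.control_events),
        control_n=int(r.control_n),
    )

    df = _read_csv(d, "unit_costs.csv", ["item", "cost"])
    unit_costs = UnitCosts(**dict(zip(df["item"], df["cost"].astype(float))))

    df = _read_csv(d, "utilities.csv", ["parameter", "value"])
    vals = dict(zip(df["parameter"], df["value"].astype(float)))
    try:
        utilities = UtilityCatalogue(
            baseline_at_43=vals.pop("baseline_at_43"),
            age_slope_per_year=vals.pop("age_slope_per_year"),
            decrement={k.removeprefix("decrement_"): v for k, v in vals.items() if k.startswith("decrement_")},
            count_decrement={
                int(k.removeprefix("count_decrement_")): v
                for k, v in vals.items()
                if k.startswith("count_decrement_")
            },
        )
    except KeyError as e:
        raise InputError(f"table utilities: missing parameter {e}") from None

    df = _read_csv(d, "initial_cohort.csv", ["sex", "age", "count"])
    cohort = np.full((2, N_AGES), np.nan)
    for row in df.itertuples(index=False):
        if not 30 <= int(row.age) <= 100:
            raise InputError(f"table initial_cohort: age {row.age} outside 30-100")
        cohort[sex_index[row.sex], int(row.age) - 30] = row.count
    if np.isnan(cohort).any():
        si, ai = np.argwhere(np.isnan(cohort))[0]
        raise InputError(f"table initial_cohort: missing ({SEXES[si]}, age {int(AGES[ai])})")

    out = ModelInputs(
        incidence_events=inc_events.astype(int).astype(float),
        incidence_py=inc_py,
        mortality_events=mort_events.astype(int).astype(float),
        mortality_py=mort_py,
        depression_events=dep_events.astype(int).astype(float),
        depression_py=dep_py,
        cost_mean=cost_mean,
        cost_sd=cost_sd,
        activity=activity,
        rr=rr,
        trial=trial,
        unit_costs=unit_costs,
        utilities=utilities,
        initial_cohort=cohort,
    )
    out.validate()
    return out
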