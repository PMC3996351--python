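"""Synthetic model-input generator.

Emulates the statistical structure of the stratified primary-care tables
the model consumes — age/sex-stratified incidence, per-combination
mortality, depression prevalence, and per-state annual costs — together
with an activity distribution, relative risks, the trial effect and the
utility catalogue.  Construction guarantees the qualitative features the
model mechanism relies on:

- incidence and mortality rates rise monotonically with age band;
- mortality is monotone over the disease-combination lattice (adding a
  disease never lowers mortality);
- depression prevalence is strictly higher in every disease state than in
  the healthy state (the route by which an intervention with no direct
  depression effect still reduces depression-years);
- costs are strictly higher with depression at fixed combination/stratum;
- colorectal-cancer incidence is identical with and without cardiovascular
  comorbidity (and vice versa), and every multi-disease combination
  containing colorectal cancer shares a single cost row.

The generator is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math

import numpy as np

from activecea import state_space as ss
from activecea.config import ConfigError, SyntheticConfig
from activecea.inputs import (
    AGE_BANDS,
    AGES,
    N_AGES,
    N_BANDS,
    SEXES,
    ModelInputs,
    TrialEffect,
    UnitCosts,
    UtilityCatalogue,
)

__all__ = ["generate_model_inputs", "generate_initial_cohort"]

_BAND_MID = np.array([(lo + hi) / 2 for lo, hi in AGE_BANDS])
# relative person-year exposure by age band (registry populations thin with age)
_PY_AGE_WEIGHT = np.array([1.0, 0.9, 0.8, 0.6, 0.4, 0.2, 0.08])


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _monotone_events(rates: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Round ``rates * py`` to integer events, then enforce that realised
    rates (events / py) are non-decreasing across the age-band axis (last)."""
    events = np.rint(rates * py)
    out = np.empty_like(events)
    prev_rate = np.zeros(events.shape[:-1])
    for b in range(events.shape[-1]):
        ev = np.maximum(events[..., b], np.ceil(prev_rate * py[..., b] - 1e-9))
        ev = np.minimum(ev, py[..., b])  # cap: cannot exceed the denominator
        out[..., b] = ev
        prev_rate = ev / py[..., b]
    return out


def generate_initial_cohort(config: SyntheticConfig, seed: int) -> np.ndarray:
    """Counts of healthy entrants per (sex, single year of age 30-100).

    The total equals ``config.cohort_size`` exactly; the male share is 49 %
    and the age mix 37 % under 45, 42 % aged 45-64 and 21 % aged 65+, each
    reproduced to well within half a percentage point by largest-remainder
    rounding of a smooth within-group age profile.
    """
    if config.cohort_size <= 0:
        raise ConfigError("cohort size must be positive")
    group_share = {"lt45": 0.37, "45to64": 0.42, "ge65": 0.21}
    # within-group profiles: gentle decline, steeper in old age
    weights = np.empty(N_AGES)
    for ai, age in enumerate(AGES):
        if age < 45:
            weights[ai] = 1.0 - 0.01 * (age - 30)
        elif age < 65:
            weights[ai] = 1.0 - 0.015 * (age - 45)
        else:
            weights[ai] = math.exp(-0.07 * (age - 65))
    target = np.empty(N_AGES)
    for lo, hi, share in ((30, 44, group_share["lt45"]), (45, 64, group_share["45to64"]), (65, 100, group_share["ge65"])):
        sel = (AGES >= lo) & (AGES <= hi)
        target[sel] = share * weights[sel] / weights[sel].sum()
    real = np.outer([0.49, 0.51], target) * config.cohort_size  # (sex, age)

    flat = real.ravel()
    floors = np.floor(flat).astype(np.int64)
    remainder = config.cohort_size - int(floors.sum())
    order = np.argsort(-(flat - floors))
    floors[order[:remainder]] += 1
    counts = floors.reshape(2, N_AGES).astype(float)
    assert counts.sum() == config.cohort_size
    return counts


def generate_model_inputs(config: SyntheticConfig | None = None, seed: int = 0) -> ModelInputs:
    """Generate a complete, validated :class:`~activecea.inputs.ModelInputs`.

    ``seed`` perturbs the base rate/cost scales with a small multiplicative
    log-normal jitter applied at the level of whole schedules (per disease
    or per combination), so the structural monotonicities above hold for
    every seed.
    """
    config = config or SyntheticConfig()
    rng = _rng(seed)
    jitter = lambda n: np.exp(rng.normal(0.0, config.rate_jitter_sd, n))  # noqa: E731

    n_tr = len(ss.INCIDENCE_TRANSITIONS)
    combo_size = np.array([len(c) for c in ss.ALL_COMBOS])

    # person-year denominators: large for the healthy state, thinning with
    # combination size and age
    combo_py_factor = np.where(combo_size == 0, 1.0, 0.02 * 0.35 ** (combo_size - 1))
    py_combo = np.maximum(
        config.person_years_base * combo_py_factor[:, None, None] * _PY_AGE_WEIGHT[None, None, :],
        200.0,
    ) * np.ones((1, 2, 1))

    # --- incidence -------------------------------------------------------
    # the rate of acquiring disease d depends on (d, sex, band) only: this
    # realises the simplifying assumption that colorectal-cancer incidence
    # is independent of cardiovascular comorbidity and vice versa
    disease_jitter = dict(zip(ss.DISEASES, jitter(len(ss.DISEASES))))
    band_factor = config.incidence_doubling_per_decade ** np.arange(N_BANDS)
    inc_rate = np.empty((n_tr, 2, N_BANDS))
    inc_py = np.empty_like(inc_rate)
    for ti, tr in enumerate(ss.INCIDENCE_TRANSITIONS):
        d = tr.disease
        base = config.incidence_per_10k_30s[d] / 10_000.0 * disease_jitter[d]
        for si, sex in enumerate(SEXES):
            sex_f = config.male_incidence_factor[d] if sex == "male" else 1.0
            inc_rate[ti, si] = np.minimum(base * sex_f * band_factor, 0.5)
        inc_py[ti] = py_combo[ss.COMBO_INDEX[tr.from_combo]]
    inc_events = _monotone_events(inc_rate, inc_py)

    # --- mortality -------------------------------------------------------
    mort_jitter = jitter(len(ss.DISEASES))
    hazard = {
        d: max(config.mortality_hazard_factor[d] * mort_jitter[i], 1.05)
        for i, d in enumerate(ss.DISEASES)
    }
    mort_rate = np.empty((ss.N_COMBOS, 2, N_BANDS))
    base_sched = config.mortality_base_30s * np.exp(
        config.mortality_log_slope_per_year * (_BAND_MID - 35.0)
    )
    for ci, combo in enumerate(ss.ALL_COMBOS):
        mult = float(np.prod([hazard[d] for d in combo])) if combo else 1.0
        for si, sex in enumerate(SEXES):
            sex_f = config.male_mortality_factor if sex == "male" else 1.0
            mort_rate[ci, si] = np.minimum(base_sched * mult * sex_f, 0.9)
    mort_events = _monotone_events(mort_rate, py_combo)
    # enforce lattice monotonicity on realised rates: a superset combination
    # never has lower mortality than any of its subsets
    realised = mort_events / py_combo
    for ci, combo in enumerate(ss.ALL_COMBOS):
        for d in combo:
            sub = ss.COMBO_INDEX[combo - {d}]
            floor_ev = np.ceil(realised[sub] * py_combo[ci] - 1e-9)
            mort_events[ci] = np.minimum(np.maximum(mort_events[ci], floor_ev), py_combo[ci])
        realised[ci] = mort_events[ci] / py_combo[ci]

    # --- depression prevalence ------------------------------------------
    dep_rate = np.clip(
        config.depression_prev_base
        + config.depression_prev_per_condition * combo_size[:, None, None]
        + 0.01 * np.arange(N_BANDS)[None, None, :] / N_BANDS,
        0.0,
        0.6,
    ) * np.ones((1, 2, 1))
    dep_events = np.rint(dep_rate * py_combo)
    # strict inequality vs the healthy state, per stratum, after rounding
    healthy = dep_events[0] / py_combo[0]
    for ci in range(1, ss.N_COMBOS):
        floor_ev = np.floor(healthy * py_combo[ci]) + 1
        dep_events[ci] = np.minimum(np.maximum(dep_events[ci], floor_ev), py_combo[ci])

    # --- costs -----------------------------------------------------------
    base_cost = config.cost_base_30s * config.cost_growth_per_band ** np.arange(N_BANDS)
    add_jitter = dict(zip(ss.DISEASES, jitter(len(ss.DISEASES))))
    cost_mean = np.empty((ss.N_COMBOS, 2, 2, N_BANDS))
    for ci, combo in enumerate(ss.ALL_COMBOS):
        if "CRC" in combo:
            # all colorectal-cancer cases costed together: one row for the
            # single-disease state, one shared row for every multi-disease
            # combination containing it
            add = config.cost_disease_add["CRC"] * add_jitter["CRC"]
            if len(combo) > 1:
                add += config.cost_crc_comorbidity_add
        else:
            add = sum(config.cost_disease_add[d] * add_jitter[d] for d in combo)
        for dep in (0, 1):
            extra = config.cost_depression_add if dep else 0.0
            cost_mean[ci, dep, :, :] = base_cost[None, :] + add + extra
    cost_sd = cost_mean * config.cost_sd_to_mean

    activity = np.tile(np.asarray(config.activity_by_band)[None, :, :], (2, 1, 1))
    rr = np.array(
        [[config.rr_inactive[d], config.rr_insufficient[d]] for d in ss.DISEASES]
    )

    out = ModelInputs(
        incidence_events=inc_events,
        incidence_py=inc_py,
        mortality_events=mort_events,
        mortality_py=py_combo.copy(),
        depression_events=dep_events,
        depression_py=py_combo.copy(),
        cost_mean=cost_mean,
        cost_sd=cost_sd,
        activity=activity,
        rr=rr,
        trial=TrialEffect(),
        unit_costs=UnitCosts(),
        utilities=UtilityCatalogue(),
        initial_cohort=generate_initial_cohort(config, seed),
    )
    out.validate()
    return out
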