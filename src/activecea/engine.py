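"""Deterministic cohort propagation through the multimorbidity state space.

One run propagates population mass, stratified by sex and single year of
age, through 70 annual cycles under one parameter draw.  Within a cycle
the event order is: death (per disease combination), then acquisition of
at most one new disease among the legal incidence transitions (with the
intervention's incidence multipliers applied to transitions out of the
healthy state during the intervention years), then a memoryless
re-partition of every combination's survivors into depressed / not
depressed by the combination's depression prevalence, then ageing by one
year.  Mass reaching beyond age 100 exits the model alive; depression has
no effect on mortality or disease incidence.

Outcome summaries apply a trapezoidal half-cycle correction (the mean of
cycle-start and cycle-end occupancy) to life years, QALYs and costs, and
discount with factor (1 + r)^-t where t is the 0-based cycle index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from activecea import state_space as ss
from activecea.config import InterventionSpec
from activecea.inputs import BAND_OF_AGE, N_AGES, ModelInputs
from activecea.pif import multiplier_schedule
from activecea.sampling import ParameterDraw

__all__ = ["N_CYCLES", "CohortTrace", "OutcomeSummary", "run_cohort", "summarise"]

logger = logging.getLogger(__name__)

N_CYCLES = 70

_ATRISK = ss.COMBO_INDEX[frozenset()]
# transitions grouped by source combination
_OUT_TRANSITIONS: list[list[int]] = [[] for _ in range(ss.N_COMBOS)]
for _ti, _tr in enumerate(ss.INCIDENCE_TRANSITIONS):
    _OUT_TRANSITIONS[ss.COMBO_INDEX[_tr.from_combo]].append(_ti)
_TO_COMBO = np.array([ss.COMBO_INDEX[t.to_combo] for t in ss.INCIDENCE_TRANSITIONS])
_DISEASE_OF_TRANSITION = np.array(
    [ss.DISEASES.index(t.disease) for t in ss.INCIDENCE_TRANSITIONS]
)
# alive-state index of (combo, depressed)
_STATE_OF = np.array(
    [
        [ss.STATE_INDEX[ss.HealthState(c, False)], ss.STATE_INDEX[ss.HealthState(c, True)]]
        for c in ss.ALL_COMBOS
    ]
)
_CLASS_OF_STATE = np.array(
    [len(s.combo) for s in ss.ALIVE_STATES]
)  # 0..4 physical diseases
_DEPRESSED_STATE = np.array([s.depressed for s in ss.ALIVE_STATES])


@dataclass
class CohortTrace:
    """Occupancy snapshots of one scenario run.

    ``occupancy[sex, cycle, age - 30, state]`` is fractional person-mass in
    each of the 32 alive states at the start of the cycle (cycle 0 is the
    initial distribution; there are ``N_CYCLES + 1`` snapshots).
    ``dead`` and ``exited`` are cumulative masses per snapshot.
    """

    occupancy: np.ndarray  # (2, N_CYCLES+1, N_AGES, 32)
    dead: np.ndarray  # (2, N_CYCLES+1)
    exited: np.ndarray  # (2, N_CYCLES+1)
    entrants: float

    def alive_mass(self) -> np.ndarray:
        """Total alive mass per (sex, cycle)."""
        return self.occupancy.sum(axis=(2, 3))

    def check_conservation(self, rtol: float = 1e-9) -> None:
        total = self.alive_mass() + self.dead + self.exited
        ref = total[:, :1]
        if not np.allclose(total, ref, rtol=rtol, atol=ref.sum() * rtol):
            raise AssertionError("mass not conserved across cycles")


@dataclass
class OutcomeSummary:
    """Per-scenario outcomes, normalised per 1,000 entrants.

    Life years are undiscounted and split by physical-morbidity class
    (depression overlaps those classes and is reported separately); QALYs
    and costs are discounted.
    """

    life_years_disease_free: float
    life_years_single: float
    life_years_dual: float
    life_years_triple: float
    life_years_quadruple: float
    life_years_depressed: float
    total_life_years: float
    qalys_discounted: float
    cost_intervention_active: float
    cost_intervention_inactive: float
    cost_utilisation: float
    cost_total: float
    qalys_discounted_alt: float | None = None

    @property
    def cost_intervention_total(self) -> float:
        return self.cost_intervention_active + self.cost_intervention_inactive


def _per_age(table: np.ndarray) -> np.ndarray:
    """Expand a band-indexed last axis to single years of age."""
    return table[..., BAND_OF_AGE]


def _transition_tensor(
    draw: ParameterDraw, sex_index: int, multipliers: np.ndarray | None
) -> np.ndarray:
    """Per-age (16+dead, 16+dead) one-cycle transition tensor for one sex.

    ``multipliers`` is an optional (4 diseases, 71 ages) array applied to
    the healthy state's incidence probabilities.  Competing incidence risks
    whose sum exceeds 1 are renormalised with a warning.
    """
    tp = _per_age(draw.transition_prob[:, sex_index, :])  # (32, ages)
    dp = _per_age(draw.death_prob[:, sex_index, :])  # (16, ages)
    n = ss.N_COMBOS
    P = np.zeros((N_AGES, n + 1, n + 1))
    P[:, n, n] = 1.0
    for ci in range(n):
        out = _OUT_TRANSITIONS[ci]
        p = tp[out].copy() if out else np.zeros((0, N_AGES))
        if ci == _ATRISK and multipliers is not None:
            p *= multipliers[_DISEASE_OF_TRANSITION[out]]
        total = p.sum(axis=0)
        over = total > 1.0
        if np.any(over):
            logger.warning(
                "renormalising competing incidence risks for combo %s at %d ages",
                ss.combo_name(ss.ALL_COMBOS[ci]),
                int(over.sum()),
            )
            p[:, over] /= total[over]
            total = np.minimum(total, 1.0)
        d = dp[ci]
        surv = 1.0 - d
        P[:, ci, n] = d
        for k, ti in enumerate(out):
            P[:, ci, _TO_COMBO[ti]] += surv * p[k]
        P[:, ci, ci] = surv * (1.0 - total)
    return P


def step_cycle(
    alive: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Advance combination-level occupancy one cycle.

    ``alive`` is (ages, 16 combos).  Returns the next occupancy (after
    ageing), the new deaths and the alive mass exiting past age 100.
    """
    stepped = np.einsum("afg,af->ag", P[:, : ss.N_COMBOS, : ss.N_COMBOS], alive)
    deaths = float(alive.sum() - stepped.sum())
    nxt = np.zeros_like(stepped)
    nxt[1:] = stepped[:-1]
    exited = float(stepped[-1].sum())
    return nxt, deaths, exited


def _depression_split(alive: np.ndarray, prev_age: np.ndarray) -> np.ndarray:
    """Expand (ages, 16) combo mass to the 32-state snapshot via depression
    prevalence per (combo, age)."""
    out = np.zeros((N_AGES, ss.N_ALIVE_STATES))
    out[:, _STATE_OF[:, 0]] = alive * (1.0 - prev_age.T)
    out[:, _STATE_OF[:, 1]] = alive * prev_age.T
    return out


def run_cohort(
    inputs: ModelInputs,
    draw: ParameterDraw,
    scenario: str,
    spec: InterventionSpec,
) -> CohortTrace:
    """Run one 70-cycle scenario ('intervention' or 'standard_care').

    Incidence multipliers derived from the draw's odds ratio apply only
    under the intervention scenario, only to transitions out of the
    healthy state, and only during the first ``spec.duration_years``
    cycles.
    """
    if scenario not in ("intervention", "standard_care"):
        raise ValueError(f"unknown scenario {scenario!r}")
    mult = (
        multiplier_schedule(spec, draw.or_draw, inputs)
        if scenario == "intervention" and spec.duration_years > 0
        else None
    )

    occupancy = np.zeros((2, N_CYCLES + 1, N_AGES, ss.N_ALIVE_STATES))
    dead = np.zeros((2, N_CYCLES + 1))
    exited = np.zeros((2, N_CYCLES + 1))

    for si in range(2):
        P_base = _transition_tensor(draw, si, None)
        P_int = _transition_tensor(draw, si, mult[:, si, :]) if mult is not None else None
        prev_age = _per_age(draw.depression_prev[:, si, :])  # (16, ages)

        alive = np.zeros((N_AGES, ss.N_COMBOS))
        # entrants are healthy and, having had prevalent disease (incl.
        # depression) excluded, start not depressed
        alive[:, _ATRISK] = inputs.initial_cohort[si]
        occupancy[si, 0, :, _STATE_OF[_ATRISK, 0]] = inputs.initial_cohort[si]

        for t in range(N_CYCLES):
            P = P_int if (P_int is not None and t < spec.duration_years) else P_base
            alive, deaths_t, exited_t = step_cycle(alive, P)
            dead[si, t + 1] = dead[si, t] + deaths_t
            exited[si, t + 1] = exited[si, t] + exited_t
            occupancy[si, t + 1] = _depression_split(alive, prev_age)

    return CohortTrace(
        occupancy=occupancy,
        dead=dead,
        exited=exited,
        entrants=float(inputs.initial_cohort.sum()),
    )


def _hcc(series: np.ndarray) -> np.ndarray:
    """Half-cycle corrected per-cycle values from N_CYCLES+1 snapshots."""
    return 0.5 * (series[..., :-1] + series[..., 1:])


def _discount_factors(rate: float) -> np.ndarray:
    return (1.0 + rate) ** -np.arange(N_CYCLES)


def summarise(
    trace: CohortTrace,
    draw: ParameterDraw,
    spec: InterventionSpec,
    scenario: str,
    inputs: ModelInputs,
    discount_rate_costs: float = 0.035,
    discount_rate_qalys: float = 0.035,
    discount_rate_qalys_alt: float | None = None,
) -> OutcomeSummary:
    """Aggregate a trace into per-1,000-entrant outcomes.

    Intervention costs accrue on healthy-state occupancy during the
    intervention cycles (intervention scenario only): the active share of
    each stratum incurs screening at ``screening_cost_fraction`` of one
    consultation per year, the non-active share the full annual
    intervention cost.  Activity shares are the baseline (unshifted)
    distribution.
    """
    per_1000 = 1000.0 / trace.entrants
    occ = trace.occupancy  # (2, cycles+1, ages, 32)

    # life years by physical-morbidity class (undiscounted)
    class_mass = np.zeros((5, N_CYCLES + 1))
    for k in range(5):
        sel = _CLASS_OF_STATE == k
        class_mass[k] = occ[:, :, :, sel].sum(axis=(0, 2, 3))
    ly_class = _hcc(class_mass).sum(axis=1) * per_1000
    dep_mass = occ[:, :, :, _DEPRESSED_STATE].sum(axis=(0, 2, 3))
    ly_dep = float(_hcc(dep_mass).sum()) * per_1000

    # QALYs: utility per (state, age) applied at each snapshot
    q = np.einsum("scak,ka->sc", occ, draw.utility)
    q_tot = q.sum(axis=0)
    qalys = float((_hcc(q_tot) * _discount_factors(discount_rate_qalys)).sum()) * per_1000
    qalys_alt = (
        float((_hcc(q_tot) * _discount_factors(discount_rate_qalys_alt)).sum()) * per_1000
        if discount_rate_qalys_alt is not None
        else None
    )

    # utilisation costs: per-state annual cost by (sex, age)
    cost_snap = np.zeros((2, N_CYCLES + 1))
    for si in range(2):
        cost_state_age = np.empty((ss.N_ALIVE_STATES, N_AGES))
        for dep in (0, 1):
            cost_state_age[_STATE_OF[:, dep]] = _per_age(draw.state_cost[:, dep, si, :])
        cost_snap[si] = np.einsum("cak,ka->c", occ[si], cost_state_age)
    df_cost = _discount_factors(discount_rate_costs)
    cost_util = float((_hcc(cost_snap.sum(axis=0)) * df_cost).sum()) * per_1000

    # intervention costs on healthy-state occupancy
    cost_int_active = cost_int_inactive = 0.0
    if scenario == "intervention" and spec.duration_years > 0:
        active_share = inputs.activity[:, :, 2][:, BAND_OF_AGE]  # (2, ages)
        atrisk = occ[:, :, :, _STATE_OF[_ATRISK, 0]] + occ[:, :, :, _STATE_OF[_ATRISK, 1]]
        screening_pp = spec.screening_cost_fraction * inputs.unit_costs.consultation
        act = np.einsum("sca,sa->c", atrisk, active_share * screening_pp)
        inact = np.einsum("sca,sa->c", atrisk, (1.0 - active_share) * spec.annual_cost_inactive)
        on = np.arange(N_CYCLES) < spec.duration_years
        cost_int_active = float((_hcc(act) * df_cost * on).sum()) * per_1000
        cost_int_inactive = float((_hcc(inact) * df_cost * on).sum()) * per_1000

    total_ly = float(ly_class.sum())
    return OutcomeSummary(
        life_years_disease_free=float(ly_class[0]),
        life_years_single=float(ly_class[1]),
        life_years_dual=float(ly_class[2]),
        life_years_triple=float(ly_class[3]),
        life_years_quadruple=float(ly_class[4]),
        life_years_depressed=ly_dep,
        total_life_years=total_ly,
        qalys_discounted=qalys,
        cost_intervention_active=cost_int_active,
        cost_intervention_inactive=cost_int_inactive,
        cost_utilisation=cost_util,
        cost_total=cost_util + cost_int_active + cost_int_inactive,
        qalys_discounted_alt=qalys_alt,
    )
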