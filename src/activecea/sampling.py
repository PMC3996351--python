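"""Probabilistic parameter sampling for the sensitivity analysis.

One :class:`ParameterDraw` holds a complete realisation of every sampled
quantity: annual transition/death/depression probabilities drawn from beta
posteriors of the observed events and person-years (Jeffreys prior, so a
stratum with zero events still yields a proper draw), per-state annual
costs from moment-matched gamma distributions, per-state utilities from
moment-matched beta distributions around the additive catalogue means, and
the trial odds ratio from a log-normal matched to its 95 % interval.

A single draw serves both the intervention and standard-care runs of a
simulation (common random numbers), so paired differences isolate the
intervention effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from activecea import state_space as ss
from activecea.inputs import AGES, N_AGES, N_BANDS, ModelInputs, TrialEffect, UtilityCatalogue

__all__ = [
    "ParameterDraw",
    "draw_transition_prob",
    "draw_state_cost",
    "state_utility",
    "draw_state_utility",
    "draw_odds_ratio",
    "make_parameter_draw",
    "simulation_rng",
]


@dataclass
class ParameterDraw:
    """One PSA realisation of every model quantity.

    Array axes follow the canonical orders of :mod:`activecea.state_space`
    and :mod:`activecea.inputs`:

    - ``transition_prob``: (32 transitions, 2 sexes, 7 bands)
    - ``death_prob``, ``depression_prev``: (16 combos, 2, 7)
    - ``state_cost``: (16 combos, 2 depressed, 2 sexes, 7 bands), GBP/year
    - ``utility``: (32 alive states, 71 ages 30-100)
    - ``or_draw``: scalar trial odds ratio
    """

    transition_prob: np.ndarray
    death_prob: np.ndarray
    depression_prev: np.ndarray
    state_cost: np.ndarray
    utility: np.ndarray
    or_draw: float


def draw_transition_prob(events, person_years, rng: np.random.Generator):
    """Draw annual probabilities from Beta(events + 1/2, person_years - events + 1/2).

    ``events`` and ``person_years`` may be scalars or broadcastable arrays.
    Event counts are treated directly as annual risks over the person-year
    denominator (no rate-to-probability transform); the beta-binomial
    posterior with a Jeffreys prior keeps the draw proper at zero events.
    """
    events = np.asarray(events, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    if np.any(person_years <= 0):
        raise ValueError("person_years must be positive")
    if np.any(events < 0) or np.any(events > person_years):
        raise ValueError("events must satisfy 0 <= events <= person_years")
    return rng.beta(events + 0.5, person_years - events + 0.5)


def draw_state_cost(mean, sd, rng: np.random.Generator):
    """Gamma draw with shape mean^2/sd^2 and scale sd^2/mean (method of moments).

    ``sd = 0`` degenerates to the mean.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("cost mean must be positive")
    if np.any(sd < 0):
        raise ValueError("cost sd must be non-negative")
    out = np.where(
        sd == 0,
        mean,
        rng.gamma(np.where(sd > 0, mean**2 / np.where(sd > 0, sd, 1.0) ** 2, 1.0),
                  np.where(sd > 0, sd**2 / mean, 1.0)),
    )
    return out if out.ndim else float(out)


def state_utility(catalogue: UtilityCatalogue, state: ss.HealthState, age: float) -> float:
    """Mean utility of an alive state at a given age, from the additive catalogue.

    baseline(43) + (age - 43) x slope + per-condition decrements (depression
    included) + the count decrement once two or more conditions are present,
    clamped to [0, 1].
    """
    if state.is_dead:
        raise ValueError("utility undefined for Dead")
    if not 30 <= age <= 100:
        raise ValueError(f"age {age} outside the modelled range 30-100")
    u = catalogue.baseline_at_43 + (age - 43.0) * catalogue.age_slope_per_year
    for d in state.combo:
        u += catalogue.decrement[d]
    if state.depressed:
        u += catalogue.decrement["DEPRESSION"]
    k = ss.condition_count(state)
    if k >= 2:
        u += catalogue.count_decrement[k]
    return float(min(max(u, 0.0), 1.0))


def draw_state_utility(mean, se, rng: np.random.Generator):
    """Beta draw moment-matched to (mean, se); ``se = 0`` returns the mean.

    Moment matching: nu = mean(1-mean)/se^2 - 1, alpha = mean*nu,
    beta = (1-mean)*nu; raises if the se is too large for a valid beta.
    """
    mean = np.asarray(mean, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(mean <= 0) or np.any(mean >= 1):
        raise ValueError("utility mean must be in (0, 1)")
    if np.any(se < 0):
        raise ValueError("utility se must be >= 0")
    nu = np.where(se > 0, mean * (1 - mean) / np.where(se > 0, se, 1.0) ** 2 - 1.0, 1.0)
    if np.any((se > 0) & (nu <= 0)):
        raise ValueError("utility se too large for a valid beta distribution")
    out = np.where(se == 0, mean, rng.beta(mean * nu, (1 - mean) * nu))
    return out if out.ndim else float(out)


def draw_odds_ratio(trial: TrialEffect, rng: np.random.Generator) -> float:
    """Log-normal draw with log-mean ln(OR) and log-SD from the 95 % CI width."""
    if trial.ci_low <= 0 or trial.ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    log_sd = (np.log(trial.ci_high) - np.log(trial.ci_low)) / (2 * 1.959963984540054)
    return float(np.exp(rng.normal(np.log(trial.odds_ratio), log_sd)))


def make_parameter_draw(
    inputs: ModelInputs,
    rng: np.random.Generator,
    utility_se: float = 0.02,
) -> ParameterDraw:
    """Draw one coherent realisation of every model quantity.

    Utilities are sampled once per alive state around the composed
    catalogue mean at the reference age of 43 (standard error
    ``utility_se``), then shifted deterministically by the age slope and
    clamped to [0, 1]; the same draw is used across ages so a state's
    utility profile moves as one block.
    """
    transition_prob = draw_transition_prob(inputs.incidence_events, inputs.incidence_py, rng)
    death_prob = draw_transition_prob(inputs.mortality_events, inputs.mortality_py, rng)
    depression_prev = draw_transition_prob(inputs.depression_events, inputs.depression_py, rng)
    state_cost = draw_state_cost(inputs.cost_mean, inputs.cost_sd, rng)

    cat = inputs.utilities
    mean43 = np.array([state_utility(cat, s, 43.0) for s in ss.ALIVE_STATES])
    u43 = draw_state_utility(np.clip(mean43, 1e-6, 1 - 1e-6), utility_se, rng)
    utility = np.clip(
        u43[:, None] + (AGES[None, :] - 43.0) * cat.age_slope_per_year, 0.0, 1.0
    )

    return ParameterDraw(
        transition_prob=transition_prob,
        death_prob=death_prob,
        depression_prev=depression_prev,
        state_cost=state_cost,
        utility=utility,
        or_draw=draw_odds_ratio(inputs.trial, rng),
    )


def simulation_rng(master_seed: int, simulation_index: int) -> np.random.Generator:
    """Independent substream for one simulation: SeedSequence(master_seed) spawn key
    ``(simulation_index,)``.  Deterministic in (master_seed, simulation_index)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(simulation_index,))
    )
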