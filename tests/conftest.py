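import numpy as np
import pytest

from activecea import state_space as ss
from activecea.config import SyntheticConfig
from activecea.inputs import N_BANDS
from activecea.sampling import ParameterDraw
from activecea.synthetic import generate_model_inputs


@pytest.fixture(scope="session")
def default_inputs():
    """Default synthetic input set, seed 1 (shared read-only across tests)."""
    return generate_model_inputs(SyntheticConfig(), seed=1)


@pytest.fixture(scope="session")
def small_inputs():
    """Synthetic inputs with a 10,000-person cohort, seed 1."""
    return generate_model_inputs(SyntheticConfig(cohort_size=10_000), seed=1)


def constant_draw(
    *,
    incidence: dict[tuple[frozenset, str], float] | float = 0.0,
    death: dict[frozenset, float] | float = 0.0,
    depression: float = 0.0,
    cost: float = 0.0,
    utility: float = 1.0,
    or_draw: float = 1.0,
) -> ParameterDraw:
    """A deterministic ParameterDraw with hand-set probabilities.

    ``incidence`` maps (from_combo, disease) to an annual probability (or a
    single scalar for all transitions); ``death`` maps combos to annual
    death probabilities (or one scalar).  Everything is uniform across sex
    and age band.
    """
    n_tr = len(ss.INCIDENCE_TRANSITIONS)
    tp = np.zeros((n_tr, 2, N_BANDS))
    if isinstance(incidence, dict):
        for ti, tr in enumerate(ss.INCIDENCE_TRANSITIONS):
            tp[ti] = incidence.get((tr.from_combo, tr.disease), 0.0)
    else:
        tp[:] = incidence
    dp = np.zeros((ss.N_COMBOS, 2, N_BANDS))
    if isinstance(death, dict):
        for ci, combo in enumerate(ss.ALL_COMBOS):
            dp[ci] = death.get(combo, 0.0)
    else:
        dp[:] = death
    return ParameterDraw(
        transition_prob=tp,
        death_prob=dp,
        depression_prev=np.full((ss.N_COMBOS, 2, N_BANDS), depression),
        state_cost=np.full((ss.N_COMBOS, 2, 2, N_BANDS), cost),
        utility=np.full((ss.N_ALIVE_STATES, 71), utility),
        or_draw=or_draw,
    )


def single_person_inputs(base, age: int = 30, sex: str = "male"):
    """Copy of an input set whose initial cohort is one person at one age."""
    out = base.copy()
    out.initial_cohort = np.zeros_like(out.initial_cohort)
    out.initial_cohort[0 if sex == "male" else 1, age - 30] = 1.0
    return out
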