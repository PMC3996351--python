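"""Health-state space of the multimorbidity Markov model.

Alive states are every subset of the four physical diseases (type 2
diabetes ``DM``, coronary heart disease ``CHD``, stroke ``STROKE``,
colorectal cancer ``CRC``) crossed with a depressed flag: 16 disease
combinations x 2 = 32 alive states, plus one absorbing ``Dead`` state.
Diseases are chronic and irreversible, so the only legal physical
transitions add exactly one disease (32 incidence transitions) or move to
death (16 mortality transitions, one per disease combination).

Canonical ordering, used for every occupancy vector and CSV column in the
package: disease combinations sorted by (size, lexicographic position in
the fixed disease order DM < CHD < STROKE < CRC); within a combination the
not-depressed state precedes the depressed one; Dead comes last.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "DISEASES",
    "MorbidityClass",
    "DiseaseCombo",
    "HealthState",
    "DEAD",
    "IncidenceTransition",
    "all_combos",
    "enumerate_alive_states",
    "enumerate_incidence_transitions",
    "condition_count",
    "morbidity_class",
    "state_name",
    "parse_state_name",
    "ALL_COMBOS",
    "ALIVE_STATES",
    "COMBO_INDEX",
    "STATE_INDEX",
    "INCIDENCE_TRANSITIONS",
    "N_COMBOS",
    "N_ALIVE_STATES",
]

#: Fixed disease order used for canonical sorting.
DISEASES: tuple[str, ...] = ("DM", "CHD", "STROKE", "CRC")

_DISEASE_RANK = {d: i for i, d in enumerate(DISEASES)}

DiseaseCombo = frozenset  # a frozenset of disease codes, subset of DISEASES


class MorbidityClass(str, Enum):
    """Physical-morbidity class of a state, by count of physical diseases only."""

    DISEASE_FREE = "disease_free"
    SINGLE = "single"
    DUAL = "dual"
    TRIPLE = "triple"
    QUADRUPLE = "quadruple"
    DEAD = "dead"


@dataclass(frozen=True)
class HealthState:
    """An alive model state (disease combination + depression flag) or Dead.

    ``combo is None`` marks the distinguished absorbing Dead state; use the
    module-level singleton :data:`DEAD`.
    """

    combo: DiseaseCombo | None
    depressed: bool = False

    @property
    def is_dead(self) -> bool:
        return self.combo is None

    @property
    def name(self) -> str:
        return state_name(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"HealthState({self.name})"


DEAD = HealthState(combo=None, depressed=False)


@dataclass(frozen=True)
class IncidenceTransition:
    """A legal disease-acquisition transition: ``to_combo = from_combo | {disease}``."""

    from_combo: DiseaseCombo
    to_combo: DiseaseCombo

    @property
    def disease(self) -> str:
        """The single disease acquired by this transition."""
        (d,) = self.to_combo - self.from_combo
        return d


def _combo_sort_key(combo: DiseaseCombo) -> tuple:
    return (len(combo), tuple(sorted(_DISEASE_RANK[d] for d in combo)))


def all_combos() -> list[DiseaseCombo]:
    """All 16 disease combinations (including the empty 'At Risk' set), canonical order."""
    combos = [
        frozenset(c)
        for k in range(len(DISEASES) + 1)
        for c in itertools.combinations(DISEASES, k)
    ]
    return sorted(combos, key=_combo_sort_key)


def enumerate_alive_states() -> list[HealthState]:
    """The 32 alive states in canonical order (not-depressed before depressed)."""
    return [
        HealthState(combo=c, depressed=dep)
        for c in all_combos()
        for dep in (False, True)
    ]


def enumerate_incidence_transitions() -> list[IncidenceTransition]:
    """The 32 transitions adding exactly one disease, ordered by (from-combo, disease)."""
    out = []
    for combo in all_combos():
        for d in DISEASES:
            if d not in combo:
                out.append(IncidenceTransition(combo, combo | {d}))
    return out


def condition_count(state: HealthState) -> int:
    """Number of chronic conditions in a state, counting depression.

    Drives the multimorbidity utility decrement, which is catalogued for
    2-5 conditions; five conditions are only reachable when depression is
    counted alongside the four physical diseases.
    """
    if state.is_dead:
        raise ValueError("no conditions defined for Dead")
    return len(state.combo) + (1 if state.depressed else 0)


_CLASS_BY_SIZE = (
    MorbidityClass.DISEASE_FREE,
    MorbidityClass.SINGLE,
    MorbidityClass.DUAL,
    MorbidityClass.TRIPLE,
    MorbidityClass.QUADRUPLE,
)


def morbidity_class(state: HealthState) -> MorbidityClass:
    """Physical-morbidity class by disease count only; depression never changes it."""
    if state.is_dead:
        return MorbidityClass.DEAD
    return _CLASS_BY_SIZE[len(state.combo)]


def combo_name(combo: DiseaseCombo) -> str:
    return "+".join(sorted(combo)) if combo else "ATRISK"


def state_name(state: HealthState) -> str:
    """Serialised state name, e.g. ``CHD+DM.dep``, ``ATRISK.nodep``, ``DEAD``."""
    if state.is_dead:
        return "DEAD"
    return f"{combo_name(state.combo)}.{'dep' if state.depressed else 'nodep'}"


def parse_state_name(name: str) -> HealthState:
    """Inverse of :func:`state_name`."""
    if name == "DEAD":
        return DEAD
    try:
        combo_part, dep_part = name.rsplit(".", 1)
        depressed = {"dep": True, "nodep": False}[dep_part]
    except (ValueError, KeyError):
        raise ValueError(f"malformed state name {name!r}") from None
    combo = frozenset() if combo_part == "ATRISK" else frozenset(combo_part.split("+"))
    if not combo <= frozenset(DISEASES):
        raise ValueError(f"unknown disease code in state name {name!r}")
    return HealthState(combo=combo, depressed=depressed)


def parse_combo_name(name: str) -> DiseaseCombo:
    combo = frozenset() if name == "ATRISK" else frozenset(name.split("+"))
    if not combo <= frozenset(DISEASES):
        raise ValueError(f"unknown disease code in combo name {name!r}")
    return combo


# Canonical, module-level enumerations; index maps are the package-wide
# coordinate system for occupancy vectors and parameter arrays.
ALL_COMBOS: tuple[DiseaseCombo, ...] = tuple(all_combos())
ALIVE_STATES: tuple[HealthState, ...] = tuple(enumerate_alive_states())
INCIDENCE_TRANSITIONS: tuple[IncidenceTransition, ...] = tuple(
    enumerate_incidence_transitions()
)
COMBO_INDEX: dict[DiseaseCombo, int] = {c: i for i, c in enumerate(ALL_COMBOS)}
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(ALIVE_STATES)}
N_COMBOS = len(ALL_COMBOS)
N_ALIVE_STATES = len(ALIVE_STATES)
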