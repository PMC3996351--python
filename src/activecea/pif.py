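"""Potential impact fraction: trial effect on activity -> incidence multipliers.

The trial odds ratio for a sedentary participant becoming active is
converted to an absolute excess conversion probability via the control-arm
event rate; that fraction of the inactive and insufficiently-active mass
is moved into the active category of each age/sex activity distribution.
The potential impact fraction for a disease then compares relative-risk-
weighted exposure sums before and after the shift; the model applies the
complement ``1 - PIF`` as a multiplier on disease incidence out of the
healthy ('At Risk') state during the intervention years.
"""

from __future__ import annotations

import numpy as np

from activecea import state_space as ss
from activecea.config import InterventionSpec
from activecea.inputs import AGES, BAND_OF_AGE, ModelInputs, TrialEffect

__all__ = ["shifted_activity", "pif_multiplier", "multiplier_schedule"]


def shifted_activity(dist_row: np.ndarray, trial: TrialEffect, or_draw: float) -> np.ndarray:
    """Post-intervention activity shares for one stratum.

    ``dist_row`` is (inactive, insufficiently_active, active) and must sum
    to 1.  The excess conversion probability is ``p1 - p0`` where ``p0`` is
    the control event rate and ``p1`` the odds-ratio-shifted probability;
    that fraction of both non-active categories moves into 'active',
    removed from each in proportion to its size.  A draw below 1 moves mass
    the other way.
    """
    dist_row = np.asarray(dist_row, dtype=float)
    if dist_row.shape[-1] != 3 or np.any(np.abs(dist_row.sum(axis=-1) - 1.0) > 1e-9):
        raise ValueError("activity row must have 3 categories summing to 1")
    if or_draw <= 0:
        raise ValueError("odds ratio draw must be positive")
    if or_draw == 1.0:  # null effect is exactly null
        return np.array(dist_row, dtype=float, copy=True)
    p0 = trial.control_event_rate
    odds1 = or_draw * p0 / (1 - p0)
    delta = odds1 / (1 + odds1) - p0
    non_active = dist_row[..., 0] + dist_row[..., 1]
    moved = delta * non_active
    out = dist_row.copy()
    safe = np.where(non_active > 0, non_active, 1.0)[..., np.newaxis]
    frac = np.where(non_active[..., np.newaxis] > 0, dist_row[..., :2] / safe, 0.0)
    out[..., :2] -= moved[..., np.newaxis] * frac
    out[..., 2] += moved
    return out


def pif_multiplier(dist_row: np.ndarray, shifted_row: np.ndarray, rr_row: np.ndarray):
    """Incidence multiplier ``1 - PIF`` for one disease and stratum.

    ``rr_row`` holds relative risks (inactive, insufficiently_active) with
    the active category as reference (RR = 1).  Returns the ratio of
    RR-weighted exposure sums, shifted over baseline.
    """
    dist_row = np.asarray(dist_row, dtype=float)
    shifted_row = np.asarray(shifted_row, dtype=float)
    for row in (dist_row, shifted_row):
        if np.any(np.abs(row.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("activity rows must sum to 1")
    weights = np.concatenate([np.asarray(rr_row, dtype=float), [1.0]])
    num = shifted_row @ weights
    den = dist_row @ weights
    return num / den


def multiplier_schedule(
    spec: InterventionSpec, or_draw: float, inputs: ModelInputs
) -> np.ndarray:
    """Incidence multipliers per (disease, sex, single year of age) at cycle 0..duration-1.

    Returns an array of shape (4, 2, 71).  Activity shares and relative
    risks are band-level inputs held constant within each band, so the
    single-year schedule is a band-wise expansion.  The multipliers apply
    only to transitions leaving the healthy state; the cohort engine
    substitutes 1 everywhere else and for cycles at or beyond the
    intervention duration.
    """
    n_d = len(ss.DISEASES)
    mult = np.ones((n_d, 2, AGES.size))
    for si in range(2):
        base = inputs.activity[si]  # (bands, 3)
        shifted = shifted_activity(base, inputs.trial, or_draw)
        for di in range(n_d):
            band_mult = pif_multiplier(base, shifted, inputs.rr[di])  # (bands,)
            mult[di, si] = band_mult[BAND_OF_AGE]
    return mult
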