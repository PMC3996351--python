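"""Probabilistic sensitivity analysis and cost-effectiveness outputs.

Each simulation draws one parameter set, runs the paired intervention and
standard-care cohorts under it (common random numbers) and stores the
per-simulation outcome pair; incremental costs and QALYs are the paired
differences.  Summaries report means with equal-tail 95 % percentile
intervals across simulations, direction probabilities, net health benefit
at a willingness-to-pay threshold, the cost-effectiveness acceptability
curve and a 95 % bivariate-normal ellipse on the cost-effectiveness plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from activecea.config import InterventionSpec
from activecea.engine import OutcomeSummary, run_cohort, summarise
from activecea.inputs import ModelInputs
from activecea.sampling import make_parameter_draw, simulation_rng

__all__ = ["PSAResult", "net_health_benefit", "run_psa", "summarise_psa", "ceac"]

logger = logging.getLogger(__name__)

#: Base-case willingness-to-pay threshold, GBP per QALY.
DEFAULT_THRESHOLD = 30_000.0

_LY_FIELDS = (
    "life_years_disease_free",
    "life_years_single",
    "life_years_dual",
    "life_years_triple",
    "life_years_quadruple",
    "life_years_depressed",
    "total_life_years",
)
# outcomes where the hypothesised intervention direction is a reduction
_LOWER_IS_EFFECT = {
    "life_years_single",
    "life_years_dual",
    "life_years_triple",
    "life_years_quadruple",
    "life_years_depressed",
    "cost_utilisation",
}


def net_health_benefit(delta_qaly, delta_cost, threshold: float = DEFAULT_THRESHOLD):
    """NHB = incremental QALYs minus incremental costs divided by the threshold.

    Positive NHB at threshold lambda is equivalent to an incremental
    cost-effectiveness ratio below lambda (for positive QALY gains).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(delta_qaly) - np.asarray(delta_cost) / threshold


@dataclass
class PSAResult:
    """Paired per-simulation outcomes of one intervention duration."""

    spec: InterventionSpec
    intervention: list[OutcomeSummary]
    control: list[OutcomeSummary]
    master_seed: int

    def __len__(self) -> int:
        return len(self.intervention)

    def _col(self, summaries: list[OutcomeSummary], name: str) -> np.ndarray:
        if name == "cost_intervention_total":
            return np.array([s.cost_intervention_total for s in summaries])
        vals = [getattr(s, name) for s in summaries]
        return np.array([np.nan if v is None else v for v in vals], dtype=float)

    def increments(self, name: str) -> np.ndarray:
        """Per-simulation paired difference (intervention minus standard care)."""
        return self._col(self.intervention, name) - self._col(self.control, name)

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.increments("qalys_discounted")

    @property
    def delta_cost_total(self) -> np.ndarray:
        return self.increments("cost_total")

    @property
    def delta_cost_utilisation(self) -> np.ndarray:
        return self.increments("cost_utilisation")

    def nhb(self, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
        return net_health_benefit(self.delta_qaly, self.delta_cost_total, threshold)


def run_psa(
    inputs: ModelInputs,
    spec: InterventionSpec,
    n_simulations: int = 2000,
    master_seed: int = 2013,
    utility_se: float = 0.02,
    discount_costs: float = 0.035,
    discount_qalys: float = 0.035,
    discount_qalys_alt: float | None = 0.015,
) -> PSAResult:
    """Run the paired PSA for one intervention duration.

    Deterministic under ``master_seed``: simulation ``s`` uses the seed
    substream ``(master_seed, s)``, and the same parameter draw serves both
    scenarios so increments are paired.
    """
    inter: list[OutcomeSummary] = []
    control: list[OutcomeSummary] = []
    for s in range(n_simulations):
        rng = simulation_rng(master_seed, s)
        draw = make_parameter_draw(inputs, rng, utility_se=utility_se)
        for scenario, store in (("intervention", inter), ("standard_care", control)):
            trace = run_cohort(inputs, draw, scenario, spec)
            store.append(
                summarise(
                    trace,
                    draw,
                    spec,
                    scenario,
                    inputs,
                    discount_rate_costs=discount_costs,
                    discount_rate_qalys=discount_qalys,
                    discount_rate_qalys_alt=discount_qalys_alt,
                )
            )
        if (s + 1) % 100 == 0:
            logger.info("completed %d/%d simulations", s + 1, n_simulations)
    return PSAResult(spec=spec, intervention=inter, control=control, master_seed=master_seed)


def _mean_ci(x: np.ndarray) -> tuple[float, float, float]:
    return float(np.mean(x)), float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))


def ceac(result: PSAResult, thresholds: np.ndarray) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(NHB(lambda) > 0) over a grid."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    dq, dc = result.delta_qaly, result.delta_cost_total
    probs = [float(np.mean(net_health_benefit(dq, dc, lam) > 0)) for lam in thresholds]
    return pd.DataFrame(
        {
            "duration_years": result.spec.duration_years,
            "threshold": thresholds,
            "probability_cost_effective": probs,
        }
    )


def _ellipse_params(dq: np.ndarray, dc: np.ndarray, level: float = 0.95) -> dict:
    """95 % bivariate-normal contour of (delta QALY, delta cost): centre,
    principal half-axes and orientation from the sample mean/covariance."""
    from scipy import stats

    xy = np.column_stack([dq, dc])
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    chi2 = stats.chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return {
        "centre_qaly": float(mean[0]),
        "centre_cost": float(mean[1]),
        "half_axis_major": float(np.sqrt(chi2 * evals[0])),
        "half_axis_minor": float(np.sqrt(chi2 * max(evals[1], 0.0))),
        "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        "level": level,
    }


def summarise_psa(
    result: PSAResult,
    thresholds: np.ndarray,
    base_threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Report tables for one PSA: life-year outcomes, cost/QALY/NHB outcomes,
    CEAC and the cost-effectiveness plane.

    Returns a dict of DataFrames keyed ``table3`` (health outcomes),
    ``table4`` (economics), ``ceac``, ``ce_plane`` and ``ellipse``.  All
    intervals are equal-tail 2.5th-97.5th percentiles across simulations;
    probabilities are the fraction of simulations in the outcome's
    hypothesised direction (higher with intervention for disease-free and
    total life years and QALYs; lower for morbidity, depression and
    utilisation costs; higher for costs of intervention).
    """
    if len(result) == 0:
        raise ValueError("empty PSA result")
    dur = result.spec.duration_years

    rows = []
    for name in _LY_FIELDS:
        d = result.increments(name)
        mean, lo, hi = _mean_ci(d)
        lower = name in _LOWER_IS_EFFECT
        rows.append(
            {
                "duration_years": dur,
                "outcome": name,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "direction": "lower" if lower else "higher",
                "probability_pct": 100.0 * float(np.mean(d < 0 if lower else d > 0)),
            }
        )
    table3 = pd.DataFrame(rows)

    dq, dc = result.delta_qaly, result.delta_cost_total
    nhb = result.nhb(base_threshold)
    econ_cols = {
        "cost_intervention_active": result.increments("cost_intervention_active"),
        "cost_intervention_inactive": result.increments("cost_intervention_inactive"),
        "cost_intervention_total": result.increments("cost_intervention_total"),
        "cost_utilisation": result.delta_cost_utilisation,
        "cost_total": dc,
        "qalys_discounted": dq,
        "nhb": nhb,
    }
    alt = result.increments("qalys_discounted_alt")
    if not np.any(np.isnan(alt.astype(float))):
        econ_cols["qalys_discounted_alt"] = alt.astype(float)
    rows = []
    for name, d in econ_cols.items():
        mean, lo, hi = _mean_ci(d)
        lower = name in _LOWER_IS_EFFECT
        rows.append(
            {
                "duration_years": dur,
                "outcome": name,
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "direction": "lower" if lower else "higher",
                "probability_pct": 100.0 * float(np.mean(d < 0 if lower else d > 0)),
            }
        )
    rows.append(
        {
            "duration_years": dur,
            "outcome": f"probability_cost_effective_at_{int(base_threshold)}",
            "mean": 100.0 * float(np.mean(nhb > 0)),
            "ci_low": np.nan,
            "ci_high": np.nan,
            "direction": "higher",
            "probability_pct": 100.0 * float(np.mean(nhb > 0)),
        }
    )
    table4 = pd.DataFrame(rows)

    ce_plane = pd.DataFrame(
        {
            "duration_years": dur,
            "simulation": np.arange(len(result)),
            "delta_qaly": dq,
            "delta_cost": dc,
        }
    )
    ellipse = pd.DataFrame([{"duration_years": dur, **_ellipse_params(dq, dc)}])
    return {
        "table3": table3,
        "table4": table4,
        "ceac": ceac(result, thresholds),
        "ce_plane": ce_plane,
        "ellipse": ellipse,
    }
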