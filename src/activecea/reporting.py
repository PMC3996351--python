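"""Human-readable summaries of PSA output tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["format_report", "OUTPUT_FILES"]

OUTPUT_FILES = ("table3.csv", "table4.csv", "ceac.csv", "ce_plane.csv", "ellipse.csv")

_LABELS = {
    "life_years_disease_free": "Life years lived without disease (per 1,000)",
    "life_years_single": "Life years with single condition (per 1,000)",
    "life_years_dual": "Life years with dual conditions (per 1,000)",
    "life_years_triple": "Life years with triple conditions (per 1,000)",
    "life_years_quadruple": "Life years with quadruple conditions (per 1,000)",
    "life_years_depressed": "Life years lived with depression (per 1,000)",
    "total_life_years": "Total life years (per 1,000)",
    "cost_intervention_active": "Intervention costs in physically active (GBP per 1,000)",
    "cost_intervention_inactive": "Intervention costs in physically inactive (GBP per 1,000)",
    "cost_intervention_total": "Total intervention costs (GBP per 1,000)",
    "cost_utilisation": "Incremental non-intervention utilisation costs (GBP per 1,000)",
    "cost_total": "Incremental total costs (GBP per 1,000)",
    "qalys_discounted": "Incremental QALYs, base discount (per 1,000)",
    "qalys_discounted_alt": "Incremental QALYs, sensitivity discount (per 1,000)",
    "nhb": "Net health benefits (QALYs per 1,000)",
}


def _fmt_row(r) -> str:
    label = _LABELS.get(r.outcome, r.outcome)
    if pd.isna(r.ci_low):
        return f"  {label}: {r.mean:.1f} %"
    return (
        f"  {label}: {r.mean:,.1f} ({r.ci_low:,.1f} to {r.ci_high:,.1f}); "
        f"P({r.direction} with intervention) = {r.probability_pct:.1f} %"
    )


def format_report(output_dir: str | Path) -> str:
    """Format the CSV outputs of a run into a markdown summary.

    Mirrors the layout of the health-outcome and cost-utility tables:
    per-duration blocks of incremental outcomes with 95 % intervals and
    direction probabilities.
    """
    d = Path(output_dir)
    for name in ("table3.csv", "table4.csv", "ceac.csv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing output {d / name}; run the model first")
    t3 = pd.read_csv(d / "table3.csv")
    t4 = pd.read_csv(d / "table4.csv")
    cc = pd.read_csv(d / "ceac.csv")

    lines = ["# Cohort simulation results", ""]
    for dur in sorted(t3["duration_years"].unique()):
        lines.append(f"## Intervention duration: {dur} years")
        lines.append("")
        lines.append("Health outcomes (difference, intervention - standard care):")
        for r in t3[t3.duration_years == dur].itertuples(index=False):
            lines.append(_fmt_row(r))
        lines.append("")
        lines.append("Costs and cost-utility (difference, intervention - standard care):")
        for r in t4[t4.duration_years == dur].itertuples(index=False):
            lines.append(_fmt_row(r))
        sub = cc[cc.duration_years == dur]
        if len(sub):
            mid = sub.iloc[(sub["threshold"] - 30_000).abs().argmin()]
            lines.append(
                f"  CEAC: P(cost-effective) = {100 * mid.probability_cost_effective:.1f} % "
                f"at GBP {mid.threshold:,.0f}/QALY "
                f"({len(sub)} grid points from {sub.threshold.min():,.0f} "
                f"to {sub.threshold.max():,.0f})"
            )
        lines.append("")
    return "\n".join(lines)
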