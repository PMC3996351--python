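"""Run configuration: study-design parameters, synthetic-input scales, intervention spec.

Defaults reproduce the base-case design: a cohort of 262,704 healthy
entrants, 2,000 paired simulations over 70 annual cycles, 3.5 % discounting
of costs and QALYs (1.5 % QALY sensitivity), intervention durations of 5
and 10 years, and intervention costs of one family-practice consultation
per inactive person-year (GBP 35) plus screening at 20 % of a consultation
(GBP 7) in the active.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["InterventionSpec", "SyntheticConfig", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass(frozen=True)
class InterventionSpec:
    """A brief physical-activity intervention offered to the healthy ('At Risk') state.

    Parameters
    ----------
    duration_years:
        Number of initial annual cycles in which the intervention is
        delivered and its incidence multipliers apply.
    annual_cost_inactive:
        Annual per-person cost (GBP) for participants who are inactive or
        insufficiently active.  Base case GBP 35 (one consultation);
        sensitivity presets GBP 70 (two consultations) and GBP 7.
    screening_cost_fraction:
        Fraction of one consultation spent per year confirming the
        activity status of already-active participants (0.20 base case).
    """

    duration_years: int = 5
    annual_cost_inactive: float = 35.0
    screening_cost_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.duration_years < 0:
            raise ConfigError("intervention duration must be >= 0 years")
        if self.annual_cost_inactive < 0:
            raise ConfigError("intervention cost must be >= 0")
        if not 0.0 <= self.screening_cost_fraction <= 1.0:
            raise ConfigError("screening cost fraction must be in [0, 1]")


#: Intervention unit-cost sensitivity presets (GBP per inactive person-year).
INTERVENTION_COST_PRESETS: tuple[float, ...] = (7.0, 35.0, 70.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Scales and shapes for the synthetic model-input generator.

    The generator emulates the statistical structure of stratified
    primary-care incidence / mortality / cost tables without claiming
    fidelity to any real registry; every magnitude here is configurable.

    Rates are annual.  ``incidence_per_10k_30s`` is the per-disease
    incidence per 10,000 person-years in the 30-39 band; incidence doubles
    with each decade of age.  ``mortality_hazard_factor`` multiplies the
    disease-free mortality hazard once per disease present (factors
    multiply across a combination, so mortality is monotone in the set of
    diseases).  Costs are GBP per person-year.
    """

    cohort_size: int = 262_704
    incidence_per_10k_30s: dict[str, float] = field(
        default_factory=lambda: {"DM": 12.0, "CHD": 10.0, "STROKE": 6.0, "CRC": 4.0}
    )
    incidence_doubling_per_decade: float = 2.0
    male_incidence_factor: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.1, "CHD": 1.4, "STROKE": 1.1, "CRC": 1.2}
    )
    mortality_base_30s: float = 4e-4
    mortality_log_slope_per_year: float = 0.085
    male_mortality_factor: float = 1.3
    mortality_hazard_factor: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.6, "CHD": 1.9, "STROKE": 2.2, "CRC": 2.8}
    )
    depression_prev_base: float = 0.07
    depression_prev_per_condition: float = 0.04
    cost_base_30s: float = 250.0
    cost_growth_per_band: float = 1.25
    cost_disease_add: dict[str, float] = field(
        default_factory=lambda: {"DM": 900.0, "CHD": 1100.0, "STROKE": 1400.0, "CRC": 2300.0}
    )
    cost_crc_comorbidity_add: float = 600.0
    cost_depression_add: float = 450.0
    cost_sd_to_mean: float = 1.0
    person_years_base: float = 100_000.0
    rate_jitter_sd: float = 0.05
    # activity shares (inactive, insufficiently_active, active) by age band,
    # youngest to oldest; active participation declines with age
    activity_by_band: tuple[tuple[float, float, float], ...] = (
        (0.25, 0.35, 0.40),
        (0.28, 0.35, 0.37),
        (0.32, 0.35, 0.33),
        (0.36, 0.35, 0.29),
        (0.40, 0.35, 0.25),
        (0.45, 0.35, 0.20),
        (0.50, 0.35, 0.15),
    )
    rr_inactive: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.45, "CHD": 1.90, "STROKE": 1.40, "CRC": 1.60}
    )
    rr_insufficient: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.15, "CHD": 1.40, "STROKE": 1.15, "CRC": 1.25}
    )

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ConfigError("cohort size must be positive")
        if len(self.activity_by_band) != 7:
            raise ConfigError("activity_by_band must cover the seven 10-year bands 30-100")
        for row in self.activity_by_band:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ConfigError(f"activity shares {row} do not sum to 1")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end PSA run configuration."""

    cohort_size: int = 262_704
    durations: tuple[int, ...] = (5, 10)
    n_simulations: int = 2000
    master_seed: int = 2013
    discount_costs: float = 0.035
    discount_qalys: float = 0.035
    discount_qalys_sensitivity: float = 0.015
    annual_cost_inactive: float = 35.0
    screening_cost_fraction: float = 0.20
    utility_se: float = 0.02
    threshold_min: float = 0.0
    threshold_max: float = 100_000.0
    threshold_step: float = 1_000.0

    def __post_init__(self) -> None:
        for r in (self.discount_costs, self.discount_qalys, self.discount_qalys_sensitivity):
            if not 0.0 <= r < 1.0:
                raise ConfigError("discount rates must be in [0, 1)")
        if self.n_simulations <= 0 or self.cohort_size <= 0:
            raise ConfigError("counts must be positive")
        if any(d < 0 or d > 70 for d in self.durations):
            raise ConfigError("intervention durations must be within the 70-cycle horizon")

    def intervention_spec(self, duration: int) -> InterventionSpec:
        return InterventionSpec(
            duration_years=duration,
            annual_cost_inactive=self.annual_cost_inactive,
            screening_cost_fraction=self.screening_cost_fraction,
        )

    def thresholds(self):
        import numpy as np

        grid = np.arange(
            self.threshold_min, self.threshold_max + self.threshold_step / 2, self.threshold_step
        )
        return grid[grid > 0] if grid.size and grid[0] == 0 else grid


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML mapping; missing keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    if "durations" in raw:
        raw["durations"] = tuple(raw["durations"])
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    d = asdict(config)
    d["durations"] = list(d["durations"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
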