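# Methods

## Model structure and assumptions

The model is a deterministic cohort (mass-propagation) simulation over a
multimorbidity state space: every subset of {type 2 diabetes, coronary
heart disease, stroke, colorectal cancer} crossed with a depressed /
not-depressed flag (32 alive states) plus absorbing death. Conditions are
chronic — no transition removes a disease — and at most one disease is
acquired per annual cycle (simultaneous onset has probability of order
p², which is negligible at the annual probabilities involved). The
perspective is health-care costs only, over a lifetime horizon: 70 annual
cycles carry every entrant (ages 30–100) to death or to exit at age 100.

Within a cycle, events are applied in the order **death → incidence →
depression re-partition → ageing**. Mortality is resolved first because
death probabilities are estimated per disease combination; incidence then
acts on survivors as competing risks (if a combination's summed incidence
probabilities exceed 1 — possible only under extreme draws — they are
renormalised and a warning logged). Depression is handled as a
*memoryless prevalence overlay*: each combination's survivors are
re-partitioned into depressed/not-depressed by the combination's
stratified prevalence every cycle. This matches estimation of depression
as prevalence rather than incidence, and encodes the assumptions that
depression affects neither mortality nor disease incidence — it affects
only utility and cost. Entrants are healthy and start not depressed; the
first re-partition applies at the end of the first cycle.

Because incidence and mortality are independent of depression, the
depression split does not alter combination-level dynamics; the engine
therefore propagates the 16-combination occupancy exactly and expands to
32 states at each snapshot. This makes the engine algebraically identical
to a per-age transition-matrix product, which the test suite exploits: a
collapsed 3-state chain must match explicit matrix powers to 1e-12.

## Parameter uncertainty

Each probabilistic-sensitivity-analysis (PSA) simulation draws one
complete parameter set and uses it for **both** scenarios (common random
numbers), so paired differences isolate the intervention effect:

- transition, death and depression probabilities:
  Beta(events + ½, person-years − events + ½). The Jeffreys prior keeps
  the posterior proper at zero events; at the large denominators involved
  it is indistinguishable from events/person-years. Event counts over
  person-years of annual follow-up are used directly as annual risks (no
  exponential rate-to-probability transform), appropriate for small
  annual probabilities; this is isolated in one function should the
  transform be preferred.
- annual state costs: gamma with shape = mean²/sd², scale = sd²/mean.
  Where an input table supplies no SD the generator uses SD = mean,
  reflecting the strong right skew typical of person-level cost data
  (configurable).
- utilities: the additive catalogue (baseline 0.828 at age 43, slope
  −0.00029/year, per-condition decrements with depression counted, and a
  condition-count decrement for 2–5 conditions — five being reachable
  only because depression counts toward the total) is composed into a
  per-state mean at age 43 and sampled once per state from a
  moment-matched beta with SE 0.02 (configurable); the age slope is then
  applied deterministically and the result clamped to [0, 1]. Sampling
  the composed per-state mean, rather than each regression coefficient,
  is a deliberate simplification: it preserves per-state uncertainty
  while avoiding an undocumented coefficient covariance.
- trial odds ratio: log-normal with log-mean ln 1.42 and log-SD
  (ln 1.73 − ln 1.17)/(2 × 1.96).

Simulation *s* uses the seed substream `SeedSequence(master_seed,
spawn_key=(s,))`, so runs are reproducible and individual simulations can
be replayed in isolation.

## Intervention effect and costing

The odds ratio is converted to an excess conversion probability on the
logistic scale: p₀ = 507/1924, odds₁ = OR × p₀/(1−p₀),
Δ = odds₁/(1+odds₁) − p₀. The fraction Δ of **both** non-active
categories moves into "active" (removed from each in proportion to its
size); the trial's "sedentary" population is read as everyone below the
activity threshold, consistent with a number-needed-to-treat framing
(an inactive-only variant is a one-line change in `shifted_activity`).
Note the published NNT of "approximately 12" is not exactly reproduced by
this conversion (it yields ≈ 13.6 = 1/0.0734); the original conversion is
unstated, and nothing downstream depends on the NNT.

The incidence multiplier for disease *d* is the ratio of RR-weighted
exposure sums after/before the shift (1 − PIF), computed per sex and age
band and expanded to single years (constant within band). Multipliers
apply only to transitions out of the healthy state, only during the first
5 or 10 cycles, with no persistence afterwards and no effect on
depression prevalence. An odds-ratio draw of exactly 1 short-circuits to
multipliers of exactly 1, making the null intervention exactly null in
floating point — a property the tests rely on.

Intervention costs accrue on healthy-state occupancy during intervention
cycles: the active share of each stratum (baseline, unshifted activity
distribution — used in both scenarios, as the costing predates the
behavioural shift) incurs screening at 20 % of one consultation (£7/year)
and the non-active share the full annual cost (£35 base case; £7 and £70
presets). Costs, QALYs and life years all use a trapezoidal half-cycle
correction (the mean of cycle-start and cycle-end occupancy), and costs
and QALYs are discounted by (1 + r)^−t with t the 0-based cycle index
(first-cycle flows undiscounted before the correction); the discounting
origin is a convention the source does not state, and it is isolated in
one function.

## Synthetic inputs

The generator emulates the *structure* of the registry-derived tables,
not their levels: stratification by sex and 10-year band over ages
30–100; per-disease incidence of order 4–12 per 10,000 person-years at
30–39 doubling per decade; Gompertz-like healthy mortality
(4 × 10⁻⁴ at the 30s midpoint, log-slope 0.085/year) multiplied by
per-disease hazard factors (1.6–2.8) that compound across combinations;
depression prevalence 0.07 + 0.04 per physical condition; annual costs
growing 25 % per band with per-disease additions and a £450 depression
excess. Colorectal-cancer simplifications are mirrored: its incidence is
generated independent of cardiovascular comorbidity (and vice versa), and
all multi-disease combinations containing it share one cost row. A small
log-normal jitter (SD 0.05) keyed to the seed perturbs whole schedules so
seeds differ without breaking structure, and deterministic fix-up passes
after integer rounding of event counts guarantee, for every seed, that
realised rates are non-decreasing in age band, mortality is monotone over
the disease lattice, and depression prevalence strictly exceeds the
healthy state's in every stratum.

The initial cohort reproduces the entry population's shape — 262,704
entrants, 49 % male, 37 % under 45 / 42 % aged 45–64 / 21 % aged 65+ —
by largest-remainder rounding of a smooth within-group age profile, exact
in total at any configured size. Activity shares decline from
40 % active at ages 30–39 to 15 % at 90+; relative risks default to
inactive 1.40–1.90 and insufficiently active 1.15–1.40, steepest for
coronary heart disease so the expected ordering of incidence multipliers
across diseases is respected. Under these defaults the multipliers fall
in ≈ 0.95–0.99 at the central odds ratio, within the plausible
0.89–1.01 band.

**What passing tests do and do not show.** The synthetic tables have
large, homogeneous person-year denominators, so beta posteriors are far
tighter than registry estimates for rare multi-disease strata; the PSA
intervals are correspondingly much narrower than would be obtained from
real data, and direction probabilities are more extreme. Qualitative
behaviour — disease-free life years up, morbidity and depression years
down, utilisation savings partially offsetting intervention costs, net
health benefit near zero at £30,000/QALY — is reproduced; absolute
magnitudes are not estimates for any real population.

## Problem sizes used in the checks

Unit and property tests run single draws or toy chains. The end-to-end
checks use 50 paired simulations for the null-intervention identity and
200 paired simulations at a 10,000-entrant cohort for the qualitative
reproduction — enough for stable directions, chosen to keep the default
suite quick on one CPU; engine cost is independent of cohort size since
occupancy is continuous mass. The acceptance script's quantities are
deterministic worked examples and run instantly.

## Known limitations

- Deterministic cohort only: no individual-level microsimulation, so no
  history dependence beyond the state definition.
- No remission, severity staging, secular trends, non-modelled-cause
  mortality effects, effect persistence beyond the intervention, social
  multiplier effects, or non-health-care costs.
- Depression as a memoryless prevalence overlay forgets individual
  depression history from cycle to cycle.
- The half-cycle correction credits only half a year in the cycle of
  alive-exit at age 100, the standard trapezoidal boundary artifact.
- Costs are per-state annual averages; real costs concentrate near
  diagnosis and death.
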