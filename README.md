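# activecea

A probabilistic Markov cohort model for the cost-utility analysis of a
universal strategy to promote physical activity in primary care.

## The problem

Brief physical-activity advice delivered during family-practice visits has
a small but real effect on behaviour: meta-analysis of randomised trials
puts the odds ratio for a sedentary adult becoming active at 1.42
(95 % CI 1.17–1.73) against a control event rate of 26 % (507/1924). Does
offering such an intervention to *every* healthy adult pay its way once
the downstream effects on chronic disease are accounted for? Answering
that requires following a population for decades through the onset of
multiple long-term conditions, and propagating the uncertainty in every
rate, cost and utility into the economic conclusion. This package is
aimed at health-economic modellers and health-services researchers who
want a fully testable, reproducible implementation of that analysis.

## The model

- **State space.** Healthy adults ("At Risk") may acquire type 2 diabetes
  (DM), coronary heart disease (CHD), stroke or colorectal cancer (CRC);
  conditions are chronic and irreversible, so the 16 subsets of
  {DM, CHD, STROKE, CRC} form a lattice. Each subset is split into
  *depressed* / *not depressed*, giving 32 alive states plus an absorbing
  dead state (33 in all), with 32 incidence transitions (each adds exactly
  one disease) and 16 mortality transitions (one per subset).
- **Dynamics.** A deterministic cohort simulation stratified by sex and
  single year of age, run for 70 annual cycles so every entrant (ages
  30–100) dies or exits at age 100. Transition probabilities per cycle are
  drawn from beta-binomial posteriors of stratified event counts and
  person-years; depression is a prevalence-based overlay with no effect on
  mortality or disease incidence.
- **Intervention.** The trial odds ratio shifts the population activity
  distribution (inactive / insufficiently active / active); the resulting
  potential impact fraction (PIF) gives a disease-, age- and sex-specific
  incidence multiplier `1 − PIF = Σ p'_c RR_c / Σ p_c RR_c`, applied only
  to transitions out of the healthy state for the first 5 or 10 annual
  cycles. Intervention costs: £35 per inactive person-year (one
  consultation; £7 and £70 as sensitivity scenarios) and 20 % of a
  consultation (£7) for screening the already active.
- **Economics.** 2,000 paired simulations (common random numbers): gamma
  costs, beta utilities from an additive decrement catalogue (0.828 at age
  43, per-condition and condition-count decrements), half-cycle-corrected
  and discounted at 3.5 % (QALYs also at 1.5 %). Outputs are incremental
  costs and QALYs per 1,000 entrants, net health benefit
  `NHB(λ) = ΔQALY − ΔCost/λ` at λ = £30,000/QALY, and the
  cost-effectiveness acceptability curve `P(NHB(λ) > 0)`.

Because the registry data behind the original rate and cost tables are not
public, the `synthetic` module generates a complete stand-in input set
with the same stratification and the documented qualitative structure
(rates rising with age, mortality monotone over the disease lattice,
depression more prevalent and costs higher with morbidity), so the whole
pipeline runs and is testable end to end.

## Worked example

```bash
activecea generate --seed 1 --out inputs/
activecea run --inputs inputs/ --out results/ --sims 50 --durations 5,10 --seed 42
activecea report --in results/
```

prints, among other rows (synthetic inputs, 50 simulations):

```
## Intervention duration: 5 years
  Life years lived without disease (per 1,000): 20.2 (10.9 to 29.7); P(higher with intervention) = 100.0 %
  Life years with single condition (per 1,000): -11.6 (-17.0 to -6.2); P(lower with intervention) = 100.0 %
  Total intervention costs (GBP per 1,000): 111,819.1 (111,722.3 to 111,938.8); P(higher with intervention) = 100.0 %
  Incremental non-intervention utilisation costs (GBP per 1,000): -14,795.5 (-25,931.6 to -5,560.1); P(lower with intervention) = 100.0 %
  Incremental QALYs, base discount (per 1,000): 3.2 (1.7 to 5.0); P(higher with intervention) = 100.0 %
  Net health benefits (QALYs per 1,000): -0.0 (-1.8 to 1.8); P(higher with intervention) = 52.0 %
```

Read: a 5-year universal intervention increases disease-free life years
(+20.2 per 1,000 entrants here) and reduces years lived with single and
multiple morbidity; part of the intervention cost is offset by lower
health-care utilisation, but net health benefit at £30,000/QALY hovers
around zero — the qualitative conclusion that a universal strategy has
only weak evidence of cost-effectiveness. Magnitudes depend on the
synthetic inputs and are not estimates for any real population.

The same analysis is available as a library:

```python
from activecea import synthetic, economics, InterventionSpec

inputs = synthetic.generate_model_inputs(seed=1)
res = economics.run_psa(inputs, InterventionSpec(duration_years=5),
                        n_simulations=200, master_seed=1)
print(res.nhb(30_000).mean())
```

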