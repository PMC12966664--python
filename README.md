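# demcvd

A cohort state-transition (Markov) model of dementia, myocardial infarction
(MI) and stroke for cost-utility analysis of lifestyle risk-factor
interventions, with bundled UK and China parameter settings.

Preventive interventions that lower blood pressure, BMI, cholesterol,
physical inactivity or smoking act on dementia *and* cardiovascular disease
through the same risk factors, but trials are far too short to observe
disease onset. `demcvd` is for health economists and epidemiologists who
need to extrapolate a short-term trial effect on risk factors into lifetime
disease events, quality-adjusted life years (QALYs), costs and a
cost-effectiveness verdict — and to stress-test that verdict across
heterogeneity, adherence, cost and discounting scenarios.

## The model in brief

**Effect translation.** Each modifiable factor $k$ carries a per-unit
relative risk $r_k$ from a published risk score (CAIDE-type for dementia,
QRISK-type for MI/stroke) and a trial mean change $\delta_k$. The composite
intervention effect on a disease is

$$RR = \prod_k r_k^{\delta_k},$$

e.g. a hypertension RR of 2.1 with a 1.1-point prevalence reduction gives
$2.1^{-0.011} = 0.992$. With annual non-adherence $q$ the effect wanes:

$$RR_{\mathrm{eff}}(t) = RR^{(1-q)^t}$$

for $t$ years since start, reverting to 1 after the maximum intervention
duration (base case: 10 years, $q = 0.10$).

**State-transition engine.** Nine states — the eight subsets of
{dementia, MI, stroke} plus death (CVD/other cause) — evolve in yearly
cycles. Onset follows log-linear GLMs in age and sex times history relative
risks; death is handled first each cycle, and disease-free mortality is
calibrated from general-population life tables by dividing each cause rate
by the prevalence-weighted mean mortality relative risk, so that the
calibrated states recombine to the life table exactly. MI and stroke recur
via their own history RRs; dementia history is absorbing.

**Economics.** Person-time and events are weighted by a general-population
utility regression times disease utility ratios (plus one-off event
disutilities), and by annual disease costs plus one-off event costs for the
health sector and informal carers. Intervention platform and coaching
prices accrue per adherent surviving user-year. With discounted totals
$E$ (QALYs) and $C$ (costs) for intervention $i$ vs standard of care $c$:

$$\mathrm{ICER} = \frac{C_i - C_c}{E_i - E_c}, \qquad
\mathrm{iNHB} = (E_i - E_c) - \frac{C_i - C_c}{\lambda},$$

with willingness to pay $\lambda$ (£20,000/QALY UK; ¥81,419/QALY China).
The headroom analysis inverts this: the annual per-user price at which
iNHB = 0.

Inputs only available in external sources (life tables, disease prevalence,
the trial's baseline cohort and per-factor effect table) are emulated by a
seeded synthetic-fixtures module and flagged `"synthetic"` in every
bundle's provenance map; see `docs/methods.md` for what that does and does
not allow you to conclude.

## Worked example

```python
from demcvd import default_bundle, economic_summary, run_cohort

bundle = default_bundle("UK")
soc = run_cohort(bundle, "standard_of_care")
inter = run_cohort(bundle, "intervention")
s = economic_summary(soc, inter, bundle)
print(f"prevented dementia onsets: {s.prevented_events['dementia']:.0f}")
print(f"QALY gain per person     : {s.delta_qalys:+.4f}")
print(f"cost change per person   : {s.delta_costs:+,.0f} GBP")
print(f"iNHB at 20,000 GBP/QALY  : {s.inhb:+.3f}")
```

prints

```
prevented dementia onsets: 157
QALY gain per person     : +0.0162
cost change per person   : +4,119 GBP
iNHB at 20,000 GBP/QALY  : -0.190
```

Out of 100,000 people aged 55–74, the waning 10-year intervention prevents
157 dementia onsets and gains 0.016 discounted QALYs per person, but costs
about £4,119 more per person (almost all of it coaching), so the
incremental net health benefit is negative: the QALYs gained are worth less
than the net cost at the £20,000/QALY threshold. The `examples/` directory
walks through each capability: effect translation and waning
(`01_effect_translation.py`), the base case (`02_base_case.py`), the
scenario grid (`03_scenarios.py`), headroom pricing (`04_headroom.py`) and
external-validity grading (`05_external_validity.py`).

A thin CLI wraps the same functions:

```sh
demcvd run --country uk --out reports
demcvd scenario --country china --scenario all
demcvd translate --country uk
demcvd headroom --country uk
```

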