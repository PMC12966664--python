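# Methods

## Model structure and assumptions

`demcvd` is a deterministic cohort state-transition model with a 12-month
cycle. The state space is the eight subsets of {dementia, MI, stroke} plus
an absorbing death state with cause bookkeeping (CVD vs other). The closed
cohort is expanded into (integer starting age, sex, MI/stroke history)
strata — uniform within 5-year age bands — and each stratum is simulated
to the horizon age (default 100) and aggregated by its starting weight.

Within a cycle, death is resolved first from the state's summed CVD and
other-cause rates (cause attribution proportional to the two rates).
Conditional on survival, each disease not yet in the history onsets
independently with probability $1-e^{-r}$ from its annual rate $r$;
simultaneous multi-disease onset in one cycle is therefore allowed as the
product of the independent onset probabilities — the combination states
need such a path, and nothing in the transition structure forbids it.
Dementia history is absorbing (no dementia→dementia events); MI and stroke
recur through their own history relative risks, accruing expected
recurrent events without changing state.

Key modelling assumptions inherited from the underlying study design:
risk-factor changes are treated as causal for disease onset; the trial
effect persists (with waning) beyond the trial horizon; and the
intervention relative risk acts on the incidence of all three diseases in
every alive state but never directly on mortality — mortality benefits
arise only through prevented disease history.

## Hazards

Disease onset follows log-linear GLMs on rates,
$r = \exp(\beta_0 + \beta_{age}\,a + \beta_{sex}\,s)$ with male coded 1
(the printed utility regression uses an explicit `*male` term and the same
convention is applied to the incidence models; both the coding and an
optional age-by-sex interaction coefficient are exposed as configuration).
The log link — rather than a logistic model on probabilities — makes the
bundled coefficients yield epidemiologically plausible annual dementia
incidence (about 1 % at age 70 and 2.7 % at 80 for UK men).

Disease-free mortality is calibrated from general-population life tables.
The all-cause rate at (age, sex) is split by the CVD death fraction, and
each cause rate is divided by the prevalence-weighted mean mortality
relative risk $\sum_s \pi_s \prod_{d \in s} RR_{d}$ over the eight states,
where the joint state prevalences $\pi_s$ combine the three marginal
disease prevalences under independence (only marginal tables exist). This
joint form was chosen over sequential per-disease calibration because it
makes the round trip exact: recombining the calibrated state-specific
rates with the same weights reproduces the life-table cause rates to
machine precision, which the test suite asserts at 1e-12. History RRs
marked "not included" in the source inputs are exactly 1.

## Effect translation, waning and uncertainty

The composite intervention relative risk per disease is
$\prod_k r_k^{\delta_k}$ over the factor table; binary factors express
$\delta$ as a change in prevalence proportion, continuous factors in
natural units, which reproduces both published worked examples'
arithmetic. The dementia composite is sex-invariant; MI/stroke composites
are sex-specific. One published worked example does not verify under this
formula: an SBP RR of 1.005/mmHg reduced by 0.8 mmHg evaluates to 0.996,
not the 0.997 printed in the source; the discrepancy is presumably a
rounding path and is deliberately not forced.

Waning raises the relative risk to the adherent fraction $(1-q)^t$, with
$t$ an integer cycle index starting at 0 in the first cycle. After the
intervention duration the effect is removed (base case) or optionally
frozen at its last in-duration value. Quitters incur no further
intervention costs: platform and coaching prices are multiplied by the
adherent fraction and the proportion alive at the start of each cycle.

Uncertainty in the trial deltas propagates by a percentile bootstrap:
each factor's delta is drawn independently from Normal(δ, se) — no
correlation matrix is published, but a covariance hook exists — and the
composite recomputed per draw. Model-outcome intervals rerun the engine
only at the 2.5th/97.5th percentile RRs, not once per draw, following the
source's own interval construction.

## Economics

State membership is counted at end-of-cycle occupancy; events accrue in
the cycle they occur; no half-cycle correction is applied (none is used in
the source model); discounting uses $(1+r)^{-t}$ with $t=0$ in the first
cycle. Utilities combine a general-population quadratic regression with
multiplicative disease ratios (an additive-decrement switch exists, since
no multimorbidity rule is published) and additive one-off event
disutilities for MI and stroke. "Additional in year 1" costs are one-off
event-attached amounts on top of the annual post-year-1 cost in the event
cycle. Platform costs are adherence-weighted exactly like coaching (the
published per-person platform total is consistent with the
adherence-discounted annuity); a switch allows unconditional accrual. The
headroom price replaces platform+coaching with a single unknown annual
cost and solves iNHB = 0 by bisection to 1e-6 relative tolerance; because
iNHB is linear in the price, the tests cross-check the root against the
closed form (λ·ΔE minus disease-cost offsets over the discounted
adherence-weighted survivor exposure).

## Synthetic fixtures: what they emulate and what they do not

Several inputs of the original analysis exist only in external or
supplementary sources: national life tables and the CVD death share,
disease prevalence tables, the trial's baseline cohort distribution and
the per-factor effect table. The fixtures module generates seeded,
clearly-flagged stand-ins:

* **Life tables** are Gompertz, $m(a) = \alpha e^{\beta a}$ clipped at 1,
  with α solved so female life expectancy at 55 matches a requested value
  (UK-like 29.5 y; China 28.5 y), a male/female rate ratio (1.5 / 1.4) and
  a CVD death share rising logistically from 0.18 to 0.35 across old age.
  Gompertz (not Gompertz–Makeham) suffices for ages 40–100.
* **Starting cohort**: bands 55–59/60–64/65–69/70–74 with weights
  0.38/0.30/0.20/0.12, 60 % women, 4 % MI and 4 % stroke history,
  independent within cells.
* **Prevalence** is generated by the engine itself from a disease-free
  cohort entering at age 40, iterated to a fixed point because calibrated
  mortality depends on prevalence — guaranteeing internal consistency
  between fixture incidence, mortality and prevalence.
* **Trial effect table**: five factors anchored on the published worked
  examples (hypertension 2.1 / −0.011; SBP 1.005 per mmHg, female,
  −0.8 mmHg) and published per-unit BMI RRs, with the remaining deltas
  fixed at design time so the composite points reproduce the published
  0.924 / 0.982 / 0.980.

Consequently the *effect-translation* outputs match the published points
by construction, and the *engine-level* base-case outputs (lifetime
dementia risk ≈ 53 % vs 45 % published; mean survival 22.5 y vs 20.7 y;
prevented dementia onsets ≈ 157 vs 206) land in the published orders of
magnitude but are not reproductions: they are conditioned on synthetic
mortality, prevalence and cohort structure. Passing tests therefore
demonstrate the correctness of the machinery and the plausibility of the
pipeline, not agreement with the original data. Fixture provenance flags
travel with every bundle and survive file round-trips so reports can
always separate published from emulated inputs.

## Numerical choices

* Rate→probability conversion $1-e^{-r\Delta t}$ per cycle.
* Death-cause split proportional to the cause rates; zero total rate gives
  zero death probability.
* Age bands expand to integer ages with uniform weights rather than
  collapsing to a midpoint; each stratum ages deterministically.
* The published iNHB arithmetic on *rounded* difference entries gives
  −0.186 (UK: 0.02 − 4127/20000) and −0.011 (China: 0.01 − 1697/81419);
  the published summary values (−0.190 / −0.009) reflect unrounded
  internals. The package asserts the former identities and never claims
  equality with the latter from rounded inputs.
* Scenario overrides are pure: applying a descriptor returns a new bundle
  and never mutates the base configuration.

## Design choices where the design was open

* **Dementia-only scenario** is a dementia-only *model* (MI and stroke
  neither simulated nor affected), matching the sensitivity analysis whose
  published MI/stroke differences are exactly zero; restricting only the
  effect scope would leave spillover MI/stroke events from longer
  dementia-free survival. The effect-scope-only restriction is retained
  for the headroom analysis, which omits the effect on MI and stroke but
  keeps both diseases in the model.
* **Repeat-without-coaching** charges coaching for the first two model
  years (the 12–18-month trial delivery spans two annual cycles) and the
  platform for the full duration; the exact costing window is not
  published. **Lifetime-full-adherence** variants extend duration and
  costs to the lifetime, with or without coaching.
* The China inputs marked "assumed same as UK" are stored as proportions
  (the CVD death fraction), not rates.
* The external-validity rule grades a simulated prevalence *good* when
  inside the observed interval (closed bounds), *moderate* when within one
  additional half-width of the violated bound — the reading adopted for
  "not more than two times beyond the observed confidence interval" — and
  *poor* otherwise.

## Problem sizes and verification

The deterministic engine is exact, so test sizes concern only the
stochastic oracles: the cohort trace is validated against seeded
individual-level microsimulations (up to 10⁶ walkers on single-stratum
instances, 3 Monte-Carlo SEs), probability conservation and monotone death
are checked on 1,000 randomly drawn parameter bundles, the bootstrap is
checked against the log-normal closed form at 10⁵ draws, and the
acceptance script runs both full country base cases (100,000-person
cohort, ages 55–100) plus the headroom analyses in well under a minute.

## Known limitations

Costs of unrelated diseases in life-years gained, productivity losses and
amyloid-therapy costs are out of scope (societal perspective = health
sector + informal care only). Probabilistic sensitivity analysis is
deliberately not implemented: plausible distributions for the causality
and long-term-adherence assumptions do not exist, and a probabilistic
analysis omitting them would misrepresent uncertainty. LIBRA/QRISK3-based
effect translation and trial-subgroup scenarios are interface-only and
require user-supplied estimates. Currencies are never converted; each
country bundle is self-contained at 2021 price level.
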