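"""Synthetic stand-ins for input tables only available in external sources.

The published model input table references several inputs by pointer only:
national life tables, the CVD share of deaths, disease prevalence tables,
the trial baseline cohort distribution and the per-factor trial effect
table. This module generates plausible, fully seeded emulations of each so
the whole pipeline is buildable and testable without downloads. Every
fixture is labelled synthetic via bundle provenance flags; absolute model
outputs driven by these fixtures characterise the method under realistic
conditions, not the original study's data.

Statistical structure
---------------------
* Life tables are Gompertz, m(age) = alpha * exp(beta * age), clipped to
  <= 1 per person-year, with a male/female rate ratio and a CVD death
  share rising smoothly (logistically) with age. ``alpha`` can be solved so
  that life expectancy at 55 matches a requested value.
* The starting cohort factorises band x sex x history with independent MI
  and stroke history within each cell.
* The prevalence table is produced by running the cohort engine itself from
  a disease-free cohort at age 40 under the fixture hazards (iterated to a
  fixed point, since calibrated mortality depends on prevalence), keeping
  fixture incidence, mortality and prevalence internally consistent.
* The trial effect table anchors the two published worked examples
  (hypertension RR 2.1 with a 1.1-point prevalence reduction; SBP RR 1.005
  per mmHg, female, reduced 0.8 mmHg) and the published per-unit BMI RRs,
  with the remaining deltas fixed so the composite relative risks
  reproduce the published point estimates (0.924 dementia; 0.982 male /
  0.980 female MI and stroke).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .parameters import (
    DISEASES,
    IncidenceGLM,
    LifeTable,
    MortalityRRs,
    ParameterError,
    PrevalenceTable,
    RiskFactorEffect,
    RiskModelSpec,
    StartingCohort,
)

__all__ = [
    "make_life_table",
    "gompertz_life_expectancy",
    "solve_gompertz_alpha",
    "make_starting_cohort",
    "make_prevalence_table",
    "make_trial_effect_table",
    "LIFE_TABLE_DEFAULTS",
    "COHORT_DEFAULTS",
]

# Study-condition defaults, chosen once: UK-like life expectancy at 55 of
# ~29.5 y (women) with a 1.5x male mortality ratio; China slightly lower;
# CVD death share rising from ~18 % to ~35 % across old age.
LIFE_TABLE_DEFAULTS = {
    "uk": dict(target_e55=29.5, beta=0.092, sex_ratio=1.5, age_min=40, age_max=100),
    "china": dict(target_e55=28.5, beta=0.095, sex_ratio=1.4, age_min=40, age_max=100),
}

COHORT_DEFAULTS = dict(
    band_weights=(0.38, 0.30, 0.20, 0.12),
    female_share=0.60,
    mi_prev=0.04,
    stroke_prev=0.04,
)

AGE_BANDS = ((55, 59), (60, 64), (65, 69), (70, 74))


def gompertz_life_expectancy(alpha: float, beta: float, start_age: int = 55) -> float:
    """Discrete life expectancy at ``start_age`` under clipped Gompertz rates."""
    e, surv = 0.0, 1.0
    for age in range(start_age, 131):
        rate = min(1.0, alpha * math.exp(beta * age))
        surv *= math.exp(-rate)
        e += surv
    return e


def solve_gompertz_alpha(target_e55: float, beta: float, start_age: int = 55) -> float:
    """Solve alpha so life expectancy at ``start_age`` matches ``target_e55``."""

    def f(log_alpha: float) -> float:
        return gompertz_life_expectancy(math.exp(log_alpha), beta, start_age) - target_e55

    return math.exp(brentq(f, math.log(1e-12), math.log(1.0), xtol=1e-12))


def _cvd_share(age: float, params: tuple[float, float, float, float]) -> float:
    low, high, mid, scale = params
    return low + (high - low) / (1.0 + math.exp(-(age - mid) / scale))


def make_life_table(
    alpha: float | None = None,
    beta: float = 0.092,
    sex_ratio: float = 1.5,
    cvd_share_params: tuple[float, float, float, float] = (0.18, 0.35, 75.0, 10.0),
    age_min: int = 55,
    age_max: int = 100,
    target_e55: float | None = None,
) -> LifeTable:
    """Gompertz life table with a smoothly rising CVD death share.

    Female rates are alpha * exp(beta * age), male rates ``sex_ratio``
    times that, both clipped to <= 1 per person-year. Pass either ``alpha``
    directly or ``target_e55`` (female life expectancy at 55) to solve for
    it numerically.
    """
    if (alpha is None) == (target_e55 is None):
        raise ParameterError("pass exactly one of alpha or target_e55")
    if target_e55 is not None:
        alpha = solve_gompertz_alpha(target_e55, beta)
    if alpha <= 0 or beta < 0:
        raise ParameterError("alpha must be > 0 and beta >= 0")
    rate: dict[tuple[int, str], float] = {}
    cvd: dict[tuple[int, str], float] = {}
    for age in range(age_min, age_max + 1):
        base = alpha * math.exp(beta * age)
        rate[(age, "female")] = min(1.0, base)
        rate[(age, "male")] = min(1.0, sex_ratio * base)
        share = _cvd_share(age, cvd_share_params)
        cvd[(age, "female")] = share
        cvd[(age, "male")] = share
    return LifeTable(rate=rate, cvd_fraction=cvd)


def make_starting_cohort(
    band_weights: tuple[float, ...] = COHORT_DEFAULTS["band_weights"],
    female_share: float = COHORT_DEFAULTS["female_share"],
    mi_prev: float = COHORT_DEFAULTS["mi_prev"],
    stroke_prev: float = COHORT_DEFAULTS["stroke_prev"],
    cohort_size: int = 100_000,
    seed: int = 0,
) -> StartingCohort:
    """Starting cohort over 4 age bands x 2 sexes x 4 MI/stroke histories.

    History combinations are independent within each cell; proportions are
    normalised to sum to 1. Fully deterministic given its arguments (the
    ``seed`` is accepted for interface uniformity).
    """
    if any(w < 0 for w in band_weights):
        raise ParameterError("band weights must be non-negative")
    w = np.asarray(band_weights, dtype=float)
    if w.sum() <= 0:
        raise ParameterError("band weights must not all be zero")
    w = w / w.sum()
    hist_probs = {
        frozenset(): (1 - mi_prev) * (1 - stroke_prev),
        frozenset({"mi"}): mi_prev * (1 - stroke_prev),
        frozenset({"stroke"}): (1 - mi_prev) * stroke_prev,
        frozenset({"mi", "stroke"}): mi_prev * stroke_prev,
    }
    sex_w = {"female": female_share, "male": 1.0 - female_share}
    cells = {}
    for band, bw in zip(AGE_BANDS, w):
        for sex, sw in sex_w.items():
            for hist, hw in hist_probs.items():
                cells[(band, sex, hist)] = float(bw * sw * hw)
    total = sum(cells.values())
    cells = {k: v / total for k, v in cells.items()}
    return StartingCohort(cells=cells, cohort_size=cohort_size)


def make_prevalence_table(
    incidence: dict[str, IncidenceGLM],
    life_table: LifeTable,
    rrs: MortalityRRs,
    start_age: int = 40,
    n_iter: int = 4,
) -> PrevalenceTable:
    """Prevalence by (age, sex, disease) generated by the engine itself.

    A disease-free cohort enters at ``start_age`` and runs to the life
    table's top age under the given hazards; age-specific marginal state
    occupancy among the alive is read off as prevalence. Because the
    calibrated disease-free mortality itself depends on prevalence, the
    procedure iterates to a fixed point (starting from zero prevalence),
    which keeps fixture incidence, mortality and prevalence internally
    consistent.
    """
    # deferred: engine imports this module's siblings
    from .engine import run_cohort, simulated_prevalence
    from .parameters import (
        CostParams,
        EconSettings,
        ParameterBundle,
        UtilityParams,
        WaningPolicy,
    )

    ages = life_table.ages
    if start_age < min(ages):
        raise ParameterError("life table does not cover start_age")
    end_age = max(ages)
    zero = PrevalenceTable(
        {(a, s, d): 0.0 for a in ages for s in ("male", "female") for d in DISEASES}
    )
    cohort = StartingCohort(
        cells={
            ((start_age, start_age), "male", frozenset()): 0.5,
            ((start_age, start_age), "female", frozenset()): 0.5,
        },
        cohort_size=100_000,
    )
    stub_bundle = dict(
        country="fixture",
        incidence=incidence,
        life_table=life_table,
        mortality_rrs=rrs,
        cohort=cohort,
        utilities=UtilityParams(genpop=(0.9, 0.0, 0.0, 0.0), ratio={}, event_disutility={}),
        costs=CostParams(
            annual={}, event={}, platform_per_user_year=0.0, coaching_per_user_year=0.0
        ),
        econ=EconSettings(
            discount_rate_costs=0.0, discount_rate_effects=0.0, wtp=1.0, max_age=end_age
        ),
        risk_models={},
        waning=WaningPolicy(),
    )

    prev = zero
    for _ in range(max(1, n_iter)):
        bundle = ParameterBundle(prevalence=prev, **stub_bundle)
        trace = run_cohort(bundle, "standard_of_care", horizon=end_age)
        sim = simulated_prevalence(trace)
        values = dict(zero.values)
        values.update(sim.values)
        prev = PrevalenceTable(values)
    return prev


def make_trial_effect_table(seed: int = 0) -> dict[str, RiskModelSpec]:
    """Synthetic per-factor trial effect table (five modifiable factors).

    Returns one risk-model spec per disease. The dementia spec uses
    CAIDE-style binary-factor RRs with trial changes expressed as
    prevalence-proportion reductions; the MI and stroke specs share a
    QRISK-style table with sex-specific per-unit RRs in natural units.
    Anchored values: hypertension 2.1 per unit prevalence with delta
    -0.011; SBP 1.005 per mmHg (female) with delta -0.8; BMI per-point RRs
    0.94 (dementia) and 0.98 (CVD) per 1-point reduction. The remaining
    deltas are fixed so the composite relative risks evaluate to the
    published point estimates (0.924; 0.982 male / 0.980 female).
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    del seed
    dementia = RiskModelSpec(
        disease="dementia",
        label="CAIDE-derived (synthetic emulation)",
        factors=(
            RiskFactorEffect("hypertension", 2.1, -0.011, 0.05, "proportion"),
            RiskFactorEffect("obesity", 2.17, -0.010, 0.04, "proportion"),
            RiskFactorEffect("high_cholesterol", 1.89, -0.012, 0.045, "proportion"),
            RiskFactorEffect("physical_inactivity", 1.82, -0.081, 0.125, "proportion"),
            RiskFactorEffect("smoking", 1.6, -0.015, 0.012, "proportion"),
        ),
    )
    cvd_factors = (
        RiskFactorEffect("sbp", {"male": 1.004, "female": 1.005}, -0.8, 1.2, "mmHg"),
        RiskFactorEffect("bmi", 1.0204, -0.33, 0.12, "kg/m2"),
        RiskFactorEffect("cholesterol", {"male": 1.03, "female": 1.05}, -0.05, 0.03, "mmol/L"),
        RiskFactorEffect("physical_inactivity", 1.07, -0.081, 0.125, "proportion"),
        RiskFactorEffect("smoking", {"male": 1.1, "female": 1.15}, -0.015, 0.012, "proportion"),
    )
    mi = RiskModelSpec(disease="mi", factors=cvd_factors, label="QRISK1-derived (synthetic emulation)")
    stroke = RiskModelSpec(
        disease="stroke", factors=cvd_factors, label="QRISK1-derived (synthetic emulation)"
    )
    return {"dementia": dementia, "mi": mi, "stroke": stroke}
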