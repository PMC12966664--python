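"""Shared test utilities: small synthetic bundles and a microsimulation oracle.

The microsimulation is an individual-level re-implementation of the cohort
dynamics (death first, then independent onsets conditional on survival)
used purely as an independent correctness oracle for the deterministic
trace; it is intentionally not part of the package.
"""

from __future__ import annotations

import math

import numpy as np

from demcvd.engine import ALIVE_STATES, IDX_DEAD_CVD, IDX_DEAD_OTHER, N_STATES, state_index
from demcvd.epidemiology import (
    calibrate_baseline_mortality,
    incidence_rate,
    state_mortality,
)
from demcvd.parameters import (
    DISEASES,
    CompositeRR,
    CostParams,
    EconSettings,
    IncidenceGLM,
    LifeTable,
    MortalityRRs,
    ParameterBundle,
    PrevalenceTable,
    RiskFactorEffect,
    RiskModelSpec,
    StartingCohort,
    UtilityParams,
    WaningPolicy,
)


def build_toy_bundle(
    start_age: int = 90,
    horizon: int = 100,
    n_ages: int = 1,
    sexes: tuple[str, ...] = ("female",),
    histories: tuple[frozenset, ...] = (frozenset(),),
    zero_mortality: bool = False,
    dementia_rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> ParameterBundle:
    """A small, fully explicit bundle for fast deterministic tests.

    With ``rng`` set, incidence coefficients, mortality levels, history and
    mortality RRs, prevalences and costs are drawn randomly (within the
    type invariants); otherwise fixed mid-range values are used.
    """
    ages = range(start_age - 1, horizon + 1)

    def draw(lo, hi):
        return float(rng.uniform(lo, hi)) if rng is not None else (lo + hi) / 2.0

    if zero_mortality:
        rate = {(a, s): 0.0 for a in ages for s in ("male", "female")}
    else:
        base = draw(0.02, 0.08)
        slope = draw(0.0, 0.1)
        rate = {
            (a, s): min(1.0, base * math.exp(slope * (a - start_age)) * (1.3 if s == "male" else 1.0))
            for a in ages
            for s in ("male", "female")
        }
    cvd_f = draw(0.1, 0.5)
    life_table = LifeTable(
        rate=rate, cvd_fraction={k: cvd_f for k in rate}
    )

    if dementia_rate is not None:
        dem_glm = IncidenceGLM("dementia", math.log(dementia_rate), 0.0, 0.0)
    else:
        dem_glm = IncidenceGLM(
            "dementia", draw(-9.0, -8.0), 0.08, 0.1, history_rr={"stroke": draw(1.0, 2.0)}
        )
    incidence = {
        "dementia": dem_glm,
        "mi": IncidenceGLM("mi", draw(-8.0, -6.0), 0.02, 0.3, history_rr={"mi": draw(1.5, 8.0)}),
        "stroke": IncidenceGLM(
            "stroke", draw(-8.0, -6.0), 0.02, 0.2, history_rr={"mi": 2.0, "stroke": draw(1.5, 5.0)}
        ),
    }
    mortality_rrs = MortalityRRs(
        cvd={d: draw(1.0, 6.0) for d in DISEASES},
        other={d: draw(1.0, 6.0) for d in DISEASES},
    )
    prevalence = PrevalenceTable(
        {
            (a, s, d): draw(0.0, 0.3)
            for a in ages
            for s in ("male", "female")
            for d in DISEASES
        }
    )
    cells = {}
    n_cells = n_ages * len(sexes) * len(histories)
    for k in range(n_ages):
        band = (start_age + k, start_age + k)
        for s in sexes:
            for h in histories:
                cells[(band, s, h)] = 1.0 / n_cells
    cohort = StartingCohort(cells=cells, cohort_size=100_000)
    utilities = UtilityParams(
        genpop=(0.95, 0.02, 0.0, -0.0000332),
        ratio={"dementia": 0.876, "mi": 0.923, "stroke": 0.839},
        event_disutility={"mi": -0.025, "stroke": -0.048},
    )
    costs = CostParams(
        annual={(d, p): draw(0.0, 5000.0) for d in DISEASES for p in ("health_sector", "informal")},
        event={(d, p): draw(0.0, 8000.0) for d in DISEASES for p in ("health_sector", "informal")},
        platform_per_user_year=5.0,
        coaching_per_user_year=800.0,
        duration_years=10,
    )
    econ = EconSettings(
        discount_rate_costs=0.035,
        discount_rate_effects=0.035,
        wtp=20_000.0,
        max_age=horizon,
    )
    risk_models = {
        d: RiskModelSpec(
            disease=d,
            factors=(RiskFactorEffect("factor", 2.0, draw(-0.2, -0.05), 0.05),),
            label="toy",
        )
        for d in DISEASES
    }
    return ParameterBundle(
        country="toy",
        incidence=incidence,
        life_table=life_table,
        mortality_rrs=mortality_rrs,
        prevalence=prevalence,
        cohort=cohort,
        utilities=utilities,
        costs=costs,
        econ=econ,
        risk_models=risk_models,
        waning=WaningPolicy(),
    )


def stratum_hazards(bundle, age, sex, state, rr=None):
    """Hazards for one (age, sex, state) exactly as the model defines them."""
    rr = rr or {d: 1.0 for d in DISEASES}
    inc = {
        d: incidence_rate(bundle.incidence[d], age, sex, state, rr[d]) for d in DISEASES
    }
    base = calibrate_baseline_mortality(
        bundle.life_table, bundle.prevalence, bundle.mortality_rrs, age, sex
    )
    m_cvd, m_oth = state_mortality(base, state, bundle.mortality_rrs)
    return inc, m_cvd, m_oth


def microsim_cohort(
    bundle: ParameterBundle,
    start_age: int,
    sex: str,
    history: frozenset,
    n_cycles: int,
    n_walkers: int,
    seed: int,
) -> np.ndarray:
    """Individual-level simulation of one stratum; returns final occupancy.

    Walkers move through the same state space with the same hazards as the
    deterministic trace: death is drawn first from the summed cause rates
    (cause assigned proportionally), then each absent disease onsets
    independently with probability 1 - exp(-rate).
    """
    rng = np.random.default_rng(seed)
    bits = {"dementia": 1, "mi": 2, "stroke": 4}
    states = np.full(n_walkers, state_index(history), dtype=np.int64)
    for t in range(n_cycles):
        age = start_age + t
        cur = states.copy()  # snapshot: one transition per walker per cycle
        alive = cur < 8
        for i, st in enumerate(ALIVE_STATES):
            mask = alive & (cur == i)
            n = int(mask.sum())
            if n == 0:
                continue
            inc, m_cvd, m_oth = stratum_hazards(bundle, age, sex, st)
            total = m_cvd + m_oth
            p_death = -math.expm1(-total)
            u = rng.random(n)
            died = u < p_death
            idx = np.flatnonzero(mask)
            if died.any() and total > 0:
                cause = rng.random(int(died.sum())) < (m_cvd / total)
                dead_idx = idx[died]
                states[dead_idx[cause]] = IDX_DEAD_CVD
                states[dead_idx[~cause]] = IDX_DEAD_OTHER
            surv_idx = idx[~died]
            for d in DISEASES:
                if d in st:
                    continue
                if d == "dementia" and "dementia" in st:
                    continue
                p_on = -math.expm1(-inc[d])
                onset = rng.random(len(surv_idx)) < p_on
                states[surv_idx[onset]] |= bits[d]
    occupancy = np.zeros(N_STATES)
    for i in range(N_STATES):
        occupancy[i] = float((states == i).sum()) / n_walkers
    return occupancy


def null_composite() -> CompositeRR:
    return CompositeRR.null()
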