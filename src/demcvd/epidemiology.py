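"""State- and age-specific incidence and cause-specific mortality.

Disease onset follows log-linear GLMs on age and sex, multiplied by relative
risks for disease history and (under the intervention) the waned composite
intervention RR. Mortality starts from a general-population life table split
into CVD and other-cause rates; because life-table rates average over people
with and without disease, the disease-free baseline is recovered by dividing
each cause rate by the prevalence-weighted mean mortality relative risk
across states (joint state prevalence from independence of the marginal
disease prevalences). State-specific mortality then multiplies the baseline
by the product of the state's per-cause history RRs, so recombining states
with the same prevalence weights reproduces the life table exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from .parameters import (
    DISEASES,
    IncidenceGLM,
    LifeTable,
    MortalityRRs,
    PrevalenceTable,
)

__all__ = [
    "HazardSet",
    "incidence_rate",
    "rate_to_probability",
    "calibrate_baseline_mortality",
    "state_mortality",
    "state_prevalence_weights",
]

State = frozenset


@dataclass(frozen=True)
class HazardSet:
    """Per person-year rates for one (age, sex, state) combination."""

    dementia: float
    mi: float
    stroke: float
    death_cvd: float
    death_other: float

    def __post_init__(self) -> None:
        for name in ("dementia", "mi", "stroke", "death_cvd", "death_other"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"hazard {name} must be finite and >= 0, got {v}")

    def incidence(self, disease: str) -> float:
        return getattr(self, disease)


def incidence_rate(
    glm: IncidenceGLM,
    age: float,
    sex: str,
    state: Iterable[str] = (),
    intervention_rr: float = 1.0,
) -> float:
    """Annual onset/event rate for ``glm.disease`` in the given state.

    exp(b0 + b_age*age + b_sex*sex + b_age_sex*age*sex) times the history
    RRs of the diseases present, times the intervention RR. Dementia onset
    is 0 once dementia history is present (absorbing); MI and stroke recur
    through their own history RRs.
    """
    state = frozenset(state)
    if glm.disease == "dementia" and "dementia" in state:
        return 0.0
    s = glm.sex_value(sex)
    rate = math.exp(glm.intercept + glm.b_age * age + glm.b_sex * s + glm.b_age_sex * age * s)
    for d in DISEASES:
        if d in state:
            rate *= glm.history_rr.get(d, 1.0)
    return rate * intervention_rr


def rate_to_probability(rate: float, cycle_length: float = 1.0) -> float:
    """Constant-rate conversion 1 - exp(-rate * cycle_length), in [0, 1)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return -math.expm1(-rate * cycle_length)


def state_prevalence_weights(
    prevalence: PrevalenceTable, age: int, sex: str
) -> dict[State, float]:
    """Joint prevalence of the 8 alive states from the marginal tables.

    Marginal prevalences are combined under independence; the weights sum
    to 1 over the 8 subsets of {dementia, mi, stroke}.
    """
    p = {d: prevalence.prevalence(age, sex, d) for d in DISEASES}
    weights: dict[State, float] = {}
    for k in range(4):
        for combo in combinations(DISEASES, k):
            w = 1.0
            for d in DISEASES:
                w *= p[d] if d in combo else (1.0 - p[d])
            weights[frozenset(combo)] = w
    return weights


def calibrate_baseline_mortality(
    life_table: LifeTable,
    prevalence: PrevalenceTable,
    rrs: MortalityRRs,
    age: int,
    sex: str,
) -> tuple[float, float]:
    """Disease-free (cvd, other) mortality rates at (age, sex).

    The life-table all-cause rate is split by the CVD death fraction, then
    each cause rate is divided by the prevalence-weighted mean relative risk
    sum_s pi_s * prod_{d in s} RR_cause,d so that recombining the calibrated
    state rates with the same weights returns the life-table rate exactly.
    """
    total = life_table.mortality(age, sex)
    frac = life_table.cvd_frac(age, sex)
    cause_rates = {"cvd": total * frac, "other": total * (1.0 - frac)}
    weights = state_prevalence_weights(prevalence, age, sex)

    out = []
    for cause in ("cvd", "other"):
        table = rrs.for_cause(cause)
        mean_rr = 0.0
        for state, w in weights.items():
            rr = 1.0
            for d in DISEASES:
                if d in state:
                    rr *= table.get(d, 1.0)
            mean_rr += w * rr
        out.append(cause_rates[cause] / mean_rr)
    return out[0], out[1]


def state_mortality(
    baseline: tuple[float, float], state: Iterable[str], rrs: MortalityRRs
) -> tuple[float, float]:
    """(cvd, other) death rates in ``state``: baseline times history RRs."""
    state = frozenset(state)
    cvd, other = baseline
    for d in DISEASES:
        if d in state:
            cvd *= rrs.cvd.get(d, 1.0)
            other *= rrs.other.get(d, 1.0)
    return cvd, other
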