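"""Translate trial risk-factor changes into per-disease relative risks.

A short trial measures mean changes ``delta_k`` in modifiable risk factors
(SBP, BMI, cholesterol, physical inactivity, smoking). Each factor carries a
per-unit relative risk ``rr_k`` for a disease, taken from a published risk
score (CAIDE for dementia, QRISK for MI/stroke). The composite intervention
effect on that disease is the product

    RR = prod_k rr_k ** delta_k

so e.g. a hypertension RR of 2.1 combined with a 1.1-point prevalence
reduction gives 2.1**(-0.011) = 0.992. The effect wanes as participants quit
the intervention: with annual non-adherence ``q``, the adherent fraction
after ``t`` years is (1-q)**t and the effective relative risk is

    RR_eff(t) = RR ** ((1-q)**t)        for t < duration,

reverting to 1 after the maximum intervention duration (or frozen at its
last value, if configured). Uncertainty in the deltas propagates to a
bootstrap percentile interval for the composite RR.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .parameters import (
    CompositeRR,
    ParameterError,
    RiskModelSpec,
    WaningPolicy,
)

__all__ = [
    "composite_relative_risk",
    "composite_from_specs",
    "effective_rr",
    "adherent_fraction",
    "bootstrap_composite_rr",
]


def composite_relative_risk(spec: RiskModelSpec, sex: str = "female") -> float:
    """Product of ``rr_per_unit ** delta`` over the spec's factors.

    Binary factors express ``delta`` as a change in prevalence proportion;
    continuous factors use natural units. Sex-specific per-unit RRs are
    resolved with ``sex``.
    """
    log_rr = 0.0
    for f in spec.factors:
        rr = f.rr_for_sex(sex)
        if rr <= 0:
            raise ParameterError(f"{f.name}.rr_per_unit must be > 0")
        log_rr += f.delta * math.log(rr)
    return math.exp(log_rr)


def composite_from_specs(risk_models: Mapping[str, RiskModelSpec]) -> CompositeRR:
    """Evaluate the composite RR for each disease from its risk-model spec.

    The dementia composite is sex-invariant (its per-unit RRs carry no sex
    split); MI and stroke composites are evaluated per sex.
    """
    return CompositeRR(
        dementia=composite_relative_risk(risk_models["dementia"]),
        mi_by_sex={s: composite_relative_risk(risk_models["mi"], s) for s in ("male", "female")},
        stroke_by_sex={
            s: composite_relative_risk(risk_models["stroke"], s) for s in ("male", "female")
        },
    )


def adherent_fraction(t: int, policy: WaningPolicy) -> float:
    """Proportion still adherent at cycle ``t`` (t = 0 in the first cycle).

    (1 - q)**t while the intervention runs, 0 from ``duration_years`` on;
    intervention costs are scaled by this (quitters incur no further costs).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t >= policy.duration_years:
        return 0.0
    return (1.0 - policy.annual_nonadherence) ** t


def effective_rr(base_rr: float, t: int, policy: WaningPolicy) -> float:
    """Waned relative risk at integer cycle ``t`` since model start.

    ``base_rr ** ((1 - q)**t)`` during the intervention; after
    ``duration_years`` either 1 (effect removed) or the value frozen at the
    last in-duration cycle, per ``policy.post_duration_effect``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t >= policy.duration_years:
        if policy.post_duration_effect == "frozen" and policy.duration_years > 0:
            t = policy.duration_years - 1
        else:
            return 1.0
    return base_rr ** ((1.0 - policy.annual_nonadherence) ** t)


def bootstrap_composite_rr(
    spec: RiskModelSpec,
    n_draws: int = 100_000,
    seed: int = 0,
    sex: str = "female",
    cov: np.ndarray | None = None,
) -> dict[str, float]:
    """Bootstrap percentile summary (2.5/50/97.5) of the composite RR.

    Each factor's delta is drawn independently from Normal(delta, se_delta)
    and the composite recomputed per draw; a factor-by-factor covariance
    matrix may be supplied via ``cov`` to correlate the draws. Identical
    seeds give identical output.
    """
    if n_draws < 2:
        raise ParameterError("n_draws must be >= 2")
    ses = np.array([f.se_delta for f in spec.factors], dtype=float)
    if np.any(np.isnan(ses)):
        raise ParameterError("every factor needs se_delta for the bootstrap")
    means = np.array([f.delta for f in spec.factors], dtype=float)
    log_rrs = np.array([math.log(f.rr_for_sex(sex)) for f in spec.factors])

    rng = np.random.default_rng(seed)
    if cov is not None:
        deltas = rng.multivariate_normal(means, cov, size=n_draws)
    else:
        deltas = rng.normal(means, ses, size=(n_draws, len(means)))
    composites = np.exp(deltas @ log_rrs)
    lo, med, hi = np.percentile(composites, [2.5, 50.0, 97.5])
    return {"p2.5": float(lo), "p50": float(med), "p97.5": float(hi)}
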