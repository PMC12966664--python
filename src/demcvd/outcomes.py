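"""Economic outcomes: person-years, QALYs, costs, ICER, iNHB and headroom.

Accounting conventions: state membership is counted at end-of-cycle
occupancy, events accrue within the cycle they occur, and there is no
half-cycle correction. Discounting uses end-of-cycle factors (1+r)^-t with
t = 0 for the first cycle. Intervention (platform and coaching) costs are
charged per adherent user-year: price x adherent fraction x proportion
alive at the start of the cycle, for cycles before the intervention
duration ends.

The decision metrics compare an intervention strategy i against standard of
care c with total discounted QALYs E and costs C:

    ICER = (Ci - Cc) / (Ei - Ec)
    iNHB = (Ei - Ec) - (Ci - Cc) / lambda

with lambda the willingness to pay per QALY. The headroom price is the
annual per-user intervention cost at which iNHB = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import effects
from .engine import ALIVE_STATES, Trace, run_cohort, scale_events
from .parameters import (
    DISEASES,
    CostParams,
    EconSettings,
    ParameterBundle,
    ParameterError,
    UtilityParams,
    WaningPolicy,
)

__all__ = [
    "StrategyOutcomes",
    "EconSummary",
    "person_years",
    "state_utility",
    "qalys",
    "costs",
    "economic_summary",
    "incremental_net_health_benefit",
    "headroom_cost",
]

COST_CATEGORIES = ("health_care", "informal_care", "platform", "coaching")


def person_years(trace: Trace) -> dict[str, float]:
    """Undiscounted per-person years alive, and with/without each disease."""
    out = {"alive": 0.0}
    for d in DISEASES:
        out[f"with_{d}"] = 0.0
    for s in trace.strata:
        occ = s.occupancy[1:]  # end-of-cycle occupancy
        out["alive"] += s.weight * occ[:, :8].sum()
        for d in DISEASES:
            idx = [i for i, st in enumerate(ALIVE_STATES) if d in st]
            out[f"with_{d}"] += s.weight * occ[:, idx].sum()
    for d in DISEASES:
        out[f"without_{d}"] = out["alive"] - out[f"with_{d}"]
    return out


def state_utility(
    params: UtilityParams,
    age: float,
    sex: str,
    state,
    combine: str = "multiplicative",
) -> float:
    """Utility of an alive state (or 0 for ``"dead"``), clamped to [0, 1].

    The general-population regression value is reduced for each disease in
    the state, multiplicatively through the disease/general-population
    utility ratios (default) or, with ``combine="additive"``, by summing the
    per-disease decrements (1 - ratio) on the general-population value.
    """
    if state == "dead":
        return 0.0
    base = params.genpop_utility(age, sex)
    state = frozenset(state)
    if combine == "multiplicative":
        u = base
        for d in DISEASES:
            if d in state:
                u *= params.ratio.get(d, 1.0)
    elif combine == "additive":
        u = base * (1.0 - sum(1.0 - params.ratio.get(d, 1.0) for d in DISEASES if d in state))
    else:
        raise ParameterError(f"unknown utility combination {combine!r}")
    return min(1.0, max(0.0, u))


def qalys(
    trace: Trace,
    params: UtilityParams,
    settings: EconSettings,
    combine: str = "multiplicative",
) -> float:
    """Discounted QALYs per person over the trace.

    Per cycle: end-of-cycle occupancy times state utility at the attained
    age, plus expected MI/stroke events times their event-year disutility,
    discounted by (1 + r)^-t.
    """
    r = settings.discount_rate_effects
    total = 0.0
    for s in trace.strata:
        for t in range(s.n_cycles):
            age = s.start_age + t + 1
            u = 0.0
            for i, st in enumerate(ALIVE_STATES):
                m = s.occupancy[t + 1, i]
                if m > 0:
                    u += m * state_utility(params, age, s.sex, st, combine)
            for j, d in enumerate(DISEASES):
                u += s.events[t, j] * params.event_disutility.get(d, 0.0)
            total += s.weight * u / (1.0 + r) ** t
    return total


def costs(
    trace: Trace,
    params: CostParams,
    policy: WaningPolicy,
    settings: EconSettings,
    strategy: str | None = None,
) -> dict[str, float]:
    """Discounted per-person costs by category.

    Disease history person-time carries the post-year-1 annual costs; each
    expected event adds its one-off year-1 cost on top. Under the
    intervention strategy, platform and coaching prices accrue per adherent
    surviving user-year while the intervention runs.
    """
    strategy = trace.strategy if strategy is None else strategy
    r = settings.discount_rate_costs
    out = {c: 0.0 for c in COST_CATEGORIES}
    for s in trace.strata:
        for t in range(s.n_cycles):
            disc = 1.0 / (1.0 + r) ** t
            health = informal = 0.0
            for i, st in enumerate(ALIVE_STATES):
                m = s.occupancy[t + 1, i]
                if m > 0:
                    for d in DISEASES:
                        if d in st:
                            health += m * params.get_annual(d, "health_sector")
                            informal += m * params.get_annual(d, "informal")
            for j, d in enumerate(DISEASES):
                ev = s.events[t, j]
                if ev > 0:
                    health += ev * params.get_event(d, "health_sector")
                    informal += ev * params.get_event(d, "informal")
            out["health_care"] += s.weight * disc * health
            out["informal_care"] += s.weight * disc * informal
            if strategy == "intervention" and t < params.duration_years:
                exposure = (
                    effects.adherent_fraction(t, policy) * s.occupancy[t, :8].sum()
                )
                out["platform"] += s.weight * disc * params.platform_per_user_year * exposure
                if t < params.effective_coaching_years:
                    out["coaching"] += s.weight * disc * params.coaching_per_user_year * exposure
    out["total"] = sum(out[c] for c in COST_CATEGORIES)
    return out


@dataclass(frozen=True)
class StrategyOutcomes:
    """Per-strategy results: events per cohort, person-years, QALYs, costs."""

    events: Mapping[str, float]
    person_years: Mapping[str, float]
    qalys: float
    costs: Mapping[str, float]


@dataclass(frozen=True)
class EconSummary:
    """Paired-strategy economic summary with ICER and iNHB.

    ``icer`` is None (undefined) when the QALY difference is zero.
    """

    soc: StrategyOutcomes
    intervention: StrategyOutcomes
    wtp: float
    cohort_size: int
    country: str = ""
    scenario: str = "base_case"

    @property
    def delta_qalys(self) -> float:
        return self.intervention.qalys - self.soc.qalys

    @property
    def delta_costs(self) -> float:
        return self.intervention.costs["total"] - self.soc.costs["total"]

    @property
    def prevented_events(self) -> dict[str, float]:
        return {d: self.soc.events[d] - self.intervention.events[d] for d in DISEASES}

    @property
    def icer(self) -> float | None:
        if self.delta_qalys == 0:
            return None
        return self.delta_costs / self.delta_qalys

    @property
    def inhb(self) -> float:
        return incremental_net_health_benefit(self.delta_qalys, self.delta_costs, self.wtp)

    def to_frame(self) -> pd.DataFrame:
        """Two-strategy summary table with difference columns."""
        rows = []

        def add(label, a, b, pct_base=None):
            diff = b - a
            base = a if pct_base is None else pct_base
            pct = (diff / base * 100.0) if base not in (0, 0.0) else np.nan
            rows.append(
                {
                    "item": label,
                    "standard_of_care": a,
                    "intervention": b,
                    "difference": diff,
                    "difference_pct": pct,
                }
            )

        for d in DISEASES:
            add(f"{d}_events_per_cohort", self.soc.events[d], self.intervention.events[d])
        for k in self.soc.person_years:
            add(f"person_years_{k}", self.soc.person_years[k], self.intervention.person_years[k])
        add("qalys", self.soc.qalys, self.intervention.qalys)
        for c in (*COST_CATEGORIES, "total"):
            add(f"cost_{c}", self.soc.costs[c], self.intervention.costs[c])
        nhb_soc = self.soc.qalys - self.soc.costs["total"] / self.wtp
        nhb_int = self.intervention.qalys - self.intervention.costs["total"] / self.wtp
        add("net_health_benefit", nhb_soc, nhb_int)
        return pd.DataFrame(rows)


def incremental_net_health_benefit(delta_qalys: float, delta_costs: float, wtp: float) -> float:
    """iNHB = (Ei - Ec) - (Ci - Cc) / lambda."""
    if wtp <= 0:
        raise ParameterError("wtp must be > 0")
    return delta_qalys - delta_costs / wtp


def _strategy_outcomes(trace: Trace, bundle: ParameterBundle, combine: str) -> StrategyOutcomes:
    return StrategyOutcomes(
        events=scale_events(trace),
        person_years=person_years(trace),
        qalys=qalys(trace, bundle.utilities, bundle.econ, combine),
        costs=costs(trace, bundle.costs, bundle.waning, bundle.econ),
    )


def economic_summary(
    trace_soc: Trace,
    trace_int: Trace,
    bundle: ParameterBundle,
    combine: str = "multiplicative",
    scenario: str = "base_case",
) -> EconSummary:
    """Full paired summary from two traces of the same bundle and horizon."""
    if trace_soc.horizon != trace_int.horizon:
        raise ParameterError("traces must share the same horizon")
    return EconSummary(
        soc=_strategy_outcomes(trace_soc, bundle, combine),
        intervention=_strategy_outcomes(trace_int, bundle, combine),
        wtp=bundle.econ.wtp,
        cohort_size=bundle.cohort.cohort_size,
        country=bundle.country,
        scenario=scenario,
    )


def headroom_cost(
    bundle: ParameterBundle,
    effect_scope: str = "dementia_only",
    policy: WaningPolicy | None = None,
    settings: EconSettings | None = None,
    rel_tol: float = 1e-6,
) -> float:
    """Maximum annual per-user intervention price at which iNHB = 0.

    The platform and coaching prices are replaced by a single unknown
    annual cost; the traces do not depend on it, so iNHB is linear and
    strictly decreasing in the price, and the root is found by bisection to
    ``rel_tol`` relative tolerance.
    """
    policy = bundle.waning if policy is None else policy
    settings = bundle.econ if settings is None else settings
    trace_soc = run_cohort(bundle, "standard_of_care")
    trace_int = run_cohort(bundle, "intervention", effect_scope=effect_scope, waning=policy)
    d_qalys = qalys(trace_int, bundle.utilities, settings) - qalys(
        trace_soc, bundle.utilities, settings
    )
    if d_qalys <= 0:
        raise ParameterError(
            "headroom requires a positive QALY gain under the chosen effect scope"
        )

    def inhb_at(price: float) -> float:
        cp = CostParams(
            annual=bundle.costs.annual,
            event=bundle.costs.event,
            platform_per_user_year=max(price, 0.0),
            coaching_per_user_year=0.0,
            duration_years=bundle.costs.duration_years,
        )
        d_costs = costs(trace_int, cp, policy, settings)["total"] - costs(
            trace_soc, cp, policy, settings
        )["total"]
        # allow negative prices through a linear extension (cp clamps at 0)
        if price < 0:
            exposure = _intervention_exposure(trace_int, policy, settings, cp.duration_years)
            d_costs += price * exposure
        return incremental_net_health_benefit(d_qalys, d_costs, settings.wtp)

    lo, hi = 0.0, 1.0
    while inhb_at(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ParameterError("headroom bracket exceeded 1e12; check inputs")
    if inhb_at(lo) < 0:
        lo = -1.0
        while inhb_at(lo) < 0:
            lo *= 2.0
            if lo < -1e12:
                raise ParameterError("headroom bracket exceeded -1e12; check inputs")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if inhb_at(mid) >= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * max(1.0, abs(mid)):
            break
    return 0.5 * (lo + hi)


def _intervention_exposure(
    trace: Trace, policy: WaningPolicy, settings: EconSettings, duration_years: int
) -> float:
    """Discounted adherence-weighted surviving user-years per person."""
    r = settings.discount_rate_costs
    total = 0.0
    for s in trace.strata:
        for t in range(min(s.n_cycles, duration_years)):
            total += (
                s.weight
                * effects.adherent_fraction(t, policy)
                * s.occupancy[t, :8].sum()
                / (1.0 + r) ** t
            )
    return total
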