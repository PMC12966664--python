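"""Nine-state cohort trace: 8 alive disease-history states plus death.

The alive states are the subsets of {dementia, mi, stroke}; death is
absorbing with cause bookkeeping (CVD vs other). Each yearly cycle handles
death first from the state's summed cause rates; conditional on survival,
each absent disease onsets independently with its converted probability
(simultaneous multi-disease onset is allowed as the product of independent
onset probabilities) and present MI/stroke contribute expected recurrent
events without changing state. The cohort is expanded into (integer age,
sex, history) strata — uniform within age bands — each simulated
deterministically to the horizon age and aggregated by starting weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import effects
from .epidemiology import (
    HazardSet,
    calibrate_baseline_mortality,
    incidence_rate,
    rate_to_probability,
)
from .parameters import (
    DISEASES,
    CompositeRR,
    ParameterBundle,
    ParameterError,
    PrevalenceTable,
    WaningPolicy,
    history_key,
)

__all__ = [
    "ALIVE_STATES",
    "N_STATES",
    "IDX_DEAD_CVD",
    "IDX_DEAD_OTHER",
    "StateSpace",
    "StratumTrace",
    "Trace",
    "transition_row",
    "run_cohort",
    "scale_events",
    "simulated_prevalence",
]

_BITS = {"dementia": 1, "mi": 2, "stroke": 4}

#: The 8 alive states ordered by bitmask (dementia=1, mi=2, stroke=4).
ALIVE_STATES: tuple[frozenset, ...] = tuple(
    frozenset(d for d in DISEASES if _BITS[d] & i) for i in range(8)
)
IDX_DEAD_CVD = 8
IDX_DEAD_OTHER = 9
N_STATES = 10


def state_index(state) -> int:
    return sum(_BITS[d] for d in state)


@dataclass(frozen=True)
class StateSpace:
    """The transition structure: 8 alive subset states plus absorbing death."""

    alive: tuple[frozenset, ...] = ALIVE_STATES

    def __post_init__(self) -> None:
        assert len(self.alive) == 8
        # closure under adding a disease
        for s in self.alive:
            for d in DISEASES:
                assert s | {d} in self.alive

    @property
    def n_states(self) -> int:
        return len(self.alive) + 1


def transition_row(
    state, hazards: HazardSet, cycle_length: float = 1.0
) -> tuple[np.ndarray, dict[str, float]]:
    """One-cycle successor distribution and event expectations per unit mass.

    Death is handled first (cause split proportional to the two cause
    rates); conditional on survival each absent disease onsets
    independently, and present MI/stroke accrue expected recurrent events
    (rate x cycle_length x survivor mass) without changing state. The
    returned row spans the 10 occupancy slots (8 alive + death by cause)
    and sums to 1.
    """
    state = frozenset(state)
    i = state_index(state)
    row = np.zeros(N_STATES)
    events = {d: 0.0 for d in DISEASES}

    total_death = hazards.death_cvd + hazards.death_other
    p_death = rate_to_probability(total_death, cycle_length)
    if total_death > 0:
        row[IDX_DEAD_CVD] = p_death * hazards.death_cvd / total_death
        row[IDX_DEAD_OTHER] = p_death * hazards.death_other / total_death
    surv = 1.0 - p_death

    absent = [d for d in DISEASES if d not in state]
    p_onset = {d: rate_to_probability(hazards.incidence(d), cycle_length) for d in absent}
    for k in range(len(absent) + 1):
        for combo in combinations(absent, k):
            prob = 1.0
            for d in absent:
                prob *= p_onset[d] if d in combo else (1.0 - p_onset[d])
            row[i | sum(_BITS[d] for d in combo)] += surv * prob

    for d in absent:
        events[d] += surv * p_onset[d]
    for d in ("mi", "stroke"):
        if d in state:
            events[d] += hazards.incidence(d) * cycle_length * surv
    return row, events


@dataclass
class StratumTrace:
    """Trace of one (start age, sex, history) stratum.

    ``occupancy[t]`` is the distribution over the 10 occupancy slots at the
    start of cycle ``t`` (equivalently the end of cycle ``t``-1), when the
    stratum is aged ``start_age + t``; ``events[t]`` and ``deaths[t]`` are
    the expectations accrued during cycle ``t``.
    """

    start_age: int
    sex: str
    weight: float
    occupancy: np.ndarray  # (T+1, 10)
    events: np.ndarray  # (T, 3) ordered dementia, mi, stroke
    deaths: np.ndarray  # (T, 2) ordered cvd, other

    @property
    def n_cycles(self) -> int:
        return self.events.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.n_cycles + 1)


@dataclass
class Trace:
    """Aggregated cohort trace: weighted strata plus bookkeeping."""

    strata: list[StratumTrace]
    horizon: int
    cohort_size: int
    strategy: str

    def cumulative_events(self) -> dict[str, float]:
        """Expected lifetime events per person, by disease (incl. recurrent)."""
        out = {d: 0.0 for d in DISEASES}
        for s in self.strata:
            totals = s.events.sum(axis=0)
            for j, d in enumerate(DISEASES):
                out[d] += s.weight * totals[j]
        return out

    def cumulative_deaths(self) -> dict[str, float]:
        out = {"cvd": 0.0, "other": 0.0}
        for s in self.strata:
            t = s.deaths.sum(axis=0)
            out["cvd"] += s.weight * t[0]
            out["other"] += s.weight * t[1]
        return out

    def occupancy_by_cycle(self) -> np.ndarray:
        """Weighted occupancy by cycle since model start, shape (T_max+1, 10).

        Strata that reach the horizon before ``T_max`` hold their final
        distribution thereafter (their simulation has ended; the frozen rows
        are a bookkeeping convention for plotting, not accrued person-time).
        """
        t_max = max(s.n_cycles for s in self.strata)
        out = np.zeros((t_max + 1, N_STATES))
        for s in self.strata:
            occ = s.occupancy
            for t in range(t_max + 1):
                out[t] += s.weight * occ[min(t, s.n_cycles)]
        return out

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy per-stratum occupancy (stratum, cycle, age, state, occupancy)."""
        rows = []
        for s in self.strata:
            label = f"{s.start_age}/{s.sex}"
            for t in range(s.n_cycles + 1):
                for i, st in enumerate(ALIVE_STATES):
                    rows.append(
                        {
                            "stratum": label,
                            "weight": s.weight,
                            "cycle": t,
                            "age": s.start_age + t,
                            "state": history_key(st) if st else "at_risk",
                            "occupancy": s.occupancy[t, i],
                        }
                    )
                rows.append(
                    {
                        "stratum": label,
                        "weight": s.weight,
                        "cycle": t,
                        "age": s.start_age + t,
                        "state": "dead",
                        "occupancy": s.occupancy[t, IDX_DEAD_CVD] + s.occupancy[t, IDX_DEAD_OTHER],
                    }
                )
        return pd.DataFrame(rows)

    def events_frame(self) -> pd.DataFrame:
        rows = []
        t_max = max(s.n_cycles for s in self.strata)
        ev = np.zeros((t_max, 3))
        dth = np.zeros((t_max, 2))
        for s in self.strata:
            ev[: s.n_cycles] += s.weight * s.events
            dth[: s.n_cycles] += s.weight * s.deaths
        for t in range(t_max):
            for j, d in enumerate(DISEASES):
                rows.append({"cycle": t, "event_type": d, "expected_count": ev[t, j]})
            rows.append({"cycle": t, "event_type": "death_cvd", "expected_count": dth[t, 0]})
            rows.append({"cycle": t, "event_type": "death_other", "expected_count": dth[t, 1]})
        return pd.DataFrame(rows)


def _expand_cohort(bundle: ParameterBundle) -> list[tuple[int, str, frozenset, float]]:
    """(integer age, sex, history, weight) strata, uniform within age bands."""
    strata: dict[tuple[int, str, frozenset], float] = {}
    for (band, sex, hist), p in bundle.cohort.cells.items():
        lo, hi = band
        ages = range(lo, hi + 1)
        w = p / len(ages)
        for a in ages:
            key = (a, sex, hist)
            strata[key] = strata.get(key, 0.0) + w
    return [(a, s, h, w) for (a, s, h), w in sorted(strata.items(), key=lambda kv: (kv[0][0], kv[0][1], history_key(kv[0][2]))) if w > 0]


def _hazard_cache(bundle: ParameterBundle, horizon: int):
    """Precompute base incidence and calibrated baseline mortality by (age, sex)."""
    ages = [a for a in bundle.life_table.ages if a <= horizon]
    base_inc: dict[tuple[str, str, int], float] = {}
    base_mort: dict[tuple[str, int], tuple[float, float]] = {}
    for sex in ("male", "female"):
        for a in ages:
            for d in DISEASES:
                base_inc[(d, sex, a)] = incidence_rate(bundle.incidence[d], a, sex)
            base_mort[(sex, a)] = calibrate_baseline_mortality(
                bundle.life_table, bundle.prevalence, bundle.mortality_rrs, a, sex
            )
    return base_inc, base_mort


def run_cohort(
    bundle: ParameterBundle,
    strategy: str = "standard_of_care",
    horizon: int | None = None,
    composite: CompositeRR | None = None,
    waning: WaningPolicy | None = None,
    effect_scope: str = "all",
    cycle_length: float = 1.0,
) -> Trace:
    """Deterministic cohort trace for one strategy.

    Under ``strategy="intervention"`` the composite intervention RR — taken
    from ``composite`` or evaluated from the bundle's risk-model specs — is
    applied, waned per the bundle's (or the supplied) waning policy, to the
    incidence of all three diseases in every alive state; it never acts on
    mortality. ``effect_scope="dementia_only"`` restricts it to dementia
    onset. ``standard_of_care`` applies no effect.
    """
    if strategy not in ("standard_of_care", "intervention"):
        raise ParameterError(f"unknown strategy {strategy!r}")
    if effect_scope not in ("all", "dementia_only"):
        raise ParameterError(f"unknown effect_scope {effect_scope!r}")
    horizon = bundle.econ.max_age if horizon is None else int(horizon)
    waning = bundle.waning if waning is None else waning
    if strategy == "intervention" and composite is None:
        composite = effects.composite_from_specs(bundle.risk_models)

    lt_max = max(bundle.life_table.ages)
    if horizon > lt_max + 1:
        raise ParameterError(
            f"horizon age {horizon} exceeds life-table coverage (max age {lt_max})"
        )

    base_inc, base_mort = _hazard_cache(bundle, horizon)

    # per-state multipliers: history RRs for incidence, per-cause mortality RRs
    hist_mult = {
        d: np.array(
            [
                math.prod(bundle.incidence[d].history_rr.get(x, 1.0) for x in DISEASES if x in st)
                for st in ALIVE_STATES
            ]
        )
        for d in DISEASES
    }
    mort_mult = {
        cause: np.array(
            [
                math.prod(bundle.mortality_rrs.for_cause(cause).get(x, 1.0) for x in DISEASES if x in st)
                for st in ALIVE_STATES
            ]
        )
        for cause in ("cvd", "other")
    }

    strata_out: list[StratumTrace] = []
    for start_age, sex, hist, weight in _expand_cohort(bundle):
        n_cycles = max(0, horizon - start_age)
        occ = np.zeros((n_cycles + 1, N_STATES))
        occ[0, state_index(hist)] = 1.0
        ev = np.zeros((n_cycles, 3))
        dth = np.zeros((n_cycles, 2))
        for t in range(n_cycles):
            age = start_age + t
            if strategy == "intervention":
                rr = {
                    d: effects.effective_rr(composite.for_disease(d, sex), t, waning)
                    for d in DISEASES
                }
                if effect_scope == "dementia_only":
                    rr["mi"] = rr["stroke"] = 1.0
            else:
                rr = {d: 1.0 for d in DISEASES}
            b_cvd, b_oth = base_mort[(sex, age)]
            nxt = occ[t].copy()
            for i, st in enumerate(ALIVE_STATES):
                mass = occ[t, i]
                if mass <= 0.0:
                    continue
                nxt[i] -= mass
                hz = HazardSet(
                    dementia=0.0
                    if "dementia" in st
                    else base_inc[("dementia", sex, age)] * hist_mult["dementia"][i] * rr["dementia"],
                    mi=base_inc[("mi", sex, age)] * hist_mult["mi"][i] * rr["mi"],
                    stroke=base_inc[("stroke", sex, age)] * hist_mult["stroke"][i] * rr["stroke"],
                    death_cvd=b_cvd * mort_mult["cvd"][i],
                    death_other=b_oth * mort_mult["other"][i],
                )
                row, events = transition_row(st, hz, cycle_length)
                nxt += mass * row
                for j, d in enumerate(DISEASES):
                    ev[t, j] += mass * events[d]
                dth[t, 0] += mass * row[IDX_DEAD_CVD]
                dth[t, 1] += mass * row[IDX_DEAD_OTHER]
            occ[t + 1] = nxt
        strata_out.append(
            StratumTrace(
                start_age=start_age,
                sex=sex,
                weight=weight,
                occupancy=occ,
                events=ev,
                deaths=dth,
            )
        )
    return Trace(
        strata=strata_out,
        horizon=horizon,
        cohort_size=bundle.cohort.cohort_size,
        strategy=strategy,
    )


def scale_events(trace: Trace, cohort_size: int | None = None) -> dict[str, float]:
    """Expected lifetime event counts per ``cohort_size`` persons."""
    n = trace.cohort_size if cohort_size is None else cohort_size
    if n <= 0:
        raise ParameterError("cohort_size must be > 0")
    return {d: v * n for d, v in trace.cumulative_events().items()}


def simulated_prevalence(trace: Trace) -> PrevalenceTable:
    """Marginal disease prevalence among the alive, by (age, sex), from a trace."""
    num: dict[tuple[int, str, str], float] = {}
    den: dict[tuple[int, str], float] = {}
    for s in trace.strata:
        for t in range(s.n_cycles + 1):
            age = s.start_age + t
            alive = s.occupancy[t, :8].sum()
            den[(age, s.sex)] = den.get((age, s.sex), 0.0) + s.weight * alive
            for d in DISEASES:
                with_d = sum(
                    s.occupancy[t, i] for i, st in enumerate(ALIVE_STATES) if d in st
                )
                key = (age, s.sex, d)
                num[key] = num.get(key, 0.0) + s.weight * with_d
    values = {
        (a, sx, d): (num[(a, sx, d)] / den[(a, sx)] if den[(a, sx)] > 0 else 0.0)
        for (a, sx, d) in num
    }
    return PrevalenceTable(values)
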