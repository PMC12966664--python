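import math

import numpy as np
import pytest

from demcvd.engine import (
    ALIVE_STATES,
    IDX_DEAD_CVD,
    IDX_DEAD_OTHER,
    N_STATES,
    StateSpace,
    run_cohort,
    scale_events,
    state_index,
    transition_row,
)
from demcvd.epidemiology import HazardSet, rate_to_probability
from demcvd.parameters import CompositeRR

from _helpers import build_toy_bundle, microsim_cohort


class TestStateSpace:
    def test_eight_alive_states_plus_death(self):
        space = StateSpace()
        assert len(space.alive) == 8
        assert space.n_states == 9
        assert frozenset() in space.alive
        assert frozenset({"dementia", "mi", "stroke"}) in space.alive

    def test_bitmask_ordering(self):
        assert state_index(frozenset()) == 0
        assert state_index(frozenset({"dementia"})) == 1
        assert state_index(frozenset({"mi", "stroke"})) == 6


class TestTransitionRow:
    def test_zero_hazards_stay_put(self):
        hz = HazardSet(0, 0, 0, 0, 0)
        row, events = transition_row(frozenset({"mi"}), hz)
        assert row[state_index({"mi"})] == 1.0
        assert row.sum() == pytest.approx(1.0, abs=1e-15)
        assert all(v == 0 for v in events.values())

    def test_row_sums_to_one(self):
        hz = HazardSet(0.05, 0.02, 0.03, 0.04, 0.08)
        for st in ALIVE_STATES:
            row, _ = transition_row(st, hz)
            assert row.sum() == pytest.approx(1.0, abs=1e-12)
            assert (row >= 0).all()

    def test_death_handled_first(self):
        """Onset probabilities act only on the surviving mass."""
        hz = HazardSet(0.5, 0.0, 0.0, 0.3, 0.2)
        row, events = transition_row(frozenset(), hz)
        p_death = rate_to_probability(0.5)
        surv = 1 - p_death
        p_on = rate_to_probability(0.5)
        assert row[IDX_DEAD_CVD] + row[IDX_DEAD_OTHER] == pytest.approx(p_death)
        assert row[IDX_DEAD_CVD] / row[IDX_DEAD_OTHER] == pytest.approx(0.3 / 0.2)
        assert row[state_index({"dementia"})] == pytest.approx(surv * p_on)
        assert events["dementia"] == pytest.approx(surv * p_on)

    def test_recurrent_events_do_not_change_state(self):
        hz = HazardSet(0.0, 0.2, 0.0, 0.0, 0.0)
        row, events = transition_row(frozenset({"mi"}), hz)
        assert row[state_index({"mi"})] == pytest.approx(1.0)
        assert events["mi"] == pytest.approx(0.2)  # rate x cycle x survivors

    def test_simultaneous_onset_allowed(self):
        hz = HazardSet(0.1, 0.1, 0.1, 0.0, 0.0)
        row, _ = transition_row(frozenset(), hz)
        assert row[state_index({"dementia", "mi", "stroke"})] > 0

    def test_matches_microsimulation(self):
        """Successor distribution agrees with a large seeded random walk."""
        hz = HazardSet(0.08, 0.05, 0.04, 0.06, 0.10)
        row, _ = transition_row(frozenset(), hz)
        n = 400_000
        rng = np.random.default_rng(42)
        total = hz.death_cvd + hz.death_other
        died = rng.random(n) < rate_to_probability(total)
        cause_cvd = rng.random(n) < hz.death_cvd / total
        onsets = {
            d: rng.random(n) < rate_to_probability(getattr(hz, d))
            for d in ("dementia", "mi", "stroke")
        }
        counts = np.zeros(N_STATES)
        bits = {"dementia": 1, "mi": 2, "stroke": 4}
        for i in range(n):
            if died[i]:
                counts[IDX_DEAD_CVD if cause_cvd[i] else IDX_DEAD_OTHER] += 1
            else:
                s = 0
                for d, b in bits.items():
                    if onsets[d][i]:
                        s |= b
                counts[s] += 1
        emp = counts / n
        for j in range(N_STATES):
            se = math.sqrt(max(row[j] * (1 - row[j]), 1e-12) / n)
            assert abs(emp[j] - row[j]) < 3 * se + 1e-9


class TestRunCohort:
    def test_conservation_and_monotone_death(self, uk_bundle):
        trace = run_cohort(uk_bundle, "standard_of_care")
        for s in trace.strata:
            sums = s.occupancy.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-10)
            dead = s.occupancy[:, IDX_DEAD_CVD] + s.occupancy[:, IDX_DEAD_OTHER]
            assert (np.diff(dead) >= -1e-12).all()
            assert (s.occupancy >= -1e-15).all()

    def test_null_intervention_matches_standard_of_care(self):
        bundle = build_toy_bundle(start_age=88, horizon=100)
        soc = run_cohort(bundle, "standard_of_care")
        null = run_cohort(bundle, "intervention", composite=CompositeRR.null())
        for a, b in zip(soc.strata, null.strata):
            assert np.array_equal(a.occupancy, b.occupancy)
            assert np.array_equal(a.events, b.events)

    def test_geometric_cumulative_incidence_without_mortality(self):
        """Zero mortality + constant dementia rate r: cumulative onset after
        t cycles is 1 - (1-p)^t with p = 1 - exp(-r)."""
        r = 0.05
        bundle = build_toy_bundle(
            start_age=90, horizon=100, zero_mortality=True, dementia_rate=r
        )
        # silence the other diseases
        from dataclasses import replace

        incidence = dict(bundle.incidence)
        incidence["mi"] = replace(incidence["mi"], intercept=-745.0, b_age=0.0, b_sex=0.0)
        incidence["stroke"] = replace(
            incidence["stroke"], intercept=-745.0, b_age=0.0, b_sex=0.0
        )
        bundle = bundle.replace(incidence=incidence)
        trace = run_cohort(bundle, "standard_of_care")
        (s,) = trace.strata
        p = 1 - math.exp(-r)
        for t in range(s.n_cycles + 1):
            expected = 1 - (1 - p) ** t
            dem_mass = s.occupancy[t, state_index({"dementia"})]
            assert dem_mass == pytest.approx(expected, abs=1e-12)
        assert s.events[:, 0].sum() == pytest.approx(1 - (1 - p) ** s.n_cycles, abs=1e-12)

    def test_reduces_to_three_state_model_with_dementia_only(self):
        """With MI/stroke hazards silenced the 9-state engine reproduces an
        independent at-risk/dementia/death reference exactly."""
        from dataclasses import replace

        from demcvd.epidemiology import calibrate_baseline_mortality, state_mortality

        bundle = build_toy_bundle(start_age=90, horizon=100)
        incidence = dict(bundle.incidence)
        for d in ("mi", "stroke"):
            incidence[d] = replace(incidence[d], intercept=-745.0, b_age=0.0, b_sex=0.0)
        bundle = bundle.replace(incidence=incidence)
        trace = run_cohort(bundle, "standard_of_care")
        (s,) = trace.strata

        # independent 3-state reference
        at_risk, dem, dead = 1.0, 0.0, 0.0
        ref = [(at_risk, dem, dead)]
        for t in range(s.n_cycles):
            age = 90 + t
            base = calibrate_baseline_mortality(
                bundle.life_table, bundle.prevalence, bundle.mortality_rrs, age, "female"
            )
            m0 = sum(state_mortality(base, frozenset(), bundle.mortality_rrs))
            m1 = sum(state_mortality(base, {"dementia"}, bundle.mortality_rrs))
            from demcvd.epidemiology import incidence_rate, rate_to_probability

            p_on = rate_to_probability(
                incidence_rate(bundle.incidence["dementia"], age, "female")
            )
            pd0, pd1 = rate_to_probability(m0), rate_to_probability(m1)
            new_dead = dead + at_risk * pd0 + dem * pd1
            new_dem = dem * (1 - pd1) + at_risk * (1 - pd0) * p_on
            new_at_risk = at_risk * (1 - pd0) * (1 - p_on)
            at_risk, dem, dead = new_at_risk, new_dem, new_dead
            ref.append((at_risk, dem, dead))
        for t, (a, d_, x) in enumerate(ref):
            assert s.occupancy[t, 0] == pytest.approx(a, abs=1e-12)
            assert s.occupancy[t, 1] == pytest.approx(d_, abs=1e-12)
            dead_t = s.occupancy[t, IDX_DEAD_CVD] + s.occupancy[t, IDX_DEAD_OTHER]
            assert dead_t == pytest.approx(x, abs=1e-12)

    def test_cohort_trace_matches_microsimulation(self):
        """Deterministic occupancy equals the mean of an individual-level
        simulation with the same hazards, within 3 Monte-Carlo SEs."""
        bundle = build_toy_bundle(start_age=92, horizon=97)
        trace = run_cohort(bundle, "standard_of_care")
        (s,) = trace.strata
        n = 200_000
        emp = microsim_cohort(bundle, 92, "female", frozenset(), s.n_cycles, n, seed=5)
        expected = s.occupancy[-1]
        for j in range(N_STATES):
            se = math.sqrt(max(expected[j] * (1 - expected[j]), 1e-12) / n)
            assert abs(emp[j] - expected[j]) < 3 * se + 1e-9

    def test_age_band_expansion_uniform(self, uk_bundle):
        trace = run_cohort(uk_bundle, "standard_of_care")
        start_ages = sorted({s.start_age for s in trace.strata})
        assert start_ages == list(range(55, 75))
        total_weight = sum(s.weight for s in trace.strata)
        assert total_weight == pytest.approx(1.0, abs=1e-12)

    def test_horizon_limits_cycles(self, uk_bundle):
        trace = run_cohort(uk_bundle, "standard_of_care", horizon=80)
        for s in trace.strata:
            assert s.n_cycles == 80 - s.start_age

    def test_intervention_reduces_dementia_onsets(self, uk_bundle):
        soc = run_cohort(uk_bundle, "standard_of_care")
        inter = run_cohort(uk_bundle, "intervention")
        assert (
            inter.cumulative_events()["dementia"] < soc.cumulative_events()["dementia"]
        )


class TestScaleEvents:
    def test_scaling(self):
        bundle = build_toy_bundle(start_age=90)
        trace = run_cohort(bundle, "standard_of_care")
        per_person = trace.cumulative_events()
        scaled = scale_events(trace, 100_000)
        for d in per_person:
            assert scaled[d] == pytest.approx(per_person[d] * 100_000)

    def test_prevented_events_is_difference_by_construction(self, uk_bundle):
        soc = run_cohort(uk_bundle, "standard_of_care")
        inter = run_cohort(uk_bundle, "intervention")
        prevented = {
            d: scale_events(soc)[d] - scale_events(inter)[d] for d in scale_events(soc)
        }
        assert prevented["dementia"] > 0
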