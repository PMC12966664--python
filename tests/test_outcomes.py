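from dataclasses import replace

import numpy as np
import pytest

from demcvd.engine import Trace, StratumTrace, run_cohort, state_index
from demcvd.outcomes import (
    costs,
    economic_summary,
    headroom_cost,
    incremental_net_health_benefit,
    person_years,
    qalys,
    state_utility,
)
from demcvd.parameters import (
    DISEASES,
    CostParams,
    EconSettings,
    ParameterError,
    UtilityParams,
    WaningPolicy,
)

from _helpers import build_toy_bundle


def single_stratum_trace(occupancy, events=None, deaths=None, strategy="standard_of_care",
                         start_age=60, sex="male"):
    occupancy = np.asarray(occupancy, dtype=float)
    n = occupancy.shape[0] - 1
    return Trace(
        strata=[
            StratumTrace(
                start_age=start_age,
                sex=sex,
                weight=1.0,
                occupancy=occupancy,
                events=np.zeros((n, 3)) if events is None else np.asarray(events, float),
                deaths=np.zeros((n, 2)) if deaths is None else np.asarray(deaths, float),
            )
        ],
        horizon=start_age + n,
        cohort_size=100_000,
        strategy=strategy,
    )


def immortal_trace(n_cycles, state=frozenset(), **kw):
    occ = np.zeros((n_cycles + 1, 10))
    occ[:, state_index(state)] = 1.0
    return single_stratum_trace(occ, **kw)


UTIL1 = UtilityParams(genpop=(1.0, 0.0, 0.0, 0.0), ratio={}, event_disutility={"mi": -0.025, "stroke": -0.048})
ECON0 = EconSettings(discount_rate_costs=0.0, discount_rate_effects=0.0, wtp=20_000.0)


class TestPersonYears:
    def test_empty_horizon(self):
        trace = immortal_trace(0)
        py = person_years(trace)
        assert all(v == 0 for v in py.values())

    def test_immortal_cohort(self):
        py = person_years(immortal_trace(12))
        assert py["alive"] == pytest.approx(12.0)

    def test_partition_identity(self, uk_bundle):
        trace = run_cohort(uk_bundle, "standard_of_care")
        py = person_years(trace)
        for d in DISEASES:
            assert py[f"with_{d}"] + py[f"without_{d}"] == pytest.approx(py["alive"])
            assert py[f"with_{d}"] <= py["alive"]


class TestStateUtility:
    def test_uk_male_65_disease_free(self, uk_bundle):
        u = state_utility(uk_bundle.utilities, 65, "male", frozenset())
        assert u == pytest.approx(0.8486, abs=5e-5)

    def test_dementia_ratio(self, uk_bundle):
        base = state_utility(uk_bundle.utilities, 65, "male", frozenset())
        dem = state_utility(uk_bundle.utilities, 65, "male", {"dementia"})
        assert dem == pytest.approx(base * 0.876)

    def test_dead_is_zero(self, uk_bundle):
        assert state_utility(uk_bundle.utilities, 65, "male", "dead") == 0.0

    def test_multiplicative_vs_additive_combination(self, uk_bundle):
        st = frozenset({"dementia", "stroke"})
        mult = state_utility(uk_bundle.utilities, 70, "female", st)
        add = state_utility(uk_bundle.utilities, 70, "female", st, combine="additive")
        base = uk_bundle.utilities.genpop_utility(70, "female")
        assert mult == pytest.approx(base * 0.876 * 0.839)
        assert add == pytest.approx(base * (1 - (1 - 0.876) - (1 - 0.839)))
        assert add < mult

    def test_clamped_to_unit_interval(self):
        params = UtilityParams(genpop=(2.0, 0.0, 0.0, 0.0), ratio={}, event_disutility={})
        assert state_utility(params, 60, "male", frozenset()) == 1.0


class TestQalys:
    def test_equal_life_years_without_discounting(self):
        trace = immortal_trace(10)
        assert qalys(trace, UTIL1, ECON0) == pytest.approx(10.0)

    def test_mi_event_disutility(self):
        events = np.zeros((1, 3))
        events[0, 1] = 1.0  # one expected MI event in cycle 0
        trace = immortal_trace(1, events=events)
        assert qalys(trace, UTIL1, ECON0) == pytest.approx(1.0 - 0.025)

    def test_discounting_never_increases_qalys(self, uk_bundle):
        trace = run_cohort(uk_bundle, "standard_of_care")
        lo = qalys(trace, uk_bundle.utilities, replace(uk_bundle.econ, discount_rate_effects=0.035))
        hi = qalys(trace, uk_bundle.utilities, replace(uk_bundle.econ, discount_rate_effects=0.07))
        assert hi <= lo


class TestCosts:
    cp = CostParams(
        annual={("dementia", "health_sector"): 100.0},
        event={("mi", "health_sector"): 500.0},
        platform_per_user_year=5.0,
        coaching_per_user_year=800.0,
        duration_years=10,
    )
    full_adherence = WaningPolicy(duration_years=10, annual_nonadherence=0.0)

    def test_standard_of_care_has_no_intervention_costs(self, uk_bundle):
        trace = run_cohort(uk_bundle, "standard_of_care")
        c = costs(trace, uk_bundle.costs, uk_bundle.waning, uk_bundle.econ)
        assert c["platform"] == 0.0
        assert c["coaching"] == 0.0

    def test_immortal_fully_adherent_coaching_total(self):
        """800/user-year for 10 years, undiscounted, everyone adherent: 8000."""
        trace = immortal_trace(20, strategy="intervention")
        c = costs(trace, self.cp, self.full_adherence, ECON0)
        assert c["coaching"] == pytest.approx(8000.0)
        assert c["platform"] == pytest.approx(50.0)

    def test_disease_annual_and_event_costs(self):
        occ = np.zeros((3, 10))
        occ[0, 0] = 1.0
        occ[1:, state_index({"dementia"})] = 1.0
        events = np.zeros((2, 3))
        events[0, 1] = 0.5
        trace = single_stratum_trace(occ, events=events)
        c = costs(trace, self.cp, self.full_adherence, ECON0)
        assert c["health_care"] == pytest.approx(2 * 100.0 + 0.5 * 500.0)
        assert c["informal_care"] == 0.0

    def test_coaching_window_cap(self):
        cp = replace(self.cp, coaching_years=2)
        trace = immortal_trace(20, strategy="intervention")
        c = costs(trace, cp, self.full_adherence, ECON0)
        assert c["coaching"] == pytest.approx(1600.0)
        assert c["platform"] == pytest.approx(50.0)

    def test_adherence_weighted_annuity(self, uk_bundle):
        """Coaching total equals the closed-form discounted adherence annuity
        weighted by the survivor proportion at the start of each year."""
        trace = run_cohort(uk_bundle, "intervention")
        c = costs(trace, uk_bundle.costs, uk_bundle.waning, uk_bundle.econ)
        expected = 0.0
        for s in trace.strata:
            for t in range(10):
                surv = s.occupancy[t, :8].sum()
                expected += s.weight * 800.0 * 0.9**t * 1.035**-t * surv
        assert c["coaching"] == pytest.approx(expected, rel=1e-12)

    def test_discounting_never_increases_costs(self, uk_bundle):
        trace = run_cohort(uk_bundle, "intervention")
        lo = costs(trace, uk_bundle.costs, uk_bundle.waning, replace(uk_bundle.econ, discount_rate_costs=0.07))
        hi = costs(trace, uk_bundle.costs, uk_bundle.waning, uk_bundle.econ)
        for k in hi:
            assert lo[k] <= hi[k] + 1e-12


class TestEconomicSummary:
    def test_inhb_of_rounded_differences(self):
        assert incremental_net_health_benefit(0.02, 4127.0, 20_000.0) == pytest.approx(
            -0.18635, abs=1e-12
        )
        assert incremental_net_health_benefit(0.01, 1697.0, 81_419.0) == pytest.approx(
            -0.01084, abs=5e-6
        )

    def test_null_differences_give_zero_inhb(self):
        assert incremental_net_health_benefit(0.0, 0.0, 20_000.0) == 0.0

    def test_icer_undefined_when_no_qaly_difference(self):
        bundle = build_toy_bundle()
        trace = run_cohort(bundle, "standard_of_care")
        summary = economic_summary(trace, trace, bundle)
        assert summary.delta_qalys == 0.0
        assert summary.icer is None

    def test_sign_agreement_inhb_vs_icer(self, uk_bundle):
        soc = run_cohort(uk_bundle, "standard_of_care")
        inter = run_cohort(uk_bundle, "intervention")
        s = economic_summary(soc, inter, uk_bundle)
        assert s.delta_qalys > 0
        # iNHB < 0 iff ICER above willingness to pay (for positive QALY gain)
        assert (s.inhb < 0) == (s.icer > s.wtp)

    def test_summary_table_shape(self, uk_bundle):
        soc = run_cohort(uk_bundle, "standard_of_care")
        inter = run_cohort(uk_bundle, "intervention")
        frame = economic_summary(soc, inter, uk_bundle).to_frame()
        assert {"item", "standard_of_care", "intervention", "difference", "difference_pct"} <= set(
            frame.columns
        )
        assert (frame[frame.item == "cost_total"].difference > 0).all()


class TestHeadroom:
    def test_bisection_matches_closed_form(self):
        """iNHB is linear in the annual price, so bisection must equal
        lambda*dE minus disease-cost offsets over the discounted
        adherence-weighted exposure."""
        bundle = build_toy_bundle(start_age=85, horizon=100)
        price = headroom_cost(bundle, effect_scope="dementia_only")
        from demcvd.outcomes import _intervention_exposure

        soc = run_cohort(bundle, "standard_of_care")
        inter = run_cohort(bundle, "intervention", effect_scope="dementia_only")
        d_e = qalys(inter, bundle.utilities, bundle.econ) - qalys(soc, bundle.utilities, bundle.econ)
        zero_price = replace(bundle.costs, platform_per_user_year=0.0, coaching_per_user_year=0.0)
        d_disease = (
            costs(inter, zero_price, bundle.waning, bundle.econ)["total"]
            - costs(soc, zero_price, bundle.waning, bundle.econ)["total"]
        )
        exposure = _intervention_exposure(inter, bundle.waning, bundle.econ, bundle.costs.duration_years)
        closed = (bundle.econ.wtp * d_e - d_disease) / exposure
        assert price == pytest.approx(closed, rel=1e-5)

    def test_linear_in_wtp_without_offsets(self):
        """With zero disease costs the headroom price doubles with lambda."""
        bundle = build_toy_bundle(start_age=85, horizon=100)
        no_disease_costs = replace(
            bundle.costs,
            annual={k: 0.0 for k in bundle.costs.annual},
            event={k: 0.0 for k in bundle.costs.event},
        )
        bundle = bundle.replace(costs=no_disease_costs)
        h1 = headroom_cost(bundle)
        bundle2 = bundle.replace(econ=replace(bundle.econ, wtp=2 * bundle.econ.wtp))
        h2 = headroom_cost(bundle2)
        assert h2 == pytest.approx(2 * h1, rel=1e-4)

    def test_requires_positive_qaly_gain(self):
        bundle = build_toy_bundle()
        # a harmful "intervention" (RR > 1) cannot have headroom
        from demcvd.parameters import RiskFactorEffect, RiskModelSpec

        harmful = {
            d: RiskModelSpec(d, (RiskFactorEffect("f", 2.0, +0.5, 0.0),), "harmful")
            for d in DISEASES
        }
        bundle = bundle.replace(risk_models=harmful)
        with pytest.raises(ParameterError, match="positive QALY gain"):
            headroom_cost(bundle)
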