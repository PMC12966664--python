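"""Scenario grid, external-validity classification and report writing.

A :class:`Scenario` is a pure override descriptor: applying it to a bundle
returns a new bundle (and run options) without mutating the original. The
bundled registry covers the base case, heterogeneity strata (start age 60
or 70, by sex), horizon ages, discounting and willingness-to-pay variants,
intervention cost multipliers, adherence/coaching variants, the
dementia-only effect, a no-CVD-history start, a direct dementia-RR
override and an incidence uplift for an increased-risk population.
Scenarios whose defining inputs are not published (alternative risk-score
coefficient tables, trial subgroup effects) are interface-only: they
refuse to run unless the user supplies the missing estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import effects
from .engine import run_cohort
from .outcomes import EconSummary, economic_summary
from .parameters import (
    DISEASES,
    CompositeRR,
    ParameterBundle,
    ParameterError,
    PrevalenceTable,
    RiskModelSpec,
    StartingCohort,
    WaningPolicy,
    config_hash,
)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "ScenarioInputError",
    "run_scenario",
    "validate_prevalence",
    "report",
]


class ScenarioInputError(ParameterError):
    """The scenario needs estimates that must be supplied by the user."""


@dataclass(frozen=True)
class Scenario:
    """A named set of overrides on the base-case analysis."""

    name: str
    description: str = ""
    start_age: int | None = None
    sex: str | None = None
    horizon: int | None = None
    discount_rate: float | None = None
    wtp: float | None = None
    intervention_cost_multiplier: float | None = None
    lifetime_full_adherence: bool = False
    coaching_years: int | None = None
    effect_scope: str = "all"
    dementia_only_model: bool = False
    no_cvd_history: bool = False
    dementia_rr_override: float | None = None
    composite_override: CompositeRR | None = None
    incidence_uplift: float | None = None
    requires_override: str | None = None

    def apply(self, bundle: ParameterBundle) -> tuple[ParameterBundle, dict]:
        """Return (new bundle, run_cohort keyword options); pure."""
        b = bundle
        run_kwargs: dict = {"effect_scope": self.effect_scope}

        if self.start_age is not None or self.sex is not None or self.no_cvd_history:
            b = b.replace(cohort=_override_cohort(b.cohort, self.start_age, self.sex, self.no_cvd_history))
        if self.horizon is not None:
            b = b.replace(econ=replace(b.econ, max_age=self.horizon))
        if self.discount_rate is not None:
            b = b.replace(
                econ=replace(
                    b.econ,
                    discount_rate_costs=self.discount_rate,
                    discount_rate_effects=self.discount_rate,
                )
            )
        if self.wtp is not None:
            b = b.replace(econ=replace(b.econ, wtp=self.wtp))
        if self.intervention_cost_multiplier is not None:
            m = self.intervention_cost_multiplier
            b = b.replace(
                costs=replace(
                    b.costs,
                    platform_per_user_year=b.costs.platform_per_user_year * m,
                    coaching_per_user_year=b.costs.coaching_per_user_year * m,
                )
            )
        if self.lifetime_full_adherence:
            lifetime = b.econ.max_age - min(band[0] for band, _, _ in b.cohort.cells)
            b = b.replace(
                waning=WaningPolicy(duration_years=lifetime, annual_nonadherence=0.0),
                costs=replace(b.costs, duration_years=lifetime),
            )
        if self.coaching_years is not None:
            b = b.replace(costs=replace(b.costs, coaching_years=self.coaching_years))
        if self.dementia_only_model:
            # a dementia-only model: MI and stroke are not simulated at all
            # (intercept -745 underflows the log-linear rate to zero)
            run_kwargs["effect_scope"] = "dementia_only"
            b = b.replace(
                incidence={
                    "dementia": b.incidence["dementia"],
                    "mi": replace(b.incidence["mi"], intercept=-745.0, b_age=0.0, b_sex=0.0, history_rr={}),
                    "stroke": replace(b.incidence["stroke"], intercept=-745.0, b_age=0.0, b_sex=0.0, history_rr={}),
                }
            )
        if self.incidence_uplift is not None:
            import math

            if self.incidence_uplift <= 0:
                raise ParameterError("incidence_uplift must be > 0")
            shift = math.log(self.incidence_uplift)
            b = b.replace(
                incidence={
                    d: replace(g, intercept=g.intercept + shift) for d, g in b.incidence.items()
                }
            )
        if self.composite_override is not None:
            run_kwargs["composite"] = self.composite_override
        elif self.dementia_rr_override is not None:
            base = effects.composite_from_specs(b.risk_models)
            run_kwargs["composite"] = CompositeRR(
                dementia=self.dementia_rr_override,
                mi_by_sex=dict(base.mi_by_sex),
                stroke_by_sex=dict(base.stroke_by_sex),
            )
        return b, run_kwargs


def _override_cohort(
    cohort: StartingCohort,
    start_age: int | None,
    sex: str | None,
    no_cvd_history: bool,
) -> StartingCohort:
    cells: dict = {}
    for (band, cell_sex, hist), p in cohort.cells.items():
        if sex is not None and cell_sex != sex:
            continue
        new_band = (start_age, start_age) if start_age is not None else band
        new_hist = frozenset() if no_cvd_history else hist
        key = (new_band, cell_sex, new_hist)
        cells[key] = cells.get(key, 0.0) + p
    total = sum(cells.values())
    if total <= 0:
        raise ParameterError("scenario cohort override removed the whole cohort")
    cells = {k: v / total for k, v in cells.items()}
    return StartingCohort(cells=cells, cohort_size=cohort.cohort_size)


def _wtp_high(country: str) -> float:
    # UK guideline upper threshold; China: 3x GDP per capita per QALY
    return 30_000.0 if country.lower() == "uk" else 3 * 81_419.0


SCENARIOS: dict[str, Scenario] = {
    "base_case": Scenario("base_case", "10-year intervention, 10 %/y non-adherence"),
    "age60_male": Scenario("age60_male", "start age 60, men", start_age=60, sex="male"),
    "age60_female": Scenario("age60_female", "start age 60, women", start_age=60, sex="female"),
    "age70_male": Scenario("age70_male", "start age 70, men", start_age=70, sex="male"),
    "age70_female": Scenario("age70_female", "start age 70, women", start_age=70, sex="female"),
    "horizon90": Scenario("horizon90", "simulate up to age 90", horizon=90),
    "horizon80": Scenario("horizon80", "simulate up to age 80", horizon=80),
    "discount1": Scenario("discount1", "1 % discounting", discount_rate=0.01),
    "discount7": Scenario("discount7", "7 % discounting", discount_rate=0.07),
    "costs_x3": Scenario("costs_x3", "3x intervention costs", intervention_cost_multiplier=3.0),
    "costs_third": Scenario(
        "costs_third", "1/3 intervention costs", intervention_cost_multiplier=1.0 / 3.0
    ),
    "repeat_without_coaching": Scenario(
        "repeat_without_coaching",
        "intervention repeated without coach support beyond the trial delivery "
        "(coaching charged for the first 2 model years only)",
        coaching_years=2,
    ),
    "lifetime_full_adherence": Scenario(
        "lifetime_full_adherence",
        "full adherence for life, coach support continued",
        lifetime_full_adherence=True,
    ),
    "lifetime_full_adherence_no_coaching": Scenario(
        "lifetime_full_adherence_no_coaching",
        "full adherence for life, platform only (no coaching costs)",
        lifetime_full_adherence=True,
        coaching_years=0,
    ),
    "dementia_only": Scenario(
        "dementia_only",
        "dementia-only model: MI and stroke neither simulated nor affected",
        dementia_only_model=True,
    ),
    "no_cvd_history": Scenario(
        "no_cvd_history", "starting cohort without MI/stroke history", no_cvd_history=True
    ),
    "caide_score_rr": Scenario(
        "caide_score_rr",
        "dementia RR from the risk-score total change (0.95) instead of per-factor products",
        dementia_rr_override=0.95,
    ),
    "increased_risk": Scenario(
        "increased_risk",
        "target population at increased risk: 1.3x incidence uplift on all diseases",
        incidence_uplift=1.3,
    ),
    # interface-only: defining estimates are not published
    "libra_qrisk3": Scenario(
        "libra_qrisk3",
        "alternative risk-score coefficient tables",
        requires_override="LIBRA/QRISK3 per-factor coefficient tables (pass risk_models=...)",
    ),
    "adherent_subgroup": Scenario(
        "adherent_subgroup",
        "trial adherent-subgroup effect",
        requires_override="adherent-subgroup effect estimates (pass composite=...)",
    ),
    "planned_lifestyle_change": Scenario(
        "planned_lifestyle_change",
        "subgroup planning lifestyle change within 6 months",
        requires_override="subgroup effect estimates (pass composite=...)",
    ),
    "country_specific_effect": Scenario(
        "country_specific_effect",
        "country-specific trial effect",
        requires_override="country-specific effect estimates (pass composite=...)",
    ),
}


def run_scenario(
    bundle: ParameterBundle,
    scenario: Scenario | str,
    composite: CompositeRR | None = None,
    risk_models: Mapping[str, RiskModelSpec] | None = None,
    wtp_high: bool = False,
) -> EconSummary:
    """Apply a scenario descriptor and run both strategies.

    ``composite`` or ``risk_models`` supply user estimates for scenarios
    whose inputs are not published; interface-only scenarios raise
    :class:`ScenarioInputError` without them. ``wtp_high`` switches to the
    country's higher willingness-to-pay threshold.
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ParameterError(
                f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}"
            ) from None
    if scenario.requires_override and composite is None and risk_models is None:
        raise ScenarioInputError(
            f"scenario {scenario.name!r} needs user-supplied inputs: {scenario.requires_override}"
        )
    if wtp_high:
        scenario = replace(scenario, wtp=_wtp_high(bundle.country))
    b, run_kwargs = scenario.apply(bundle)
    if risk_models is not None:
        b = b.replace(risk_models=dict(risk_models))
    if composite is not None:
        run_kwargs["composite"] = composite
    trace_soc = run_cohort(b, "standard_of_care")
    trace_int = run_cohort(b, "intervention", **run_kwargs)
    return economic_summary(trace_soc, trace_int, b, scenario=scenario.name)


# ---------------------------------------------------------------------------
# external validity


def validate_prevalence(simulated: PrevalenceTable, observed: pd.DataFrame) -> pd.DataFrame:
    """Classify simulated prevalence against observed confidence intervals.

    ``observed`` needs columns (age, sex, disease, lo, hi). A cell is
    ``good`` if the simulated value lies within the closed interval
    [lo, hi]; ``moderate`` if outside but within one additional half-width
    of the violated bound (i.e. no more than two times beyond the
    interval); ``poor`` otherwise.
    """
    required = {"age", "sex", "disease", "lo", "hi"}
    if not required.issubset(observed.columns):
        raise ParameterError(f"observed table needs columns {sorted(required)}")
    rows = []
    for r in observed.itertuples():
        key = (int(r.age), str(r.sex), str(r.disease))
        if key not in simulated.values:
            raise ParameterError(f"simulated prevalence missing cell {key}")
        v = simulated.values[key]
        lo, hi = float(r.lo), float(r.hi)
        half = (hi - lo) / 2.0
        if lo <= v <= hi:
            grade = "good"
        elif lo - half <= v <= hi + half:
            grade = "moderate"
        else:
            grade = "poor"
        rows.append(
            {"age": key[0], "sex": key[1], "disease": key[2], "simulated": v, "lo": lo, "hi": hi, "grade": grade}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def _scenario_row(s: EconSummary) -> dict:
    months = 12.0
    row: dict = {"country": s.country, "scenario": s.scenario}
    for d in DISEASES:
        row[f"prevented_{d}_events"] = s.prevented_events[d]
    for d in DISEASES:
        row[f"months_with_{d}_diff"] = months * (
            s.intervention.person_years[f"with_{d}"] - s.soc.person_years[f"with_{d}"]
        )
    for d in DISEASES:
        row[f"months_without_{d}_diff"] = months * (
            s.intervention.person_years[f"without_{d}"] - s.soc.person_years[f"without_{d}"]
        )
    row["months_alive_diff"] = months * (
        s.intervention.person_years["alive"] - s.soc.person_years["alive"]
    )
    row["delta_qalys"] = s.delta_qalys
    row["delta_costs"] = s.delta_costs
    row["icer"] = s.icer if s.icer is not None else float("nan")
    row["inhb"] = s.inhb
    return row


def report(
    summaries: list[EconSummary],
    out_dir: str | Path,
    fmt: str = "csv",
    seed: int | None = None,
    bundles: Mapping[str, ParameterBundle] | None = None,
) -> list[Path]:
    """Write per-run two-strategy tables, a scenario-difference table and a
    run manifest (seed, config hashes, provenance flags). Deterministic
    given identical inputs."""
    if not summaries:
        raise ParameterError("report needs at least one summary")
    if fmt not in ("csv", "json"):
        raise ParameterError(f"unknown report format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for s in summaries:
        stem = f"{s.country.lower()}_{s.scenario}"
        frame = s.to_frame()
        path = out / f"{stem}.{fmt}"
        if fmt == "csv":
            frame.to_csv(path, index=False, float_format="%.10g")
        else:
            path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
        written.append(path)
    diff = pd.DataFrame([_scenario_row(s) for s in summaries])
    diff_path = out / f"scenario_differences.{fmt}"
    if fmt == "csv":
        diff.to_csv(diff_path, index=False, float_format="%.10g")
    else:
        diff_path.write_text(json.dumps(diff.to_dict(orient="records"), indent=1))
    written.append(diff_path)

    manifest = {
        "seed": seed,
        "runs": [{"country": s.country, "scenario": s.scenario} for s in summaries],
        "config_hash": {k: config_hash(b) for k, b in (bundles or {}).items()},
        "provenance": {k: dict(b.provenance) for k, b in (bundles or {}).items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    return written
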