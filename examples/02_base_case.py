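"""Lifetime base-case cohort simulation for the UK setting.

Runs 100,000 people aged 55-74 to age 100 under standard of care and under
the coach-supported intervention, then prints the paired economic summary.
Absolute levels reflect the bundled synthetic life-table/prevalence/cohort
fixtures; the published-input sections (incidence models, costs, utilities)
are exact transcriptions.
"""

from demcvd import default_bundle, economic_summary, run_cohort

bundle = default_bundle("UK")
soc = run_cohort(bundle, "standard_of_care")
inter = run_cohort(bundle, "intervention")
s = economic_summary(soc, inter, bundle)

n = s.cohort_size
print(f"standard of care, per {n:,} persons:")
print(f"  lifetime dementia onsets : {s.soc.events['dementia']:,.0f}")
print(f"  mean survival            : {s.soc.person_years['alive']:.1f} years")
print(f"  mean years with dementia : {s.soc.person_years['with_dementia']:.1f}")
print("\nintervention vs standard of care:")
for d in ("dementia", "mi", "stroke"):
    print(f"  prevented {d:8s} events : {s.prevented_events[d]:7.0f}")
print(f"  QALY gain per person     : {s.delta_qalys:+.4f}")
print(f"  cost change per person   : {s.delta_costs:+,.0f} GBP")
print(f"  ICER                     : {s.icer:,.0f} GBP/QALY")
print(f"  iNHB at 20,000 GBP/QALY  : {s.inhb:+.3f} QALYs")
print(
    "\nA negative incremental net health benefit means the QALYs gained are "
    "worth less than the intervention's net cost at the willingness-to-pay "
    "threshold: the intervention is not cost-effective under these inputs."
)
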