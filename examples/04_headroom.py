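"""Headroom analysis: the highest annual price that is still cost-effective.

Replaces the platform+coaching prices with a single unknown annual cost and
solves for the value at which the incremental net health benefit is zero,
counting only the intervention's effect on dementia onset.
"""

from demcvd import default_bundle, headroom_cost

for country in ("UK", "China"):
    bundle = default_bundle(country)
    price = headroom_cost(bundle, effect_scope="dementia_only")
    print(
        f"{country:5s}: max annual intervention cost {price:8,.0f} "
        f"{bundle.econ.currency} per adherent user-year"
    )
print(
    "\nAny yearly per-user price above these values makes the intervention "
    "cost-ineffective at the national willingness-to-pay threshold, which "
    "constrains how much long-term coach support can cost."
)
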