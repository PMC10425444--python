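"""How many more patients would settle the open questions?

Appends deterministic expected-count trials (100 patients each, 1:1) at
assumed event rates to an inconclusive evidence base and reports the
smallest added total at which the cumulative Z-curve crosses the chosen
boundary - superiority under an assumed benefit, futility under assumed
equal rates.
"""

from tsameta import (
    Crossing,
    FutureTrialPlan,
    Outcome,
    design_spec,
    estimate_additional_n,
    load_lvt_fixture,
)

data = load_lvt_fixture()

scenarios = [
    (Outcome.MAJOR_BLEEDING, 0.03, 0.03, Crossing.FUTILITY),
    (Outcome.ANY_BLEEDING, 0.08, 0.10, Crossing.SUPERIORITY),
    (Outcome.ANY_BLEEDING, 0.10, 0.10, Crossing.FUTILITY),
]
for outcome, r_int, r_ctl, target in scenarios:
    plan = FutureTrialPlan(
        base=data[outcome],
        rate_int=r_int,
        rate_ctl=r_ctl,
        target=target,
        increment=100,
        max_added=10_000,
        ris_spec=design_spec(outcome),
    )
    result = estimate_additional_n(plan)
    added = result.added_n if result.added_n is not None else "unreachable"
    print(
        f"{outcome.value}, assumed {100*r_int:.0f}% vs {100*r_ctl:.0f}%, "
        f"target {target.value}: additional patients = {added} "
        f"({result.looks_added} appended trials)"
    )
print("\nEach appended trial re-derives the diversity-adjusted information "
      "size and the full boundary set before re-scanning for a crossing.")
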