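"""Full trial sequential analysis of all six outcomes.

Each added study is an interim look: the cumulative DL Z-curve is tested
against O'Brien-Fleming-type alpha-spending superiority boundaries and
beta-spending futility boundaries anchored to the diversity-adjusted
required information size. The four-way verdict says whether the evidence
is conclusive (superiority / futility crossing) or still insufficient.
"""

from tsameta import design_spec, load_lvt_fixture, run_tsa

data = load_lvt_fixture()
for outcome, dataset in data.items():
    verdict, plan, curve = run_tsa(dataset, design_spec(outcome))
    print(verdict.summary())
    print()
print("true positive/negative verdicts are conclusive; false positive "
      "(traditional-only) and false negative (no crossing) call for more trials.")
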