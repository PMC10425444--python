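# tsameta

Trial sequential analysis (TSA) for binary-outcome meta-analysis: a
cumulative meta-analysis engine that treats every added trial as an interim
look at the evidence, with error-spending monitoring boundaries, required
information sizes, four-way conclusiveness verdicts, and future-trial
sample-size estimation.

Conventional meta-analyses test the pooled effect afresh each time a trial
is added, which inflates the false-positive rate exactly the way unplanned
interim analyses inflate it in a single trial, and they routinely declare
"significance" long before the accumulated patients could support a
reliable conclusion. TSA imports the machinery of group-sequential trial
monitoring: a **required information size** (RIS) plays the role of the
trial's sample size, and **alpha/beta-spending boundaries** decide, at each
look, whether the cumulative evidence is conclusively positive, conclusively
null, or still insufficient.

The package ships a worked evidence base: 25 studies directly comparing
direct oral anticoagulants (DOACs) with vitamin K antagonists (VKAs) for
left-ventricular thrombus, across six outcomes (thrombus resolution,
stroke, any thromboembolism, major bleeding, any bleeding, all-cause
death).

## The model

Per study *i*, a 2×2 table yields a log odds ratio and variance

θ̂ᵢ = ln(aᵢdᵢ / bᵢcᵢ),  vᵢ = 1/aᵢ + 1/bᵢ + 1/cᵢ + 1/dᵢ,

with 0.5 added to all four cells when any cell is zero. Pooling is
DerSimonian–Laird random effects: τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)),
w*ᵢ = 1/(vᵢ+τ²), θ̂ = Σw*ᵢθ̂ᵢ/Σw*ᵢ. The diversity D² = 1 − v_F/v_R is the
fraction of the random-effects variance due to between-trial variation.

The RIS for detecting a difference between event proportions p₁, p₂ at
two-sided level α with power 1−β (1:1 allocation, both arms) is

N = 4 (z₁₋α/₂ + z₁₋β)² p̄(1−p̄) / (p₁−p₂)²,  inflated to N/(1−D²),

with p̄ = (p₁+p₂)/2. At information fraction t = n/RIS the cumulative
Z-statistic behaves like Brownian motion B(t)/√t; superiority boundaries
spend the O'Brien–Fleming-type Lan–DeMets budget per side,
2(1−Φ(z₁₋α/₄/√t)), and the futility wedge spends β = 1−power with the same
shape under the design drift z₁₋α/₂+z₁₋β. Boundary values solve the
first-crossing equations by recursive numerical integration of the
non-stopped density (trapezoid grid, bisection per look).

A cumulative Z-curve then classifies as: **true positive** (crossed the
superiority boundary), **true negative** (entered the futility wedge),
**false positive** (crossed only the traditional ±1.96 line) or **false
negative** (crossed nothing).

## Worked example

```sh
python examples/03_tsa_verdicts.py
```

prints, for the packaged DOAC-vs-VKA data (excerpt):

```
Outcome: thrombus_resolution
  accrued patients: 1625 of required 1796 (90%)
  final signed Z: +2.38
  crossing: superiority at look 20
  verdict: true positive

Outcome: any_bleeding
  accrued patients: 2922 of required 6429 (45%)
  final signed Z: +2.91
  crossing: traditional_only at look 4
  verdict: false positive
```

Thrombus resolution is conclusive: with 90% of the required information
accrued, the Z-curve has crossed the spending boundary, so DOACs resolve
thrombi more often than VKAs and further trials are unnecessary. Any
bleeding is a warning case: the curve is past ±1.96 (a conventional
meta-analysis would call it significant) but only 45% of the required
information exists and the spending boundary is uncrossed — the
"significance" may be a random high. `examples/04_future_trial_sizes.py`
then estimates how many patients a future trial needs to settle it, e.g.

```
major_bleeding, assumed 3% vs 3%, target futility: additional patients = 200
```

— 200 more patients at equal bleeding rates would push the curve into the
futility wedge and close the question of a major-bleeding difference.

The same analyses are scriptable via the thin CLI:

```sh
tsameta analyze --outcome stroke
tsameta future --outcome any_bleeding --rate-int 0.08 --rate-ctl 0.10 --target superiority
```

Synthetic evidence bases with known truth (true odds ratio, between-trial
heterogeneity, arm-size law) come from `tsameta.generate_series`; see
`examples/05_why_sequential_boundaries.py` for the type-I-error
demonstration that motivates the whole apparatus.

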