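# cesize

Sample-size planning for **binary composite endpoints** in two-arm
randomized trials.

Trialists often combine several dichotomous outcomes into a single
primary endpoint — a patient "has the event" if any component occurs —
because the pooled event rate can cut the sample size requirement (SSR)
substantially. How much it cuts depends not only on each component's
rate and treatment effect but on how strongly the components are
*associated*: the more two outcomes co-occur, the less the union gains
over its larger member. `cesize` is for statisticians and clinical
trialists deciding **which of K ≤ 10 candidate outcomes to combine**
when the pairwise associations are only roughly known.

## The model

For outcome *k* let π<sub>ik</sub> be its event probability in arm
*i* (control *i* = 1, treatment *i* = 2), with treatment effect given
as a risk ratio RR<sub>k</sub> = π<sub>2k</sub>/π<sub>1k</sub>. The
composite of two outcomes has, per arm,

> π<sub>CE</sub> = π<sub>a</sub> + π<sub>b</sub> − π<sub>ab</sub>

where the joint probability π<sub>ab</sub> is constrained by the
Fréchet bounds

> max(0, π<sub>a</sub> + π<sub>b</sub> − 1) ≤ π<sub>ab</sub> ≤ min(π<sub>a</sub>, π<sub>b</sub>).

When π<sub>ab</sub> is unknown the user picks one of **nine categorical
scenarios** (lowest, strong/moderate/low negative, none, low/moderate/
strong positive, highest); the joint is imputed as the independence
product π<sub>a</sub>π<sub>b</sub> moved θ/4 of the way toward the
relevant bound (θ = 1, 2, 3; 4 sits on the bound itself). Scenarios are
applied per arm from that arm's own marginals. When a third component
is considered, the joint between the running composite and the
candidate is rebuilt by the same inclusion–exclusion step, imputing the
unknown three-way co-occurrence as the product of the pairwise joints.

The per-group SSR for the resulting two-proportion comparison uses, by
default, the normal approximation with pooled variance under H₀ and
unpooled variance under H₁ at two-sided α = 0.05 and power 0.80
(arcsine kernels, with and without continuity correction, are also
available). A greedy forward search seeds the composite with the
*relevant endpoint* (flagged, or the candidate with the smallest
single-endpoint SSR) and absorbs whichever remaining candidate lowers
the SSR most, stopping when none strictly improves.

## Worked example

Five bleeding outcomes from a radial-vs-femoral access trial, femoral
arm rates, assumed independent (`bleeding.json` holds the rates and
risk ratios; `"relevant": true` marks the hematoma endpoint):

```sh
cesize run --config bleeding.json --out out
cat out/trace.csv
```

```
step,components,rate_control_pct,rate_treatment_pct,rr,ssr,pct_of_reference
1,Hematoma > 15 cm,6.00,0.54,0.09,166,100.00
2,Hematoma > 15 cm + Hb drop >= 3 g/dl with overt bleeding,9.52,1.36,0.14,121,72.89
3,Hematoma > 15 cm + Hb drop >= 3 g/dl with overt bleeding + GI Bleeding,10.82,1.63,0.15,108,65.06
4,Hematoma > 15 cm + Hb drop >= 3 g/dl with overt bleeding + GI Bleeding + Vascular Access Complication,11.84,1.90,0.16,101,60.84
```

Reading the trace: the hematoma endpoint alone needs **166 subjects per
group**; adding the hemoglobin-drop endpoint raises the control-arm
event rate from 6.00% to 9.52% and cuts the requirement to **121**
(72.89% of the reference, a 27.11% saving). Two further additions reach
**101** per group; the remaining candidate would not reduce the SSR and
is left out. The same engine is available programmatically:

```python
from cesize import OutcomeSpec, Panel, greedy_select, sweep

panel = Panel(outcomes=[
    OutcomeSpec("CABG/Revascularization", 0.092, 0.85),
    OutcomeSpec("Infarction", 0.0115, 0.73),
])
print(greedy_select(panel).final.ssr)   # 4917
```

Other subcommands: `cesize sensitivity` (nine-scenario association
sweep), `cesize ranges` (SSR at the Fréchet extremes for each pairing
with the relevant endpoint), `cesize simulate` (Monte-Carlo power check
of the selected composite at its computed size).

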