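# Methods

## Setting and assumptions

A two-arm randomized trial with 1:1 allocation compares event
probabilities. Each of K ≤ 10 candidate binary outcomes is described by
its control-arm rate π₁ₖ ∈ (0,1) and a risk ratio RRₖ > 0 with
RRₖ·π₁ₖ < 1, so the treatment-arm rate is π₂ₖ = RRₖ·π₁ₖ. A composite
endpoint is the union event over a subset of outcomes; its per-arm rate
follows from inclusion–exclusion given the joint probabilities of
co-occurrence. Effects may be entered as odds ratios or rate
differences; both are converted to risk ratios on load
(OR = RR(1−π₁)/(1−RR·π₁) and its inverse).

Everything here is a *planning* calculation: rates, effects and
associations are assumptions supplied by the analyst, not estimates
from data, and the outputs are the sample sizes those assumptions
imply.

## Association model

The joint probability π_ab of two binary events with fixed marginals is
confined to the Fréchet interval [max(0, π_a+π_b−1), min(π_a, π_b)].
Exact joints, when known, are entered directly; a value outside the
interval is impossible for the stated marginals and is replaced by the
independence product π_a·π_b with a warning (the correction is
idempotent and applied against each arm's own bounds).

Unknown joints are imputed from one of nine categorical scenarios by
linear interpolation in quarters between the independence product and
the relevant bound:

| scenario | joint |
|---|---|
| none | π_a·π_b |
| low / moderate / strong positive | ind + (up − ind)·θ/4, θ = 1, 2, 3 |
| highest | up |
| low / moderate / strong negative | ind − (ind − low)·θ/4, θ = 1, 2, 3 |
| lowest | low |

The quarter step makes the two four-step ladders meet the bounds
exactly at θ = 4 and keeps every imputed joint inside the interval for
any marginals (property-tested over a grid). Scenarios are applied
**per arm** from that arm's own marginals — carrying the control-arm
*value* into the treatment arm could exceed the treatment arm's bounds,
whereas carrying the categorical *strength* cannot.

## Composite recursion beyond two components

Only pairwise associations are elicited. When the running composite
C = A∪B is paired with a further candidate X, inclusion–exclusion gives
π_{CX} = π_{AX} + π_{BX} − π_{ABX}; the unobservable three-way term
π_{ABX} is imputed as the product π_{AX}·π_{BX}. The approximation can
drift slightly outside the Fréchet bounds of (composite rate, candidate
rate) in corners — extreme scenarios especially — so the recursed joint
is clamped into bounds and every clamp is logged. This makes rates of
three-or-more-component composites approximations by design; they are
validated against published reference tables rather than simulation,
and a consequence worth knowing is that the recursed value depends on
the order in which members were absorbed.

## Sample-size kernels

For composite rates p₁ (control) and p₂ (treatment), per-group size at
two-sided level α and power 1−β:

- `normal_mixed` (default): n = (z_{1−α/2}·√(2p̄(1−p̄)) +
  z_{1−β}·√(p₁(1−p₁)+p₂(1−p₂)))² / (p₁−p₂)², p̄ = (p₁+p₂)/2 — pooled
  variance under the null, unpooled under the alternative, matching the
  pooled two-proportion z-test that would analyse the trial.
- `normal_pooled`, `normal_unpooled`: the textbook single-variance
  variants; all three agree within 5% for moderate proportions.
- `arcsine`: n = (z_{1−α/2}+z_{1−β})²/h² with Cohen's
  h = 2·asin√p₁ − 2·asin√p₂, for small planned sizes.
- `arcsine_corrected`: the continuity-corrected transform
  2·asin√((pn+3/8)/(n+3/4)) depends on n, so the solution is a fixed
  point, iterated to 1e−9 (cap 100 iterations; non-convergence raises
  with diagnostics).

All kernels round up (ceiling) and reject p₁ = p₂ (no effect — no
finite size). Normal quantiles come from `scipy.stats.norm.ppf` at full
double precision. Defaults α = 0.05, power = 0.80: the conventional
pair for planning calculations of this kind. Monte-Carlo validation
(pooled z-test on simulated binomial trials) shows empirical power
within ±0.02 of target at the computed `normal_mixed` sizes.

## Greedy selection

The relevant endpoint (RE) seeds the composite: the flagged outcome, or
the candidate with the smallest single-endpoint SSR (ties to the lowest
index). Each iteration provisionally absorbs every remaining candidate,
computes the provisional composite's SSR per arm, and keeps the
candidate with the smallest SSR **iff it is strictly below** the
incumbent's — a tie does not grow the composite, since smaller
composites are easier to interpret. Candidates with harmful effects
(RR ≥ 1) are still evaluated every round; they are simply never
selected unless they reduce the SSR. The trace records each step's
components, per-arm rates, composite RR, SSR and percent of the
reference (step-1) SSR.

The search is local. The bundled `exhaustive_search` oracle enumerates
every subset containing the RE **and every insertion order** (RE
first), returning the minimum — over orders as well, because the
recursion's order dependence means a fixed-order enumeration is not a
true lower bound on what greedy can reach. On both worked-example
panels greedy attains the exhaustive optimum; on random panels it can
fall short, which is the price of linear-time selection.

## Sensitivity analyses

The nine-scenario sweep overwrites *all* pairwise entries with one
scenario, reruns the greedy selection, and reports the final composite
per scenario, ordered lowest → highest; the % column is relative to the
RE's own (scenario-free) SSR. For panels where every selected effect is
protective, the SSR column is non-decreasing in association strength —
stronger positive association leaves less union gain. The effect sweep
replaces one outcome's risk ratio over a grid and reruns the selection,
reporting per-point results and continuing past inadmissible values.

## Simulation module

`sample_pair` draws subjects from the four-cell distribution {both,
A-only, B-only, neither}, whose cells are non-negative exactly when the
joint respects the Fréchet bounds; it validates the inclusion–exclusion
rate empirically. `empirical_power` simulates two-arm binomial trials
and applies the pooled z-test. Only *pairwise* simulation is offered:
K-variate binary simulation would require the very higher-order
parameters the method exists to avoid, so multi-component rates are
checked against reference tables instead. `generate_panel` produces
seeded random panels (default rates 0.5–15%, risk ratios 0.1–1.4,
random scenarios per pair — the regime of cardiovascular trial planning
this tool targets); all randomness flows from a single seed.

## Numerical choices

- Bound checks use absolute tolerance 1e−12; degenerate composites
  (p₁ = p₂ up to roundoff, rel 1e−12) are reported as undefined rather
  than raising mid-table.
- Ties everywhere break to the lowest index; the exhaustive oracle
  prefers smaller subsets, then lexicographic order.
- Display rounding is half-up to 2 decimals (percents and risk ratios);
  all internal arithmetic is at full precision and SSRs are exact
  integers.
- Output tables contain no timestamps and are byte-identical across
  reruns for fixed inputs.

## Known limitations

- Rates of composites with ≥ 3 components rest on the product
  imputation of higher-order terms and are order-dependent
  approximations; published reference values for such composites are
  matched to within a few subjects, not exactly.
- The greedy search has no optimality guarantee (the oracle is provided
  to quantify the gap), and clinical relevance of a combination is
  outside its objective entirely.
- No multiplicity adjustment, unequal allocation, more than two arms,
  exact (binomial/Fisher) power, or time-to-event endpoints; binary
  outcomes are assessed at a fixed horizon.
- The upper-Fréchet pair-range value for the worked bleeding pair is
  192 here; the original report printed 191, consistent with its inputs
  having been rounded slightly differently (6.03% vs 6.00%) — the
  difference is one subject and does not affect any conclusion.
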