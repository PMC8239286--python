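# Methods

## Model

`oligocea` implements a three-state partitioned survival model for comparing
stereotactic ablative radiotherapy (SABR) plus standard care against standard
care (SC) alone in oligometastatic cancer. State occupancy is read directly
off the arm's survival curves at every monthly cycle boundary:

* **OMD** (oligometastatic, progression-free) = PFS(t)
* **PMD** (polymetastatic, progressed) = OS(t) − PFS(t)
* **dead** = 1 − OS(t)

There are no transition probabilities to estimate; the partition is exact by
construction, which is the defining property (and the defining assumption) of
partitioned survival analysis: the model inherits whatever the survival
curves say, including any inconsistency between OS and PFS. A pointwise clip
(PFS ≤ OS) guards the partition and logs when it fires.

## Survival curves

Inputs are annual OS/PFS anchors per arm (the published yearly Kaplan-Meier
estimates from the SABR-COMET randomized trial). Between anchors the model
uses **constant-hazard (piecewise-exponential) interpolation**,
`S(t) = S_a (S_b/S_a)^{(t−a)/(b−a)}`, the standard convention for converting
interval survival to cycle probabilities; beyond the last anchor the last
value is carried flat (the published anchor sets themselves repeat their
final values). A curve that touches zero stays at zero.

This interpolation is the package's declared approximation of record. The
analysis that these inputs come from worked from monthly curves digitized
from the trial's Kaplan-Meier plots, which are not public. Annual anchors
cannot recover them: back-solving state occupancy from the published
(cost, QALY) pairs shows the digitized curves sat *above* any single
interpolation of the annual anchors for the SC arm, while no uniform
convention (constant-hazard, linear, or annual-step) matches all published
totals simultaneously. Constant-hazard interpolation reproduces the SABR
arm's totals within ~2% and the qualitative conclusions (SABR cost-effective
by a wide margin; state costs dominate the tornado) exactly; the SC arm's
totals land ~3.5% low, and small differences of large totals (incremental
cost, hence the ICER and the PSA dominance share) inherit that gap. Users
fitting their own monthly curves can supply them directly as anchors.

### Long-term extrapolation

For horizons beyond the trial (16 years here), the OS curve is **spliced**
onto a registry reference curve: the reference is entered at the earliest
time `t*` where it passes through the trial's final survival level and
followed from there, giving a curve that is continuous at the junction and
monotone. The junction is solved with the same constant-hazard rule on the
reference's grid (earliest solution on ties). PFS, for which registries
carry no data, is extended **proportionally**: the trial-end ratio
PFS(T)/OS(T) multiplies the extended OS. Since the ratio is ≤ 1, extended
PFS never exceeds extended OS.

The bundled reference curve is a **synthetic stand-in**: a weighted mixture
of exponential/Weibull entity curves (labels follow the trial's four most
frequent entities) whose parameters are round values in the range typical of
metastatic-stage registry survival, chosen once so the pooled curve declines
through both arms' trial-end survival well inside the 16-year horizon. It
emulates the *shape* of pooled registry survival — smooth, monotone,
slowly-flattening hazard — and nothing else: passing long-term tests shows
the extrapolation machinery is correct, not that long-term results match any
published number derived from real registry data.

## Accrual conventions

* **Cycle**: 1 month, fixed. Horizons: 72 months (trial duration) and 192
  months (long-term).
* **Mid-cycle evaluation** (half-cycle correction): state membership for
  month *m* is the mean of the month-start and month-end occupancy, and
  discounting is evaluated at t = m − ½. This is the best discrete
  approximation of the continuous integral; the engine agrees with an
  independent daily-step integration oracle within 1% on the bundled inputs
  (start-of-cycle and end-of-cycle variants were examined and change totals
  by well under 1%, so the choice is not load-bearing).
* **Discounting**: 3%/year for both costs and QALYs, `(1.03)^(−t/12)`.
* **State costs**: annual OMD/PMD costs prorated per month and, by default,
  scaled by the arm's systemic-therapy fraction (55% SABR / 63.6% SC). The
  scaling mode is configurable (`cost_scaling_mode: none` applies full costs
  to every patient); fraction scaling is the reading that back-calculates to
  the published arm totals.
* **One-time items at t = 0, undiscounted**: primary SABR delivery
  ($11,700), per-patient expected salvage radiotherapy and salvage SABR
  (trial head-counts 23/16/9 divided by arm sizes 33/66), and the
  adverse-event treatment cost ($1,443 / $997). Arm sizes are the trial's
  randomization and exist purely as salvage denominators.
* **End-of-life cost**: $19,174 (last 180 days) charged as a lump sum at the
  cycle of death, on the incremental death probability, discounted at that
  cycle. Charging at death rather than spreading over the prior 180 days
  changes discounted totals negligibly at 3%/year. Patients alive at the
  horizon never accrue it.
* **QALYs**: occupancy × utility (0.82 OMD, 0.59 PMD), minus the one-time
  adverse-event disutility (0.002 / 0.0008, stored as positive magnitudes
  and subtracted at t = 0).

## Comparison metrics

Incremental cost and effect, ICER with quadrant handling (dominant /
dominated comparisons carry a status flag, not a negative ratio), and net
monetary benefit `NMB = effect × WTP − cost` at WTP $100,000/QALY.
Incremental NMB crosses zero exactly at WTP = ICER whenever ΔE > 0.

## Deterministic sensitivity analysis

One-way DSA substitutes one parameter at a time at its range ends (costs
±20% — the SABR unit cost carries its published asymmetric range
$8,190–14,040 — utilities at their published intervals, adverse-event
disutilities ±10%) and re-runs the full model. Tornado endpoints report the
signed ΔC/ΔE ratio, as decision-analytic software plots it, because with an
incremental cost this small many perturbations legitimately cross the
dominance boundary.

Survival anchors are *not* varied in the default tornado. A ±15% shift of an
early OS anchor moves incremental cost by tens of thousands of dollars and
throws the ICER across the dominance boundary, so such bars dwarf every
other parameter under any metric — which contradicts the published tornado
ranking and mostly restates "the model is driven by survival". Survival
uncertainty is instead carried entirely by the probabilistic analysis, which
varies the same anchors jointly; per-anchor tornado rows remain available
via `reference_dsa_ranges(inputs, include_survival=True)`.

The **threshold search** bisects the SABR unit cost (tolerance $1) until
incremental NMB is zero. The unit cost enters linearly (primary course plus
the expected salvage-SABR course), so the zero is unique and equals the
closed form `c* = c_base + iNMB_base / (1 + n_salvage_sabr/n_arm)`; the
bisection is validated against it. `include_salvage=False` re-prices the
primary course only.

## Probabilistic sensitivity analysis

Each (mean, low, high) triple becomes a distribution by **moment matching**
with the range read as a 95% interval: `sd = (high − low)/3.92`. Utilities,
disutilities and survival anchors get beta distributions; costs get gamma.
Moment matching was chosen over quantile matching for its closed forms,
which the tests verify exactly. Anchors at 0 or 1 are degenerate (a beta
cannot sit there); zero-spread parameters likewise.

Per iteration, shared parameters (state costs, end-of-life and unit prices,
utilities) are drawn **once and applied to both arms** — a cohort model's
arms face the same price and preference environment, and correlating them
this way is what makes the dominance share meaningful. Arm-specific items
(adverse-event burden, each arm's OS/PFS anchors) are drawn per arm.
Anchors are drawn independently around their base values and repaired
(clip to [0, 1], sequential minimum; repairs moving an anchor by more than
0.2 are logged); PFS is clipped to OS inside the engine. All randomness
flows through one `numpy` generator seeded explicitly; degenerate-only specs
reproduce the base case bit for bit.

Summaries: acceptability at WTP (share of iterations with positive
incremental NMB), dominant-strategy share (cheaper *and* more effective),
mean incremental cost/effect, ICER of means, and a CEAC over a WTP grid.

## Problem sizes

The default analyses run the 72-month model (~10 ms), the 192-month
extrapolated model, the 11-parameter tornado, the $1-tolerance bisection and
a 10,000-iteration PSA (~7 s); the property suites sweep 1,000 random valid
input sets through the engine.

## Known limitations

* Annual anchors under-resolve the first trial year, where both PFS curves
  fall fastest; this is the dominant source of disagreement with results
  computed from digitized monthly curves (see Survival curves above), and it
  concentrates in the SC arm and in small incremental differences.
* The partitioned structure cannot model treatment switching, and the t = 0
  placement of salvage costs (as published) slightly overweights them
  relative to discounting them at their unknown administration times.
* The synthetic registry stand-in supports correctness tests only; published
  long-term results rest on real registry curves that are not redistributed
  here.
* PSA anchor draws are independent across years before repair; no joint
  (e.g. correlated or monotone-process) sampling scheme is imposed.
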