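# Methods

## Model

A non-adherence tree (NAT) is a fault tree whose top event is
discontinuation of a medication regimen.  Basic nodes are non-adherence
factors — binary events such as "stopped because of side effects" — and
intermediate nodes group them under Boolean gates.  In the bundled case
study the grouping layer is the five WHO adherence dimensions and every
gate is an OR except the medicine-supply subtree, where the ICT and manual
delivery systems must *both* be unavailable (an AND) to cause a missed
dose.

Three analyses operate on a tree:

1. **Qualitative** — exact symbolic reduction to minimal cut sets (MCS):
   OR gates concatenate child cut-set lists, AND/PAND gates take pairwise
   unions, and the absorption law removes dominated products.  Singleton
   cut sets are single points of failure.  Priority-AND gates are treated
   as plain AND for cut-set purposes — sequencing can only make an event
   less likely, never change which factor combinations suffice — but the
   required order is retained on the cut set.  The expansion is guarded at
   2^20 intermediate products; trees in this domain are far smaller.  A
   brute-force truth-table evaluator (`evaluate_truth`) serves as an
   independent oracle: the test suite checks the cut-set representation
   against all 2^n assignments for every fixture and for randomized trees.

2. **Analytic** — for trees whose leaves have constant hazards, the
   top-event probability over `d` days is exact: leaves via the
   exponential CDF `1 − e^(−λd)`, OR via `1 − Π(1 − pᵢ)`, AND via `Π pᵢ`,
   and priority-AND via the exponential sequential closed form

   ```
   P = (Π λᵢ) Σₖ e^(aₖ t) / Πⱼ≠ₖ (aₖ − aⱼ),   a₀ = 0,  aₘ = −Σⱼ≤ₘ λⱼ
   ```

   in which the partial sums run over the *reverse* occurrence order (the
   event required last enters first).  This convention was pinned down by
   checking the closed form against a 10⁶-draw sampling oracle and against
   direct integration of the two-event case; both checks are in the test
   suite.  Age-stratified leaves are handled exactly as finite mixtures of
   exponentials.  Decaying and repairable leaves are rejected here with a
   pointer to the simulator — they have no single-hazard closed form.

3. **Monte Carlo** — a time-stepped cohort simulation for the general
   case, described below.

## Rate estimation

Factor hazards come from pooling published study counts:

* `NARS = count / NoP` (per-study proportion), `NAR = NARS / DoM` (per-day
  rate), and the pooled `WNAR = Σ NARᵢ · NoPᵢ / GrandNoP`.
* `GrandNoP` sums `NoP` over **all** pooled studies, including those that
  never observed the factor.  This choice is deliberate: treating the
  participant base as common across factors is what makes pooled rates
  comparable, and it is the only reading that reproduces the published
  pooled row of the six-study table (e.g. the limited-tablets rate
  2.488e-3 · 201/1450 = 3.448e-4/day).  The alternative reading — a
  denominator of non-adherent patients only — does not.
* A factor absent from a study's table is *not observed*, which is
  distinct from an observed zero: unobserved factors are excluded from the
  numerator (and requesting their per-study rate raises an error), but the
  study's cohort still enters `GrandNoP`.
* Comparisons against published values use 4-significant-figure
  scientific-notation formatting, matching how the source table prints.

## Simulator

One trajectory is sampled per simulated participant (the case-study cohort
is 1000), stepping every `timestep_hours` (default 1 h) over `days`
(default 10).  Per step of length Δt days:

* every constant / decaying / age-stratified leaf fires with probability
  `1 − e^(−r(d)·Δt)`.  Using the exponential form rather than `r·Δt` makes
  the scheme exact for constant rates — the probability of surviving all
  240 hourly steps is exactly `e^(−10r)` — and therefore robust to the
  step size (halving Δt is a distributional no-op for constant leaves);
* decaying rates use whole-elapsed-day semantics: day `d` (from 0 at the
  regimen start) covers `[d, d+1)`, so Day-1 dosing uses the undecayed
  rate.  The decayed rate is floored at zero;
* each patient draws an age band once at entry (equal-thirds cohort
  weights by default) and keeps that band's hazard for stratified leaves;
* repairable leaves evolve as a single shared facility-level alternating
  renewal process per cohort run: exponential time to failure at the daily
  rate, then a fixed repair window (4 h and 2 h for the two delivery
  systems).  These are hospital systems, so one trajectory is common to
  the whole cohort.  A cut set of repairable leaves fires for a patient
  only if every member is down at that patient's dosing step, drawn
  uniformly at random within each day;
* a patient discontinues at the first step in which any minimal cut set is
  satisfied (cumulative fired leaves for hazard members, instantaneous
  downtime for repairable members).  Discontinuation is absorbing: the
  patient is counted non-adherent from that day and no later event
  changes their outcome.  The triggering factor is recorded for the
  contribution analysis, with ties inside one step broken uniformly at
  random.  The limited-tablets factor's 2-day resupply delay only affects
  event timing under absorbing semantics, so it is carried as descriptive
  metadata rather than simulated.

**Common random numbers.**  Four independent streams are spawned from the
seed — cohort setup, leaf firing, supply availability, attribution — and
the firing uniforms are drawn for *every* patient at *every* step,
including already-absorbed patients.  Two runs under one seed therefore
share their randomness exactly, and because a smaller rate can only shrink
the set of fired leaves, scaling any leaf rate down can never increase the
non-adherent count.  What-if comparisons (`apply_improvement` + same seed)
are thus paired and monotone by construction, not merely in expectation.

**Summary statistics.**  The run summary reports the non-adherent fraction
p, the per-patient Bernoulli standard deviation `√(p(1−p))` (≈ 0.41 at
p ≈ 0.22), and 5%/95% normal-approximation bounds of the cohort mean,
`p ± 1.645·√(p(1−p)/n)` (≈ 0.20–0.24 at n = 1000).

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `patients` | 1000 | — | case-study cohort size |
| `days` | 10 | days | case-study regimen length, one pill per day |
| `timestep_hours` | 1 | hours | hourly resolution for dosing and supply downtime |
| age-band weights | ⅓ / ⅓ / ⅓ | — | no published cohort age mix; equal thirds, overridable per tree file |
| `HeaAcc` rate | 1.2e-4 | /day | assumed ambulatory healthcare-access barrier |
| `PriKno` | 1.5e-4 decaying 8%/day | /day | knowledge gap closing as the care team learns |
| `IctSys`, `ManSys` | 8.12e-5 (4 h repair), 5.34e-5 (2 h) | /day, hours | assumed supply-system reliability |
| remaining leaves | pooled WNARs | /day | recomputed at full precision from the six-study counts |

The what-if scenario reduces the four dominant factor rates (side effects,
forgetfulness, asymptomatic disease, other patient factors) by 20% each.

## Synthetic study generator

`generate_synthetic_studies` draws per-factor counts as
`Binomial(NoP, 1 − e^(−rate·DoM))`, truncated so a study's total never
exceeds its cohort, with NoP and DoM uniform over configurable ranges.  It
emulates the *summary table* of a multi-study pooling exercise — not
individual-level data, staggered enrolment, correlated factors or
reporting heterogeneity — so parameter-recovery tests demonstrate that the
estimator inverts the generator's sampling model, not that real studies
are this clean.  Note the deliberate mismatch between generation
(exponential occurrence probability) and estimation (`NARS/DoM`
linearisation): at the rates of interest (`rate·DoM` ≲ 0.06) the resulting
bias is under 3% and shrinks with `rate·DoM`; tests either use small
`rate·DoM` or correct for the known offset explicitly.

## Numerical choices

* `expm1` is used for every `1 − e^(−x)` to keep precision at small
  hazards.
* The sequential closed form checks for coincident partial sums (within
  1e-15) and raises a degeneracy error suggesting a rate perturbation;
  with strictly positive rates the sums are strictly decreasing, so this
  only triggers on effectively-zero rates.  A result outside [0, 1] by
  more than 1e-9 raises a numerical-instability error rather than being
  silently clipped harder.
* Cut sets are emitted sorted by size then lexicographically so reports
  diff cleanly; tie-breaks and all stochastic choices derive from the run
  seed, making every result bit-reproducible.
* Repair durations are rounded to whole steps (minimum one step); with
  the default hourly step the 4 h and 2 h windows are exact.

## Limitations

* Factor independence is assumed throughout, as is standard in fault-tree
  practice; correlated barriers (e.g. side effects driving a choice not to
  medicate) are not modelled.
* Shared basic events across branches are rejected by the tree validator;
  the analytic engine's exactness depends on the tree property.
* All participants start on the same day; staggered enrolment and
  within-day dose-timing adherence (timing/consistency) are out of scope.
* The analytic path covers constant (and mixture-constant) hazards only;
  decaying and repairable leaves require the simulator.
* Pooled rates inherit the source studies' definitions of non-adherence;
  no heterogeneity modelling or quality weighting beyond cohort size is
  applied.
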