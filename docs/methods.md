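# Methods

## Model

`clonefate` simulates clonal populations founded by single stimulated CD4+
T cells as a discrete-time stochastic decision tree. Time advances in 1 h
steps over a fixed horizon (default 100 h, matching an hourly time-lapse
acquisition). Each cell is a 7-field state vector: clone id, generation,
alive flag, differentiation (GFP) flag, birth hour, scheduled event and
scheduled hour.

Two regimes apply:

* **First event (founder).** The founder draws one of
  {divide, differentiate, remain unchanged} from the first-event
  probability table. Founders cannot die in the model: the high early
  mortality observed in culture is bead-independent transfer stress and is
  generated separately by the synthetic-data layer, not by the fate model.
  "Remain" is terminal — the cell persists untouched to the horizon
  (encoded as an infinite schedule).
* **Subsequent events.** Every cell that enters the population by division,
  and every cell that has just differentiated, draws from a second table in
  which death is a fourth option. Tables are conditioned on the cell's GFP
  state; GFP+ cells cannot differentiate again (no de-differentiation).
  Daughters inherit the mother's GFP state (no asymmetric division is
  modelled; division-independent differentiation is a separate event).

Event *timing* is empirical: each (event, regime, GFP-state) combination
carries a cumulative distribution on the hourly grid, and times are drawn
by inverse transform — the smallest support hour whose CDF reaches the
uniform draw. Waits are offsets from the cell's regime entry (t = 0 for
founders, birth hour for daughters, the differentiation hour for a newly
GFP+ cell). Draws that land beyond the horizon simply never fire; there is
no truncation or renormalisation, which mirrors what an observer of a
100 h record can actually see.

The implementation is event-driven (a heap of scheduled events) but
reproduces the hourly matrix-update bookkeeping exactly; same-hour ties
within a clone resolve in cell-creation order, making runs bit-reproducible
for a given seed. Per-run child seeds are spawned from a master seed
(`numpy.random.SeedSequence`), so populations of runs are reproducible and
runs are mutually independent.

## Inequality statistics

Clonal dominance is quantified by the Gini coefficient of the clone-size
vector (living cells per founder clone, extinct clones retained as zeros):

    G = Σ_ij |x_i − x_j| / (2 N² μ),  μ = mean clone size.

G = 0 for equal contributions; for finite N the attainable maximum is
(N−1)/N (single surviving founder), approaching the theoretical bound of 1.
The production implementation uses the sorted rearrangement
Σ_i (2i − N − 1) x_(i) / (N Σ x), algebraically identical to the pairwise
double sum at O(N log N); the explicit O(N²) sum is kept in the test suite
as an independent oracle. When every clone is empty (μ = 0) the value is
*undefined* and reported as NaN — never as 0, which would fake equality.

The trapezoid-rule Gini of the empirical Lorenz polygon equals the
pairwise form exactly (no small-sample correction is needed); the Lorenz
module exists for diagnostics and as a second cross-check route.

The GFP+ Gini series is computed over clones holding at least one GFP+
cell at the final hour. By default each such clone is credited one GFP+
cell from hour 0 until its first real GFP+ cell appears (the "GFP
artifice"), which keeps the vector non-zero over the whole series; the
artifice is switchable for sensitivity analysis.

## Estimation

The estimator reproduces the manual-tabulation procedure: per well, the
first event (earliest of division 1→2, differentiation 0→1 while single,
founder death 1→0) and its hour; compiling wells yields three first-event
frequencies and empirical time CDFs. Subsequent events are tabulated from
the per-cell event log (well id, hour, wait since regime entry, event, GFP
state, first-event flag) that the generator emits natively — aggregate
counts alone cannot disentangle simultaneous events once several cells
coexist, and the `wait` column is required to estimate subsequent-event
time distributions, which are regime-relative.

Subsequent "remain" decisions are not observable as events. Their count is
recovered by bookkeeping: each division creates two regime entries and each
differentiation one, so remain = entries − observed events per GFP state.
Cells whose drawn event lies beyond the horizon are observationally
identical to remaining cells and are absorbed there, as are wells whose
first event never occurred. Consequently the estimator is consistent only
when event-time supports are short relative to the horizon; with the
default tables' 15–100 h lag, late-born cells are censored and the
subsequent-regime "remain" frequency is over-estimated by construction.
The recovery tests therefore use tables with supports ≤ 30 h and
subcritical growth, where the bias is negligible.

Wells whose *first* event is a death are excluded from the fate-model
tables (first-regime death is culture stress, outside the model) but are
retained for the mortality analysis.

## Synthetic data

The generator emulates the micro-well experiment: each well receives a
bead count (default: 0 beads 33%, 1 bead 45%, 2 beads 15%, 3 beads 7% —
seeding aims at single-bead wells) and an independent first-24 h death
draw with probability 0.41 *identical across bead groups*; the death hour
is uniform on 1–24 h (the within-24 h profile is not published; this is a
synthetic stand-in). Survivors with at least one bead evolve under the
fate model; survivors without beads stay single and GFP−. Counts carry no
observation noise (manual counts are treated as exact).

What the generator does *not* emulate: spatial bead–cell contact dynamics,
cytokine fields, fluorescence intensities (GFP state is binary), imaging
artefacts, or well-to-well micro-environment differences. Passing tests
therefore show that the pipeline is self-consistent under the model's own
assumptions, not that the model is the unique explanation of real records.

## Default parameter tables and calibration

The original per-event tables are unpublished, so the defaults are
calibrated (grid search, `scripts/calibrate.py`, fixed evaluation seed
20240901) to the reported population-level facts: clone-type composition
among stimulated clones (roughly half mixed GFP+/GFP−, ~20% pure GFP+,
~15% pure GFP−, ~10% of founders mitotically inactive, a small minority
extinct), a first-division lag spanning 15–100 h with subsequent cycles
shorter and much less variable, final clone sizes mostly under ~12 cells
with a tail beyond 30, a rising-then-plateauing Gini trajectory, and a
collapse of the Gini to a very low level (< 0.1) when all division times
are fixed and death is removed.

The calibrated defaults:

| quantity | value |
|---|---|
| first event: divide / differentiate / remain | 0.89 / 0.05 / 0.06 |
| first-division lag | discretised Gamma(0.7, 110) + 15 h on 15–100 h (median ≈ 39 h, heavy tail) |
| first differentiation time | Normal(44, 8) on 26–70 h |
| subsequent GFP−: divide / diff / die / remain | 0.617 / 0.16 / 0.22 / 0.003 |
| subsequent GFP+: divide / die / remain | 0.877 / 0.12 / 0.003 |
| cycle length (both phenotypes) | Normal(22, 9) on 6–44 h |
| differentiation wait after regime entry | Gamma(1.5, 1.5) + 1 h, ≤ 6 h |
| death wait | Gamma(1.5, 5) + 3 h, ≤ 30 h |
| founders per run / horizon | 133 / 100 h |

Calibration notes (design choices that were genuinely open):

* The synchronized-immortal floor is dominated by the mitotically inactive
  fraction (a fraction q of size-1 clones among equal large clones yields
  G ≈ q) plus fate-choice randomness that compounds with each division
  round. This pins the first-event remain probability to the lower half of
  the tolerated inactive band (0.06) and keeps the differentiation and
  remain choice probabilities, and the differentiation waiting time, small.
* The synchronized variants' clone sizes are bimodal — hence the Gini floor
  is discontinuous — whenever the fixed lag plus an integral number of fixed
  cycles lands near the horizon. The default medians (39 h lag, 22 h cycle)
  leave a ≥ 5 h buffer (39 + 3·22 = 105 > 100), so all synchronized clones
  complete the same number of divisions.
* Fixing a time distribution replaces it by a point mass at its *median*.
  For a right-skewed distribution the median point mass accelerates growth
  (and can *raise* inequality by amplifying the lag spread); the calibrated
  cycle distribution is symmetric, so the fixed variants are never faster
  than the stochastic model — randomness in cycle length speeds up
  branching growth (Jensen), and removing it slows the variant down and
  lowers the final Gini, as required for the ablation ordering.
* With these tables the full model's final Gini median is ≈ 0.44. Pushing
  it towards the high-0.5 range observed experimentally requires either
  heavier lag tails or higher death rates than the clone-composition and
  ablation-ordering constraints tolerate; clonal dominance strength was
  given lower calibration priority than composition and ablation structure,
  and the trajectory's rise-and-plateau shape is unaffected.

## Numerical and statistical choices

* Probability vectors validated to sum to 1 within 1e-9 (1e-6 at the
  sampling boundary); empirical tables built from integer counts are exact.
* Event draws traverse events in the fixed order divide, differentiate,
  die, remain, so seeded results do not depend on dict insertion order.
* Kruskal–Wallis (scipy) compares the six ablation groups on the
  final-hour Gini of the total clone-size vector (one value per run, not
  time-averaged). All-pairs post-hoc comparisons use Dunn's rank z test
  with tie correction, Bonferroni-adjusted by default (switchable to raw).
  When every group is a single identical constant the test is degenerate
  and reported as statistic 0, p = 1.
* The dye-dilution profile assigns each final living cell intensity
  F0·2^−d (d = completed divisions) with multiplicative log-normal noise of
  sd `noise_sd` on the log₂ scale (defaults F0 = 10⁴ a.u., sd 0.15 —
  presentational, config-exposed). Modes then sit 1 log₂ unit apart while
  the noise is small; peak detection uses a moving-average-smoothed
  histogram.
* Two-sample death-time comparisons use the Kolmogorov–Smirnov test; the
  degenerate identical-sample case reports statistic 0, p = 1.

## Problem sizes

Default experiment sizes are those of the study design: 133 founders per
run, 100 h horizon, 100 runs for the Gini band and for each ablation group,
940 wells (≈ 630 with beads) for synthetic datasets, 2000 wells for
estimation recovery checks. The full six-variant ablation at these sizes
runs in well under a minute on a single core.

## Known limitations

* The estimator has no censoring correction (by design — it mirrors raw
  empirical tabulation), so it is biased for tables whose event times are
  long relative to the horizon; see Estimation above.
* Founder death is excluded from the fate model; a founder that would die
  after 24 h without ever dividing is not representable except through the
  stress-death channel.
* The experimental final Gini values reported for the original records
  (≈ 0.58 total, ≈ 0.54 GFP+) cannot be recomputed here — the raw
  time-lapse records are unpublished; the package asserts instead the
  structural properties (trajectory shape, total-vs-GFP+ agreement,
  ablation ordering) that are reproducible from simulation alone.
* CellState's seven fields are a functional reconstruction of the cell
  state vector; the original column semantics are not publicly documented.
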