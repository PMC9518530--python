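# Methods

This note documents the models the package implements, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the known limitations.

## Standardization and orientation

Indicators arrive in incommensurable units with mixed orientation.
Min-max standardization maps each column to [0, 1] with the attribute
deciding the branch: positive `(x − min)/(max − min)`, negative
`(max − x)/(max − min)`. After the transform, larger always means
better and every column attains both 0 and 1, so a multiplicative
rescaling of any raw column leaves all downstream results exactly
unchanged. A constant column has no defined transform; it raises a
degenerate-column error naming the indicator, or is dropped with a
warning under an explicit flag.

## Imputation

Missing cells are assumed sparse and missing-at-random (the intended
data situation has about six gaps in a 17 × 27 panel, at most one per
indicator). Each incomplete column is predicted by ordinary least
squares from the fully observed columns (intercept-only fallback when
none exist or the design is too small); each gap receives
`n_candidates` draws of prediction + Gaussian noise with scale
`noise_scale × residual SD`, and one value is kept — by default the
candidate closest to the candidate mean (`closest_to_mean`), with the
candidate mean itself (`pooled_mean`) as the alternative. Defaults:
`n_candidates = 5`, `noise_scale = 1.0`. With `noise_scale → 0` the
procedure degenerates to the deterministic regression prediction.
Observed cells are never modified, and the whole procedure is a
deterministic function of its seed. This is deliberately *not*
chained-equations multiple imputation: the target setting has too few
gaps to support posterior simulation, and the noisy-candidate scheme
keeps every stated property (predictive, stochastic, multi-candidate,
rule-selected) at minimal model complexity.

## The projection index

For direction `a` (unit Euclidean norm) and standardized matrix X, the
projections are `y = X a`, the spread `S_y` the sample SD with the
m − 1 denominator, and the density

    D_y = Σ_{i≠j} (R − r_ij) · u(R − r_ij),  r_ij = |y_i − y_j|,

summed over *ordered* pairs. Three quantities the index needs are left
open by its usual statement and are fixed here as configuration with
these defaults:

* **r_ij** is the absolute difference of projected values — the only
  distance available in the one-dimensional projected space.
* **R** defaults to `0.1 · S_y` (the `fraction_of_spread` rule, the
  common convention for this index); a `fixed` radius is available.
  A pair exactly at distance R contributes zero weight (the step
  function is 1 there but the triangular weight vanishes), so the
  boundary convention is immaterial.
* **Self-pairs** are excluded by default: each contributes exactly R,
  so under the fraction rule their total `m · R = 0.1 m S_y` grows
  with the spread and would distort the spread–density trade-off. A
  flag restores them.

The unit-norm constraint is enforced by renormalizing every candidate
direction before evaluation — exact feasibility with no penalty
parameter. `F(a) = F(−a)` by construction, and `F = 0` whenever the
projections carry no spread.

Direction components are by default decoded from nonnegative genes
([0, 1] before renormalization), giving interpretable nonnegative
weights for oriented indicators; a signed mode ([−1, 1]) is available.

## The genetic algorithm

Real-coded genes on [0, 1]ⁿ decode linearly into the current variable
bounds. Per generation: geometric rank fitness
`α(1 − α)^(rank−1)` with `α = 0.05` (the printed exponent convention
`1 − i` would reward worse ranks and contradicts the requirement that
replication probability be proportional to fitness, so the standard
`i − 1` is used); roulette selection of N parents on the cumulative
fitness; arithmetic per-gene blend crossover of randomly paired
parents (entry probability Pc); directional mutation `x + M·d` with
`d` uniform on the unit sphere and `M` uniform on (0, 1), clamped to
the box (probability Pm); then elitist truncation of the pooled
parents + offspring + mutants back to N, with the best-so-far
individual always carried. Defaults N = 40, Pc = 0.8, Pm = 0.2,
250 iterations, matching the index-weighting configuration of the
intended study; the dimension-wise scoring runs default to the
printed per-dimension iteration counts (15 / 200 / 400 / 150).

**Acceleration.** Every `acceleration_period` (default 5) generations
the bounds contract around the elite fraction (default 0.2) of the
population, elites are re-encoded into the tighter box and the rest of
the population re-initialized inside it. The textbook contraction —
the raw [min, max] envelope of the elite decoded values — proved
unusable in this design: arithmetic crossover plus truncation cluster
the population within a few generations, so the envelope collapses to
a point and freezes the search box wherever the population happened to
sit (observed sphere-recovery errors up to 7 × 10⁻²). The implemented
rule floors the new interval at `acceleration_min_width` (default 0.5)
of the current width, centered on the envelope, slid back inside and
never wider than the current bounds. The box still contracts
geometrically — 40 accelerations reach widths near 10⁻¹² — but can
migrate toward an optimum near its edge; certified-optimum recovery is
then at the 10⁻⁵ level across seeds. Setting the floor to 0 restores
the literal envelope rule (a fully collapsed interval is then widened
by 10⁻⁶ of the original span).

Termination: the iteration cap, or best-objective improvement below
10⁻¹⁰ over 20 generations. The best-so-far trace is non-decreasing by
construction, and identical seeds give identical results.

## Weighting, scoring, classification, comparator

The index weights are the optimal projection values of the
*transposed* standardized matrix (indicators as observations) — the
projection-value convention, not the components of the direction
vector, which are exposed separately. Raw projection values and
sum-to-one normalized weights are both reported, since either scale
may be wanted. Region scores are the optimal projection values in the
natural orientation. Per-dimension scores rerun the scoring on one
dimension's columns only; the composite score is *not* the weighted
mean of the dimension scores, and the report carries both plus their
difference as an observation rather than a constraint.

Jenks natural breaks are computed by exact dynamic programming over
the sorted scores (O(k·m²)), not by a heuristic; quality is summarized
as goodness-of-variance-fit `1 − SSE_within / SSE_total`. Break
values are the minima of the upper classes, levels are numbered 1 =
highest, a value equal to a break belongs to the class that break
opens (level 1 iff value ≥ top break), and interior classes are
left-closed right-open going downward.

The entropy-TOPSIS comparator uses column-share entropy
`e_j = −(1/ln m) Σ_i p_ij ln p_ij` (zero shares contribute zero),
weights `(1 − e_j)/Σ(1 − e_k)`, and closeness `d⁻/(d⁺ + d⁻)` to the
weighted ideal/anti-ideal. It is an independent cross-check, never a
fallback implementation of the projection model.

## Spatial analysis

Weights default to inverse Euclidean distance (`1/d^power`, power 1)
with the minimum-coverage cutoff — the largest nearest-neighbor
distance, the smallest cutoff leaving no region neighborless. Row
standardization is off by default because the global statistic already
carries the `n/S₀` normalizer; it is a flag. Distance-band and
k-nearest-neighbor weights are available; polygon contiguity is out of
scope (the intended use has point coordinates only).

Global Moran's I uses the standard cross-product form with
`E[I] = −1/(n − 1)` and Cliff–Ord variance moments under either the
normality or the randomization null (default randomization, the
convention of common GIS reports). The randomization moments were
verified against exact enumeration of all permutations on toy
instances (agreement at 10⁻¹⁵); the two variances are *not* equal at
sample kurtosis 3 — they only converge asymptotically — so no such
identity is asserted anywhere. Two-sided normal p-values are always
accompanied, never silently replaced, by a permutation pseudo-p
`(1 + #extreme)/(n_perm + 1)` counting permutations at least as far
from E[I] as the observation.

The local statistic `I_i = n(x_i − x̄)·Σ_j w_ij(x_j − x̄)/Σ(x_i − x̄)²`
satisfies `Σ_i I_i = S₀ · I` identically for any weight matrix under
this scaling. Quadrants follow the signs of deviation and lag with
zero counted as high; per-region pseudo-p values use conditional
permutation (region i's value held fixed, the rest permuted).
Subgroup analysis restricts the weights to the subset (re-standardized
when applicable) and reports *both* the subset's own global I and the
mean of its local values, because a single per-group association
number is ambiguous between those conventions. The often-quoted
[−1, 1] range for I is treated as approximate; `moran_bounds` reports
the exact attainable range from the spectral range of the centered
symmetrized weights.

## Synthetic data

The generator emulates the study-shaped data situation: 17 regions ×
27 indicators laid out 7/8/6/6 over the four dimensions, with the
population-density, disaster-count and direct-loss indicators negative
and scale families imitating real magnitudes (counts, percentages,
10⁴-Yuan amounts, mileage) so standardization is exercised over
heterogeneous units. Latent per-dimension quality factors are
simultaneous-autoregressive (SAR) fields `x = (I − ρW)⁻¹ε` on
row-standardized inverse-distance weights over uniform random planar
coordinates — one parameter ρ spans the negative/null/positive
autocorrelation regimes the method must distinguish. Indicators load
on their dimension's factor (loadings U(0.6, 1.0) times a strength
parameter) plus unit noise, mapped through the Gaussian CDF onto the
family's range; negative indicators flip the latent sign so larger raw
values mean worse status. Missing cells default to rate 0.013 (about
six cells on the default layout, at most one per column), mirroring
the sparsity of the intended application.

What the generator does **not** emulate: real administrative-unit
geography (coordinates are uniform, not a river-basin province),
reporting artifacts (rounding, censoring, unit mix-ups), non-Gaussian
indicator tails, and structured missingness. Passing tests therefore
demonstrate correctness of the *procedures* under realistic shape,
scale and spatial-dependence conditions — not that any particular
real province's published figures are reproduced. The real panel the
method was designed around is not publicly deposited, so region-level
numeric agreement with published scores is out of reach by
construction; the published *closed-form* quantities (the expectation
magnitude 0.0625 at n = 17, and the z = −0.317817 / p = 0.750624
worked example implied by the printed report fields) are recomputed
exactly.

At m = 17 observations the chance level of a mean absolute pairwise
correlation between independent indicators is `√(2/π)/√(m−1) ≈ 0.20`;
tests of the zero-strength generator assert proximity to that floor
rather than an absolute small value, which no independent data of this
size could attain.

## Problem sizes and determinism

Test and acceptance runs use the study-scale default panel (17 × 27),
a 49-node lattice with 999 permutations and 200 replicates for
size/power calibration, 10 seeds for optimizer-recovery checks, and
exhaustive enumeration oracles at m ≤ 12 (Jenks), n ≤ 8 (Moran double
sums) and n = 6 (720-permutation variance enumeration) — sizes chosen
so each oracle is literally exhaustive while the suite stays quick.
Every stochastic component takes an explicit seed; the pipeline fans
one root seed out to per-stage seeds through a counter-based
`SeedSequence` derivation, so any stage can be reproduced in
isolation. Two runs with equal inputs, configuration and root seed
produce byte-identical reports.

## Known limitations

* Imputation assumes approximately linear inter-indicator relations;
  grossly nonlinear panels would need a richer predictor.
* The projection index with the fraction-of-spread radius makes F
  scale-free in R but leaves a genuine tuning choice (0.1) that can
  shift weights on small panels; both the rule and the value are
  configuration, and results should be read with that sensitivity in
  mind.
* GA convergence is stochastic: certified-optimum recovery is tested
  across 10 seeds, not proved; pathological multimodal objectives can
  still trap the search despite the acceleration floor.
* Analytic Moran inference leans on moment approximations that are
  rough for n ≲ 20; the permutation test is the primary inference at
  study scale and the analytic z is reported for comparability with
  standard GIS reports.
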