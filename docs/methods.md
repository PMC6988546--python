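# Methods

This note documents the statistical machinery, the synthetic data the
package is validated on, the numerical choices, and the known limits of
both.

## Presence-background model

The engine fits a Gibbs density over a finite background of N stream
segments. With features f_j scaled to [0,1] over the background and
presence segments x_1..x_n, the penalized log-likelihood

    L(λ) = (1/n) Σ_i η(x_i) − ln Σ_bg e^{η(x)} − Σ_j β_j |λ_j|,
    η(x) = Σ_j λ_j f_j(x)

is concave; its maximizer gives the unique fitted density
raw(x) = e^{η(x)}/Z. Minimizing the relative entropy of the presence
covariate distribution against the background subject to feature-mean
constraints yields the same solution (convex duality); the per-feature
L1 penalty is the regularized form of allowing each presence feature
mean to be matched only within β_j.

**Features.** Per covariate: linear (the scaled covariate u), quadratic
(u²), pairwise products (u_a·u_b), and forward/reverse hinge pieces
max(0, (u−t)/(1−t)) and max(0, (t−u)/t) with knots t at background
quantiles (50 per covariate and direction by default; duplicate
quantiles are collapsed). Threshold and categorical features are not
implemented. The *autofeature* rule enables classes by presence count:
linear always, quadratic at n ≥ 10, hinge at n ≥ 15, product at n ≥ 80.

**Penalties.** β_j = β · r_class(n) · s_j/√n where β is the
user-facing multiplier, s_j the feature's sample deviation over the
presences, and r_class(n) the class default: piecewise-linear in n
through (10, 1.0), (30, 0.2), (100, 0.05) for linear, quadratic and
product classes, and constant 0.5 for hinges. Two floors stabilize
this: s_j ≥ 1e−3 for all features (a feature constant across presences
must still be penalized), and s_j ≥ 1/√n for hinge features — the
canonical Maxent default. The hinge floor matters: hinge pieces active
on only a few presences otherwise carry vanishing penalties, the
nonzero-coefficient count k stays near the feature count at every β,
and AICc (below) is undefined across the whole grid at realistic
sample sizes.

**Solver.** Cyclic coordinate descent with proximal-Newton updates and
soft-thresholding: for feature j with model mean m_j and variance v_j
under the current density, λ_j ← S(λ_j + (p̄_j − m_j)/v_j, β_j/v_j),
S the soft-threshold. Every step is backtracked (halved up to 25
times) until the penalized objective does not decrease, so the ascent
is monotone by construction; the objective after each cycle is
retained on the model for inspection. Convergence is declared when a
full cycle improves the objective by less than `tol` (default 1e−5);
after each full pass, inner passes iterate only the active (nonzero)
set, glmnet-style. The iteration cap (10,000 cycles) raises rather
than returning silently. Features constant over the background are
dropped with a log entry. Exact zeros from the soft-threshold are what
make k = #{λ_j ≠ 0} well-defined without a tolerance.

**Output scales.** raw sums to one over the training background.
Reported suitability is cloglog: 1 − exp(−e^H·raw) with
H = −Σ raw·ln raw, a 0–1 index equal to 1 − e⁻¹ ≈ 0.632 everywhere for
the uniform (fully shrunk) model. Predictions on new rows reuse the
training normalizer and scaling, with covariates clamped to the
training background range.

**Interpretation aids.** Percent contribution is path-dependent: each
accepted coordinate update's objective gain is credited to the updated
feature's source covariate(s) (split equally for products), floored at
zero and normalized to 100. Permutation importance permutes one
covariate across all rows (presences are background rows), re-evaluates
the model, and reports the training-AUC drop, normalized to 100.
Response curves are *marginal*: one covariate swept across its
background range with the others fixed at their presence-sample means —
not single-variable refits; both conventions exist, and the marginal
curve was chosen because it interrogates the fitted model itself.

**Missing data.** Covariate gaps are permitted and imputed with the
background mean of the covariate at fit/predict time, with a logged
warning.

## Complexity selection

For each β on an inclusive grid (default 1.0–5.0 by 0.5) a model is
fitted and scored by AICc = 2k − 2·logL + 2k(k+1)/(n−k−1), where
logL = Σ_presences ln raw (raw re-normalized over whatever background
is supplied) and n is the post-deduplication presence count. Rows with
n − k − 1 ≤ 0 are flagged undefined rather than scored; if every row is
undefined, selection raises. k counts nonzero feature coefficients
only — no intercept or normalizer terms. AICc ties break toward larger
β (parsimony). Cross-validation folds are drawn once per
(dataset, seed) and reused across the grid; by default CV metrics are
computed only for the default and chosen rows (a flag evaluates the
full grid).

## Evaluation

Fivefold cross-validation partitions the presence segments into folds
differing in size by at most one. Per fold the model is refitted on
the training folds (feature classes fixed by the full-data presence
count so the specification is constant across folds) and two metrics
are averaged: AUC_test, the rank-based (Mann–Whitney, ties 0.5)
discrimination of held-out presences against predictions at *all*
background segments — test presences are not removed from the
background side; and OR_mtp, the fraction of held-out predictions
strictly below the minimum training-presence prediction. The strict
inequality makes MTP inclusive: a record exactly at the threshold is
not omitted, and training omission at its own MTP is identically zero.
AUC is invariant to monotone transforms, so raw and cloglog agree.

## Model comparison

Niche overlap is computed on background-normalized **raw** output
(each model's raw re-normalized to sum 1): D = 1 − ½Σ|p−q| and
I = 1 − ½Σ(√p−√q)². The cloglog scale can be compared instead via the
array interface, but raw is the default because both statistics are
defined on probability distributions. Binary maps threshold cloglog at
each model's own MTP (inclusive ≥). The ensemble map sums binary maps
over any M models (the study design gives M = 6).

## Synthetic riverscape

The generator is the package's test bed and defines the conditions the
validation suite runs under.

* **Topology** — a rooted tree grown from the outlet; each new segment
  either extends a channel tip or (with probability `branching_prob`,
  default 0.35) forms a binary confluence. This yields the right-skewed
  Strahler distribution of real dendritic networks (at the default
  2,000 segments: ~60% order 1, maximum order ≈ 7). Strahler orders are
  computed by the standard rule; drainage area accumulates a lognormal
  local catchment per segment downstream.
* **Watersheds** — the tree is cut into `n_watersheds` (default 8)
  connected subtrees. Cutting the globally largest subtrees is
  degenerate (the candidates are nested along the mainstem, stranding
  sliver watersheds), so cuts greedily pick the subtree closest in size
  to n/n_watersheds, recomputing sizes after each cut.
* **Covariates** — discharge Q = c·A^0.9 · lognormal(0, 0.3), rescaled
  so the basin maximum is 1,279 m³/s (a large-river mainstem); maximum
  elevation accumulates strictly positive increments upstream mapped
  onto 63,271–396,264 cm; slope, % sand, bedrock depth and % CaO are
  AR(1) fields along the tree (ρ = 0.9) pushed through the normal CDF
  onto their published ranges; downstream link order is the parent
  segment's Strahler order. Planar coordinates have x increasing
  downstream with 8–25 km reaches, so the default basin spans several
  hundred km and a 20-km distance filter is a meaningful thinning
  scale rather than a near-total cull.
* **Truth and sampling** — true suitability is
  logistic(steepness·(ln q − ln q50)) with q50 = 15 m³/s and
  steepness = 2, i.e. low in headwaters, ≈ 0.5 at 15 m³/s and
  approaching 1 beyond ~50–60 m³/s. Presences are drawn without
  replacement with weight suit·(q/q_max)^bias_strength; the default
  bias_strength = 3 congregates records on the largest, most
  downstream segments — the access-driven sampling bias the filters
  are designed to correct. bias_strength = 0 recovers
  suitability-proportional sampling.
* **Determinism** — every stage derives a CRC32 sub-seed from the
  master seed, so stages regenerate independently and full runs are
  bit-reproducible.

What the generator does **not** emulate: hydrological routing,
climate covariates, detection error, temporal structure in records,
or the raw scale of a real basin (~10⁵ segments; the default 2,000
keeps the full study design in seconds-to-minutes on one core — the
suite's problem sizes are stated in the tests themselves). A test
passing on this world shows the algorithms are implemented correctly
under known truth, not that any real species follows a logistic in
log-discharge.

## Bias filters

The distance filter removes, per repetition, the record with the most
neighbors closer than `min_km` (seeded random tie-breaks) until no
violating pair remains, and keeps the best of `reps` repetitions
(default 100, the thinning literature's convention). It is a heuristic
for maximum independent set; on ≤ 12-record instances the suite checks
it against exhaustive enumeration. The riverscape filter retains one
record per (HUC8, stream-order) combination, chosen uniformly under a
seed — a reproducible stand-in for a haphazard manual pick; its
retained *count* is seed-invariant by construction. Distances are
Euclidean on planar km coordinates, or great-circle when the table is
flagged lat/lon.

## Study pipeline

`run_study` wires the design together: generate/load → dedup →
correlation screen (with a greedy auto-selected covariate subset when
none is configured; a configured subset is validated and warned about,
matching a workflow where the subset is an ecological choice) → three
presence datasets → per-dataset AICc selection → six final models →
CV metrics, contribution/importance tables, D/I matrices, MTP binary
maps, ensemble map → manifest with SHA-256 per artifact. CSV floats are
written with a fixed format so reruns hash identically.

## Known limitations

* No bit-level parity with the reference Java implementation is
  attempted: knot placement, default-table interpolation and solver
  order differ, so coefficient files are not interchangeable — only
  the model class and its statistics are.
* Percent contribution is path-dependent by definition; different
  update orders redistribute credit among correlated covariates.
  Permutation importance is the stabler measure and the one the
  recovery tests assert on.
* The distance filter is a heuristic; optimality is verified only at
  enumeration scale.
* AUC against the full background (with presences included on the
  background side) is the standard presence-background convention; it
  is bounded below 1 in principle but the bound is negligible at the
  background sizes used here.
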