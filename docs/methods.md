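# Methods

`mesoconn` implements a workflow for asking how much information about
region-level axonal projection patterns is contained in region-level gene
expression of the mouse brain, and for characterizing *which* genes carry
that information. This note documents the models and procedures, the
parameters that matter, the synthetic data the package is validated on,
and the numerical conventions adopted where the design was genuinely open.

## Data model

Both modalities are unionized summaries over atlas-defined brain areas:

* **Expression energy** `X` (areas × genes): per area and gene, summed
  in-situ-hybridization intensity divided by the area's pixel count.
  Non-negative, right-skewed, with NaNs where unionization produced no
  value.
* **Normalized projection volume** `Y_c` (areas × injections), one matrix
  per tract-tracing category `c`: detected projection pixels in a target
  area divided by the area's pixel count and the injection size.
  Non-negative and zero-inflated — exactly 0 where no projection signal
  was detected.

Categories distinguish pan-neuronal ("wild-type") experiments from
cre-line experiments whose labeled neurons belong to a projection cell
class (IT, PT or CT) with a dominant laminar profile. Assembly
reconciles every matrix onto the lexicographically sorted intersection of
their area sets, so all downstream stages can assume aligned rows.

## Preprocessing

Fixed order: **filter → impute → cube root → z-score**.

1. *Area filtering.* An area is dropped when its NaN fraction strictly
   exceeds `max_nan_frac` (default 0.8) in the expression matrix **or**
   in any projection matrix.
2. *Expression imputation.* Each remaining NaN is replaced by the gene's
   median over observed areas.
3. *Projection imputation.* Per injection column, observed values are
   stratified into the exact-zero group and the non-zero group; each NaN
   picks a group with probability equal to the group's observed fraction
   and draws uniformly from it (the zero group always yields exactly 0).
   This preserves the zero-inflation point mass instead of smearing it
   with a central-value imputation.
4. *Rescaling.* A cube root reduces the right-skew of both modalities;
   a per-column z-score across areas then equalizes scales for the
   regression solvers. The **population** (ddof = 0) standard deviation
   is used throughout the package — the convention was open, so it was
   fixed once and applied consistently here, in the binarization
   threshold, and in tests. Constant columns map to all-zero columns
   rather than raising: imputation can legitimately produce them and they
   carry no signal. Column means/stds of the cube-root values are kept
   so predictions can be mapped back to the raw scale (invert z-score,
   clip negatives to 0, cube).

Whether the z-score should run over areas (per column) or over genes (per
row) was ambiguous; per-column across areas is implemented, which is the
standard feature-wise convention for the downstream regressions.

## Dictionary learning of spatial gene modules

Expression is decomposed as `X ≈ D a` with non-negative spatial modules
`D` (areas × K) and non-negative sparse gene loadings `a` (K × genes), by
minimizing

```
0.5 ‖X − D a‖²_F + λ Σ|a|    s.t.  D ≥ 0,  a ≥ 0,  ‖d_k‖₂ ≤ 1.
```

Design choices:

* The l1 constraint on the coefficients is implemented in **Lagrangian
  (penalty) form** with weight `λ` per coefficient (default 1.0). A hard
  global bound `‖a‖₁ ≤ λ` would be degenerate at realistic matrix sizes;
  the penalty form is the standard sparse-coding formulation and what the
  common solvers implement.
* The **coefficient step** solves, per gene column, non-negative
  l1-penalized least squares exactly (coordinate descent; plain NNLS when
  `λ = 0`). The **dictionary step** is block-coordinate: with the other
  columns fixed, the exact minimizer for column `d_k` is the Euclidean
  projection of the unconstrained update onto `{d ≥ 0, ‖d‖ ≤ 1}` (clip
  negatives, then scale into the unit ball). Because both half-steps are
  exact convex solves over a convex set, the recorded objective trace is
  non-increasing **by construction** — constraining the column norm
  inside the update, rather than renormalizing after an unconstrained
  NNLS solve, is what makes that guarantee unconditional.
* *Initialization:* `D` starts from K randomly chosen data columns
  (unit-normalized), a scale-matched start. *Dead atoms* (zero
  coefficient rows) are re-seeded from the worst-reconstructed data
  column; a dead atom does not touch the objective, so re-seeding
  preserves monotonicity. Stopping: `|Δ objective| < tol` (default 1e-6)
  or `max_iter` (default 100).
* DLSC input must be non-negative. Z-scored data are shifted by their
  global minimum (`shift_nonnegative`), preserving ordering and
  contrasts; feeding raw cube-root data instead is a caller choice.

The **constrained** variant fixes `a` to an external cell-types × genes
signature grid (gene axes intersected and identically reordered first)
and solves only `D ≥ 0` by row-wise NNLS — one module per cell type.

**Module-count selection** refits the factorization for each candidate K,
uses the dictionary columns as features in the nested-CV ridge fit of
every category, and records the median/IQR of out-of-fold r² over all
injections. The chosen K is the *smallest* candidate whose median score
is within a margin (default 0.01) of the maximum — near-ties are
attributed to variability and parsimony wins.

## Prediction and controls

One model per tracing category predicts all of the category's injections
jointly (multi-output) from the shared feature grid — genes, or module
footprints — with a single hyperparameter setting, mirroring how a single
model must serve a whole category. Validation is **nested 3-fold
cross-validation over areas**: the inner 3-fold grid search selects
hyperparameters by mean r² over all injections; the outer split yields
out-of-fold predictions for every area. Per injection,

```
r² = 1 − Σᵢ(yᵢ − fᵢ)² / Σᵢ(yᵢ − ȳ)²
```

is computed on the **concatenated** out-of-fold vector (less fold-size
bias than averaging per-fold scores; the alternative convention was
open). r² is unbounded below; constant measured columns are flagged
degenerate (NaN) rather than scored. Default grids: ridge
`α ∈ 10^{−3..3}` (7 log-spaced points); random forest
{100, 300} trees × depth {∞, 10} × min-leaf {1, 5}.

Controls:

* **Surrogate models** — each gene's expression independently permuted
  across areas (value multisets conserved exactly), refit with the same
  protocol; skill should vanish.
* **Null models** — predict each held-out area by the training-fold mean
  of the injection; out-of-fold r² is at best ≈ 0.
* **Wild-type subset permutation test** — for each cre-line of size n,
  compare |median(line r²) − median(all wild-type r²)| against the same
  statistic for random size-n wild-type subsets (default 100 permutations
  per line; configurable, since the reference protocol's total count is
  ambiguous). Exceedance counts are pooled over lines into a single
  p-value; the statistic and pooling rule are package decisions, as the
  underlying test was described only by its inputs.

## Binarization and ROC analysis

Each measured pattern is binarized at a data-driven, per-experiment
threshold `t = median(values) + std(values)` on the raw non-negative
scale. The exact published rule was not available; median-plus-std was
adopted because the degenerate behavior of the reference analysis is
attributed to "median and standard deviation being too low", implying
both statistics enter the rule. The rule is a replaceable strategy
object (quantile-based alternatives are provided). If no value exceeds
`t` the pattern binarizes to all-zero and the experiment scores **0 for
both auROC and f1** — a deliberate convention (not NaN, not 0.5) that
keeps such experiments visible as outliers; they are flagged so users can
exclude them.

auROC is rank-based with midrank tie handling; f1 is `2TP/(2TP+FP+FN)`
with 0 when TP = 0, computed from the binarized prediction under the same
rule. `multi_roc` sweeps external thresholds (quantiles of the positive
measured values) to show how ranking quality depends on where
"connected" is cut. Predictions enter on the raw scale: invert the
z-score with stored column statistics, clip negatives, cube.

## Module footprint analysis

Per injection, modules are ranked by |Pearson r| with the pattern; the
top 3 predict the pattern by out-of-fold OLS (OLS rather than ridge for
an unregularized 3-parameter fit; configurable). The per-area overlap
between the pattern and its top-3 modules is coded on six levels, with
presence meaning a raw value above `presence_eps = 1e-6` (z-scored data
have no meaningful zero, so coding happens pre-rescale):

| code | meaning |
|------|---------|
| 1.0 | pattern + all three modules |
| 0.8 | pattern + exactly two modules |
| 0.6 | pattern + exactly one module |
| 0.4 | pattern only |
| 0.2 | ≥ 1 module, pattern absent (regardless of how many modules) |
| 0.0 | absent everywhere |

## Enrichment

Query sets are either the genes whose |ridge coefficient| strictly
exceeds the 99th percentile of the coefficient-magnitude distribution
(magnitude, because ridge coefficients are signed; switchable), or all
genes with a non-zero (> 1e-12) module loading. Each query is tested
against every annotation term with the exact upper-tail hypergeometric
probability; the background is the set of genes surviving preprocessing.
Significance is raw `p ≤ 0.05` by default — no multiple-testing
correction, matching the reference reporting — with Benjamini–Hochberg
available as an option.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure the analysis assumes, so every
stage has a ground truth to be tested against:

* `D_true` (areas × K_true): contiguous, evenly spaced area blocks
  (footprint fraction 0.3 by default) with uniform(0.5, 1.5) values —
  disjoint-leaning spatial modules.
* `a_true` (K_true × genes): 10 % non-zero loadings per module.
* Expression: `(D_true a_true + |ε|)³` with half-normal noise — cubing a
  non-negative linear model plants the right-skew of real expression
  energies, so the cube-root rescale *exactly* linearizes the signal at
  zero noise.
* Projections: per category, `clip(X_clean W_c + ε, 0)` where `X_clean =
  D_true a_true` and each injection's map `W_c[:, j]` combines 5 random
  expressed genes non-negatively; the lowest 30 % of each column is
  hard-set to 0 (zero-inflation) and the result is cubed onto the same
  skewed scale. Cubing both modalities is what makes the planted
  expression-to-projection map linear again after preprocessing — the
  pipeline's self-consistency anchor.
* Both signals are normalized to peak 1, so the default noise SDs
  (0.05 on the linear scale, ~5 % of full scale) read directly as
  realistic measurement-noise fractions. NaN masks are uniform at 5 %.
* Category sizes default to 60 wild-type + 3 cre-lines of 15 —
  preserving the dominant-wild-type imbalance of real tracing corpora at
  a scale that keeps the full suite in minutes. Cell classes and layer
  profiles are assigned cyclically from a fixed label table.
* Annotations: n terms of 10–30 genes; planted-enriched terms draw
  ≥ 80 % of their genes from one module's loading set, the rest are
  uniform.

A single seed expands into fixed per-stage child streams
(`SeedSequence(seed, spawn_key=(stage, sub))`), so each stage is
individually and jointly reproducible, bit-identically.

The **noiseless anchor configuration** sets the noise SDs, the NaN
fractions *and* the zero-inflation fraction to 0: it is the configuration
in which the planted map is exactly linear end-to-end, and nested-CV
ridge must reach median out-of-fold r² ≥ 0.95 (observed ≈ 1.0). Under
the default noisy configuration the observed median is ≈ 0.76, the
surrogate control ≈ −0.03 and the null control ≈ −0.01.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial autocorrelation beyond block
footprints (real modules have smoother, anatomically structured
footprints), non-linear or source-target-coupled projection rules,
structured (non-uniform) missingness, heavy-tailed measurement noise, and
annotation hierarchies. Performance numbers on synthetic data are
self-consistency checks, not forecasts of performance on atlas data.

## Problem sizes and numerical conventions

Defaults were chosen so the whole test suite and the worked example run
on a laptop-class single core in well under a minute each: 200 areas ×
500 genes × K_true = 10 for pipeline-level checks; 60 × 120 × 8 for
factorization recovery; 25 surrogate replicates. Tolerances: objective
monotonicity asserted to 1e-8; DLSC stopping tol 1e-6 (1e-10 to 1e-12 in
recovery tests); z-score mean/std checked to 1e-10; hypergeometric
exactness to 1e-12. Ties in top-k module selection and in hyperparameter
search break deterministically (lowest index / first candidate).

## Known limitations

* The DLSC solver is exact per half-step but, like all alternating NMF
  schemes, converges to a local optimum; recovery guarantees in tests
  hold for the planted, well-conditioned regime.
* The permutation test's pooled p-value treats lines as exchangeable and
  is not corrected for the number of lines.
* `select_module_count` refits the dictionary per candidate K with a
  fixed seed; sweep scores inherit factorization variability.
* The binarization rule is one member of a family; conclusions that
  depend on the exact threshold should be checked against the quantile
  alternatives.
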