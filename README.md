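# mesoconn

Predicting the mouse **mesoconnectome** — region-level axonal projection
patterns — from region-level gene expression, and characterizing which
spatial gene modules and functional gene groups carry the predictive
signal.

## The problem

Anterograde tract tracing measures, for an injection into a source brain
area, the *normalized projection volume* delivered to every target area.
In-situ hybridization measures, for each gene, an *expression energy* in
every area. Connected neurons tend to share transcriptomic programs, so
region-level co-expression should contain information about region-level
connectivity. `mesoconn` quantifies that information for continuous
projection strengths (not just binary connected/not-connected calls) and
for cell-class-specific tracing categories (wild-type experiments and
cre-lines labeling IT / PT / CT projection classes).

## What the package computes

Given an areas × genes expression matrix `X` and one areas × injections
projection matrix per tracing category:

1. **Preprocessing** — drop areas with > 80 % NaNs in either modality;
   impute expression NaNs by gene medians and projection NaNs by
   zero/non-zero stratified sampling; cube-root then z-score both
   modalities.
2. **Spatial gene modules** — non-negative dictionary learning / sparse
   coding: `X ≈ D a`, minimizing `½‖X − Da‖²_F + λΣ|a|` with `D ≥ 0`
   (spatial modules over areas), `a ≥ 0` sparse (gene loadings), plus a
   constrained variant that fixes `a` to cell-type expression signatures,
   and a parsimony-based module-count sweep.
3. **Prediction** — per tracing category, a multi-output Ridge (or Random
   Forest) model maps expression (or module footprints) to all of the
   category's injections jointly, validated by nested 3-fold
   cross-validation over areas and scored per injection by
   `r² = 1 − Σ(yᵢ−fᵢ)²/Σ(yᵢ−ȳ)²` on out-of-fold predictions. Surrogate
   models (gene-wise permuted expression), null models (training-fold
   means) and a wild-type subset permutation test guard the claims.
4. **Binarization** — each pattern thresholds itself at
   `median + std`; predictions are evaluated by auROC (midrank ties;
   single-class truths score 0 by convention) and f1, plus multi-ROC
   curves over a family of external thresholds.
5. **Module analysis** — Pearson correlation of modules with each
   pattern, out-of-fold OLS prediction from the top-3 modules, and the
   six-level footprint overlap code
   {1.0, 0.8, 0.6, 0.4, 0.2, 0.0} over areas.
6. **Enrichment** — exact hypergeometric tests of the most predictive
   genes (|coefficient| above the 99th percentile) and of module gene
   sets against an annotation table (`p ≤ 0.05`, optional
   Benjamini–Hochberg).

A first-class synthetic-data generator plants modules, a linear
expression-to-projection map, skew, zero-inflation, NaN masks, unequal
category sizes and enriched annotation terms, so the full workflow is
testable end to end without any download. See `docs/methods.md` for the
models, conventions and limitations.

## Worked example

```python
import numpy as np
from mesoconn import run_pipeline, surrogate_median_r2

run = run_pipeline(seed=1)   # default synthetic config: 200 areas,
                             # 500 genes, 10 modules, 60+15+15+15 injections
print(f"median r2 (all)     : {run.median_r2():.3f}")
for cat, res in run.results.items():
    print(f"  {cat:<12} median r2 = {res.median_r2():.3f}")
null = np.median(np.concatenate([r.r2_values() for r in run.null_results.values()]))
print(f"null-model median r2: {null:.3f}")
sur, _ = surrogate_median_r2(run.preprocessed, n_replicates=5, seed=1)
print(f"surrogate median r2 : {sur:.3f}")
aucs = run.all_auroc()
print(f"median auROC        : {np.median(aucs):.3f}")
```

prints

```
median r2 (all)     : 0.764
  wild-type    median r2 = 0.757
  cre_line_1   median r2 = 0.778
  cre_line_2   median r2 = 0.786
  cre_line_3   median r2 = 0.761
null-model median r2: -0.009
surrogate median r2 : -0.037
median auROC        : 0.952
```

Reading: with ~5 % measurement noise and 30 % zero-inflation planted in
the synthetic data, gene expression explains ~76 % of the variance of a
typical held-out projection pattern, while permuted-expression
surrogates and mean-predictor nulls explain none — so the signal is the
planted spatial correspondence, not an artifact of the fitting protocol.
The binarized predictions rank connected areas almost perfectly (median
auROC 0.95): binary connectivity is an easier target than continuous
strength. On a noiseless, unmasked configuration the same pipeline
reaches median r² ≈ 1.0, confirming that preprocessing exactly
linearizes the planted map.

The same stages are available from the shell:

```bash
mesoconn simulate --out data/ --seed 1
mesoconn preprocess --in data/ --out pre/ --seed 1
mesoconn dlsc --in pre/ --out dict/ --k 10 --lambda 1.0
mesoconn fit --in pre/ --out fit/ --seed 1
mesoconn binarize --in pre/ --fit-dir fit/ --out bin/
mesoconn modules --dict dict/D.tsv --in pre/ --out mod/
mesoconn report --fit-dir fit/ --binary-dir bin/ --out rep/
```

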