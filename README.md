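# cscd — covariance-based single-cell decomposition of bulk RNA-seq

Bulk RNA-seq measures the pooled expression of a heterogeneous tissue.
`cscd` estimates the fraction of each cell type contributing to every bulk
sample, using an annotated single-cell RNA-seq dataset as the reference.
It is aimed at researchers who have cell-type- and subject-labelled
scRNA-seq for a tissue and want cell-type composition for (many more)
bulk samples from the same or comparable cohorts.

## The model

From the single-cell data (C cell types, J subjects) the package builds

* a reference profile **Z** (genes × types): the mean CPM expression of
  each gene over all cells of a type, pooled across subjects;
* the observed subject proportions **p**<sub>cj</sub>; and
* the pseudo-bulk **Y = Z P** (genes × subjects).

Sequencing technology differences mean bulk expression **X** is not
directly proportional to **Y**. The core of the method is a multivariate
location–scale transform that maps the bulk columns onto the pseudo-bulk
distribution:

```
X^m = Ȳ + √(J/(J+1)) · S_Y,s^{1/2} · S_X,s^{−1/2} · (X − X̄)
```

where S<sub>Y,s</sub> and S<sub>X,s</sub> are **Ledoit–Wolf linear
shrinkage** estimates of the pseudo-bulk and bulk sample covariances
(computed on marker genes only; with far more genes than subjects the raw
covariances are singular, and shrinkage towards a scaled identity restores
an invertible, well-conditioned estimate), matrix powers are symmetric
eigendecomposition roots, and √(J/(J+1)) deflates the single-cell-derived
variance for the small subject count J. Unlike gene-wise (univariate)
matching, the multivariate transform also aligns gene–gene correlations.

Proportions for bulk sample *i* then solve the simplex-constrained least
squares problem

```
min ‖Z p_i − X^m_i‖²   s.t.  p_i ≥ 0,  Σ_c p_ci = 1 .
```

Marker genes are selected per cluster by detection percentage: gene g is a
marker of type c when the fraction of type-c cells detecting it exceeds
the fraction of all other cells by at least 0.5 (configurable), and genes
marking more than one cluster are removed, so the final marker sets of any
two types are disjoint.

## Worked example

```python
from cscd import (CSCD, SimulationConfig, simulate_single_cell,
                  subject_pseudo_bulk, ProportionMatrix,
                  spearman_r, mse, mae)

cfg = SimulationConfig(n_genes=2000, n_cells=500, n_types=4, n_subjects=5,
                       coexpr_blocks=5, seed=7)
sc, P_sc = simulate_single_cell(cfg)          # annotated single-cell counts
bulk, P_true = subject_pseudo_bulk(sc)        # per-subject pseudo-bulk

results = CSCD(sc, bulk, mode="multivariate").fit()
print(results.summary())

est = ProportionMatrix(results.proportions.P,
                       results.proportions.cell_types, P_true.column_ids)
print(f"Spearman R = {spearman_r(P_true, est):.4f}")
print(f"MSE        = {mse(P_true, est):.6f}")
print(f"MAE        = {mae(P_true, est):.5f}")
```

prints

```
CSCD decomposition results
============================================================
mode:                 multivariate
cell types (C):       4
bulk samples (I):     5
sc subjects (J):      5
common genes:         2000
genes after filters:  1964
marker genes used:    585
mean residual norm:   340.7
------------------------------------------------------------
estimated proportions (cell types x samples):
       bulk_subject1  bulk_subject3  bulk_subject4  bulk_subject5  bulk_subject2
type1         0.2245         0.4138         0.0832         0.3114         0.1786
type4         0.0722         0.0776         0.1822         0.2758         0.0709
type2         0.0429         0.2578         0.6108         0.3620         0.1588
type3         0.6603         0.2508         0.1238         0.0508         0.5917
============================================================

Spearman R = 0.9940
MSE        = 0.000282
MAE        = 0.01429
```

Each proportion column lies on the unit simplex; R/MSE/MAE compare the
estimates with the proportions actually realized in the simulated cells.
The pipeline kept 1964 of 2000 genes after pre-processing (zero-variance,
unexpressed and mitochondrial genes removed) and used 585 cluster markers
for the transform and the fit.

A command-line interface mirrors the library:

```bash
cscd decompose --sc sc.csv --sc-annot annot.tsv --bulk bulk.csv \
     --mode multivariate --out proportions.csv
cscd simulate  --config sim.yaml --out simdata/
cscd benchmark --config sim.yaml --iters 100 \
     --modes multivariate,univariate,none --out table.csv
```

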