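# flda — factorized linear discriminant analysis for expression data

`flda` is a supervised linear dimensionality-reduction toolkit for
single-cell (or bulk) expression data whose cell types are labeled by
**two or more categorical phenotypic features** — for example *Drosophila*
T4/T5 optic-lobe neurons, which form a complete 2 (dendritic location) × 4
(axonal lamination layer) contingency table.  Where PCA ignores the labels
and ordinary LDA mixes them, FLDA returns discriminant axes that are each
aligned with **one** feature (or with the feature interaction), so every
axis of the embedding has a direct phenotypic reading.

## The model

Write the expression vector of cell *k* of type (*i*, *j*) as
*x*<sub>*ijk*</sub> ∈ ℝ<sup>*g*</sup>.  A two-way ANOVA partition of the
type means yields covariance matrices attributable to feature *i*
(*M*<sub>*A*</sub>), feature *j* (*M*<sub>*B*</sub>), their interaction
(*M*<sub>*AB*</sub>), and the pooled within-type residual
(*M*<sub>*e*</sub>).  The axis for feature *i* maximizes the generalized
Rayleigh quotient

&nbsp;&nbsp;&nbsp;&nbsp;*u*\* = argmax<sub>*u*</sub>
(*u*ᵀ *N*<sub>*A*</sub> *u*) / (*u*ᵀ *M*<sub>*e*</sub> *u*),
&nbsp;&nbsp; *N*<sub>*A*</sub> = *M*<sub>*A*</sub> − λ₁ *M*<sub>*B*</sub> − λ₂ *M*<sub>*AB*</sub>,

a symmetric-definite generalized eigenproblem (analogous contrasts give the
feature-*j* and interaction axes).  When genes outnumber residual degrees
of freedom, the diagonal of *M*<sub>*e*</sub> replaces the full matrix, as
is standard for high-dimensional discriminant analysis.  A sparse variant
solves the same objective under ‖*u*‖₀ ≤ *l* with truncated Rayleigh flow
(gradient ascent on the quotient followed by hard truncation to the *l*
largest-magnitude gene weights), yielding compact per-axis gene signatures.

The package also ships the surrounding evaluation harness: PCA / LDA /
two-separate-LDAs / CCA baselines, per-axis metrics (SNR, explained
variance, mutual information, modularity) plus embedding silhouette, a
calibrated factorial synthetic-data generator with a noise sweep, and a
label-perturbation scan that flags annotation errors (swapped, merged or
split labels score worse than the correct annotation).

## Worked example

```python
from flda import FLDA, SyntheticSpec, generate

em, fd = generate(SyntheticSpec(sigma=2.0, seed=1))   # 1000 genes x 1000 cells, 2x2 types
res = FLDA(em, fd, lambda1=1.0, lambda2=1.0).fit()
print(res.summary())
```

```
               component    eigenvalue  top20_weight_share
axis
feature_i      feature_i  45670.804129            0.081156
feature_j      feature_j  46093.230072            0.082459
interaction  interaction  91400.038973            0.080379
```

Each row is one discriminant axis; the eigenvalue is the generalized
Rayleigh quotient at the axis (signal variance in units of the scaled
residual — far above noise here), and the last column shows how spread the
gene weights are (≈ 0.08 means the top 20 genes carry 8 % of the weight,
i.e. the dense axis uses the whole 250-gene signal block).  Sparse
signatures and projections follow from the same results object:

```python
sigs = res.sparse_signatures(l=20, targets=["feature_i"])  # 20-gene signature
coords = res.project().to_frame()                          # cells x axes
```

The same pipeline is scriptable from the shell:

```bash
flda simulate --sigma 6 --seed 1 --out data/
flda fit --expr data/expr.csv --labels data/labels.csv \
     --features feature_i,feature_j --dims i=1,j=1,ij=1 --out fit/
flda compare --expr data/expr.csv --labels data/labels.csv \
     --features feature_i,feature_j --out cmp/
flda benchmark --sigmas 2,4,6,8,10 --reps 10 --out bench/
```

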