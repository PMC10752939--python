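"""Standard single-cell preprocessing: median-depth normalization, log
transform, and highly-variable-gene (HVG) selection.

Normalization rescales each cell's counts so its total equals the median of
the raw per-cell totals; the log transform is ``ln(value + 1)``.  HVG
selection ranks genes by the residual of an ordinary least-squares fit of
log coefficient-of-variation on log mean across genes — genes dispersed
above the mean-CV trend are kept.  All steps are optional: the model itself
accepts any real-valued matrix.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionMatrix

__all__ = ["tpm_normalize", "log_transform", "select_hvg", "hvg_residuals"]


def tpm_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell so its total count equals the median raw total."""
    if em.layer_tag != "counts":
        raise ValueError(f"expected counts layer, got {em.layer_tag!r}")
    totals = em.values.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        names = [em.cell_ids[k] for k in zero[:10]]
        raise ValueError(f"cells with zero total count: {names}")
    target = float(np.median(totals))
    values = em.values * (target / totals)
    return ExpressionMatrix(values, em.gene_ids, em.cell_ids, "tpm")


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log of (value + 1)."""
    if em.layer_tag != "tpm":
        raise ValueError(f"expected tpm layer, got {em.layer_tag!r}")
    if np.any(em.values < 0):
        raise ValueError("negative values cannot be log1p-transformed")
    return ExpressionMatrix(np.log1p(em.values), em.gene_ids, em.cell_ids, "log")


def hvg_residuals(em: ExpressionMatrix) -> tuple[list[str], np.ndarray]:
    """Dispersion residuals of the log(CV)-vs-log(mean) OLS trend.

    Genes with zero mean are excluded.  Returns the retained gene ids and
    their residuals (observed log CV minus the fitted trend value).
    """
    means = em.values.mean(axis=1)
    sds = em.values.std(axis=1, ddof=1)
    keep = np.flatnonzero(means > 0)
    if keep.size < 2:
        raise ValueError("need at least 2 genes with positive mean")
    log_mean = np.log(means[keep])
    # CV of an all-constant gene is 0; keep it on the log scale via a floor
    cv = sds[keep] / means[keep]
    log_cv = np.log(np.maximum(cv, 1e-12))
    slope, intercept = np.polyfit(log_mean, log_cv, 1)
    residuals = log_cv - (slope * log_mean + intercept)
    gene_ids = [em.gene_ids[k] for k in keep]
    return gene_ids, residuals


def select_hvg(em: ExpressionMatrix, n_genes: int) -> ExpressionMatrix:
    """Top ``n_genes`` genes by positive deviation from the mean-CV trend."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    gene_ids, residuals = hvg_residuals(em)
    if n_genes > len(gene_ids):
        raise ValueError(
            f"requested {n_genes} genes but only {len(gene_ids)} have positive mean"
        )
    order = np.argsort(-residuals, kind="stable")[:n_genes]
    selected = [gene_ids[k] for k in order]
    return em.subset_genes(selected)
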