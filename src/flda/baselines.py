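"""Reference linear embeddings: PCA, LDA, the two-separate-LDAs scheme, and
CCA against a phenotype design matrix.

All baselines share the model's scatter conventions (unweighted between
means with divisor classes-1, pooled within with divisor n-classes, same
diagonal fallback for singular within-class covariance) so signal-to-noise
comparisons across methods are apples-to-apples.  All are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datatypes import ExpressionMatrix, FactorDesign
from .model import FLDAConfig, _fix_signs, solve_component

__all__ = [
    "BaselineResult",
    "pca_embed",
    "lda_embed",
    "two_ldas_embed",
    "cca_embed",
]


@dataclass
class BaselineResult:
    method: str
    axes: np.ndarray          # (r, g)
    coordinates: np.ndarray   # (r, n)
    axis_tags: list[str]
    extras: dict | None = None


def pca_embed(em: ExpressionMatrix, r: int) -> BaselineResult:
    """Top-r principal axes of the centered genes x cells matrix."""
    X = em.values
    g, n = X.shape
    if r > min(g, n):
        raise ValueError(f"r={r} exceeds min(genes, cells)={min(g, n)}")
    Xc = X - X.mean(axis=1, keepdims=True)
    # genes >> cells is common: take left singular vectors via the n x n Gram
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    axes = _fix_signs(U[:, :r].T)
    return BaselineResult(
        method="pca",
        axes=axes,
        coordinates=axes @ X,
        axis_tags=[f"PC_{k + 1}" for k in range(r)],
        extras={"singular_values": s[:r]},
    )


def _scatter(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Between-class scatter (over unweighted class means, divisor T-1),
    pooled within-class covariance (divisor n-T) and its diagonal."""
    classes = np.unique(labels)
    T = classes.size
    g, n = X.shape
    means = np.stack([X[:, labels == c].mean(axis=1) for c in classes])
    Cb = means - means.mean(axis=0)
    Sb = Cb.T @ Cb / (T - 1)
    resid = X.copy()
    for c, m in zip(classes, means):
        resid[:, labels == c] -= m[:, None]
    Sw_diag = (resid**2).sum(axis=1) / (n - T)
    return Sb, resid, Sw_diag


def lda_embed(
    em: ExpressionMatrix,
    class_labels: np.ndarray,
    r: int,
    residual_mode: str = "auto",
    eig_tol: float = 1e-8,
) -> BaselineResult:
    """Fisher LDA: top-r generalized eigenvectors of (between, within)."""
    X = em.values
    labels = np.asarray(class_labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    if r > classes.size - 1:
        raise ValueError(f"r={r} exceeds classes-1={classes.size - 1}")
    g, n = X.shape
    Sb, resid, Sw_diag = _scatter(X, labels)
    mode = residual_mode
    if mode == "auto":
        mode = "full" if g < n - classes.size else "diagonal"
    if mode == "full":
        Sw = resid @ resid.T / (n - classes.size)
        evals = scipy.linalg.eigvalsh(Sw)
        if evals[0] <= eig_tol * max(evals[-1], 0):
            mode = "diagonal"
        else:
            axes, vals = solve_component(Sb, Sw, r)
    if mode == "diagonal":
        d = Sw_diag.copy()
        d[d < eig_tol * d.max()] = eig_tol * d.max()
        axes, vals = solve_component(Sb, d, r)
    return BaselineResult(
        method="lda",
        axes=axes,
        coordinates=axes @ X,
        axis_tags=[f"LD_{k + 1}" for k in range(r)],
        extras={"eigenvalues": vals},
    )


def two_ldas_embed(em: ExpressionMatrix, fd: FactorDesign) -> BaselineResult:
    """One LDA per phenotypic feature, axes stacked with feature tags.

    Each LDA uses that feature's levels as classes (levels-1 axes), so the
    other feature's structured variation counts as within-class noise.
    """
    if fd.n_features != 2:
        raise ValueError("two_ldas needs exactly 2 features")
    axes_list, tags, coords_list = [], [], []
    for f in fd.features:
        labels = fd.feature_labels(f)
        n_levels = np.unique(labels).size
        res = lda_embed(em, labels, n_levels - 1)
        axes_list.append(res.axes)
        coords_list.append(res.coordinates)
        for k in range(n_levels - 1):
            tags.append(f"LD_{f}" if n_levels == 2 else f"LD_{f}_{k + 1}")
    return BaselineResult(
        method="two_ldas",
        axes=np.vstack(axes_list),
        coordinates=np.vstack(coords_list),
        axis_tags=tags,
    )


def _phenotype_matrix(fd: FactorDesign) -> np.ndarray:
    """Centered numeric design matrix, one block per feature.

    Two-level features become a single centered +/-1 column; features with
    more levels become centered drop-one one-hot blocks.
    """
    cols = []
    for f in fd.features:
        labels = fd.feature_labels(f)
        n_levels = np.unique(labels).size
        if n_levels == 2:
            cols.append(np.where(labels == 0, 1.0, -1.0))
        else:
            for lev in range(1, n_levels):
                cols.append((labels == lev).astype(float))
    Xb = np.stack(cols)
    return Xb - Xb.mean(axis=1, keepdims=True)


def cca_embed(
    em: ExpressionMatrix, fd: FactorDesign, r: int, ridge: float | None = None
) -> BaselineResult:
    """Canonical directions of expression against the phenotype matrix.

    Maximizes the canonical correlation between projections of the centered
    expression matrix X_a and the phenotype design X_b, with a small ridge
    on both autocovariances for invertibility.
    """
    Xa = em.values - em.values.mean(axis=1, keepdims=True)
    Xb = _phenotype_matrix(fd)
    g, n = Xa.shape
    d = Xb.shape[0]
    rank_b = np.linalg.matrix_rank(Xb)
    if r > rank_b:
        raise ValueError(f"r={r} exceeds rank of the phenotype matrix ({rank_b})")
    Caa = Xa @ Xa.T / n
    Cbb = Xb @ Xb.T / n
    Cab = Xa @ Xb.T / n
    eps = ridge if ridge is not None else 1e-6 * np.trace(Caa) / g
    Caa[np.diag_indices_from(Caa)] += eps
    Cbb[np.diag_indices_from(Cbb)] += 1e-6 * np.trace(Cbb) / d
    # whiten the phenotype side and reduce to a d x d eigenproblem
    Lb = scipy.linalg.cholesky(Cbb, lower=True)
    W = scipy.linalg.solve(Caa, Cab, assume_a="pos")          # Caa^-1 Cab, (g, d)
    K = scipy.linalg.solve_triangular(Lb, (Cab.T @ W).T, lower=True)
    K = scipy.linalg.solve_triangular(Lb, K.T, lower=True).T  # Lb^-1 Cba W Lb^-T
    K = (K + K.T) / 2
    vals, vecs = scipy.linalg.eigh(K)
    vals, vecs = vals[::-1][:r], vecs[:, ::-1][:, :r]
    U = W @ scipy.linalg.solve_triangular(Lb, np.eye(d), lower=True).T @ vecs  # (g, r)
    axes = U.T
    # normalize so the projected expression coordinates have unit variance
    proj = axes @ Xa
    scale = proj.std(axis=1, ddof=1)
    scale[scale == 0] = 1.0
    axes = axes / scale[:, None]
    axes = _fix_signs(axes)
    corr = np.sqrt(np.clip(vals, 0, 1))
    return BaselineResult(
        method="cca",
        axes=axes,
        coordinates=axes @ em.values,
        axis_tags=[f"CCA_{k + 1}" for k in range(r)],
        extras={"canonical_correlations": corr},
    )
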