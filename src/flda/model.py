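"""Factorized linear discriminant analysis (FLDA).

FLDA embeds expression data whose cell-type labels form a Cartesian product
of categorical phenotypic features (a complete, or partially observed,
contingency table).  A two-way ANOVA partition of the between-type
covariance yields matrices attributable to feature i (``M_A``), feature j
(``M_B``) and their interaction (``M_AB``), plus the pooled within-type
residual ``M_e``.  For each target component the method maximizes the
generalized Rayleigh quotient

    u* = argmax  u' N u / u' M_e u,    e.g.  N = M_A - l1*M_B - l2*M_AB

whose solutions are the top generalized eigenvectors of the symmetric
pencil ``(N, M_e)``.  When ``M_e`` is singular (more genes than residual
degrees of freedom) its diagonal estimate is used instead, following
standard practice for high-dimensional discriminant analysis.

The public surface follows the Model/Results convention: build an
:class:`FLDA` model from data, call :meth:`FLDA.fit`, and work with the
returned :class:`FLDAResults`.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .datatypes import ExpressionMatrix, FactorDesign

__all__ = [
    "FLDA",
    "FLDAResults",
    "FLDAConfig",
    "CovarianceDecomposition",
    "DiscriminantBasis",
    "ProjectedData",
    "compute_decomposition",
    "build_contrast",
    "solve_component",
    "fit_flda",
    "fit_flda_partial",
    "project",
]

COMPONENT_TAGS = ("feature_i", "feature_j", "interaction")


@dataclass
class FLDAConfig:
    """Hyper-parameters of the FLDA solve.

    lambda1, lambda2
        Weights of the two penalty terms in the contrast (default 1.0 each,
        the setting used throughout the reference analyses).
    dims_per_component
        Map component tag -> number of axes; defaults to the full degrees of
        freedom (a-1, b-1, (a-1)(b-1)).
    residual_mode
        "full" solves against the full residual covariance, "diagonal"
        against its diagonal, "auto" picks full only when the residual is
        comfortably non-singular (more residual degrees of freedom than
        genes and smallest eigenvalue above ``eig_tol`` x largest).
    eig_tol
        Relative floor for diagonal residual entries and the auto-mode
        conditioning test.
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    dims_per_component: dict[str, int] | None = None
    residual_mode: str = "auto"
    eig_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be non-negative")
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("lambda weights must be finite")
        if self.residual_mode not in ("full", "diagonal", "auto"):
            raise ValueError("residual_mode must be full|diagonal|auto")
        if self.eig_tol <= 0:
            raise ValueError("eig_tol must be positive")


@dataclass
class CovarianceDecomposition:
    """Two-way ANOVA partition of the covariance of a complete table.

    ``cell_means`` rows follow ``types`` (Cartesian order).  ``M_e_diag``
    is always available; the full residual matrix is formed lazily from the
    stored per-cell residuals, each cell weighted by 1/n_ij within its type
    before the global 1/(N - a*b) divisor.
    """

    grand_mean: np.ndarray            # (g,)
    row_means: np.ndarray             # (a, g)
    col_means: np.ndarray             # (b, g)
    cell_means: np.ndarray            # (a*b, g) or (T, g) for partial tables
    types: list[tuple]                # level tuples matching cell_means rows
    M_A: np.ndarray                   # (g, g)
    M_B: np.ndarray
    M_AB: np.ndarray | None           # None for partial tables
    a: int
    b: int
    N: int
    complete: bool
    _residuals: np.ndarray = field(repr=False, default=None)   # (g, N)
    _cell_weights: np.ndarray = field(repr=False, default=None)  # (N,) 1/n_ij
    _M_e: np.ndarray | None = field(repr=False, default=None)
    _resid_divisor: int = 0

    @property
    def g(self) -> int:
        return self.grand_mean.shape[0]

    @property
    def M_e_diag(self) -> np.ndarray:
        return (self._residuals**2 * self._cell_weights).sum(axis=1) / self._resid_divisor

    @property
    def M_e(self) -> np.ndarray:
        if self._M_e is None:
            R = self._residuals * self._cell_weights
            self._M_e = (R @ self._residuals.T) / self._resid_divisor
        return self._M_e

    def component_dof(self) -> dict[str, int]:
        dof = {"feature_i": self.a - 1, "feature_j": self.b - 1}
        if self.complete:
            dof["interaction"] = (self.a - 1) * (self.b - 1)
        return dof


@dataclass
class DiscriminantBasis:
    """Fitted discriminant axes grouped by component.

    Axes are normalized to ``u' M_e_eff u = 1`` with the largest-magnitude
    weight made positive; eigenvalues are the generalized Rayleigh quotients
    and are non-increasing within a component.
    """

    gene_ids: list[str]
    components: list[dict]            # {tag, axes: (d, g), eigenvalues: (d,)}
    residual_mode_used: str
    normalization: str = "u'Mu=1"
    sign_convention: str = "max-abs-positive"

    @property
    def axis_tags(self) -> list[str]:
        tags = []
        for comp in self.components:
            d = comp["axes"].shape[0]
            for k in range(d):
                tags.append(comp["tag"] if d == 1 else f"{comp['tag']}_{k + 1}")
        return tags

    @property
    def axes_matrix(self) -> np.ndarray:
        """All axes stacked, shape (r_total, g)."""
        return np.vstack([comp["axes"] for comp in self.components])

    @property
    def eigenvalues(self) -> dict[str, list[float]]:
        return {c["tag"]: [float(v) for v in c["eigenvalues"]] for c in self.components}

    def component(self, tag: str) -> dict:
        for comp in self.components:
            if comp["tag"] == tag:
                return comp
        raise KeyError(f"no component {tag!r}; have {[c['tag'] for c in self.components]}")


@dataclass
class ProjectedData:
    """Cells projected onto discriminant axes: coordinates are (r, n)."""

    coordinates: np.ndarray
    axis_tags: list[str]
    cell_ids: list[str]
    design: FactorDesign | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates.T, index=self.cell_ids, columns=self.axis_tags
        )


# ---------------------------------------------------------------------------
# covariance decomposition


def _check_two_features(fd: FactorDesign) -> None:
    if fd.n_features != 2:
        raise ValueError(
            f"the two-way decomposition needs exactly 2 features, got {fd.n_features}"
        )


def compute_decomposition(
    em: ExpressionMatrix, fd: FactorDesign
) -> CovarianceDecomposition:
    """Two-way ANOVA covariance partition for a complete contingency table.

    Type means are averaged unweighted into row/column/grand means, so
    unbalanced designs are handled exactly as the balanced formulas state.
    Requires ``N > a*b`` for a positive residual divisor.
    """
    _check_two_features(fd)
    if not fd.complete:
        raise ValueError(
            "partial contingency table: use fit_flda_partial / FLDA(..., "
            "allow_partial=True)"
        )
    return _decompose(em, fd, partial=False)


def _decompose(
    em: ExpressionMatrix, fd: FactorDesign, partial: bool
) -> CovarianceDecomposition:
    X = em.values  # (g, n)
    g, n = X.shape
    fi, fj = fd.features
    levels_i, levels_j = fd.level_sets[fi], fd.level_sets[fj]
    a, b = len(levels_i), len(levels_j)
    types = fd.observed_types
    T = len(types)
    if n <= T:
        raise ValueError(
            f"residual dof <= 0: need more cells ({n}) than observed types ({T})"
        )

    type_index = {t: k for k, t in enumerate(types)}
    type_of_cell = np.array([type_index[lab] for lab in fd.labels])
    n_t = np.bincount(type_of_cell, minlength=T).astype(float)

    # per-type means (T, g)
    cell_means = np.zeros((T, g))
    np.add.at(cell_means, type_of_cell, X.T)
    cell_means /= n_t[:, None]

    # marginal means: unweighted averages of the observed type means
    li = np.array([levels_i.index(t[0]) for t in types])
    lj = np.array([levels_j.index(t[1]) for t in types])
    row_means = np.zeros((a, g))
    col_means = np.zeros((b, g))
    for i in range(a):
        row_means[i] = cell_means[li == i].mean(axis=0)
    for j in range(b):
        col_means[j] = cell_means[lj == j].mean(axis=0)
    grand_mean = cell_means.mean(axis=0)

    if a < 2 or b < 2:
        # a single-level feature contributes no effect matrix
        pass
    CA = row_means - grand_mean
    CB = col_means - grand_mean
    M_A = CA.T @ CA / max(a - 1, 1)
    M_B = CB.T @ CB / max(b - 1, 1)
    if a < 2:
        M_A = np.zeros((g, g))
    if b < 2:
        M_B = np.zeros((g, g))

    M_AB = None
    if not partial and a >= 2 and b >= 2:
        CI = cell_means - row_means[li] - col_means[lj] + grand_mean
        M_AB = CI.T @ CI / ((a - 1) * (b - 1))

    residuals = X - cell_means[type_of_cell].T       # (g, n)
    cell_weights = 1.0 / n_t[type_of_cell]
    resid_divisor = n - T

    return CovarianceDecomposition(
        grand_mean=grand_mean,
        row_means=row_means,
        col_means=col_means,
        cell_means=cell_means,
        types=types,
        M_A=M_A,
        M_B=M_B,
        M_AB=M_AB,
        a=a,
        b=b,
        N=n,
        complete=fd.complete,
        _residuals=residuals,
        _cell_weights=cell_weights,
        _resid_divisor=resid_divisor,
    )


# ---------------------------------------------------------------------------
# contrasts and the generalized eigensolve


def build_contrast(
    cd: CovarianceDecomposition, target: str, cfg: FLDAConfig
) -> np.ndarray:
    """Signed covariance contrast for one component.

    feature_i:    M_A - l1*M_B - l2*M_AB
    feature_j:    M_B - l1*M_A - l2*M_AB
    interaction:  M_AB - l1*M_A - l2*M_B   (both main effects penalized)

    On a partial table the interaction matrix is unavailable and the main
    effect contrasts drop the interaction penalty.
    """
    l1, l2 = cfg.lambda1, cfg.lambda2
    if target == "feature_i":
        out = cd.M_A - l1 * cd.M_B
        if cd.M_AB is not None:
            out = out - l2 * cd.M_AB
    elif target == "feature_j":
        out = cd.M_B - l1 * cd.M_A
        if cd.M_AB is not None:
            out = out - l2 * cd.M_AB
    elif target == "interaction":
        if cd.M_AB is None:
            raise ValueError("interaction component is undefined on a partial table")
        out = cd.M_AB - l1 * cd.M_A - l2 * cd.M_B
    else:
        raise ValueError(f"unknown component {target!r}")
    return out


def _resolve_residual(cd: CovarianceDecomposition, cfg: FLDAConfig) -> tuple[np.ndarray, str]:
    """Effective residual matrix per the configured mode.

    Returns ``(M_e_eff, mode_used)`` where ``M_e_eff`` is either the full
    matrix or a 1-D diagonal with entries floored at eig_tol x max entry.
    """
    mode = cfg.residual_mode
    if mode == "auto":
        if cd.g < cd._resid_divisor:
            evals = scipy.linalg.eigvalsh(cd.M_e)
            mode = "full" if evals[0] > cfg.eig_tol * max(evals[-1], 0) else "diagonal"
        else:
            mode = "diagonal"
    if mode == "full":
        return cd.M_e, "full"
    diag = cd.M_e_diag.copy()
    floor = cfg.eig_tol * diag.max()
    if floor <= 0:
        raise ValueError("residual covariance is identically zero")
    diag[diag < floor] = floor
    return diag, "diagonal"


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-|weight| entry is positive."""
    axes = axes.copy()
    for k in range(axes.shape[0]):
        idx = int(np.argmax(np.abs(axes[k])))
        if axes[k, idx] < 0:
            axes[k] = -axes[k]
    return axes


def solve_component(
    contrast: np.ndarray,
    M_e_eff: np.ndarray,
    d: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-``d`` generalized eigenpairs of the pencil ``(contrast, M_e_eff)``.

    ``M_e_eff`` may be a full SPD matrix or a 1-D array of positive diagonal
    entries.  Axes (rows of the returned matrix) are normalized to
    ``u' M_e_eff u = 1`` and sign-fixed; eigenvalues are returned
    non-increasing and equal the Rayleigh quotients at the axes.
    """
    contrast = np.asarray(contrast, dtype=float)
    g = contrast.shape[0]
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > g:
        raise ValueError(f"d={d} exceeds dimensionality g={g}")
    if np.max(np.abs(contrast)) == 0:
        raise ValueError("no signal for component: contrast is identically zero")
    if np.max(np.abs(contrast - contrast.T)) > 1e-8 * max(np.max(np.abs(contrast)), 1):
        raise ValueError("contrast must be symmetric")
    contrast = (contrast + contrast.T) / 2

    M_e_eff = np.asarray(M_e_eff, dtype=float)
    if M_e_eff.ndim == 1:
        scale = 1.0 / np.sqrt(M_e_eff)
        A = contrast * scale[:, None] * scale[None, :]
        A = (A + A.T) / 2
        vals, vecs = scipy.linalg.eigh(A, subset_by_index=[g - d, g - 1])
        axes = (vecs * scale[:, None]).T[::-1]          # (d, g), descending
        vals = vals[::-1]
    else:
        vals, vecs = scipy.linalg.eigh(contrast, M_e_eff)
        axes = vecs.T[::-1][:d]
        vals = vals[::-1][:d]

    # normalize u' M u = 1 (eigh already does for the pencil path; redo for safety)
    if M_e_eff.ndim == 1:
        norms = np.sqrt(np.einsum("kg,g,kg->k", axes, M_e_eff, axes))
    else:
        norms = np.sqrt(np.einsum("kg,gh,kh->k", axes, M_e_eff, axes))
    axes = axes / norms[:, None]
    axes = _fix_signs(axes)
    return axes, np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# the Model / Results surface


class FLDA:
    """Factorized linear discriminant analysis model.

    Parameters
    ----------
    em : ExpressionMatrix
        Genes x cells values (any real-valued layer).
    fd : FactorDesign
        Two categorical features per cell.  A complete contingency table
        enables the interaction component; a partial table restricts the
        fit to the two main-effect components.
    lambda1, lambda2, dims, residual_mode, eig_tol
        See :class:`FLDAConfig`.  ``dims`` maps component tags
        (``feature_i``/``feature_j``/``interaction``) to axis counts and
        defaults to the full per-component degrees of freedom.

    Examples
    --------
    >>> model = FLDA(em, fd, lambda1=1.0, lambda2=1.0)
    >>> res = model.fit()
    >>> res.summary()           # doctest: +SKIP
    >>> coords = res.project(em)
    """

    def __init__(
        self,
        em: ExpressionMatrix,
        fd: FactorDesign,
        lambda1: float = 1.0,
        lambda2: float = 1.0,
        dims: Mapping[str, int] | None = None,
        residual_mode: str = "auto",
        eig_tol: float = 1e-8,
    ) -> None:
        if em.cell_ids != fd.cell_ids:
            # align by id; order of the expression matrix wins
            fd = _align_design(em, fd)
        self.em = em
        self.fd = fd
        self.config = FLDAConfig(
            lambda1=lambda1,
            lambda2=lambda2,
            dims_per_component=dict(dims) if dims else None,
            residual_mode=residual_mode,
            eig_tol=eig_tol,
        )

    @classmethod
    def from_dataframe(
        cls,
        expr: pd.DataFrame,
        labels: pd.DataFrame,
        features: Sequence[str],
        cell_id_column: str = "cell_id",
        **kwargs,
    ) -> "FLDA":
        """Build from a genes x cells DataFrame and a label table."""
        em = ExpressionMatrix(
            expr.to_numpy(dtype=float),
            [str(i) for i in expr.index],
            [str(c) for c in expr.columns],
            layer_tag=kwargs.pop("layer_tag", "log"),
        )
        fd = FactorDesign(
            cell_ids=[str(c) for c in labels[cell_id_column]],
            features=list(features),
            labels=[tuple(r) for r in labels[list(features)].itertuples(index=False)],
        )
        return cls(em, fd, **kwargs)

    def fit(self) -> "FLDAResults":
        """Solve the requested components and return the results object."""
        cfg = self.config
        _check_two_features(self.fd)
        cd = _decompose(self.em, self.fd, partial=not self.fd.complete)
        dof = cd.component_dof()
        if cfg.dims_per_component is None:
            dims = {tag: dof[tag] for tag in dof if dof[tag] >= 1}
        else:
            dims = dict(cfg.dims_per_component)
            for tag, d in dims.items():
                if tag not in dof:
                    raise ValueError(
                        f"component {tag!r} is unavailable on this design"
                    )
                if d > dof[tag]:
                    raise ValueError(
                        f"d exceeds available dof: {tag} allows at most {dof[tag]}"
                    )
        M_e_eff, mode_used = _resolve_residual(cd, cfg)
        components = []
        for tag in COMPONENT_TAGS:
            if tag not in dims or dims[tag] < 1:
                continue
            contrast = build_contrast(cd, tag, cfg)
            axes, vals = solve_component(contrast, M_e_eff, dims[tag])
            components.append({"tag": tag, "axes": axes, "eigenvalues": vals})
        basis = DiscriminantBasis(
            gene_ids=list(self.em.gene_ids),
            components=components,
            residual_mode_used=mode_used,
        )
        return FLDAResults(self, cd, basis, M_e_eff)


def _align_design(em: ExpressionMatrix, fd: FactorDesign) -> FactorDesign:
    lab = {c: l for c, l in zip(fd.cell_ids, fd.labels)}
    missing = [c for c in em.cell_ids if c not in lab]
    if missing:
        raise ValueError(f"cells without labels: {missing[:10]}")
    return FactorDesign(
        cell_ids=list(em.cell_ids),
        features=list(fd.features),
        labels=[lab[c] for c in em.cell_ids],
        level_sets={f: list(v) for f, v in fd.level_sets.items()},
    )


class FLDAResults:
    """Fitted FLDA: discriminant axes, eigenvalues and diagnostics.

    Attributes
    ----------
    basis : DiscriminantBasis
    decomposition : CovarianceDecomposition
    residual : effective residual used in the solve (full matrix or diagonal)
    """

    def __init__(
        self,
        model: FLDA,
        decomposition: CovarianceDecomposition,
        basis: DiscriminantBasis,
        residual: np.ndarray,
    ) -> None:
        self.model = model
        self.decomposition = decomposition
        self.basis = basis
        self.residual = residual

    @property
    def axis_tags(self) -> list[str]:
        return self.basis.axis_tags

    @property
    def n_axes(self) -> int:
        return self.basis.axes_matrix.shape[0]

    def project(self, em: ExpressionMatrix | None = None) -> ProjectedData:
        """Project cells (training data by default) onto the fitted axes."""
        em = em if em is not None else self.model.em
        return project(em, self.basis, design=self.model.fd if em is self.model.em else None)

    def summary(self) -> pd.DataFrame:
        """Per-axis table: component, eigenvalue (Rayleigh quotient), and
        the share of absolute weight carried by the top 20 genes."""
        rows = []
        for comp in self.basis.components:
            for k, (axis, val) in enumerate(zip(comp["axes"], comp["eigenvalues"])):
                w = np.abs(axis)
                top20 = np.sort(w)[::-1][:20].sum() / w.sum()
                rows.append(
                    {
                        "axis": comp["tag"] if len(comp["axes"]) == 1 else f"{comp['tag']}_{k + 1}",
                        "component": comp["tag"],
                        "eigenvalue": float(val),
                        "top20_weight_share": float(top20),
                    }
                )
        return pd.DataFrame(rows).set_index("axis")

    def sparse_signatures(
        self,
        l: int = 20,
        targets: Sequence[str] | None = None,
        eta: float | None = None,
        max_iter: int = 1000,
        tol: float = 1e-8,
    ) -> dict:
        """Sparse per-axis gene signatures via truncated Rayleigh flow."""
        from .rifle import sparse_signatures as _ss

        return _ss(self, l=l, targets=targets, eta=eta, max_iter=max_iter, tol=tol)

    def save(self, out_dir: str) -> None:
        """Write axes.csv, eigenvalues.json and projections.csv."""
        os.makedirs(out_dir, exist_ok=True)
        axes = pd.DataFrame(
            self.basis.axes_matrix.T,
            index=self.basis.gene_ids,
            columns=self.axis_tags,
        )
        axes.index.name = "gene_id"
        axes.to_csv(os.path.join(out_dir, "axes.csv"))
        with open(os.path.join(out_dir, "eigenvalues.json"), "w") as fh:
            json.dump(self.basis.eigenvalues, fh, indent=2)
        proj = self.project().to_frame()
        proj.index.name = "cell_id"
        proj.to_csv(os.path.join(out_dir, "projections.csv"))


def project(
    em: ExpressionMatrix, basis: DiscriminantBasis, design: FactorDesign | None = None
) -> ProjectedData:
    """Project an expression matrix onto fitted axes, aligning genes by id."""
    if em.gene_ids != basis.gene_ids:
        missing = [g for g in basis.gene_ids if g not in set(em.gene_ids)]
        if missing:
            raise ValueError(f"expression matrix lacks genes: {missing[:10]}")
        em = em.subset_genes(basis.gene_ids)
    coords = basis.axes_matrix @ em.values
    return ProjectedData(
        coordinates=coords,
        axis_tags=basis.axis_tags,
        cell_ids=list(em.cell_ids),
        design=design,
    )


# ---------------------------------------------------------------------------
# functional wrappers


def fit_flda(
    em: ExpressionMatrix, fd: FactorDesign, cfg: FLDAConfig | None = None
) -> DiscriminantBasis:
    """Fit on a complete table; returns the discriminant basis."""
    if not fd.complete:
        raise ValueError("table is partial; use fit_flda_partial")
    cfg = cfg or FLDAConfig()
    model = FLDA(
        em,
        fd,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
        dims=cfg.dims_per_component,
        residual_mode=cfg.residual_mode,
        eig_tol=cfg.eig_tol,
    )
    return model.fit().basis


def fit_flda_partial(
    em: ExpressionMatrix, fd: FactorDesign, cfg: FLDAConfig | None = None
) -> DiscriminantBasis:
    """Fit the main-effect components on a partial contingency table.

    Marginal means average the observed type means only; the interaction
    matrix is not estimated and the interaction component is unavailable.
    """
    cfg = cfg or FLDAConfig()
    if cfg.dims_per_component and "interaction" in cfg.dims_per_component:
        raise ValueError("interaction component is undefined on a partial table")
    dims = cfg.dims_per_component
    model = FLDA(
        em,
        fd,
        lambda1=cfg.lambda1,
        lambda2=cfg.lambda2,
        dims=dims,
        residual_mode=cfg.residual_mode,
        eig_tol=cfg.eig_tol,
    )
    if fd.complete:
        # route a complete table through the partial estimator for checks
        cd = _decompose(em, fd, partial=True)
        M_e_eff, mode = _resolve_residual(cd, cfg)
        dof = cd.component_dof()
        use = dims or {t: dof[t] for t in ("feature_i", "feature_j") if dof[t] >= 1}
        comps = []
        for tag in ("feature_i", "feature_j"):
            if tag not in use or use[tag] < 1:
                continue
            axes, vals = solve_component(build_contrast(cd, tag, cfg), M_e_eff, use[tag])
            comps.append({"tag": tag, "axes": axes, "eigenvalues": vals})
        return DiscriminantBasis(list(em.gene_ids), comps, mode)
    return model.fit().basis
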