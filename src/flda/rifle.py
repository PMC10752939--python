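"""Sparse generalized eigenvectors via truncated Rayleigh flow (Rifle).

Solves  max_u  u'Au / u'Bu  subject to  ||u||_0 <= l  for a symmetric
contrast ``A`` and SPD residual ``B`` by iterating a gradient ascent step
on the generalized Rayleigh quotient followed by hard truncation to the
``l`` largest-magnitude coordinates:

    rho_t = u'Au / u'Bu
    u     <- u + (eta / rho_t) (A - rho_t B) u
    u     <- truncate(u / ||u||, l);  u <- u / ||u||

The step size must satisfy ``eta * lambda_max(B) < 1``.  Initialization at
the dense FLDA axis is recommended; the iteration is deterministic given
the initial vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["RifleConfig", "SparseSolution", "rifle", "sparse_signatures"]


@dataclass
class RifleConfig:
    """Truncated-Rayleigh-flow settings.

    l : support size (number of non-zero gene weights to retain)
    eta : step size; None picks 0.9 / lambda_max(B)
    max_iter, tol : stop when the quotient changes by less than ``tol``
    seed : used only if random initialization is requested elsewhere
    """

    l: int
    eta: float | None = None
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("support size l must be >= 1")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")


@dataclass
class SparseSolution:
    weights: np.ndarray
    support: list[int]
    quotient_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    @property
    def quotient(self) -> float:
        return self.quotient_trace[-1]


def _lambda_max(B: np.ndarray) -> float:
    if B.ndim == 1:
        return float(B.max())
    # a few power iterations suffice for the step-size bound
    rng = np.random.default_rng(0)
    v = rng.standard_normal(B.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(50):
        w = B @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
    return float(v @ B @ v)


def _truncate(u: np.ndarray, l: int) -> np.ndarray:
    """Keep the l largest-|entry| coordinates; ties keep the lower index."""
    if l >= u.size:
        return u
    # stable sort on (-|u|, index) so equal magnitudes keep the lower index
    order = np.argsort(-np.abs(u), kind="stable")
    out = np.zeros_like(u)
    keep = order[:l]
    out[keep] = u[keep]
    return out


def rifle(
    contrast: np.ndarray,
    M_e_eff: np.ndarray,
    init: np.ndarray,
    cfg: RifleConfig,
) -> SparseSolution:
    """Run truncated Rayleigh flow from ``init``.

    ``contrast`` is a symmetric matrix or a low-rank factorization tuple
    ``(W, s)`` meaning ``W @ diag(s) @ W.T``.  ``M_e_eff`` may be a full SPD
    matrix or a 1-D positive diagonal.  The returned vector carries <= l
    non-zeros, is unit-Euclidean-norm, and is sign-fixed so its
    largest-magnitude entry is positive.
    """
    if isinstance(contrast, tuple):
        # low-rank factorization A = W diag(s) W': O(rank * g) per matvec,
        # which with a diagonal residual makes each iteration linear in g
        W, s = (np.asarray(x, dtype=float) for x in contrast)

        def Adot(v: np.ndarray) -> np.ndarray:
            return W @ (s * (W.T @ v))

    else:
        A = np.asarray(contrast, dtype=float)

        def Adot(v: np.ndarray) -> np.ndarray:
            return A @ v

    B = np.asarray(M_e_eff, dtype=float)
    u = np.asarray(init, dtype=float).copy()
    if np.linalg.norm(u) == 0:
        raise ValueError("initial vector must be non-zero")
    lam_max = _lambda_max(B)
    eta = cfg.eta if cfg.eta is not None else 0.9 / lam_max
    if eta * lam_max >= 1:
        raise ValueError(
            f"step size too large: eta * lambda_max(B) = {eta * lam_max:.3g} >= 1"
        )

    def Bdot(v: np.ndarray) -> np.ndarray:
        return B * v if B.ndim == 1 else B @ v

    u = _truncate(u / np.linalg.norm(u), cfg.l)
    u /= np.linalg.norm(u)
    rho = float(u @ Adot(u)) / float(u @ Bdot(u))
    trace = [rho]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Bu = Bdot(u)
        denom = float(u @ Bu)
        if denom <= 0:
            raise FloatingPointError("u'Bu <= 0: residual matrix is not positive")
        grad = Adot(u) - rho * Bu
        # |rho| keeps the scaled step an ascent direction even when the
        # current quotient is negative (indefinite contrasts are allowed)
        u = u + (eta / abs(rho)) * grad if rho != 0 else u + eta * grad
        u /= np.linalg.norm(u)
        u = _truncate(u, cfg.l)
        u /= np.linalg.norm(u)
        rho_new = float(u @ Adot(u)) / float(u @ Bdot(u))
        trace.append(rho_new)
        if abs(rho_new - rho) < cfg.tol:
            rho = rho_new
            converged = True
            break
        rho = rho_new

    idx = int(np.argmax(np.abs(u)))
    if u[idx] < 0:
        u = -u
    support = sorted(int(k) for k in np.flatnonzero(u))
    return SparseSolution(
        weights=u,
        support=support,
        quotient_trace=[float(r) for r in trace],
        iterations=it,
        converged=converged,
    )


def sparse_signatures(
    results,
    l: int = 20,
    targets: Sequence[str] | None = None,
    eta: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> dict[str, SparseSolution]:
    """Per-axis sparse gene signatures for a fitted :class:`~flda.FLDAResults`.

    For each target axis tag the matching contrast is rebuilt and Rifle is
    run initialized at the dense axis.  Returns a map tag -> solution.
    """
    from .model import build_contrast

    basis = results.basis
    cd = results.decomposition
    cfg_model = results.model.config
    B = results.residual
    tags = list(targets) if targets is not None else basis.axis_tags
    tag_to_axis = dict(zip(basis.axis_tags, basis.axes_matrix))
    out: dict[str, SparseSolution] = {}
    for tag in tags:
        if tag not in tag_to_axis:
            raise KeyError(f"axis {tag!r} not in fitted basis {basis.axis_tags}")
        comp_tag = tag.rsplit("_", 1)[0] if tag not in ("feature_i", "feature_j", "interaction") else tag
        contrast = build_contrast(cd, comp_tag, cfg_model)
        sol = rifle(
            contrast,
            B,
            tag_to_axis[tag],
            RifleConfig(l=l, eta=eta, max_iter=max_iter, tol=tol),
        )
        out[tag] = sol
    return out
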