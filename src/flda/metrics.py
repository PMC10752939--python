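"""Embedding evaluation metrics.

Per-axis: SNR (between-type over within-type variance of the projected
coordinates — the 1-D analogue of the quotient the model maximizes),
explained variance (one-way ANOVA R^2 against one feature), mutual
information (plug-in estimate in bits between the equal-frequency-binned
axis and a feature), and modularity (1 minus the normalized squared MI the
axis carries about non-dominant features).  Whole-embedding: the mean
silhouette score over cells against cell-type labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .datatypes import FactorDesign

__all__ = [
    "snr_axis",
    "explained_variance",
    "mutual_information",
    "modularity_axis",
    "silhouette_embedding",
    "MetricsReport",
    "evaluate_embedding",
    "overall_report",
]


def snr_axis(coords: np.ndarray, type_labels: np.ndarray) -> float:
    """Between-type variance (unweighted over type means, divisor T-1) over
    pooled within-type variance (divisor n-T) of one axis."""
    coords = np.asarray(coords, dtype=float).ravel()
    labels = np.asarray(type_labels)
    types = np.unique(labels)
    if types.size < 2:
        raise ValueError("need at least 2 cell types")
    n = coords.size
    means = np.array([coords[labels == t].mean() for t in types])
    within_ss = sum(((coords[labels == t] - m) ** 2).sum() for t, m in zip(types, means))
    if n - types.size <= 0:
        raise ValueError("need more cells than types for the within variance")
    between = ((means - means.mean()) ** 2).sum() / (types.size - 1)
    within = within_ss / (n - types.size)
    if within == 0:
        warnings.warn("zero within-type variance; SNR is infinite")
        return float("inf")
    return float(between / within)


def explained_variance(coords: np.ndarray, feature_labels: np.ndarray) -> float:
    """One-way ANOVA R^2 of the axis against one feature's levels."""
    coords = np.asarray(coords, dtype=float).ravel()
    labels = np.asarray(feature_labels)
    total_ss = ((coords - coords.mean()) ** 2).sum()
    if total_ss == 0:
        return 0.0
    between_ss = sum(
        (labels == lev).sum() * (coords[labels == lev].mean() - coords.mean()) ** 2
        for lev in np.unique(labels)
    )
    return float(between_ss / total_ss)


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin assignment; tied quantile edges merge bins."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    interior = np.unique(edges[1:-1])
    # drop interior edges equal to the extremes so no bin is empty
    interior = interior[(interior > x.min()) & (interior < x.max())]
    return np.searchsorted(interior, x, side="left")


def mutual_information(
    coords: np.ndarray, feature_labels: np.ndarray, n_bins: int = 20
) -> float:
    """Plug-in mutual information in bits between the discretized axis
    (equal-frequency bins) and a categorical feature."""
    coords = np.asarray(coords, dtype=float).ravel()
    labels = np.asarray(feature_labels)
    n = coords.size
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples")
    bins = _equal_frequency_bins(coords, n_bins)
    joint = pd.crosstab(bins, labels).to_numpy(dtype=float)
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def modularity_axis(mi_values: Mapping[str, float]) -> float:
    """1 - mean over non-dominant features of (mi_f / max mi)^2.

    1 when the axis informs exactly one feature, 0 when it informs two
    features equally (or carries no information at all).
    """
    vals = np.array(list(mi_values.values()), dtype=float)
    if vals.size < 2:
        raise ValueError("modularity needs at least 2 features")
    theta = vals.max()
    if theta <= 0:
        return 0.0
    k = int(np.argmax(vals))
    others = np.delete(vals, k)
    delta = float(((others / theta) ** 2).sum() / (vals.size - 1))
    return 1.0 - delta


def silhouette_embedding(coords: np.ndarray, type_labels: np.ndarray) -> float:
    """Mean silhouette of cells in the embedding (Euclidean metric).

    ``coords`` is (r, n) with axes as rows; singleton types score 0.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    labels = np.asarray(type_labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 cell types")
    return float(silhouette_score(coords.T, labels, metric="euclidean"))


@dataclass
class MetricsReport:
    """Per-axis and embedding-level metrics for one method."""

    per_axis: list[dict]
    overall_snr: float
    overall_modularity: float
    silhouette: float
    overall_snr_normalized: float | None = None
    method: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ax in self.per_axis:
            row = {"axis": ax["tag"], "snr": ax["snr"], "modularity": ax["modularity"]}
            row.update({f"ev_{f}": v for f, v in ax["ev"].items()})
            row.update({f"mi_{f}": v for f, v in ax["mi"].items()})
            rows.append(row)
        return pd.DataFrame(rows).set_index("axis")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "overall_snr": self.overall_snr,
            "overall_snr_normalized": self.overall_snr_normalized,
            "overall_modularity": self.overall_modularity,
            "silhouette": self.silhouette,
            "per_axis": self.per_axis,
        }


def evaluate_embedding(
    coordinates: np.ndarray,
    axis_tags: Sequence[str],
    fd: FactorDesign,
    n_bins: int = 20,
    method: str | None = None,
) -> MetricsReport:
    """Full metric suite for one embedding (axes as rows of ``coordinates``)."""
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    type_labels = fd.type_labels()
    feat_labels = {f: fd.feature_labels(f) for f in fd.features}
    per_axis = []
    for tag, axis in zip(axis_tags, coords):
        mi = {f: mutual_information(axis, lab, n_bins) for f, lab in feat_labels.items()}
        ev = {f: explained_variance(axis, lab) for f, lab in feat_labels.items()}
        per_axis.append(
            {
                "tag": tag,
                "snr": snr_axis(axis, type_labels),
                "ev": ev,
                "mi": mi,
                "modularity": modularity_axis(mi),
            }
        )
    return MetricsReport(
        per_axis=per_axis,
        overall_snr=float(np.mean([ax["snr"] for ax in per_axis])),
        overall_modularity=float(np.mean([ax["modularity"] for ax in per_axis])),
        silhouette=silhouette_embedding(coords, type_labels),
        method=method,
    )


def overall_report(
    embeddings: Mapping[str, tuple[np.ndarray, Sequence[str]]],
    fd: FactorDesign,
    reference: str = "lda",
    n_bins: int = 20,
) -> dict[str, MetricsReport]:
    """Evaluate several embeddings on the same cells and normalize overall
    SNR by the reference method's.

    ``embeddings`` maps method name -> (coordinates (r, n), axis tags).
    """
    if reference not in embeddings:
        raise ValueError(f"reference {reference!r} not among {list(embeddings)}")
    reports = {
        name: evaluate_embedding(coords, tags, fd, n_bins=n_bins, method=name)
        for name, (coords, tags) in embeddings.items()
    }
    ref_snr = reports[reference].overall_snr
    for rep in reports.values():
        rep.overall_snr_normalized = rep.overall_snr / ref_snr if ref_snr > 0 else float("nan")
    return reports
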