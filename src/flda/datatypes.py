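"""Core containers: expression matrices and factorial cell-label designs.

An :class:`ExpressionMatrix` is a dense genes x cells array with string ids
and a tag recording which processing layer the values are on (raw counts,
median-normalized counts, or log-transformed).  A :class:`FactorDesign`
assigns every cell a level of each categorical phenotypic feature; the
cross-tabulation of levels is the contingency table of cell types, which may
be complete (every feature combination observed) or partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "FactorDesign"]

_LAYERS = ("counts", "tpm", "log")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_cells)
    gene_ids, cell_ids : sequences of unique strings
    layer_tag : {"counts", "tpm", "log"}
        "counts" requires non-negative values; "log" requires finite values.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.layer_tag not in _LAYERS:
            raise ValueError(f"layer_tag must be one of {_LAYERS}")
        if self.layer_tag == "counts" and np.any(self.values < 0):
            raise ValueError("counts layer must be non-negative")
        if self.layer_tag == "log" and not np.all(np.isfinite(self.values)):
            raise ValueError("log layer must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the submatrix for ``gene_ids``, preserving the given order."""
        index = {g: k for k, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows], list(gene_ids), list(self.cell_ids), self.layer_tag
        )

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {c: k for k, c in enumerate(self.cell_ids)}
        cols = [index[c] for c in cell_ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(cell_ids), self.layer_tag
        )


@dataclass
class FactorDesign:
    """Per-cell categorical labels over one or more phenotypic features.

    ``labels[k]`` is the tuple of levels for cell ``cell_ids[k]``, ordered as
    ``features``.  ``level_sets`` keeps each feature's levels in first-appearance
    order.  ``complete`` is True iff every tuple in the Cartesian product of the
    level sets is observed in at least one cell.
    """

    cell_ids: list[str]
    features: list[str]
    labels: list[tuple]
    level_sets: dict[str, list] = field(default_factory=dict)
    counts: dict[tuple, int] = field(default_factory=dict)
    complete: bool = field(default=False)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = pd.Series(self.cell_ids).value_counts()
            raise ValueError(
                f"duplicate cell ids: {list(dupes[dupes > 1].index[:5])}"
            )
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("labels / cell_ids length mismatch")
        self.labels = [tuple(lab) for lab in self.labels]
        for lab in self.labels:
            if len(lab) != len(self.features):
                raise ValueError("every cell needs a level for every feature")
        if not self.level_sets:
            self.level_sets = {
                f: list(dict.fromkeys(lab[k] for lab in self.labels))
                for k, f in enumerate(self.features)
            }
        if not self.counts:
            counts: dict[tuple, int] = {}
            for lab in self.labels:
                counts[lab] = counts.get(lab, 0) + 1
            self.counts = counts
        full = product(*(self.level_sets[f] for f in self.features))
        self.complete = all(self.counts.get(t, 0) >= 1 for t in full)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def observed_types(self) -> list[tuple]:
        """Observed level tuples, in Cartesian-product order where possible."""
        ordered = [
            t
            for t in product(*(self.level_sets[f] for f in self.features))
            if t in self.counts
        ]
        return ordered

    def type_labels(self) -> np.ndarray:
        """Per-cell cell-type index into :attr:`observed_types`."""
        index = {t: k for k, t in enumerate(self.observed_types)}
        return np.array([index[lab] for lab in self.labels], dtype=int)

    def feature_labels(self, feature: str) -> np.ndarray:
        """Per-cell level index for one feature."""
        k = self.features.index(feature)
        index = {lev: i for i, lev in enumerate(self.level_sets[feature])}
        return np.array([index[lab[k]] for lab in self.labels], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.labels, columns=self.features)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def replace_labels(self, labels: Sequence[tuple]) -> "FactorDesign":
        """New design with the same cells and features but different labels."""
        return FactorDesign(
            cell_ids=list(self.cell_ids),
            features=list(self.features),
            labels=[tuple(lab) for lab in labels],
        )
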