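"""Reading and writing expression matrices and label tables.

Dense matrices are CSV/TSV with a header row of cell ids and the first
column holding gene ids.  Sparse matrices use Matrix Market coordinate
format with one-id-per-line sidecar files (``genes.tsv`` / ``barcodes.tsv``)
next to the ``.mtx`` file.  Label tables are CSV with a ``cell_id`` column
plus one column per phenotypic feature.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import ExpressionMatrix, FactorDesign

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
]

_SEPS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("csv", "tsv", "mtx"):
        return ext
    raise ValueError(f"cannot infer format from extension of {path!r}")


def read_expression(
    path: str,
    format: str | None = None,
    layer_tag: str = "counts",
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or Matrix Market.

    Parameters
    ----------
    path : file path; for ``mtx``, sidecars ``genes.tsv`` and ``barcodes.tsv``
        must sit in the same directory.
    format : "csv", "tsv" or "mtx"; inferred from the extension when None.
    layer_tag : layer the stored values are on (default raw counts).
    orientation : "genes_by_cells" (native) or "cells_by_genes" (transposed
        on read so the in-memory object is always genes x cells).
    """
    fmt = format or _infer_format(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt in _SEPS:
        try:
            df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed {fmt} file {path!r}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    elif fmt == "mtx":
        d = os.path.dirname(path)
        gene_path = os.path.join(d, "genes.tsv")
        cell_path = os.path.join(d, "barcodes.tsv")
        for p in (gene_path, cell_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"missing sidecar id file {p!r}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_ids = _read_id_file(gene_path)
        col_ids = _read_id_file(cell_path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "cells_by_genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")

    if values.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"{path!r}: matrix shape {values.shape} does not match "
            f"{len(row_ids)} gene ids x {len(col_ids)} cell ids"
        )
    return ExpressionMatrix(values, row_ids, col_ids, layer_tag)


def _read_id_file(path: str) -> list[str]:
    with open(path) as fh:
        # keep only the first column if the sidecar has several
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_expression(em: ExpressionMatrix, path: str, format: str | None = None) -> None:
    """Write genes x cells values to CSV/TSV, or MTX + id sidecars."""
    fmt = format or _infer_format(path)
    if fmt in _SEPS:
        em.to_frame().to_csv(path, sep=_SEPS[fmt])
    elif fmt == "mtx":
        d = os.path.dirname(path) or "."
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(em.values))
        with open(os.path.join(d, "genes.tsv"), "w") as fh:
            fh.write("\n".join(em.gene_ids) + "\n")
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(em.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_labels(
    path: str,
    feature_columns: Sequence[str],
    cell_id_column: str = "cell_id",
) -> FactorDesign:
    """Read a cell-label table into a :class:`FactorDesign`.

    Levels keep first-appearance order; the completeness flag is computed
    from the observed contingency table.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in [cell_id_column, *feature_columns] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path!r} lacks columns {missing_cols}")
    sub = df[list(feature_columns)]
    bad = df[sub.isna().any(axis=1)][cell_id_column].tolist()
    if bad:
        raise ValueError(f"cells with missing levels: {bad[:10]}")
    return FactorDesign(
        cell_ids=[str(c) for c in df[cell_id_column]],
        features=list(feature_columns),
        labels=[tuple(row) for row in sub.itertuples(index=False)],
    )


def write_labels(fd: FactorDesign, path: str) -> None:
    fd.to_frame().to_csv(path, index=False)
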