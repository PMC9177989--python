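"""Reading and writing count matrices, annotations and fraction outputs.

Supported on-disk formats: MatrixMarket coordinate (.mtx) with companion
``features.tsv``/``barcodes.tsv`` files (10x convention: matrix rows are
genes), and dense CSV with genes as rows and a header row of sample ids.
Gene identifiers are matched case-sensitively by exact string.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import AnnotationTable, CountMatrix, FractionMap, LayerTag

__all__ = ["read_count_matrix", "write_count_matrix", "write_fraction_map", "read_fraction_map"]


def _read_id_column(path: str) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_count_matrix(
    path: str,
    fmt: str = "mtx",
    genes_path: Optional[str] = None,
    barcodes_path: Optional[str] = None,
    orientation: str = "genes_by_samples",
) -> CountMatrix:
    """Read a raw count matrix from disk.

    Parameters
    ----------
    path
        The .mtx file (``fmt="mtx"``) or the CSV file (``fmt="csv"``).
    genes_path, barcodes_path
        Companion TSVs for the MTX dialect; default to ``features.tsv`` and
        ``barcodes.tsv`` next to the matrix.
    orientation
        ``genes_by_samples`` (10x convention, default) or
        ``samples_by_genes`` if the on-disk matrix is transposed.

    Returns
    -------
    CountMatrix
        With ``layer_tag="raw"`` and orientation normalized to
        genes x samples.
    """
    if fmt == "mtx":
        base = os.path.dirname(path)
        genes_path = genes_path or os.path.join(base, "features.tsv")
        barcodes_path = barcodes_path or os.path.join(base, "barcodes.tsv")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=np.float64)
        if orientation == "samples_by_genes":
            mat = mat.T
        elif orientation != "genes_by_samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        genes = _read_id_column(genes_path)
        barcodes = _read_id_column(barcodes_path)
        if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
            raise ValueError(
                f"matrix is {mat.shape[0]} x {mat.shape[1]} but id files list "
                f"{len(genes)} genes and {len(barcodes)} barcodes"
            )
    elif fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        if orientation == "samples_by_genes":
            df = df.T
        mat = df.to_numpy(dtype=np.float64)
        genes = [str(g) for g in df.index]
        barcodes = [str(b) for b in df.columns]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'mtx' or 'csv'")

    if np.any(mat < 0):
        raise ValueError("count matrix contains negative entries")
    return CountMatrix(mat, genes, barcodes, layer_tag=LayerTag.RAW)


def write_count_matrix(m: CountMatrix, directory: str, fmt: str = "mtx") -> None:
    """Write a count matrix as MTX + TSVs (or dense CSV) under ``directory``."""
    os.makedirs(directory, exist_ok=True)
    if fmt == "mtx":
        scipy.io.mmwrite(
            os.path.join(directory, "matrix.mtx"), scipy.sparse.coo_matrix(m.values)
        )
        pd.Series(m.gene_ids).to_csv(
            os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(m.sample_ids).to_csv(
            os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    elif fmt == "csv":
        pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_ids).to_csv(
            os.path.join(directory, "matrix.csv")
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_fraction_map(fractions: FractionMap, path: str) -> None:
    """Write predicted fractions as CSV: spot_id column plus one column per type.

    Values are written at full float precision so a read-back reproduces the
    matrix to better than 1e-12.
    """
    df = fractions.to_frame()
    df.to_csv(path, float_format="%.17g")


def read_fraction_map(path: str) -> FractionMap:
    df = pd.read_csv(path, index_col=0)
    return FractionMap(
        spot_ids=[str(i) for i in df.index],
        cell_types=[str(c) for c in df.columns],
        fractions=df.to_numpy(dtype=np.float64),
    )
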