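"""Core in-memory containers shared across the pipeline.

Expression data moves through the pipeline as a :class:`CountMatrix` whose
``layer_tag`` records which preprocessing stages have been applied.  The tag
acts as a small state machine (raw -> normalized -> lognorm -> scaled01);
each preprocessing operation checks the tag of its input and stamps the tag
of its output, so stages cannot silently run out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LayerTag",
    "CountMatrix",
    "AnnotationTable",
    "MarkerSet",
    "PseudospotBatch",
    "FractionMap",
]


class LayerTag:
    """Valid preprocessing states for a :class:`CountMatrix`."""

    RAW = "raw"
    NORMALIZED = "normalized"
    LOGNORM = "lognorm"
    SCALED01 = "scaled01"

    ORDER = (RAW, NORMALIZED, LOGNORM, SCALED01)


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CountMatrix:
    """Genes x samples expression matrix with identifiers and a layer tag.

    Parameters
    ----------
    values
        Dense 2-D array of shape (n_genes, n_samples).  Non-negative for
        ``raw`` data; within [0, 1] for ``scaled01`` data.
    gene_ids, sample_ids
        Ordered, duplicate-free identifier lists matching the matrix axes.
    sample_meta
        Optional per-sample table (indexed by sample id) carrying cell-type
        labels, coordinates or region labels.
    layer_tag
        One of ``raw | normalized | lognorm | scaled01``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    sample_meta: Optional[pd.DataFrame] = None
    layer_tag: str = LayerTag.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.layer_tag not in LayerTag.ORDER:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == LayerTag.RAW and np.any(self.values < 0):
            raise ValueError("raw count matrix contains negative entries")
        if self.layer_tag == LayerTag.SCALED01 and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise ValueError("scaled01 matrix has entries outside [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def require_tag(self, tag: str, op: str) -> None:
        if self.layer_tag != tag:
            raise ValueError(
                f"{op} expects a {tag!r} matrix but got {self.layer_tag!r}; "
                "the pipeline order is normalize -> log1p -> subset -> scale"
            )

    def with_values(self, values: np.ndarray, layer_tag: str) -> "CountMatrix":
        return replace(self, values=values, layer_tag=layer_tag)

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return replace(self, values=self.values[rows, :], gene_ids=list(genes))


@dataclass
class AnnotationTable:
    """Mapping from sample id to a categorical label.

    Labels are cell types for single-cell data and tissue domains / cortical
    layers for spatial data.  An explicit ``"unknown"`` label is permitted.
    """

    labels: pd.Series  # index: sample_id, values: str

    def __post_init__(self) -> None:
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(self.labels, dtype=object)
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].unique()
            raise ValueError(f"duplicate sample ids in annotation: {list(dups[:10])}")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError("annotation TSV needs two columns: sample_id, label")
        # tolerate a header row
        if df.iloc[0, 0] in ("sample_id", "barcode", "cell_id", "spot_id"):
            df = df.iloc[1:]
        return cls(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"sample_id": self.labels.index, "label": self.labels.values}).to_csv(
            path, sep="\t", header=False, index=False
        )

    def for_samples(self, sample_ids: list[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.labels.index]
        if missing:
            raise KeyError(f"samples without annotation: {missing[:10]}")
        return self.labels.loc[sample_ids].to_numpy()

    @property
    def label_set(self) -> list[str]:
        return sorted(set(self.labels))


@dataclass
class MarkerSet:
    """Per-cluster ranked markers and the pooled signature panel.

    ``per_cluster`` maps each cluster label to an ordered list of
    ``(gene_id, adjusted_p, effect_direction)`` tuples (at most ``l`` per
    cluster); ``pooled_panel`` is the order-preserving deduplicated union.
    """

    per_cluster: dict[str, list[tuple[str, float, str]]]
    l: int
    pooled_panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pooled_panel:
            seen: set[str] = set()
            panel: list[str] = []
            for markers in self.per_cluster.values():
                for gene, _, _ in markers:
                    if gene not in seen:
                        seen.add(gene)
                        panel.append(gene)
            self.pooled_panel = panel
        for cluster, markers in self.per_cluster.items():
            genes = [g for g, _, _ in markers]
            if len(genes) != len(set(genes)):
                raise ValueError(f"duplicate markers within cluster {cluster!r}")
            if len(genes) > self.l:
                raise ValueError(f"cluster {cluster!r} has more than l={self.l} markers")

    def to_tsv(self, path) -> None:
        rows = [
            (cluster, rank + 1, gene, padj, direction)
            for cluster, markers in self.per_cluster.items()
            for rank, (gene, padj, direction) in enumerate(markers)
        ]
        pd.DataFrame(
            rows, columns=["cluster", "rank", "gene", "adjusted_p", "direction"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class PseudospotBatch:
    """Simulated spots with known mixing fractions.

    ``X`` holds composite expression (pseudospots x panel genes) on the
    log-normalized scale (later scaled to [0, 1] alongside the real spots);
    ``Y`` holds the ground-truth type fractions, one row per pseudospot.
    ``provenance`` logs the (cell index, weight) pairs behind every
    pseudospot so any row can be recomposed independently.
    """

    X: np.ndarray  # (n, n_genes)
    Y: np.ndarray  # (n, n_types), rows sum to 1
    gene_ids: list[str]
    cell_type_order: list[str]
    k_cells: int
    provenance: list[list[tuple[int, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y disagree on the number of pseudospots")
        if self.Y.shape[1] != len(self.cell_type_order):
            raise ValueError("Y columns do not match cell_type_order")
        if np.any(self.Y < 0):
            raise ValueError("negative fraction in Y")
        sums = self.Y.sum(axis=1)
        if self.Y.shape[0] and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("Y rows must sum to 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def scaled01(self) -> "PseudospotBatch":
        """Copy with each pseudospot's gene vector min-max scaled to [0, 1]."""
        from .preprocess import scale01_rows

        return replace(self, X=scale01_rows(self.X))


@dataclass
class FractionMap:
    """Spots x cell types predicted (or true) proportions.

    Rows are probability vectors; optional per-spot region labels and
    coordinates make the map joinable to tissue annotations.
    """

    spot_ids: list[str]
    cell_types: list[str]
    fractions: np.ndarray  # (n_spots, n_types), row-stochastic
    region_label: Optional[np.ndarray] = None  # (n_spots,) strings
    coords: Optional[np.ndarray] = None  # (n_spots, 2)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.cell_types = [str(c) for c in self.cell_types]
        if self.fractions.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("fractions shape does not match ids")
        _check_unique(self.spot_ids, "spot ids")
        if self.fractions.size:
            if np.any(self.fractions < -1e-9) or np.any(self.fractions > 1 + 1e-9):
                raise ValueError("fractions outside [0, 1]")
            if not np.allclose(self.fractions.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("fraction rows must sum to 1 (+/- 1e-6)")
        if self.region_label is not None:
            self.region_label = np.asarray(self.region_label, dtype=object)
            if self.region_label.shape[0] != len(self.spot_ids):
                raise ValueError("region_label length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions, index=pd.Index(self.spot_ids, name="spot_id"),
            columns=self.cell_types,
        )
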