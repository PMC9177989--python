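"""Marker gene selection by one-vs-rest Wilcoxon rank-sum tests.

For each cell cluster, every gene is tested for enrichment (cluster > rest)
with the tie-corrected normal approximation of the Wilcoxon rank-sum /
Mann-Whitney statistic, including a 0.5 continuity correction.  P-values are
Benjamini-Hochberg adjusted within each cluster comparison, genes are ranked
by adjusted p (ties broken by descending rank-sum statistic, then gene id),
and the top ``l`` genes per cluster are pooled into the signature panel.

Statistics are computed on log-normalized values, not the [0,1]-scaled
values fed to the network.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import AnnotationTable, CountMatrix, LayerTag, MarkerSet

__all__ = ["bh_adjust", "rank_sum_enrichment", "rank_sum_markers"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def rank_sum_enrichment(
    values: np.ndarray, in_group: np.ndarray, alternative: str = "greater"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Mann-Whitney test of group vs rest for every gene.

    Parameters
    ----------
    values
        (n_genes, n_cells) array of expression values.
    in_group
        Boolean mask of length n_cells selecting the cluster.
    alternative
        ``greater`` (default, enrichment) or ``two-sided``.

    Returns
    -------
    (U, p)
        Mann-Whitney U statistics for the cluster side and p-values from the
        tie-corrected normal approximation with continuity correction.
    """
    values = np.asarray(values, dtype=np.float64)
    in_group = np.asarray(in_group, dtype=bool)
    n1 = int(in_group.sum())
    n2 = int((~in_group).sum())
    n = n1 + n2
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one sample")

    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # per-gene tie correction term sum(t^3 - t) over tied groups
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tied = counts[counts > 1]
        if tied.size:
            tie_term[i] = np.sum(tied.astype(np.float64) ** 3 - tied)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))

    sd = np.sqrt(var)
    degenerate = sd == 0  # gene constant across all cells
    sd_safe = np.where(degenerate, 1.0, sd)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd_safe
        p = stats.norm.sf(z)
    elif alternative == "two-sided":
        z = (np.abs(u - mu) - 0.5) / sd_safe
        p = 2.0 * stats.norm.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = np.clip(p, 0.0, 1.0)
    p[degenerate] = 1.0
    return u, p


def rank_sum_markers(
    sc: CountMatrix,
    annot: AnnotationTable,
    l: int,
    alternative: str = "greater",
) -> MarkerSet:
    """Select the top-``l`` enriched genes per cluster and pool the panel.

    Raises if any cluster has fewer than two cells or fewer than two
    clusters exist.
    """
    sc.require_tag(LayerTag.LOGNORM, "rank_sum_markers")
    if l <= 0:
        raise ValueError("l must be a positive integer")
    labels = annot.for_samples(sc.sample_ids)
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("marker selection needs at least two clusters")
    for c in clusters:
        if int((labels == c).sum()) < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 cells")

    gene_ids = np.asarray(sc.gene_ids)
    per_cluster: dict[str, list[tuple[str, float, str]]] = {}
    for c in clusters:
        mask = labels == c
        u, p = rank_sum_enrichment(sc.values, mask, alternative=alternative)
        padj = bh_adjust(p)
        mu = mask.sum() * (~mask).sum() / 2.0
        order = sorted(
            range(len(gene_ids)), key=lambda i: (padj[i], -u[i], gene_ids[i])
        )
        top = order[:l]
        per_cluster[c] = [
            (str(gene_ids[i]), float(padj[i]), "up" if u[i] >= mu else "down")
            for i in top
        ]
    return MarkerSet(per_cluster=per_cluster, l=l)
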