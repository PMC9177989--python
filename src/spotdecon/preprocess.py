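"""Normalization, log transform, gene intersection and per-sample scaling.

The pipeline order is fixed and enforced through the ``layer_tag`` state
machine on :class:`~spotdecon.containers.CountMatrix`:

    normalize_total -> log1p_transform -> subset to marker panel
    -> minmax_scale_per_sample

Scaling is per sample (each cell, pseudospot or spot independently) over its
panel genes, so every sample's feature vector spans [0, 1] before it reaches
the network.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CountMatrix, LayerTag

__all__ = [
    "normalize_total",
    "log1p_transform",
    "intersect_genes",
    "minmax_scale_per_sample",
    "scale01_rows",
]

logger = logging.getLogger(__name__)


def normalize_total(m: CountMatrix, target_sum: float = 1e4) -> CountMatrix:
    """Scale each sample so its counts sum to ``target_sum`` (counts-per-10k default).

    All-zero samples are left all-zero with a logged warning rather than
    raising, since downstream stages tolerate them.
    """
    m.require_tag(LayerTag.RAW, "normalize_total")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = m.values.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        logger.warning(
            "%d all-zero sample(s) left unnormalized: %s",
            int(zero.sum()),
            [m.sample_ids[i] for i in np.flatnonzero(zero)[:5]],
        )
    safe = np.where(zero, 1.0, totals)
    values = m.values * (target_sum / safe)
    values[:, zero] = 0.0
    return m.with_values(values, LayerTag.NORMALIZED)


def log1p_transform(m: CountMatrix) -> CountMatrix:
    """Elementwise natural log(1 + x)."""
    m.require_tag(LayerTag.NORMALIZED, "log1p_transform")
    if np.any(m.values < 0):
        raise ValueError("log1p_transform requires non-negative values")
    return m.with_values(np.log1p(m.values), LayerTag.LOGNORM)


def intersect_genes(
    panel: list[str], spatial: CountMatrix, sc: CountMatrix
) -> list[str]:
    """Genes present in the panel AND both matrices, panel order, deduplicated."""
    spatial_set = set(spatial.gene_ids)
    sc_set = set(sc.gene_ids)
    seen: set[str] = set()
    shared: list[str] = []
    for g in panel:
        if g in seen:
            continue
        seen.add(g)
        if g in spatial_set and g in sc_set:
            shared.append(g)
    if not shared:
        raise ValueError(
            "no overlap between the marker panel and both datasets; "
            "increase the number of markers per cluster or check gene identifiers"
        )
    return shared


def scale01_rows(x: np.ndarray) -> np.ndarray:
    """Min-max scale each row of a samples x genes array to [0, 1].

    Constant rows map to all zeros (they carry no signal and this avoids a
    divide by zero).
    """
    x = np.asarray(x, dtype=np.float64)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0
    out = (x - lo) / span
    out[constant, :] = 0.0
    return out


def minmax_scale_per_sample(m: CountMatrix) -> CountMatrix:
    """Scale each sample's gene vector to [0, 1] independently.

    Applied after subsetting to the shared marker panel, so the model sees
    each spot/cell stretched across the full unit interval over panel genes.
    """
    m.require_tag(LayerTag.LOGNORM, "minmax_scale_per_sample")
    scaled = scale01_rows(m.values.T).T
    return m.with_values(scaled, LayerTag.SCALED01)
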