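"""Synthetic single-cell references and domain-shifted spatial spots.

The generator provides fully labelled inputs for testing and benchmarking
without any external download:

* :func:`make_reference` draws cluster-structured single-cell counts from a
  negative-binomial (gamma-Poisson) model.  Each cell type over-expresses a
  disjoint block of marker genes by ``fold_change``; per-cell library sizes
  vary log-normally, as in droplet data.
* :func:`make_spatial` composes spots exactly like pseudospots (k cells,
  normalized uniform weights) and then applies a domain shift — global
  library-size scaling, per-entry multiplicative log-normal noise, and
  independent dropout — so the gap between pseudospots and "real" spots can
  be dialled from zero to signal-destroying.  Region-dependent cell-type
  priors let particular types be restricted to particular regions, giving
  ground truth for ROC-style localization scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnnotationTable, CountMatrix, FractionMap, LayerTag

__all__ = ["ShiftParams", "make_reference", "make_spatial", "region_restricted_priors"]


@dataclass
class ShiftParams:
    """Domain shift applied to synthetic spots (relative to pseudospots).

    libsize_factor : multiplies all counts (sequencing-depth difference).
    noise_sd : sd of per-entry multiplicative log-normal noise.
    dropout_rate : probability each entry is independently zeroed.
    """

    libsize_factor: float = 1.0
    noise_sd: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.libsize_factor <= 0:
            raise ValueError("libsize_factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def make_reference(
    n_types: int,
    n_cells_per_type: int,
    n_genes: int,
    n_markers_per_type: int,
    fold_change: float,
    seed: int,
    dispersion: float = 2.0,
    lib_sigma: float = 0.3,
    base_mean_log: float = np.log(0.5),
    base_mean_sigma: float = 1.0,
) -> tuple[CountMatrix, AnnotationTable]:
    """Simulate a clustered single-cell reference with planted markers.

    Counts follow NB(mean mu, dispersion theta) via the gamma-Poisson
    mixture; ``mu`` is a per-gene log-normal baseline, multiplied by
    ``fold_change`` on each type's disjoint marker block and by a per-cell
    log-normal library factor.  Reproducible from ``seed``.
    """
    if n_markers_per_type * n_types > n_genes:
        raise ValueError("n_markers_per_type * n_types must not exceed n_genes")
    if fold_change < 1:
        raise ValueError("fold_change must be >= 1")
    rng = np.random.default_rng(seed)
    n_cells = n_types * n_cells_per_type

    base_mu = rng.lognormal(mean=base_mean_log, sigma=base_mean_sigma, size=n_genes)
    lib = rng.lognormal(mean=0.0, sigma=lib_sigma, size=n_cells)
    type_of_cell = np.repeat(np.arange(n_types), n_cells_per_type)

    mean = np.tile(base_mu[:, None], (1, n_cells))
    for t in range(n_types):
        block = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        mean[block, :][:, type_of_cell == t] *= fold_change
    mean *= lib[None, :]

    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    counts = rng.poisson(lam).astype(np.float64)

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    labels = pd.Series([f"type_{t}" for t in type_of_cell], index=cell_ids)
    ref = CountMatrix(counts, gene_ids, cell_ids, layer_tag=LayerTag.RAW)
    return ref, AnnotationTable(labels)


def region_restricted_priors(
    cell_types: list[str], restricted_type: str, n_regions: int = 2
) -> dict[str, np.ndarray]:
    """Uniform type priors per region, with one type confined to region_0.

    The restricted type has prior 0 in every region except ``region_0``, so
    its true fraction is exactly zero on all out-region spots.
    """
    k = len(cell_types)
    j = cell_types.index(restricted_type)
    priors: dict[str, np.ndarray] = {}
    for r in range(n_regions):
        p = np.full(k, 1.0 / k)
        if r != 0:
            p[j] = 0.0
            p /= p.sum()
        priors[f"region_{r}"] = p
    return priors


def make_spatial(
    reference: CountMatrix,
    annot: AnnotationTable,
    n_spots: int,
    k: int,
    shift: ShiftParams | None = None,
    region_priors: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, FractionMap]:
    """Simulate spatial spots as shifted k-cell mixtures with known truth.

    Each spot mixes ``k`` distinct cells with normalized uniform weights on
    the raw-count scale, then the domain shift is applied.  With
    ``region_priors`` (region -> prior over sorted cell types), spots are
    assigned to regions in equal contiguous blocks and cells are drawn
    type-first from the region's prior.  Returns the raw spot matrix (with
    a ``region`` column in ``sample_meta``) and the true FractionMap.
    """
    reference.require_tag(LayerTag.RAW, "make_spatial")
    shift = shift or ShiftParams()
    if n_spots <= 0:
        raise ValueError("n_spots must be positive")
    n_cells = reference.n_samples
    if k <= 0 or k > n_cells:
        raise ValueError(f"k must be in [1, {n_cells}]")

    labels = annot.for_samples(reference.sample_ids)
    cell_types = sorted(set(labels))
    type_index = {t: j for j, t in enumerate(cell_types)}
    cells_by_type = {t: np.flatnonzero(labels == t) for t in cell_types}

    if region_priors is not None:
        regions = sorted(region_priors)
        for r in regions:
            p = np.asarray(region_priors[r], dtype=float)
            if p.shape != (len(cell_types),) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"invalid prior for region {r!r}")
        bounds = np.linspace(0, n_spots, len(regions) + 1).astype(int)
        region_of_spot = np.empty(n_spots, dtype=object)
        for i, r in enumerate(regions):
            region_of_spot[bounds[i] : bounds[i + 1]] = r
    else:
        region_of_spot = None

    rng = np.random.default_rng(seed)
    counts = reference.values  # genes x cells
    X = np.empty((reference.n_genes, n_spots))
    Y = np.zeros((n_spots, len(cell_types)))
    for s in range(n_spots):
        if region_of_spot is not None:
            prior = np.asarray(region_priors[region_of_spot[s]], dtype=float)
            # draw slot types from the prior, then distinct cells per type
            slot_types = rng.choice(len(cell_types), size=k, p=prior)
            chosen: list[int] = []
            for t_idx in np.unique(slot_types):
                pool = cells_by_type[cell_types[t_idx]]
                m = int((slot_types == t_idx).sum())
                chosen.extend(rng.choice(pool, size=min(m, pool.size), replace=False))
            cells = np.asarray(chosen)
        else:
            cells = rng.choice(n_cells, size=k, replace=False)
        u = rng.uniform(size=cells.size)
        w = u / u.sum()
        X[:, s] = counts[:, cells] @ w
        for c, wi in zip(cells, w):
            Y[s, type_index[labels[c]]] += wi

    X *= shift.libsize_factor
    if shift.noise_sd > 0:
        X *= np.exp(rng.normal(0.0, shift.noise_sd, size=X.shape))
    if shift.dropout_rate > 0:
        X *= rng.random(X.shape) >= shift.dropout_rate

    spot_ids = [f"spot_{i:05d}" for i in range(n_spots)]
    meta = None
    if region_of_spot is not None:
        meta = pd.DataFrame({"region": region_of_spot}, index=spot_ids)
    spots = CountMatrix(
        X, list(reference.gene_ids), spot_ids, sample_meta=meta, layer_tag=LayerTag.RAW
    )
    truth = FractionMap(
        spot_ids=spot_ids,
        cell_types=cell_types,
        fractions=Y,
        region_label=region_of_spot,
    )
    return spots, truth
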