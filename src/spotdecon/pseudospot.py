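"""Pseudospot generation: random weighted mixtures of single cells.

A pseudospot mimics a spatial capture spot: ``k`` cells drawn uniformly
without replacement, given random weights w_i = u_i / sum(u_j) with
u_i ~ Uniform(0, 1) (equivalently a draw biased toward a flat Dirichlet),
and combined as a weighted sum of their log-normalized expression vectors.
The true cell-type fractions of each pseudospot are the weights summed by
type, so the batch provides fully labelled training data for the fraction
predictor.
"""

from __future__ import annotations

import numpy as np

from .containers import AnnotationTable, CountMatrix, LayerTag, PseudospotBatch

__all__ = ["generate_pseudospots"]


def _draw_weights(rng: np.random.Generator, k: int, law: str, dirichlet_alpha: float) -> np.ndarray:
    if law == "uniform":
        u = rng.uniform(size=k)
        total = u.sum()
        if total == 0:  # astronomically unlikely; keep it defined
            return np.full(k, 1.0 / k)
        return u / total
    if law == "dirichlet":
        return rng.dirichlet(np.full(k, dirichlet_alpha))
    raise ValueError(f"unknown weight law {law!r}")


def generate_pseudospots(
    sc: CountMatrix,
    annot: AnnotationTable,
    k: int,
    n: int,
    seed: int,
    weight_law: str = "uniform",
    dirichlet_alpha: float = 1.0,
    keep_provenance: bool = True,
) -> PseudospotBatch:
    """Generate ``n`` pseudospots of ``k`` cells each from the reference.

    ``sc`` must already be subset to the marker panel and log-normalized;
    the composite expression is computed on the log-normalized values and
    the batch is later min-max scaled together with the real spots.
    Cells are sampled without replacement within a pseudospot and with
    replacement across pseudospots.  Fully reproducible from ``seed``.
    """
    sc.require_tag(LayerTag.LOGNORM, "generate_pseudospots")
    n_cells = sc.n_samples
    if k <= 0 or k > n_cells:
        raise ValueError(f"k must be in [1, {n_cells}], got {k}")
    if n <= 0:
        raise ValueError("n must be positive")

    labels = annot.for_samples(sc.sample_ids)
    cell_types = sorted(set(labels))
    type_index = {t: j for j, t in enumerate(cell_types)}
    label_codes = np.array([type_index[t] for t in labels])

    expr = sc.values.T  # cells x genes
    rng = np.random.default_rng(seed)

    X = np.empty((n, sc.n_genes))
    Y = np.zeros((n, len(cell_types)))
    provenance: list[list[tuple[int, float]]] = []
    for s in range(n):
        cells = rng.choice(n_cells, size=k, replace=False)
        w = _draw_weights(rng, k, weight_law, dirichlet_alpha)
        X[s] = w @ expr[cells]
        np.add.at(Y[s], label_codes[cells], w)
        if keep_provenance:
            provenance.append([(int(c), float(wi)) for c, wi in zip(cells, w)])

    return PseudospotBatch(
        X=X,
        Y=Y,
        gene_ids=list(sc.gene_ids),
        cell_type_order=cell_types,
        k_cells=k,
        provenance=provenance,
    )
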