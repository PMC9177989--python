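"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from spotdecon.markers import rank_sum_markers
from spotdecon.preprocess import (
    intersect_genes,
    log1p_transform,
    minmax_scale_per_sample,
    normalize_total,
)
from spotdecon.pseudospot import generate_pseudospots
from spotdecon.synthetic import make_reference, make_spatial


@pytest.fixture(scope="session")
def small_reference():
    """3 well-separated types, 40 cells each, 90 genes (fold change 8)."""
    return make_reference(
        n_types=3, n_cells_per_type=40, n_genes=90, n_markers_per_type=6,
        fold_change=8.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_lognorm(small_reference):
    ref, annot = small_reference
    return log1p_transform(normalize_total(ref)), annot


@pytest.fixture(scope="session")
def small_panel_data(small_lognorm):
    """Log-normalized reference subset to its marker panel, plus scaled spots."""
    sc, annot = small_lognorm
    ref, _ = sc, annot
    markers = rank_sum_markers(sc, annot, l=6)
    spots_raw, truth = make_spatial(
        *_raw_pair(sc, annot), n_spots=60, k=4, seed=12
    )
    sp = log1p_transform(normalize_total(spots_raw))
    panel = intersect_genes(markers.pooled_panel, sp, sc)
    sc_panel = sc.subset_genes(panel)
    sp_scaled = minmax_scale_per_sample(sp.subset_genes(panel))
    return sc_panel, annot, sp_scaled, truth


def _raw_pair(sc_lognorm, annot):
    # regenerate the raw reference deterministically for spot construction
    return make_reference(
        n_types=3, n_cells_per_type=40, n_genes=90, n_markers_per_type=6,
        fold_change=8.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_batch(small_panel_data):
    sc_panel, annot, _, _ = small_panel_data
    return generate_pseudospots(sc_panel, annot, k=4, n=400, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
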