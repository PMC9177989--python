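"""End-to-end orchestration: raw inputs to a per-spot fraction map.

Stage order (fixed, enforced by the layer-tag state machine):

    normalize_total -> log1p -> marker selection (single-cell)
    -> gene intersection -> pseudospot generation -> per-sample [0,1]
    scaling -> pretraining -> adversarial adaptation -> prediction

Every random stage is seeded from one master seed, so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .containers import AnnotationTable, CountMatrix, FractionMap
from .markers import rank_sum_markers
from .networks import AdversarialNet
from .preprocess import (
    intersect_genes,
    log1p_transform,
    minmax_scale_per_sample,
    normalize_total,
)
from .pseudospot import generate_pseudospots
from .trainer import TrainingConfig, adversarial_train, predict_fractions, pretrain_source

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All knobs of the end-to-end run (mirrors the CLI flags)."""

    n_markers: int = 20          # l: markers per cluster
    k_cells: int = 8             # cells per pseudospot
    n_pseudospots: int = 20_000  # n
    target_sum: float = 1e4
    alpha: float = 0.6
    iterations: int = 3000
    batch_size: int = 512
    lr_domain: float = 0.005
    lr_main: float = 0.001
    pretrain_epochs: int = 10
    baseline: bool = False       # True: NN_wo_da (skip adversarial phases)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    fractions: FractionMap
    model: AdversarialNet
    panel: list[str]
    cell_types: list[str]
    params: PipelineParams
    truth: Optional[FractionMap] = None
    sub_seeds: dict = field(default_factory=dict)


def run_pipeline(
    sc: CountMatrix,
    sc_annot: AnnotationTable,
    spatial: CountMatrix,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full deconvolution pipeline on raw count matrices."""
    params = params or PipelineParams()
    seeds = np.random.SeedSequence(params.seed).generate_state(3) % (2**31)
    seed_pseudo, seed_model = int(seeds[0]), int(seeds[1])
    logger.info("stage normalize: target_sum=%g", params.target_sum)
    sc_norm = log1p_transform(normalize_total(sc, params.target_sum))
    sp_norm = log1p_transform(normalize_total(spatial, params.target_sum))

    logger.info("stage markers: l=%d", params.n_markers)
    marker_set = rank_sum_markers(sc_norm, sc_annot, params.n_markers)
    panel = intersect_genes(marker_set.pooled_panel, sp_norm, sc_norm)
    logger.info("stage intersect: %d panel genes", len(panel))
    sc_panel = sc_norm.subset_genes(panel)
    sp_panel = sp_norm.subset_genes(panel)

    logger.info(
        "stage pseudospots: k=%d n=%d seed=%d",
        params.k_cells, params.n_pseudospots, seed_pseudo,
    )
    batch = generate_pseudospots(
        sc_panel, sc_annot, k=params.k_cells, n=params.n_pseudospots,
        seed=seed_pseudo, keep_provenance=False,
    )
    batch_scaled = batch.scaled01()
    spots_scaled = minmax_scale_per_sample(sp_panel)

    cfg = TrainingConfig(
        iterations=params.iterations,
        batch_size=params.batch_size,
        lr_domain=params.lr_domain,
        lr_main=params.lr_main,
        alpha=params.alpha,
        pretrain_epochs=params.pretrain_epochs,
        seed=seed_model,
    )
    model = AdversarialNet(
        n_genes=len(panel),
        n_types=len(batch.cell_type_order),
        alpha=params.alpha,
        seed=seed_model,
    )
    logger.info("stage pretrain: epochs=%d", cfg.pretrain_epochs)
    pretrain_source(model, batch_scaled, cfg)
    if not params.baseline:
        logger.info("stage adversarial: iterations=%d alpha=%g", cfg.iterations, cfg.alpha)
        adversarial_train(model, batch_scaled, spots_scaled, cfg)
    else:
        logger.info("baseline mode: adversarial phases skipped (NN_wo_da)")

    logger.info("stage predict: %d spots", spots_scaled.n_samples)
    fractions = predict_fractions(model, spots_scaled, batch.cell_type_order)
    return PipelineResult(
        fractions=fractions,
        model=model,
        panel=panel,
        cell_types=batch.cell_type_order,
        params=params,
        sub_seeds={"pseudospot": seed_pseudo, "model": seed_model},
    )
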