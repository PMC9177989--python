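"""Training loops: source pretraining and two-phase adversarial adaptation.

Training alternates two phases per iteration:

* **Phase A** — sample a minibatch of pseudospots and an equal-size
  minibatch of real spots; update the embedder ``f`` and source classifier
  ``S`` to minimize ``L_s + alpha * L_adv,1`` with the domain classifier
  ``D`` frozen.
* **Phase B** — update ``D`` to minimize ``L_adv,2`` (real spots labelled
  1, pseudospots 0) at its own learning rate, with ``f`` and ``S`` frozen.

Frozen blocks normalize with the current minibatch's batch-norm statistics
(dropout active) but their parameters and running statistics are
byte-identical before and after the step; gradients still flow *through*
the frozen domain classifier into the embedder in phase A.

All updates use Adam, with independent optimizer states for the source,
adversarial and domain objectives.  The baseline ``NN_wo_da`` model is the
same ``f``+``S`` architecture trained by pretraining alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import losses
from .containers import CountMatrix, FractionMap, LayerTag, PseudospotBatch
from .networks import DTYPE, Adam, AdversarialNet, sigmoid, softmax

__all__ = [
    "TrainingConfig",
    "pretrain_source",
    "adversarial_train",
    "predict_fractions",
    "train_nn_wo_da",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the two-step optimization.

    Defaults follow the brain-tissue setting: 3000 iterations, minibatch
    512, domain-classifier learning rate 0.005, adversarial weight
    alpha=0.6 (use 1.0 for the lung-style setting).  The main learning rate
    (pretraining and phase A) defaults to 0.001.
    """

    iterations: int = 3000
    batch_size: int = 512
    lr_domain: float = 0.005
    lr_main: float = 0.001
    alpha: float = 0.6
    pretrain_epochs: int = 10
    seed: int = 0
    check_freeze: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.batch_size <= 0 or self.pretrain_epochs < 0:
            raise ValueError("iterations/batch_size must be positive, pretrain_epochs >= 0")
        if self.lr_domain <= 0 or self.lr_main <= 0:
            raise ValueError("learning rates must be strictly positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def _check_scaled01(X: np.ndarray, what: str) -> np.ndarray:
    X = np.asarray(X)
    if X.size and (X.min() < -1e-6 or X.max() > 1 + 1e-6):
        raise ValueError(f"{what} must be min-max scaled to [0, 1] before training")
    return X.astype(DTYPE)


def _abort_on_nan(loss: float, stage: str, iteration: int) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(
            f"non-finite loss ({loss}) in {stage} at iteration {iteration}; "
            "lower the learning rate or check the inputs"
        )


def _source_step(model: AdversarialNet, xb, yb, adam: Adam) -> float:
    """One minibatch gradient step on L_s; returns the batch KLD."""
    E, cf = model.embed(xb, training=True, update_stats=True)
    logits, cs = model.source_logits(E, training=True)
    probs = softmax(logits)
    B = xb.shape[0]
    dlogits = ((probs - yb) / B).astype(DTYPE)
    dE, gS = model.S.backward(dlogits, cs)
    _, gF = model.f.backward(dE, cf)
    adam.step(gF + gS)
    return losses.kld_source_loss(yb, probs)


def pretrain_source(
    model: AdversarialNet,
    batch: PseudospotBatch,
    cfg: TrainingConfig,
    _adam: Adam | None = None,
) -> AdversarialNet:
    """Pretrain ``f`` and ``S`` on labelled pseudospots by minimizing L_s.

    The domain classifier is untouched.  ``batch.X`` must already be scaled
    to [0, 1].  The per-epoch mean KLD trajectory is stored on
    ``model.history_["pretrain_kld"]``.
    """
    X = _check_scaled01(batch.X, "pseudospot batch")
    Y = np.asarray(batch.Y, dtype=DTYPE)
    adam = _adam or Adam(model.f.params + model.S.params, lr=cfg.lr_main)
    rng = np.random.default_rng(cfg.seed)
    history = getattr(model, "history_", {})
    trajectory = history.setdefault("pretrain_kld", [])
    n = X.shape[0]
    for epoch in range(cfg.pretrain_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            loss = _source_step(model, X[idx], Y[idx], adam)
            _abort_on_nan(loss, "pretraining", epoch)
            epoch_losses.append(loss)
        trajectory.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
    model.history_ = history
    return model


def adversarial_train(
    model: AdversarialNet,
    pseudo: PseudospotBatch,
    spots: CountMatrix,
    cfg: TrainingConfig,
) -> AdversarialNet:
    """Run the two-phase adversarial adaptation for ``cfg.iterations`` steps.

    ``pseudo.X`` and ``spots`` must be scaled to [0, 1] over the same gene
    panel in the same order.  Per-iteration values of L_s, L_adv,1 and
    L_adv,2 are appended to ``model.history_``.
    """
    if list(pseudo.gene_ids) != list(spots.gene_ids):
        raise ValueError("pseudospots and spots disagree on the gene panel or its order")
    spots.require_tag(LayerTag.SCALED01, "adversarial_train")
    Xp = _check_scaled01(pseudo.X, "pseudospot batch")
    Y = np.asarray(pseudo.Y, dtype=DTYPE)
    Xr = np.asarray(spots.values.T, dtype=DTYPE)  # spots x genes

    # Phase A is realized as two sub-steps with independent Adam states —
    # one on L_s (f and S), one on alpha * L_adv,1 (f only, through the
    # frozen D) — mirroring the separately compiled source and adversarial
    # models of the reference training scheme.  Sharing one optimizer state
    # between the two objectives lets the adversarial gradient pollute the
    # source-loss moment estimates and measurably degrades recovery.
    adam_src = Adam(model.f.params + model.S.params, lr=cfg.lr_main)
    adam_adv = Adam(model.f.params, lr=cfg.lr_main)
    adam_domain = Adam(model.D.params, lr=cfg.lr_domain)
    rng = np.random.default_rng(cfg.seed)
    alpha = model.alpha

    history = getattr(model, "history_", {})
    for key in ("L_s", "L_adv1", "L_adv2"):
        history.setdefault(key, [])

    n_pseudo, n_real = Xp.shape[0], Xr.shape[0]
    B = cfg.batch_size
    for it in range(cfg.iterations):
        ip = rng.choice(n_pseudo, size=min(B, n_pseudo), replace=n_pseudo < B)
        ir = rng.choice(n_real, size=min(B, n_real), replace=n_real < B)
        xp, yb, xr = Xp[ip], Y[ip], Xr[ir]
        bp, br = xp.shape[0], xr.shape[0]

        if cfg.check_freeze:
            d_hash_before = model.D.hash()

        # ---- phase A, step 1: minimize L_s on the pseudospot minibatch ----
        l_s = _source_step(model, xp, yb, adam_src)
        _abort_on_nan(l_s, "phase A (source)", it)

        # ---- phase A, step 2: minimize alpha * L_adv,1 w.r.t. f, D frozen ----
        # The frozen D normalizes with the minibatch's statistics (dropout
        # active) but its parameters and running statistics never change;
        # gradients flow through it into the embedder.
        e_p, cfp = model.embed(xp, training=True, update_stats=False)
        t_p, cdp = model.domain_logits(e_p, training=True)
        e_r, cfr = model.embed(xr, training=True, update_stats=True)
        t_r, cdr = model.domain_logits(e_r, training=True)
        d_p, d_r = sigmoid(t_p), sigmoid(t_r)
        l_adv1 = losses.adv_loss_generator(d_p, d_r)
        _abort_on_nan(l_adv1, "phase A (adversarial)", it)
        dt_p = (alpha * (d_p - 1.0) / bp).astype(DTYPE)[:, None]
        dt_r = (alpha * d_r / br).astype(DTYPE)[:, None]
        dE_p, _ = model.D.backward(dt_p, cdp, collect_grads=False)
        dE_r, _ = model.D.backward(dt_r, cdr, collect_grads=False)
        _, gF1 = model.f.backward(dE_p, cfp)
        _, gF2 = model.f.backward(dE_r, cfr)
        adam_adv.step([a + b for a, b in zip(gF1, gF2)])

        if cfg.check_freeze:
            assert model.D.hash() == d_hash_before, "phase A mutated the domain classifier"
            f_hash_before, s_hash_before = model.f.hash(), model.S.hash()

        # ---- phase B: update D on L_adv,2 (f, S frozen) ----
        E, _ = model.embed(
            np.concatenate([xr, xp], axis=0), training=True, update_stats=False
        )
        t, cd = model.domain_logits(E, training=True, update_stats=True)
        d = sigmoid(t)
        targets = np.concatenate([np.ones(br), np.zeros(bp)]).astype(DTYPE)
        l_adv2 = losses.adv_loss_discriminator(d[:br], d[br:])
        _abort_on_nan(l_adv2, "phase B", it)
        dt = ((d - targets) / br).astype(DTYPE)[:, None]
        _, gD = model.D.backward(dt, cd)
        adam_domain.step(gD)

        if cfg.check_freeze:
            assert model.f.hash() == f_hash_before, "phase B mutated the embedder"
            assert model.S.hash() == s_hash_before, "phase B mutated the source classifier"

        history["L_s"].append(l_s)
        history["L_adv1"].append(l_adv1)
        history["L_adv2"].append(l_adv2)

    model.history_ = history
    return model


def predict_fractions(
    model: AdversarialNet, spots: CountMatrix, cell_type_order: list[str]
) -> FractionMap:
    """Predict per-spot cell-type fractions (inference mode, deterministic)."""
    spots.require_tag(LayerTag.SCALED01, "predict_fractions")
    if spots.n_genes != model.n_genes:
        raise ValueError(
            f"spot matrix has {spots.n_genes} genes but the model was trained on "
            f"{model.n_genes}; subset/order spots to the training panel"
        )
    probs = model.predict_proportions(np.asarray(spots.values.T, dtype=DTYPE))
    meta = spots.sample_meta
    region = None
    coords = None
    if meta is not None:
        if "region" in meta.columns:
            region = meta.loc[spots.sample_ids, "region"].to_numpy()
        if {"x", "y"}.issubset(meta.columns):
            coords = meta.loc[spots.sample_ids, ["x", "y"]].to_numpy(dtype=float)
    return FractionMap(
        spot_ids=list(spots.sample_ids),
        cell_types=list(cell_type_order),
        fractions=probs,
        region_label=region,
        coords=coords,
    )


def train_nn_wo_da(pseudo: PseudospotBatch, cfg: TrainingConfig) -> AdversarialNet:
    """Train the no-domain-adaptation baseline (pretraining only).

    Same ``f``+``S`` architecture; the domain classifier stays at its
    initialization.
    """
    model = AdversarialNet(
        n_genes=len(pseudo.gene_ids),
        n_types=pseudo.Y.shape[1],
        alpha=cfg.alpha,
        seed=cfg.seed,
    )
    return pretrain_source(model, pseudo, cfg)
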