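"""Loss functions for the adversarial deconvolution model.

Four losses drive training:

* ``L_s`` — Kullback-Leibler divergence between true and predicted cell-type
  fraction vectors (the source classifier's objective).
* ``L_adv,1`` — inverted-label adversarial term: the embedder is rewarded
  when the domain classifier assigns pseudospots to the "real" side and real
  spots to the "pseudo" side.
* ``L_total = L_s + alpha * L_adv,1`` — the phase-A objective.
* ``L_adv,2`` — ordinary binary cross-entropy for the domain classifier
  (real spots labelled 1, pseudospots 0), the phase-B objective.

All logs are natural; probabilities are clipped at ``EPS`` inside logs and
``0 * log(0/q)`` is taken as 0 in the KLD.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EPS",
    "kld_source_loss",
    "adv_loss_generator",
    "adv_loss_discriminator",
    "total_loss",
]

EPS = 1e-8


def kld_source_loss(Y: np.ndarray, S_out: np.ndarray) -> float:
    """Mean KL divergence sum_k Y_k log(Y_k / S_k) over the batch.

    ``Y`` and ``S_out`` are (batch, n_types) row-stochastic matrices.
    """
    Y = np.asarray(Y, dtype=np.float64)
    S_out = np.asarray(S_out, dtype=np.float64)
    if Y.shape != S_out.shape:
        raise ValueError(f"shape mismatch: Y {Y.shape} vs S_out {S_out.shape}")
    ratio = np.zeros_like(Y)
    pos = Y > 0
    ratio[pos] = Y[pos] * np.log(Y[pos] / (S_out[pos] + EPS))
    return float(ratio.sum(axis=-1).mean())


def adv_loss_generator(D_p: np.ndarray, D_r: np.ndarray) -> float:
    """Inverted-label adversarial loss: mean(-log D_p - log(1 - D_r)).

    ``D_p``/``D_r`` are the domain classifier's probabilities on pseudospots
    and real spots.  Minimizing this w.r.t. the embedder pushes the
    classifier toward mistaking each domain for the other.
    """
    D_p = np.clip(np.asarray(D_p, dtype=np.float64), EPS, 1 - EPS)
    D_r = np.clip(np.asarray(D_r, dtype=np.float64), EPS, 1 - EPS)
    return float(np.mean(-np.log(D_p)) + np.mean(-np.log(1.0 - D_r)))


def adv_loss_discriminator(D_r: np.ndarray, D_p: np.ndarray) -> float:
    """Domain classifier loss: mean(-log D_r - log(1 - D_p))."""
    return adv_loss_generator(D_r, D_p)


def total_loss(Y: np.ndarray, S_out: np.ndarray, D_p: np.ndarray, D_r: np.ndarray, alpha: float) -> float:
    """Phase-A objective L_s + alpha * L_adv,1."""
    return kld_source_loss(Y, S_out) + alpha * adv_loss_generator(D_p, D_r)
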