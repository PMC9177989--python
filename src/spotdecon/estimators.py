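"""Scikit-learn style estimators wrapping the adversarial deconvolution model.

:class:`MixtureFractionRegressor` is the plain fraction predictor trained on
labelled pseudospots only (the ``NN_wo_da`` ablation baseline);
:class:`AdversarialDeconvolver` additionally runs the two-phase adversarial
adaptation against an unlabelled target matrix of real spots.  Both follow
sklearn conventions (``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``n_features_in_``) so they compose with
``sklearn.base.clone`` and model-selection utilities.

Inputs are samples x features arrays of min-max scaled ([0, 1]) expression
over a shared marker panel; ``Y`` rows are cell-type fractions summing to 1.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import losses
from .containers import PseudospotBatch
from .networks import AdversarialNet
from .trainer import TrainingConfig, adversarial_train, pretrain_source

__all__ = ["MixtureFractionRegressor", "AdversarialDeconvolver"]


def _validate_xy(X, Y):
    X = check_array(X, dtype=np.float64)
    Y = check_array(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if np.any(Y < 0) or not np.allclose(Y.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Y rows must be non-negative and sum to 1")
    if X.size and (X.min() < -1e-6 or X.max() > 1 + 1e-6):
        raise ValueError("X must be min-max scaled to [0, 1]")
    return X, Y


class MixtureFractionRegressor(BaseEstimator):
    """Cell-fraction predictor trained on pseudospots without domain adaptation.

    Parameters
    ----------
    pretrain_epochs : int
        Epochs of minibatch KLD minimization over the pseudospot set.
    batch_size, lr_main : minibatch size and Adam learning rate.
    embed_dims : (hidden, embedding) widths of the feature embedder.
    dropout_rate : dropout in the (unused here) domain classifier.
    random_state : seeds initialization, shuffling and dropout.

    Attributes
    ----------
    network_ : AdversarialNet
        The fitted numpy network (domain classifier left at initialization).
    n_features_in_ : int
    n_types_ : int
    history_ : dict
        Loss trajectories recorded during fitting.
    """

    def __init__(
        self,
        iterations: int = 3000,
        batch_size: int = 512,
        lr_main: float = 0.001,
        lr_domain: float = 0.005,
        alpha: float = 0.6,
        pretrain_epochs: int = 10,
        embed_dims: tuple[int, int] = (1024, 64),
        domain_hidden: int = 32,
        dropout_rate: float = 0.5,
        random_state: int = 0,
        check_freeze: bool = False,
    ):
        self.iterations = iterations
        self.batch_size = batch_size
        self.lr_main = lr_main
        self.lr_domain = lr_domain
        self.alpha = alpha
        self.pretrain_epochs = pretrain_epochs
        self.embed_dims = embed_dims
        self.domain_hidden = domain_hidden
        self.dropout_rate = dropout_rate
        self.random_state = random_state
        self.check_freeze = check_freeze

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            iterations=self.iterations,
            batch_size=self.batch_size,
            lr_domain=self.lr_domain,
            lr_main=self.lr_main,
            alpha=self.alpha,
            pretrain_epochs=self.pretrain_epochs,
            seed=self.random_state,
            check_freeze=self.check_freeze,
        )

    def _init_network(self, n_genes: int, n_types: int) -> AdversarialNet:
        return AdversarialNet(
            n_genes,
            n_types,
            alpha=self.alpha,
            seed=self.random_state,
            embed_dims=tuple(self.embed_dims),
            domain_hidden=self.domain_hidden,
            dropout_rate=self.dropout_rate,
        )

    @staticmethod
    def _as_batch(X, Y) -> PseudospotBatch:
        n_genes = X.shape[1]
        return PseudospotBatch(
            X=X,
            Y=Y,
            gene_ids=[f"feature_{i}" for i in range(n_genes)],
            cell_type_order=[f"type_{j}" for j in range(Y.shape[1])],
            k_cells=1,
            provenance=[],
        )

    def fit(self, X, Y):
        X, Y = _validate_xy(X, Y)
        self.n_features_in_ = X.shape[1]
        self.n_types_ = Y.shape[1]
        self.network_ = self._init_network(X.shape[1], Y.shape[1])
        pretrain_source(self.network_, self._as_batch(X, Y), self._config())
        self.history_ = self.network_.history_
        return self

    def predict(self, X) -> np.ndarray:
        """Row-stochastic (n_samples, n_types) fraction matrix."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fitted on {self.n_features_in_}"
            )
        return self.network_.predict_proportions(X)

    def score(self, X, Y) -> float:
        """Negative mean KL divergence between Y and predictions (higher is better)."""
        return -losses.kld_source_loss(np.asarray(Y, dtype=np.float64), self.predict(X))


class AdversarialDeconvolver(MixtureFractionRegressor):
    """Full model: pretraining plus two-phase adversarial domain adaptation.

    ``fit(X, Y, X_target)`` pretrains on the labelled pseudospots ``(X, Y)``
    and then alternates the adversarial phases against the unlabelled real
    spots ``X_target``; ``predict`` maps scaled spot expression to
    cell-type fractions.
    """

    def fit(self, X, Y, X_target=None):
        if X_target is None:
            raise ValueError("AdversarialDeconvolver.fit requires X_target (real spots)")
        X, Y = _validate_xy(X, Y)
        X_target = check_array(X_target, dtype=np.float64)
        if X_target.shape[1] != X.shape[1]:
            raise ValueError("X and X_target must share the same gene panel")
        self.n_features_in_ = X.shape[1]
        self.n_types_ = Y.shape[1]
        self.network_ = self._init_network(X.shape[1], Y.shape[1])
        cfg = self._config()
        batch = self._as_batch(X, Y)
        pretrain_source(self.network_, batch, cfg)

        from .containers import CountMatrix, LayerTag

        spots = CountMatrix(
            X_target.T,
            gene_ids=batch.gene_ids,
            sample_ids=[f"spot_{i}" for i in range(X_target.shape[0])],
            layer_tag=LayerTag.SCALED01,
        )
        adversarial_train(self.network_, batch, spots, cfg)
        self.history_ = self.network_.history_
        return self
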