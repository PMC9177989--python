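"""Numpy implementation of the adversarial deconvolution network.

Architecture:

* feature embedder ``f``: genes -> 1024 -> 64, each stage an affine layer
  followed by batch normalization and ELU activation;
* source classifier ``S``: a single affine layer 64 -> K with softmax
  output (predicted cell-type fractions);
* domain classifier ``D``: 64 -> 32 affine + batch normalization + ELU +
  dropout, then 32 -> 1 affine with sigmoid output (probability the input
  is from the labelled/pseudospot side in phase B's convention).

The embedder is literally shared: the same parameter arrays feed both the
S path and the D path.  Layers are implemented functionally (forward
returns a cache, backward consumes it) so the embedder can be forwarded
several times per optimization step and gradients accumulated.

Affine weights use Glorot-uniform initialization with zero biases;
batch-norm starts at gamma=1, beta=0.  Everything is reproducible from the
construction seed; computations run in float32 for speed with float64
conversion at the prediction boundary.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np

DTYPE = np.float32
BN_EPS = 1e-5
BN_MOMENTUM = 0.9  # running = momentum * running + (1 - momentum) * batch
ELU_ALPHA = 1.0

__all__ = ["AdversarialNet", "Adam", "softmax", "sigmoid", "init_model"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    ez = np.exp(t[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, update_stats, rng):
        return x @ self.W + self.b, x

    def backward(self, dout, cache):
        x = cache
        dW = x.T @ dout
        db = dout.sum(axis=0)
        return dout @ self.W.T, [dW, db]

    @property
    def state(self):
        return []


class BatchNorm:
    def __init__(self, n: int):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def state(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training, update_stats, rng):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            if update_stats:
                self.running_mean *= BN_MOMENTUM
                self.running_mean += (1 - BN_MOMENTUM) * mu
                self.running_var *= BN_MOMENTUM
                self.running_var += (1 - BN_MOMENTUM) * var
        else:
            mu = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mu) * inv_std
        return self.gamma * xhat + self.beta, (xhat, inv_std, training)

    def backward(self, dout, cache):
        xhat, inv_std, training = cache
        dgamma = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        if training:
            B = xhat.shape[0]
            dx = (inv_std / B) * (
                B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            dx = dxhat * inv_std
        return dx, [dgamma, dbeta]


class ELU:
    params: list = []
    state: list = []

    def forward(self, x, training, update_stats, rng):
        neg = x < 0
        out = x.copy()
        out[neg] = ELU_ALPHA * (np.exp(x[neg]) - 1.0)
        return out, (neg, out)

    def backward(self, dout, cache):
        neg, out = cache
        dx = dout.copy()
        dx[neg] *= out[neg] + ELU_ALPHA
        return dx, []


class Dropout:
    params: list = []
    state: list = []

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, update_stats, rng):
        if not training or self.rate == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= self.rate).astype(DTYPE) / (1.0 - self.rate)
        return x * mask, mask

    def backward(self, dout, cache):
        if cache is None:
            return dout, []
        return dout * cache, []


class _Block:
    """A sequential stack of layers with cached forward/backward."""

    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def state(self):
        return [s for layer in self.layers for s in layer.state]

    def forward(self, x, training=False, update_stats=False, rng=None):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, training, update_stats, rng)
            caches.append(cache)
        return x, caches

    def backward(self, dout, caches, collect_grads=True):
        grads = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dout, g = layer.backward(dout, cache)
            if collect_grads:
                grads = g + grads
        return dout, grads

    def hash(self) -> str:
        h = hashlib.sha256()
        for arr in self.params + self.state:
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class AdversarialNet:
    """Shared embedder + source classifier + domain classifier.

    Parameters
    ----------
    n_genes
        Size of the input marker panel.
    n_types
        Number of cell types (softmax output width of S).
    alpha
        Weight of the adversarial term in the phase-A loss
        ``L_s + alpha * L_adv,1``.
    seed
        Seeds both parameter initialization and the dropout stream.
    """

    def __init__(
        self,
        n_genes: int,
        n_types: int,
        alpha: float = 0.6,
        seed: int = 0,
        embed_dims: tuple[int, int] = (1024, 64),
        domain_hidden: int = 32,
        dropout_rate: float = 0.5,
    ):
        if n_genes < 1 or n_types < 2:
            raise ValueError("need n_genes >= 1 and n_types >= 2")
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.n_genes, self.n_types = int(n_genes), int(n_types)
        self.alpha = float(alpha)
        self.seed = int(seed)
        self.embed_dims = tuple(int(d) for d in embed_dims)
        self.domain_hidden = int(domain_hidden)
        self.dropout_rate = float(dropout_rate)

        init_rng = np.random.default_rng(seed)
        h1, h2 = self.embed_dims
        self.f = _Block([
            Dense(n_genes, h1, init_rng), BatchNorm(h1), ELU(),
            Dense(h1, h2, init_rng), BatchNorm(h2), ELU(),
        ])
        self.S = _Block([Dense(h2, n_types, init_rng)])
        self.D = _Block([
            Dense(h2, domain_hidden, init_rng), BatchNorm(domain_hidden), ELU(),
            Dropout(dropout_rate), Dense(domain_hidden, 1, init_rng),
        ])
        self.dropout_rng = np.random.default_rng(init_rng.integers(2**31))

    # ---- forward passes -------------------------------------------------
    def embed(self, X, training=False, update_stats=False):
        X = np.asarray(X, dtype=DTYPE)
        return self.f.forward(X, training=training, update_stats=update_stats)

    def source_logits(self, E, training=False):
        return self.S.forward(E, training=training)

    def domain_logits(self, E, training=False, update_stats=False):
        out, caches = self.D.forward(
            E, training=training, update_stats=update_stats, rng=self.dropout_rng
        )
        return out[:, 0], caches

    def predict_proportions(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode cell-fraction prediction; rows sum to 1."""
        E, _ = self.embed(X, training=False)
        logits, _ = self.source_logits(E, training=False)
        return softmax(logits.astype(np.float64))

    def predict_domain(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode domain probability for each sample."""
        E, _ = self.embed(X, training=False)
        t, _ = self.domain_logits(E, training=False)
        return sigmoid(t.astype(np.float64))

    # ---- bookkeeping ----------------------------------------------------
    def hashes(self) -> dict[str, str]:
        """Content hashes of the three parameter blocks (incl. BN statistics)."""
        return {"f": self.f.hash(), "S": self.S.hash(), "D": self.D.hash()}

    def save(self, path: str) -> None:
        """Single-file versioned checkpoint; load -> predict reproduces outputs."""
        arrays = {}
        for name, block in (("f", self.f), ("S", self.S), ("D", self.D)):
            for i, p in enumerate(block.params):
                arrays[f"{name}_p{i}"] = p
            for i, s in enumerate(block.state):
                arrays[f"{name}_s{i}"] = s
        config = json.dumps({
            "format_version": 1,
            "n_genes": self.n_genes, "n_types": self.n_types,
            "alpha": self.alpha, "seed": self.seed,
            "embed_dims": list(self.embed_dims),
            "domain_hidden": self.domain_hidden,
            "dropout_rate": self.dropout_rate,
        })
        np.savez(path, __config__=np.frombuffer(config.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "AdversarialNet":
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            if config.get("format_version") != 1:
                raise ValueError("unsupported checkpoint version")
            net = cls(
                config["n_genes"], config["n_types"], alpha=config["alpha"],
                seed=config["seed"], embed_dims=tuple(config["embed_dims"]),
                domain_hidden=config["domain_hidden"],
                dropout_rate=config["dropout_rate"],
            )
            for name, block in (("f", net.f), ("S", net.S), ("D", net.D)):
                for i, p in enumerate(block.params):
                    p[...] = data[f"{name}_p{i}"]
                for i, s in enumerate(block.state):
                    s[...] = data[f"{name}_s{i}"]
        return net


def init_model(n_genes: int, n_types: int, alpha: float = 0.6, seed: int = 0, **kwargs) -> AdversarialNet:
    """Construct a freshly initialized :class:`AdversarialNet` (64-dim embedding)."""
    return AdversarialNet(n_genes, n_types, alpha=alpha, seed=seed, **kwargs)
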