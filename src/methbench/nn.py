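"""Compact feed-forward networks for methylation classification.

Three architectures, written directly in numpy with explicit backprop and
an Adam optimizer:

* ``SimpleDNN`` — a small fully-connected classifier on N selected CpGs,
  ending in a single sigmoid node trained with binary cross-entropy.
* ``JointAE`` — a fully-connected autoencoder (encoder N-128-64, bottleneck
  32, decoder 64-128-N) whose 32-unit code also feeds a small classifier
  head; the total loss is w * reconstruction + (1 - w) * classification.
* ``JointVAE`` — the variational variant: the bottleneck is a 32-unit
  Gaussian sampling layer, and the total loss is reconstruction + KL
  divergence + c * classification.

Reconstruction loss follows the input scale: squared error for M-values,
binary cross-entropy for beta-values (whose decoder output is a sigmoid).
Default training schedule: batch size 128, Adam at learning rate 1e-4,
and 1000 / 2000 / 2250 epochs for the DNN / joint AE / joint VAE; the
``epochs`` argument scales this down for desk-size experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SimpleDNN",
    "JointAE",
    "JointVAE",
    "joint_ae_total_loss",
    "vae_total_loss",
    "gaussian_kl",
]


# ----------------------------------------------------------------------
# loss combinators (exposed because the composite objective is the point)

def joint_ae_total_loss(recon: float, clf: float, w: float) -> float:
    """Weighted average of reconstruction and classification losses."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("loss weight w must lie in [0, 1]")
    return w * recon + (1.0 - w) * clf


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(N(mu, sigma^2) || N(0, 1)) summed over latent units, averaged
    over the batch: -0.5 * sum(1 + log sigma^2 - mu^2 - sigma^2)."""
    kl_per = -0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar), axis=-1)
    return float(np.mean(kl_per))


def vae_total_loss(recon: float, kl: float, clf: float, c: float) -> float:
    """Sum of reconstruction, KL and classification loss scaled by c."""
    if kl < 0:
        raise ValueError("KL divergence cannot be negative")
    return recon + kl + c * clf


# ----------------------------------------------------------------------
# layers

def _act(name, z):
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return expit(z)
    if name == "tanh":
        return np.tanh(z)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name, z, a):
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "tanh":
        return 1.0 - a ** 2
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(name)


class _Dense:
    """Fully-connected layer with activation and optional L2 penalty."""

    def __init__(self, n_in, n_out, activation, rng, l2=0.0):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.l2 = l2
        self._x = self._z = self._a = None

    def forward(self, x):
        self._x = x
        self._z = x @ self.W + self.b
        self._a = _act(self.activation, self._z)
        return self._a

    def backward(self, grad_a):
        dz = grad_a * _act_grad(self.activation, self._z, self._a)
        self.dW = self._x.T @ dz + self.l2 * 2.0 * self.W
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def backward_from_logits(self, dz):
        """Backward pass when the loss gradient is already w.r.t. z."""
        self.dW = self._x.T @ dz + self.l2 * 2.0 * self.W
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class _Adam:
    def __init__(self, layers, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for l in layers for p in l.params]
        self.v = [np.zeros_like(p) for l in layers for p in l.params]
        self.t = 0

    def step(self):
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
                mhat = self.m[i] / (1 - self.b1 ** self.t)
                vhat = self.v[i] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


def _bce(p, y):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _check_inputs(X, y=None):
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("NaN in features")
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        return X, y
    return X


def _minibatches(n, batch_size, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


class SimpleDNN:
    """Small fully-connected classifier: N -> 64 -> 16 -> 1 (sigmoid)."""

    default_epochs = 1000

    def __init__(self, n_features, hidden=(64, 16), lr=1e-4, l2=1e-4,
                 dropout=0.0, seed=0):
        rng = np.random.default_rng(seed)
        self.rng = rng
        widths = [n_features, *hidden]
        self.layers = [_Dense(widths[i], widths[i + 1], "relu", rng, l2=l2)
                       for i in range(len(widths) - 1)]
        self.out = _Dense(widths[-1], 1, "linear", rng, l2=l2)
        self.dropout = dropout
        self.lr = lr
        self._all = [*self.layers, self.out]

    def _forward(self, X, training=False):
        h = X
        self._masks = []
        for layer in self.layers:
            h = layer.forward(h)
            if training and self.dropout > 0:
                mask = (self.rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        logits = self.out.forward(h).ravel()
        return logits

    def fit(self, X, y, epochs=None, batch_size=128, verbose=False):
        X, y = _check_inputs(X, y)
        epochs = self.default_epochs if epochs is None else epochs
        opt = _Adam(self._all, lr=self.lr)
        n = X.shape[0]
        for epoch in range(epochs):
            for batch in _minibatches(n, batch_size, self.rng):
                xb, yb = X[batch], y[batch]
                logits = self._forward(xb, training=True)
                p = expit(logits)
                loss = _bce(p, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"loss diverged at epoch {epoch}")
                dlogits = ((p - yb) / len(yb))[:, None]
                g = self.out.backward_from_logits(dlogits)
                for layer, mask in zip(reversed(self.layers),
                                       reversed(self._masks)):
                    if mask is not None:
                        g = g * mask
                    g = layer.backward(g)
                opt.step()
        return self

    def score(self, X):
        """Per-sample case probability in [0, 1]."""
        X = _check_inputs(X)
        return expit(self._forward(X, training=False))


class JointAE:
    """Joint autoencoder-classifier with a 32-unit bottleneck.

    Encoder N-128-64-32, decoder 32-64-128-N, classifier head 32-16-1.
    The decoder output is a sigmoid trained with binary cross-entropy for
    beta-scale input and linear with squared error for M-scale input.
    Total loss: w * reconstruction + (1 - w) * classification.
    """

    default_epochs = 2000

    def __init__(self, n_features, scale="M", loss_weight=0.5, lr=1e-4,
                 l2=0.0, seed=0):
        if scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")
        if not 0.0 <= loss_weight <= 1.0:
            raise ValueError("loss_weight must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.scale = scale
        self.w = loss_weight
        self.lr = lr
        self.encoder = [_Dense(n_features, 128, "relu", rng, l2=l2),
                        _Dense(128, 64, "relu", rng, l2=l2),
                        _Dense(64, 32, "linear", rng, l2=l2)]
        dec_out_act = "sigmoid" if scale == "beta" else "linear"
        self.decoder = [_Dense(32, 64, "relu", rng, l2=l2),
                        _Dense(64, 128, "relu", rng, l2=l2),
                        _Dense(128, n_features, dec_out_act, rng, l2=l2)]
        self.head = [_Dense(32, 16, "relu", rng, l2=l2),
                     _Dense(16, 1, "linear", rng, l2=l2)]
        self._all = [*self.encoder, *self.decoder, *self.head]

    def _encode(self, X):
        h = X
        for layer in self.encoder:
            h = layer.forward(h)
        return h

    def _decode(self, z):
        h = z
        for layer in self.decoder:
            h = layer.forward(h)
        return h

    def _classify(self, z):
        h = z
        for layer in self.head:
            h = layer.forward(h)
        return h.ravel()

    def _recon_loss_grad(self, xhat, x):
        n_elem = x.size
        if self.scale == "M":
            loss = float(np.mean((xhat - x) ** 2))
            # gradient w.r.t. the decoder's linear output
            dz = 2.0 * (xhat - x) / n_elem
        else:
            p = np.clip(xhat, 1e-12, 1 - 1e-12)
            loss = float(-np.mean(x * np.log(p) + (1 - x) * np.log(1 - p)))
            dz = (xhat - x) / n_elem  # sigmoid + BCE combined gradient
        return loss, dz

    def fit(self, X, y, epochs=None, batch_size=128, verbose=False):
        X, y = _check_inputs(X, y)
        if self.scale == "beta" and (X.min() < 0 or X.max() > 1):
            raise ValueError("beta-scale model requires values in [0, 1]")
        epochs = self.default_epochs if epochs is None else epochs
        opt = _Adam(self._all, lr=self.lr)
        n = X.shape[0]
        self.history = []
        for epoch in range(epochs):
            ep_loss = 0.0
            for batch in _minibatches(n, batch_size, self.rng):
                xb, yb = X[batch], y[batch]
                z = self._encode(xb)
                xhat = self._decode(z)
                logits = self._classify(z)
                p = expit(logits)
                recon, d_dec_out = self._recon_loss_grad(xhat, xb)
                clf = _bce(p, yb)
                total = joint_ae_total_loss(recon, clf, self.w)
                if not np.isfinite(total):
                    raise FloatingPointError(f"loss diverged at epoch {epoch}")
                ep_loss += total
                # backward: decoder branch (w) -------------------------------
                g = self.w * d_dec_out
                g = self.decoder[-1].backward_from_logits(g)
                for layer in reversed(self.decoder[:-1]):
                    g = layer.backward(g)
                dz_dec = g
                # classifier branch (1 - w) ----------------------------------
                dlogits = (1.0 - self.w) * ((p - yb) / len(yb))[:, None]
                g = self.head[-1].backward_from_logits(dlogits)
                for layer in reversed(self.head[:-1]):
                    g = layer.backward(g)
                dz_head = g
                # encoder -----------------------------------------------------
                g = dz_dec + dz_head
                for layer in reversed(self.encoder):
                    g = layer.backward(g)
                opt.step()
            self.history.append(ep_loss)
        return self

    def score(self, X):
        X = _check_inputs(X)
        return expit(self._classify(self._encode(X)))

    def reconstruct(self, X):
        X = _check_inputs(X)
        return self._decode(self._encode(X))

    def reconstruction_quality(self, X) -> float:
        """Pearson correlation between flattened input and reconstruction."""
        X = _check_inputs(X)
        xhat = self.reconstruct(X)
        return float(np.corrcoef(X.ravel(), xhat.ravel())[0, 1])


class JointVAE:
    """Joint variational autoencoder-classifier (32-unit sampling layer).

    Shared encoder trunk N-128-64, then separate linear maps to the
    32-unit posterior mean and log-variance; the reparameterized sample
    feeds both the decoder and the classifier head.  Total loss:
    reconstruction + KL + c * classification.
    """

    default_epochs = 2250

    def __init__(self, n_features, scale="M", clf_scale=1.0, lr=1e-4,
                 l2=0.0, seed=0):
        if scale not in ("beta", "M"):
            raise ValueError("scale must be 'beta' or 'M'")
        if clf_scale <= 0:
            raise ValueError("clf_scale must be positive")
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.scale = scale
        self.c = clf_scale
        self.lr = lr
        self.n_features = n_features
        self.trunk = [_Dense(n_features, 128, "relu", rng, l2=l2),
                      _Dense(128, 64, "relu", rng, l2=l2)]
        self.mu_layer = _Dense(64, 32, "linear", rng, l2=l2)
        self.logvar_layer = _Dense(64, 32, "linear", rng, l2=l2)
        dec_out_act = "sigmoid" if scale == "beta" else "linear"
        self.decoder = [_Dense(32, 64, "relu", rng, l2=l2),
                        _Dense(64, 128, "relu", rng, l2=l2),
                        _Dense(128, n_features, dec_out_act, rng, l2=l2)]
        self.head = [_Dense(32, 16, "relu", rng, l2=l2),
                     _Dense(16, 1, "linear", rng, l2=l2)]
        self._all = [*self.trunk, self.mu_layer, self.logvar_layer,
                     *self.decoder, *self.head]

    def _encode(self, X):
        h = X
        for layer in self.trunk:
            h = layer.forward(h)
        return self.mu_layer.forward(h), self.logvar_layer.forward(h)

    def _decode(self, z):
        h = z
        for layer in self.decoder:
            h = layer.forward(h)
        return h

    def _classify(self, z):
        h = z
        for layer in self.head:
            h = layer.forward(h)
        return h.ravel()

    def _recon_loss_grad(self, xhat, x):
        # summed over features, averaged over batch (standard VAE scaling,
        # keeps reconstruction and KL on comparable scales)
        nb = x.shape[0]
        if self.scale == "M":
            loss = float(np.sum((xhat - x) ** 2) / nb)
            dz = 2.0 * (xhat - x) / nb
        else:
            p = np.clip(xhat, 1e-12, 1 - 1e-12)
            loss = float(-np.sum(x * np.log(p) + (1 - x) * np.log(1 - p)) / nb)
            dz = (xhat - x) / nb
        return loss, dz

    def fit(self, X, y, epochs=None, batch_size=128, verbose=False):
        X, y = _check_inputs(X, y)
        epochs = self.default_epochs if epochs is None else epochs
        opt = _Adam(self._all, lr=self.lr)
        n = X.shape[0]
        self.history = []
        for epoch in range(epochs):
            ep_loss = 0.0
            for batch in _minibatches(n, batch_size, self.rng):
                xb, yb = X[batch], y[batch]
                nb = len(batch)
                mu, logvar = self._encode(xb)
                logvar = np.clip(logvar, -10.0, 10.0)
                sigma = np.exp(0.5 * logvar)
                eps = self.rng.standard_normal(mu.shape)
                z = mu + sigma * eps
                xhat = self._decode(z)
                logits = self._classify(z)
                p = expit(logits)
                recon, d_dec_out = self._recon_loss_grad(xhat, xb)
                kl = gaussian_kl(mu, logvar)
                clf = _bce(p, yb)
                total = vae_total_loss(recon, kl, clf, self.c)
                if not np.isfinite(total):
                    raise FloatingPointError(f"loss diverged at epoch {epoch}")
                ep_loss += total
                # decoder branch
                g = self.decoder[-1].backward_from_logits(d_dec_out)
                for layer in reversed(self.decoder[:-1]):
                    g = layer.backward(g)
                dz_dec = g
                # classifier branch
                dlogits = self.c * ((p - yb) / nb)[:, None]
                g = self.head[-1].backward_from_logits(dlogits)
                for layer in reversed(self.head[:-1]):
                    g = layer.backward(g)
                dz_head = g
                dz = dz_dec + dz_head
                # reparameterization + KL gradients
                dmu = dz + mu / nb
                dlogvar = dz * eps * 0.5 * sigma - 0.5 * (1.0 - np.exp(logvar)) / nb
                g_mu = self.mu_layer.backward(dmu)
                g_lv = self.logvar_layer.backward(dlogvar)
                g = g_mu + g_lv
                for layer in reversed(self.trunk):
                    g = layer.backward(g)
                opt.step()
            self.history.append(ep_loss)
        return self

    def score(self, X):
        """Case probability from the posterior mean (no sampling)."""
        X = _check_inputs(X)
        mu, _ = self._encode(X)
        return expit(self._classify(mu))

    def reconstruct(self, X):
        X = _check_inputs(X)
        mu, _ = self._encode(X)
        return self._decode(mu)

    def reconstruction_quality(self, X) -> float:
        X = _check_inputs(X)
        xhat = self.reconstruct(X)
        return float(np.corrcoef(X.ravel(), xhat.ravel())[0, 1])
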