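"""Minimal dense neural-network building blocks for the latent benchmark.

Implements exactly what the gene-subset benchmark needs and nothing
more: fully connected layers with ReLU, input dropout, a batch-normalized
linear latent layer, mean-squared-error reconstruction, the
linked-latent penalty, and the Adam optimizer — all in numpy with
explicit backward passes.  Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np


class TrainingError(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Dense:
    """Affine layer with optional ReLU."""

    def __init__(self, n_in: int, n_out: int, relu: bool,
                 rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.W = _Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = _Param(np.zeros(n_out))
        self.relu = relu

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        h = x @ self.W.value + self.b.value
        if self.relu:
            self._mask = h > 0
            h = h * self._mask
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = grad * self._mask
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Dropout:
    """Inverted dropout on the input features."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm:
    """Per-feature batch normalization with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        self.gamma = _Param(np.ones(dim))
        self.beta = _Param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        if not self._train:
            return g / std
        n = grad.shape[0]
        return (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) / std


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


class Autoencoder:
    """Symmetric dense autoencoder with a batch-normalized linear latent.

    Encoder: Dropout(rate) → [Dense+ReLU] × len(hidden) → Dense(d, linear)
    → BatchNorm (the latent representation).  Decoder mirrors the hidden
    stack and ends in a linear reconstruction layer.
    """

    def __init__(self, input_dim: int, hidden_widths: tuple[int, ...],
                 latent_dim: int, input_dropout: float, seed: int,
                 lr: float = 1e-3) -> None:
        if latent_dim < 2:
            raise ValueError("latent dimension must be ≥ 2")
        rng = np.random.default_rng(seed)
        self.rng = rng
        enc: list = [Dropout(input_dropout, rng)]
        d_prev = input_dim
        for w in hidden_widths:
            enc.append(Dense(d_prev, w, relu=True, rng=rng))
            d_prev = w
        enc.append(Dense(d_prev, latent_dim, relu=False, rng=rng))
        enc.append(BatchNorm(latent_dim))
        dec: list = []
        d_prev = latent_dim
        for w in reversed(hidden_widths):
            dec.append(Dense(d_prev, w, relu=True, rng=rng))
            d_prev = w
        dec.append(Dense(d_prev, input_dim, relu=False, rng=rng))
        self.encoder, self.decoder = enc, dec
        params = [p for layer in enc + dec for p in layer.params]
        self.opt = Adam(params, lr=lr)
        self.latent_dim = latent_dim

    # -- passes -------------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool):
        h = x
        for layer in self.encoder:
            h = layer.forward(h, train)
        z = h
        for layer in self.decoder:
            h = layer.forward(h, train)
        return z, h

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent coordinates in inference mode (running batch statistics)."""
        h = x
        for layer in self.encoder:
            h = layer.forward(h, train=False)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x, train=False)[1]

    # -- training -----------------------------------------------------------
    def _step(self, xb: np.ndarray, z_target: np.ndarray | None,
              lam: float) -> tuple[float, float]:
        """One Adam step; returns (reconstruction MSE, latent penalty C)."""
        self.opt.zero_grad()
        z, recon = self._forward(xb, train=True)
        n, d_in = xb.shape
        diff = recon - xb
        R = float((diff ** 2).mean())
        grad_recon = 2.0 * diff / diff.size
        C = 0.0
        grad_z_extra = None
        if z_target is not None and lam > 0:
            zdiff = z - z_target
            C = float((zdiff ** 2).mean())
            grad_z_extra = lam * 2.0 * zdiff / zdiff.size
            # variance-floor along the narrowest principal direction of
            # the z batch: penalty (σ_min − 1)²
            if n > self.latent_dim:
                zc = z - z.mean(axis=0)
                A = zc / np.sqrt(n - 1)
                U, S, Vt = np.linalg.svd(A, full_matrices=False)
                k = int(np.argmin(S))
                s_min = float(S[k])
                C += (s_min - 1.0) ** 2
                # d s_min / dA = u_k v_k^T; centering projects out row means
                gA = 2.0 * (s_min - 1.0) * np.outer(U[:, k], Vt[k])
                gz = gA / np.sqrt(n - 1)
                gz = gz - gz.mean(axis=0)
                grad_z_extra = grad_z_extra + lam * gz
        if not np.isfinite(R) or not np.isfinite(C):
            raise TrainingError("non-finite loss; try a lower learning rate")
        # backward through decoder, add latent-penalty gradient, then encoder
        g = grad_recon
        for layer in reversed(self.decoder):
            g = layer.backward(g)
        if grad_z_extra is not None:
            g = g + grad_z_extra
        for layer in reversed(self.encoder):
            g = layer.backward(g)
        self.opt.step()
        return R, C

    def fit(self, X: np.ndarray, epochs: int, batch_size: int,
            z_target: np.ndarray | None = None, lam: float = 0.0):
        """Train; returns a per-epoch loss report (R, C, λ, L)."""
        n = X.shape[0]
        history = []
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            r_sum = c_sum = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                if idx.size < 2:
                    continue
                zt = z_target[idx] if z_target is not None else None
                R, C = self._step(X[idx], zt, lam)
                r_sum += R
                c_sum += C
                n_batches += 1
            history.append({
                "epoch": epoch,
                "R": r_sum / max(n_batches, 1),
                "C": c_sum / max(n_batches, 1),
                "lambda": lam,
            })
            history[-1]["L"] = history[-1]["R"] + lam * history[-1]["C"]
        return history
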