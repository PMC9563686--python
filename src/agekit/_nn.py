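"""Minimal feed-forward building blocks with manual backpropagation.

Just enough machinery for the package's variational autoencoder: dense
layers, batch normalization, ELU, and Adam. Everything is float64 numpy;
forward passes cache what the matching backward pass needs. ``train``
mode uses batch statistics in batch norm and updates running moments;
``eval`` mode uses the running moments, so inference is deterministic.
"""

from __future__ import annotations

import numpy as np


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        # in-place so optimizer-held references stay valid
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._istd
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        # standard batch-norm gradient (Ioffe & Szegedy form)
        m = grad.shape[0]
        xhat, istd = self._xhat, self._istd
        self.dgamma[...] = (grad * xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return (istd / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train: bool):
        self._neg = x < 0
        self._y = np.where(self._neg, self.alpha * np.expm1(x), x)
        return self._y

    def backward(self, grad):
        return grad * np.where(self._neg, self._y + self.alpha, 1.0)

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (value, grad) array pairs, updated in place
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
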