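"""Closed-form toy models used as integrated-gradients oracles."""

import numpy as np


class LogisticToy:
    """Softmax regression presented through the model protocol (T=1, C
    features); closed-form losses and input gradients."""

    def __init__(self, W, b):
        self.W = np.asarray(W, dtype=float)  # (C, F)
        self.b = np.asarray(b, dtype=float)

    def _probs(self, X):
        z = X[:, 0, :] @ self.W + self.b
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def sample_losses(self, X, y):
        p = self._probs(X)
        return -np.log(p[np.arange(len(X)), y] + 1e-300)

    def input_gradients(self, X, y):
        p = self._probs(X)
        d = p - np.eye(self.W.shape[1])[y]
        return (d @ self.W.T)[:, None, :]


class LinearToy:
    """L(x) = w . x — constant gradient, so IG must equal x * w exactly."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)  # (T, C)

    def sample_losses(self, X, y):
        return np.sum(X * self.w, axis=(1, 2))

    def input_gradients(self, X, y):
        return np.broadcast_to(self.w, X.shape).copy()


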