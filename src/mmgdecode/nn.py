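"""Residual 1-D convolutional classifier, implemented in NumPy.

Architecture (input is a batch of T x C envelope windows; convolution runs
along the time axis with channels as feature maps):

    input (T x C)
      -> residual block:
           pointwise conv (128 filters, stride 1, no bias) -> BN -> GELU
           -> conv (kernel 3, C filters, stride 1, "same" padding, no bias)
           -> BN -> GELU -> add block input -> GELU
      -> conv (kernel 3, 16 filters, stride 2, "same" padding, with bias) -> GELU
      -> flatten -> dropout 0.1
      -> FC(100) -> GELU -> dropout 0.1
      -> FC(100) -> GELU -> dropout 0.1
      -> FC(3) -> softmax

Training: categorical cross-entropy, Adam (lr 0.01, beta1 0.9, beta2 0.999),
batch size 250, shuffling each epoch. Forward, backward, and the optimizer
are written directly in NumPy: the network is small enough (T=20, C<=8) that
this trains in seconds on one CPU core, and it keeps runs bit-reproducible
from a single integer seed. The backward pass also yields the gradient of
the per-sample loss with respect to the input, which the attribution module
integrates along the baseline path.

Implementation notes: convolutions are unrolled into reshaped 2-D BLAS
matmuls (one per kernel tap); the normal CDF of every GELU pre-activation is
cached in the forward pass and reused by the backward pass; arithmetic runs
in float32 by default (``ModelConfig.dtype``), which does not affect any
stated tolerance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

# python float, not np.float64: a float64 scalar would silently promote
# float32 activations to float64 under NEP 50 promotion rules
_INV_SQRT_2PI = float(1.0 / np.sqrt(2.0 * np.pi))
_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99


def gelu(x: np.ndarray) -> np.ndarray:
    """Gaussian error linear unit: x * Phi(x), Phi the standard normal CDF."""
    return x * ndtr(x)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d/dx gelu(x) = Phi(x) + x * phi(x)."""
    return ndtr(x) + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier and its training protocol."""

    T: int = 20  # window samples (100 ms at 200 Hz)
    C: int = 8  # channels (8 MMG or 4 EMG)
    residual_filters: int = 128
    kernel: int = 3
    head_filters: int = 16
    head_stride: int = 2
    fc_units: int = 100
    n_classes: int = 3
    dropout: float = 0.1
    batch_size: int = 250
    epochs: int = 250
    lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("T", "C", "residual_filters", "kernel", "head_filters",
                     "head_stride", "fc_units", "n_classes", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.T < self.kernel:
            raise ValueError("window shorter than the convolution kernel")


def _same_pad_stride(T: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """TensorFlow-style "same" padding for a strided convolution: output
    length ceil(T/stride); the extra pad sample goes on the right."""
    out = -(-T // stride)
    total = max((out - 1) * stride + kernel - T, 0)
    left = total // 2
    return out, left, total - left


def _gelu_cached(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (gelu(x), Phi(x)); the CDF is reused in the backward pass."""
    phi = ndtr(x)
    return x * phi, phi


def _gelu_grad_cached(x: np.ndarray, phi: np.ndarray) -> np.ndarray:
    return phi + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI


class ResidualConv1DNet:
    """The classifier. Parameters live in a flat dict of NumPy arrays."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        T, C, R = cfg.T, cfg.C, cfg.residual_filters
        K, H = cfg.kernel, cfg.head_filters
        self.t_out, self._pl, self._pr = _same_pad_stride(T, K, cfg.head_stride)
        self.flat = self.t_out * H
        rng = np.random.default_rng(cfg.seed)
        dt = self.dtype

        def init(shape, fan_in):
            return (rng.standard_normal(shape) / np.sqrt(fan_in)).astype(dt)

        self.params: dict[str, np.ndarray] = {
            "W1": init((C, R), C),
            "g1": np.ones(R, dt), "b1": np.zeros(R, dt),
            "W2": init((K, R, C), K * R),
            "g2": np.ones(C, dt), "b2": np.zeros(C, dt),
            "W3": init((K, C, H), K * C),
            "b3": np.zeros(H, dt),
            "Wf1": init((self.flat, cfg.fc_units), self.flat),
            "bf1": np.zeros(cfg.fc_units, dt),
            "Wf2": init((cfg.fc_units, cfg.fc_units), cfg.fc_units),
            "bf2": np.zeros(cfg.fc_units, dt),
            "Wf3": init((cfg.fc_units, cfg.n_classes), cfg.fc_units),
            "bf3": np.zeros(cfg.n_classes, dt),
        }
        # batch-norm running moments (inference mode)
        self.running: dict[str, np.ndarray] = {
            "m1": np.zeros(R, dt), "v1": np.ones(R, dt),
            "m2": np.zeros(C, dt), "v2": np.ones(C, dt),
        }
        self.loss_curve: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------------ #
    def _bn_forward(self, h, tag, training):
        g, b = self.params[f"g{tag}"], self.params[f"b{tag}"]
        if training:
            mu = h.mean(axis=(0, 1))
            var = h.var(axis=(0, 1))
            self.running[f"m{tag}"] = (
                _BN_MOMENTUM * self.running[f"m{tag}"] + (1 - _BN_MOMENTUM) * mu
            ).astype(h.dtype)
            self.running[f"v{tag}"] = (
                _BN_MOMENTUM * self.running[f"v{tag}"] + (1 - _BN_MOMENTUM) * var
            ).astype(h.dtype)
        else:
            mu = self.running[f"m{tag}"]
            var = self.running[f"v{tag}"]
        inv = (1.0 / np.sqrt(var + _BN_EPS)).astype(h.dtype)
        xhat = (h - mu) * inv
        return g * xhat + b, (xhat, inv, mu, training)

    @staticmethod
    def _bn_backward(dz, cache, h, g):
        xhat, inv, mu, training = cache
        dg = (dz * xhat).sum(axis=(0, 1))
        db = dz.sum(axis=(0, 1))
        dxhat = dz * g
        if not training:
            return dxhat * inv, dg, db
        m = h.shape[0] * h.shape[1]
        hc = h - mu
        dvar = (dxhat * hc).sum(axis=(0, 1)) * (-0.5) * inv**3
        dmu = -(dxhat.sum(axis=(0, 1))) * inv
        dh = dxhat * inv + dvar * (2.0 / m) * hc + dmu * (1.0 / m)
        return dh, dg, db

    # ------------------------------------------------------------------ #
    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None):
        """Forward pass; returns (probabilities, cache)."""
        cfg = self.cfg
        p = self.params
        K, T, C, R = cfg.kernel, cfg.T, cfg.C, cfg.residual_filters
        if x.ndim != 3 or x.shape[1] != T or x.shape[2] != C:
            raise ValueError(f"expected input (N, {T}, {C}), got {x.shape}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        N = len(x)

        h1 = (x.reshape(-1, C) @ p["W1"]).reshape(N, T, R)
        z1, bn1 = self._bn_forward(h1, 1, training)
        a1, phi1 = _gelu_cached(z1)

        pad1 = np.pad(a1, ((0, 0), (K // 2, K // 2), (0, 0)))
        h2 = np.zeros((N, T, C), dtype=self.dtype)
        taps1 = []
        for k in range(K):
            tap = np.ascontiguousarray(pad1[:, k : k + T]).reshape(-1, R)
            taps1.append(tap)
            h2 += (tap @ p["W2"][k]).reshape(N, T, C)
        z2, bn2 = self._bn_forward(h2, 2, training)
        a2, phi2 = _gelu_cached(z2)

        r = x + a2
        a3, phi3 = _gelu_cached(r)

        p3 = np.pad(a3, ((0, 0), (self._pl, self._pr), (0, 0)))
        span = cfg.head_stride * (self.t_out - 1) + 1
        h3 = np.tile(p["b3"], (N, self.t_out, 1))
        taps3 = []
        for k in range(K):
            tap = np.ascontiguousarray(p3[:, k : k + span : cfg.head_stride]).reshape(-1, C)
            taps3.append(tap)
            h3 += (tap @ p["W3"][k]).reshape(N, self.t_out, cfg.head_filters)
        a4, phi4 = _gelu_cached(h3)

        f = a4.reshape(N, self.flat)
        masks = []
        drop = cfg.dropout

        def apply_dropout(v):
            if training and drop > 0.0:
                mask = ((rng.random(v.shape) >= drop) / (1.0 - drop)).astype(self.dtype)
                masks.append(mask)
                return v * mask
            masks.append(None)
            return v

        d1 = apply_dropout(f)
        u1 = d1 @ p["Wf1"] + p["bf1"]
        a5, phi5 = _gelu_cached(u1)
        d2 = apply_dropout(a5)
        u2 = d2 @ p["Wf2"] + p["bf2"]
        a6, phi6 = _gelu_cached(u2)
        d3 = apply_dropout(a6)
        logits = d3 @ p["Wf3"] + p["bf3"]
        probs = softmax(logits.astype(np.float64))

        cache = dict(
            x=x, h1=h1, z1=z1, bn1=bn1, phi1=phi1, taps1=taps1, h2=h2, z2=z2,
            bn2=bn2, phi2=phi2, r=r, phi3=phi3, taps3=taps3, h3=h3, phi4=phi4,
            d1=d1, u1=u1, phi5=phi5, d2=d2, u2=u2, phi6=phi6, d3=d3,
            masks=masks, span=span,
        )
        return probs, cache

    # ------------------------------------------------------------------ #
    def backward(self, cache, dlogits: np.ndarray, param_grads: bool = True):
        """Backpropagate; returns (input gradient, parameter-gradient dict)."""
        cfg = self.cfg
        p = self.params
        K, T, C, R = cfg.kernel, cfg.T, cfg.C, cfg.residual_filters
        dlogits = dlogits.astype(self.dtype)
        N = len(dlogits)
        g: dict[str, np.ndarray] = {}
        m1, m2, m3 = cache["masks"]

        if param_grads:
            g["Wf3"] = cache["d3"].T @ dlogits
            g["bf3"] = dlogits.sum(axis=0)
        d_d3 = dlogits @ p["Wf3"].T
        if m3 is not None:
            d_d3 *= m3
        d_u2 = d_d3 * _gelu_grad_cached(cache["u2"], cache["phi6"])
        if param_grads:
            g["Wf2"] = cache["d2"].T @ d_u2
            g["bf2"] = d_u2.sum(axis=0)
        d_d2 = d_u2 @ p["Wf2"].T
        if m2 is not None:
            d_d2 *= m2
        d_u1 = d_d2 * _gelu_grad_cached(cache["u1"], cache["phi5"])
        if param_grads:
            g["Wf1"] = cache["d1"].T @ d_u1
            g["bf1"] = d_u1.sum(axis=0)
        d_f = d_u1 @ p["Wf1"].T
        if m1 is not None:
            d_f *= m1

        d_a4 = d_f.reshape(N, self.t_out, cfg.head_filters)
        d_h3 = d_a4 * _gelu_grad_cached(cache["h3"], cache["phi4"])
        d_h3f = d_h3.reshape(-1, cfg.head_filters)
        if param_grads:
            g["b3"] = d_h3f.sum(axis=0)
            g["W3"] = np.stack([cache["taps3"][k].T @ d_h3f for k in range(K)])
        d_p3 = np.zeros((N, T + self._pl + self._pr, C), dtype=self.dtype)
        for k in range(K):
            d_p3[:, k : k + cache["span"] : cfg.head_stride] += (
                d_h3f @ p["W3"][k].T
            ).reshape(N, self.t_out, C)
        d_a3 = d_p3[:, self._pl : self._pl + T]

        d_r = d_a3 * _gelu_grad_cached(cache["r"], cache["phi3"])
        dx = d_r.copy()
        d_z2 = d_r * _gelu_grad_cached(cache["z2"], cache["phi2"])
        d_h2, dg2, db2 = self._bn_backward(d_z2, cache["bn2"], cache["h2"], p["g2"])
        d_h2f = d_h2.reshape(-1, C)
        if param_grads:
            g["g2"], g["b2"] = dg2, db2
            g["W2"] = np.stack([cache["taps1"][k].T @ d_h2f for k in range(K)])
        d_pad1 = np.zeros((N, T + 2 * (K // 2), R), dtype=self.dtype)
        for k in range(K):
            d_pad1[:, k : k + T] += (d_h2f @ p["W2"][k].T).reshape(N, T, R)
        d_a1 = d_pad1[:, K // 2 : K // 2 + T]

        d_z1 = d_a1 * _gelu_grad_cached(cache["z1"], cache["phi1"])
        d_h1, dg1, db1 = self._bn_backward(d_z1, cache["bn1"], cache["h1"], p["g1"])
        d_h1f = d_h1.reshape(-1, R)
        if param_grads:
            g["g1"], g["b1"] = dg1, db1
            g["W1"] = cache["x"].reshape(-1, C).T @ d_h1f
        dx += (d_h1f @ p["W1"].T).reshape(N, T, C)
        return dx, g

    # ------------------------------------------------------------------ #
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int | None = None,
        seed: int | None = None,
    ) -> "ResidualConv1DNet":
        """Train with Adam on categorical cross-entropy; records the per-epoch
        mean loss in ``self.loss_curve``. Deterministic given the seed."""
        cfg = self.cfg
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        n = len(X)
        if n == 0:
            raise ValueError("empty training set")
        X = np.ascontiguousarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=int)
        onehot = np.eye(cfg.n_classes)[y]
        bs = min(cfg.batch_size, n)

        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        losses = np.empty(epochs)
        for epoch in range(epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                xb, yb = X[idx], onehot[idx]
                probs, cache = self.forward(xb, training=True, rng=rng)
                loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/Inf loss at epoch {epoch}, step {start // bs}; training diverged"
                    )
                batch_losses.append(loss)
                dlogits = (probs - yb) / len(idx)
                _, grads = self.backward(cache, dlogits, param_grads=True)
                t += 1
                b1c = 1.0 - cfg.beta1**t
                b2c = 1.0 - cfg.beta2**t
                for k, gr in grads.items():
                    m = m_state[k]
                    v = v_state[k]
                    m *= cfg.beta1
                    m += (1 - cfg.beta1) * gr
                    v *= cfg.beta2
                    v += (1 - cfg.beta2) * gr * gr
                    self.params[k] -= (cfg.lr * (m / b1c) / (np.sqrt(v / b2c) + 1e-8)).astype(
                        self.dtype
                    )
            losses[epoch] = np.mean(batch_losses)
        self.loss_curve = losses
        return self

    # ------------------------------------------------------------------ #
    def predict_proba(self, X: np.ndarray, batch: int = 2048) -> np.ndarray:
        """Class probabilities in inference mode (dropout off, BN running
        moments); deterministic."""
        out = np.empty((len(X), self.cfg.n_classes))
        for start in range(0, len(X), batch):
            probs, _ = self.forward(X[start : start + batch], training=False)
            out[start : start + batch] = probs
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # ------------------------------------------------------------------ #
    def save(self, path) -> None:
        """Write a self-describing checkpoint: weights, batch-norm running
        moments, loss curve, and the JSON-encoded configuration."""
        payload = {f"param_{k}": v for k, v in self.params.items()}
        payload |= {f"running_{k}": v for k, v in self.running.items()}
        if self.loss_curve is not None:
            payload["loss_curve"] = self.loss_curve
        payload["config_json"] = np.array(json.dumps(dataclasses.asdict(self.cfg)))
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "ResidualConv1DNet":
        with np.load(path, allow_pickle=False) as data:
            cfg = ModelConfig(**json.loads(str(data["config_json"])))
            net = cls(cfg)
            for k in net.params:
                net.params[k] = data[f"param_{k}"]
            for k in net.running:
                net.running[k] = data[f"running_{k}"]
            if "loss_curve" in data:
                net.loss_curve = data["loss_curve"]
        return net

    # ------------------------------------------------------------------ #
    def sample_losses(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-sample cross-entropy loss at the true label (inference mode)."""
        probs = self.predict_proba(X)
        return -np.log(probs[np.arange(len(X)), np.asarray(y, dtype=int)] + 1e-12)

    def input_gradients(self, X: np.ndarray, y: np.ndarray, batch: int = 2048) -> np.ndarray:
        """Gradient of each sample's loss with respect to its own input
        (inference mode; samples do not interact)."""
        y = np.asarray(y, dtype=int)
        out = np.empty(X.shape)
        for start in range(0, len(X), batch):
            xb = X[start : start + batch]
            yb = y[start : start + batch]
            probs, cache = self.forward(xb, training=False)
            dlogits = probs - np.eye(self.cfg.n_classes)[yb]
            dx, _ = self.backward(cache, dlogits, param_grads=False)
            out[start : start + batch] = dx
        return out
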