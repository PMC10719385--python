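"""Integrated-gradients channel-importance attribution.

For each test window x (a T x C matrix) the sample is interpolated with an
all-zeros baseline at m transparency levels linearly spaced on [0, 1]; the
gradient of the per-sample loss at the true label is taken with respect to
each interpolated input, the gradients are combined by a Riemann-sum average,
and the result is scaled elementwise by (x - baseline).  Per-sample
attribution maps are L1-normalized (so every sample contributes on the same
scale), averaged over the time dimension, and then over the samples of the
test set, giving one importance value per channel per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttributionConfig:
    m: int = 6  # interpolation levels, endpoints included
    baseline: np.ndarray | None = None  # default: all zeros

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 interpolation levels")


@dataclass
class AttributionResult:
    """Per-channel importance for one fold (signed and absolute variants)."""

    signed: np.ndarray  # (C,)
    absolute: np.ndarray  # (C,)
    maps: np.ndarray | None = None  # optional per-sample (N, T, C) attributions


def integrated_gradients(
    model, x: np.ndarray, y: int, baseline: np.ndarray | None = None, m: int = 6
) -> np.ndarray:
    """Integrated gradients of one sample's loss at its true label.

    ``model`` must expose ``input_gradients(X, y)`` returning the gradient of
    each sample's loss with respect to its own input.
    """
    x = np.asarray(x, dtype=float)
    return integrated_gradients_for(model, x[None], np.array([y]), baseline=baseline, m=m)[0]


def integrated_gradients_for(
    model, X: np.ndarray, y: np.ndarray, baseline: np.ndarray | None = None, m: int = 6
) -> np.ndarray:
    """Attribution maps (same shape as X) for a labelled batch.

    attribution_i = (x_i - baseline_i) * mean_k dL(baseline + a_k (x - baseline))/dx_i
    with a_k the m levels linearly spaced on [0, 1], endpoints included.
    """
    if m < 2:
        raise ValueError("need at least 2 interpolation levels")
    X = np.asarray(X, dtype=float)
    if baseline is None:
        baseline = np.zeros(X.shape[1:])
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != X.shape[1:]:
        raise ValueError(f"baseline shape {baseline.shape} != sample shape {X.shape[1:]}")
    alphas = np.linspace(0.0, 1.0, m)
    diff = X - baseline
    grad_sum = np.zeros_like(X)
    for a in alphas:
        grad_sum += model.input_gradients(baseline + a * diff, y)
    return diff * grad_sum / m


def channel_importance(
    model, X: np.ndarray, y: np.ndarray, cfg: AttributionConfig | None = None,
    keep_maps: bool = False,
) -> AttributionResult:
    """Per-channel importance scores for one fold's test set.

    Each sample's T x C attribution map is divided by the sum of its absolute
    values (L1 normalization), averaged across time, then across samples.
    """
    if len(X) == 0:
        raise ValueError("empty test set")
    cfg = cfg or AttributionConfig()
    maps = integrated_gradients_for(model, X, y, baseline=cfg.baseline, m=cfg.m)
    norms = np.sum(np.abs(maps), axis=(1, 2), keepdims=True)
    norms[norms == 0] = 1.0  # all-zero map stays all-zero
    normed = maps / norms
    per_sample_channel = normed.mean(axis=1)  # average over time -> (N, C)
    signed = per_sample_channel.mean(axis=0)
    absolute = np.abs(per_sample_channel).mean(axis=0)
    return AttributionResult(
        signed=signed, absolute=absolute, maps=maps if keep_maps else None
    )
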