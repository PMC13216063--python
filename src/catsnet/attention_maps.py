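"""Gating-weighted class activation maps.

A Grad-CAM variant for the concept-configured network: neuron-importance
weights are the global-average-pooled gradients of the pre-softmax Yes
score with respect to the convolutional feature maps, additionally scaled
by the first-layer gate derived from the active concept:

    alpha_k = g_{1,k} * (1/Z) * sum_ij  d y_Yes / d A^k_ij
    L = ReLU( sum_k alpha_k * A^k )

The backbone producing the feature maps is supplied through an adapter;
a small two-layer convolutional stub is included for testing.  Feature
maps reach the network through global average pooling, so map ``k`` feeds
feature ``k`` and the gradient of the Yes score spreads uniformly over
each map's ``Z = u*v`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndi

from .core_model import CatsNetError, DimensionError

__all__ = [
    "FeatureStack",
    "CAMResult",
    "CapabilityError",
    "gated_gradcam",
    "compute_yes_gradients",
    "yes_score_from_maps",
    "ConvStubAdapter",
]


class CapabilityError(CatsNetError):
    """The backbone adapter cannot provide what was asked of it."""


@dataclass
class FeatureStack:
    """K convolutional feature maps of identical spatial size u x v."""

    A: np.ndarray  # (K, u, v)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 3:
            raise DimensionError("feature stack must be (K, u, v)")

    @property
    def K(self):
        return self.A.shape[0]

    @property
    def Z(self):
        return self.A.shape[1] * self.A.shape[2]


@dataclass
class CAMResult:
    alpha: np.ndarray     # (K,) neuron-importance weights
    L: np.ndarray         # (u, v) nonnegative localization map
    score: float          # the targeted pre-softmax Yes score
    L_scaled: np.ndarray | None = None


def gated_gradcam(feature_stack, grad_of_yes, g1, score=np.nan,
                  out_size=None) -> CAMResult:
    """Combine feature maps, their Yes-score gradients and the gate.

    ``out_size`` optionally requests a bilinearly rescaled copy of the
    map (e.g. back to input-image resolution).
    """
    if not isinstance(feature_stack, FeatureStack):
        feature_stack = FeatureStack(np.asarray(feature_stack))
    A = feature_stack.A
    grads = np.asarray(grad_of_yes, dtype=float)
    g1 = np.asarray(g1, dtype=float).ravel()
    if grads.shape != A.shape:
        raise DimensionError(
            f"gradient stack {grads.shape} must match maps {A.shape}")
    if g1.shape[0] != A.shape[0]:
        raise DimensionError("gate length must equal the number of maps")
    alpha = g1 * grads.mean(axis=(1, 2))
    pre = np.tensordot(alpha, A, axes=1)
    L = np.maximum(pre, 0.0)
    L_scaled = None
    if out_size is not None:
        zoom = (out_size[0] / L.shape[0], out_size[1] / L.shape[1])
        L_scaled = np.maximum(_ndi.zoom(L, zoom, order=1), 0.0)
    return CAMResult(alpha=alpha, L=L, score=float(score), L_scaled=L_scaled)


def yes_score_from_maps(net, concept, feature_maps):
    """Pre-softmax Yes score when the maps are global-average-pooled."""
    A = np.asarray(feature_maps, dtype=float)
    features = A.mean(axis=(1, 2))
    _, scores = net.forward(features, concept)
    return float(scores[1])


def compute_yes_gradients(adapter, net, concept, image_or_maps):
    """Gradient of the Yes score with respect to each feature map pixel.

    The adapter exposes ``feature_maps(image)``; alternatively a raw
    (K, u, v) stack may be passed directly.  Pooling is global average, so
    ``d y / d A^k_ij = (d y / d x_k) / Z``.  Returns ``(grads, stack, g1,
    score)`` where ``g1`` is the first-layer gating vector for the concept.
    """
    if isinstance(image_or_maps, np.ndarray) and image_or_maps.ndim == 3:
        A = image_or_maps.astype(float)
    else:
        if adapter is None or not hasattr(adapter, "feature_maps"):
            raise CapabilityError(
                "adapter must provide feature_maps(image)")
        A = np.asarray(adapter.feature_maps(image_or_maps), dtype=float)
    stack = FeatureStack(A)
    if stack.K != net.ts_sizes[0]:
        raise DimensionError(
            f"{stack.K} maps but the network expects {net.ts_sizes[0]} "
            "pooled features")
    features = A.mean(axis=(1, 2))
    dx = net.input_gradient(features, concept, unit=1)
    grads = np.repeat(dx, stack.Z).reshape(A.shape) / stack.Z
    decision, scores, trace = net.forward(features, concept, capture=True)
    return grads, stack, trace.g[0], float(scores[1])


class ConvStubAdapter:
    """Tiny fixed two-layer convolutional backbone for tests and demos.

    Two 3x3 valid convolutions with an intermediate ReLU turn a
    single-channel image into ``n_maps`` feature maps.  Weights are
    seeded random constants; the adapter is deterministic.
    """

    def __init__(self, n_maps, seed=0):
        rng = np.random.default_rng(seed)
        self.w1 = rng.standard_normal((4, 3, 3)) * 0.5
        self.w2 = rng.standard_normal((n_maps, 4, 3, 3)) * 0.5
        self.n_maps = n_maps

    @staticmethod
    def _conv(stack, weights):
        # stack: (C, H, W); weights: (O, C, 3, 3) -> (O, H-2, W-2)
        C, H, W = stack.shape
        O = weights.shape[0]
        out = np.zeros((O, H - 2, W - 2))
        for di in range(3):
            for dj in range(3):
                patch = stack[:, di:H - 2 + di, dj:W - 2 + dj]
                out += np.tensordot(weights[:, :, di, dj], patch, axes=1)
        return out

    def feature_maps(self, image):
        img = np.asarray(image, dtype=float)
        if img.ndim == 2:
            img = img[None]
        h1 = np.maximum(self._conv(img, self.w1[:, None]), 0.0)
        return self._conv(h1, self.w2)
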