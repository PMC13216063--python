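"""Core dual-module gated network.

The model couples two multilayer perceptrons:

* a task-solving (TS) module that maps backbone feature vectors to a
  two-unit Yes/No judgment head, and
* a concept-abstraction (CA) module that maps a low-dimensional concept
  vector to layer-wise gating signals.

At every TS layer ``l`` the input ``x_{l-1}`` is multiplied elementwise by a
gate ``g_l = sigmoid(a_l)`` derived from the concept, so a single set of TS
weights realises a different effective classifier for every concept vector.
Default sizes follow the reference configuration: TS ``[2048-100-100-2]``
(Yes encoded at output index 1), CA ``[d_c-2048-100-100]`` with concept
dimension ``d_c = 20``.

Everything is plain numpy; forward and backward passes are written out by
hand so that gradients with respect to the concept input (needed by the
concept-learning phase and by concept expansion) are first-class outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CatsNetError",
    "DimensionError",
    "InvalidInputError",
    "ConfigurationError",
    "DegenerateVectorError",
    "ConceptSet",
    "ActivationTrace",
    "CatsNet",
    "sigmoid",
    "apply_gating",
    "softmax_cross_entropy",
    "DEFAULT_TS_SIZES",
    "DEFAULT_CA_HIDDEN",
    "DEFAULT_CONCEPT_DIM",
]


# ----------------------------------------------------------------- errors

class CatsNetError(Exception):
    """Base class for package errors."""


class DimensionError(CatsNetError, ValueError):
    """Shapes of interacting arrays are inconsistent."""


class InvalidInputError(CatsNetError, ValueError):
    """Input contains non-finite or otherwise invalid values."""


class ConfigurationError(CatsNetError, ValueError):
    """A configuration value is out of its documented range."""


class DegenerateVectorError(CatsNetError, ValueError):
    """A vector is constant/zero where the operation needs variation."""


DEFAULT_CONCEPT_DIM = 20
DEFAULT_TS_SIZES = (2048, 100, 100, 2)
DEFAULT_CA_HIDDEN = (2048, 100, 100)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# ------------------------------------------------------- basic operations

def sigmoid(a):
    """Numerically stable elementwise logistic function.

    Raises :class:`InvalidInputError` on non-finite input.  Output is in
    the closed interval (0, 1) up to floating-point saturation.
    """
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("sigmoid input must be finite")
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def apply_gating(x, g):
    """Hadamard (elementwise) product of an activation and a gate vector."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    if x.shape != g.shape:
        raise DimensionError(
            f"gating shape mismatch: x{x.shape} vs g{g.shape}"
        )
    return x * g


def softmax_cross_entropy(scores, labels):
    """Mean cross-entropy of a 2-column score matrix and 0/1 labels.

    Returns ``(loss, dscores)`` where ``dscores`` is the gradient of the
    mean loss with respect to the raw scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = scores.shape[0]
    shifted = scores - scores.max(axis=1, keepdims=True)
    exps = np.exp(shifted)
    probs = exps / exps.sum(axis=1, keepdims=True)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), labels] + eps))
    dscores = probs.copy()
    dscores[np.arange(n), labels] -= 1.0
    dscores /= n
    return loss, dscores


# ------------------------------------------------------------ concept set

@dataclass
class ConceptSet:
    """Ordered map from category id to its concept vector.

    The matrix holds one row per category, all of length ``d_c``.
    """

    ids: list
    matrix: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise DimensionError("concept matrix must be (n_categories, d_c)")
        if len(set(self.ids)) != len(self.ids):
            raise ConfigurationError("category ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidInputError("concept vectors must be finite")
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    @property
    def d_c(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, cid) -> bool:
        return cid in self._index

    def row(self, cid) -> int:
        try:
            return self._index[cid]
        except KeyError:
            raise KeyError(f"unknown category id: {cid!r}") from None

    def vector(self, cid) -> np.ndarray:
        return self.matrix[self.row(cid)]

    def copy(self) -> "ConceptSet":
        return ConceptSet(list(self.ids), self.matrix.copy())

    def checksum(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.matrix).tobytes()
        ).hexdigest()

    @classmethod
    def random(cls, ids, d_c, seed=0, init="normal"):
        """Seeded random initial concepts (standard normal or U(-1,1))."""
        rng = np.random.default_rng(seed)
        n = len(ids)
        if init == "normal":
            m = rng.standard_normal((n, d_c))
        elif init == "uniform":
            m = rng.uniform(-1.0, 1.0, size=(n, d_c))
        else:
            raise ConfigurationError(f"unknown concept init {init!r}")
        return cls(list(ids), m)


@dataclass
class ActivationTrace:
    """Per-layer activations of one forward pass.

    ``x``: TS layer inputs; ``z``: gated TS inputs; ``o``: TS affine
    outputs; ``g``: gating vectors (entries in (0, 1)); ``c``: CA chain
    inputs; ``y``: the final two scores (No at index 0, Yes at index 1).
    """

    x: list
    z: list
    o: list
    g: list
    c: list
    y: np.ndarray


# ------------------------------------------------------- batchnorm helpers

def _bn_forward(x, gamma, beta, rmean, rvar, training):
    if training:
        n = x.shape[0]
        if n < 2:
            raise ConfigurationError(
                "batch normalization needs batch size >= 2 in training mode"
            )
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        istd = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * istd
        rmean *= 1.0 - _BN_MOMENTUM
        rmean += _BN_MOMENTUM * mu
        rvar *= 1.0 - _BN_MOMENTUM
        rvar += _BN_MOMENTUM * var * n / max(n - 1, 1)
    else:
        istd = 1.0 / np.sqrt(rvar + _BN_EPS)
        xhat = (x - rmean) * istd
    return gamma * xhat + beta, (xhat, istd, training)


def _bn_backward(dout, gamma, cache):
    xhat, istd, training = cache
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    if training:
        n = dout.shape[0]
        dx = (istd / n) * (
            n * dxhat
            - dxhat.sum(axis=0)
            - xhat * (dxhat * xhat).sum(axis=0)
        )
    else:
        dx = dxhat * istd
    return dx, dgamma, dbeta


# ------------------------------------------------------------- the network

class CatsNet:
    """Gated dual-module network with hand-written forward/backward.

    Parameters
    ----------
    ts_sizes : sequence of int
        TS layer widths, input first, two-unit head last.
    d_c : int
        Concept dimension (CA input width).
    seed : int
        Seed for weight initialisation.

    The CA module has one affine layer per TS layer; CA layer ``l``
    produces pre-activations ``a_l`` of the same width as TS layer ``l``'s
    input.  The gate is ``g_l = sigmoid(a_l)``; the CA chain continues
    with ``c_l = ReLU(BatchNorm(a_l))`` (the last chain output is unused).
    TS layers apply affine -> batchnorm -> ReLU except for the raw-score
    output head.
    """

    def __init__(self, ts_sizes=DEFAULT_TS_SIZES, d_c=DEFAULT_CONCEPT_DIM,
                 seed=0):
        ts_sizes = [int(s) for s in ts_sizes]
        if len(ts_sizes) < 2:
            raise ConfigurationError("need at least one TS layer")
        if ts_sizes[-1] != 2:
            raise ConfigurationError("TS output head must have 2 units")
        self.ts_sizes = ts_sizes
        self.d_c = int(d_c)
        # CA widths: concept in, then one output per gated TS input
        self.ca_sizes = [self.d_c] + ts_sizes[:-1]
        self.n_layers = len(ts_sizes) - 1  # == number of CA layers

        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        for l in range(self.n_layers):
            fan_in, fan_out = ts_sizes[l], ts_sizes[l + 1]
            self.params[f"ts{l}_W"] = rng.standard_normal(
                (fan_out, fan_in)) * np.sqrt(2.0 / fan_in)
            self.params[f"ts{l}_b"] = np.zeros(fan_out)
            if l < self.n_layers - 1:
                self._add_bn(f"ts{l}", fan_out)
        for l in range(self.n_layers):
            fan_in, fan_out = self.ca_sizes[l], self.ca_sizes[l + 1]
            self.params[f"ca{l}_W"] = rng.standard_normal(
                (fan_out, fan_in)) * np.sqrt(1.0 / fan_in)
            self.params[f"ca{l}_b"] = np.zeros(fan_out)
            if l < self.n_layers - 1:
                self._add_bn(f"ca{l}", fan_out)

    def _add_bn(self, prefix, width):
        self.params[f"{prefix}_gamma"] = np.ones(width)
        self.params[f"{prefix}_beta"] = np.zeros(width)
        self.buffers[f"{prefix}_rmean"] = np.zeros(width)
        self.buffers[f"{prefix}_rvar"] = np.ones(width)

    # -------------------------------------------------------- persistence

    def state_dict(self) -> dict:
        state = {k: v.copy() for k, v in self.params.items()}
        state.update({k: v.copy() for k, v in self.buffers.items()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).copy()
        for k in self.buffers:
            self.buffers[k] = np.asarray(state[k], dtype=float).copy()

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params) + sorted(self.buffers):
            src = self.params.get(k)
            if src is None:
                src = self.buffers[k]
            h.update(k.encode())
            h.update(np.ascontiguousarray(src).tobytes())
        return h.hexdigest()

    def copy(self) -> "CatsNet":
        net = CatsNet(self.ts_sizes, self.d_c, seed=0)
        net.load_state_dict(self.state_dict())
        return net

    # ------------------------------------------------------------ forward

    def forward_batch(self, X, C, training=False, capture=False,
                      gate_override=None):
        """Run a batch through CA gating and the TS perceptron.

        Parameters
        ----------
        X : (n, ts_sizes[0]) features; C : (n, d_c) concept inputs.
        training : bool
            Batch-statistics mode for all normalization layers.
        gate_override : list of arrays or None
            If given, replaces every gating vector (used to test the
            identity-gate equivalence with the plain perceptron).

        Returns ``(scores, cache)``; ``cache`` feeds :meth:`backward_batch`.
        """
        X = np.asarray(X, dtype=float)
        C = np.asarray(C, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.ts_sizes[0]:
            raise DimensionError(
                f"features must be (n, {self.ts_sizes[0]}), got {X.shape}")
        if C.ndim != 2 or C.shape[1] != self.d_c:
            raise DimensionError(
                f"concepts must be (n, {self.d_c}), got {C.shape}")
        if X.shape[0] != C.shape[0]:
            raise DimensionError("feature and concept batch sizes differ")

        L = self.n_layers
        cache = {"training": training, "gate_override": gate_override,
                 "c_in": [], "a": [], "g": [], "ca_bn": [], "ca_relu": [],
                 "x": [], "z": [], "o": [], "ts_bn": [], "ts_relu": []}

        c = C
        for l in range(L):
            cache["c_in"].append(c)
            a = c @ self.params[f"ca{l}_W"].T + self.params[f"ca{l}_b"]
            cache["a"].append(a)
            cache["g"].append(sigmoid(a))
            if l < L - 1:
                h, bnc = _bn_forward(
                    a, self.params[f"ca{l}_gamma"], self.params[f"ca{l}_beta"],
                    self.buffers[f"ca{l}_rmean"], self.buffers[f"ca{l}_rvar"],
                    training)
                cache["ca_bn"].append(bnc)
                c = np.maximum(h, 0.0)
                cache["ca_relu"].append(c)

        gates = cache["g"] if gate_override is None else [
            np.broadcast_to(np.asarray(g, dtype=float), (X.shape[0],
                            self.ts_sizes[l])).copy()
            for l, g in enumerate(gate_override)]
        cache["gates"] = gates

        x = X
        for l in range(L):
            cache["x"].append(x)
            z = x * gates[l]
            cache["z"].append(z)
            o = z @ self.params[f"ts{l}_W"].T + self.params[f"ts{l}_b"]
            cache["o"].append(o)
            if l < L - 1:
                h, bnc = _bn_forward(
                    o, self.params[f"ts{l}_gamma"], self.params[f"ts{l}_beta"],
                    self.buffers[f"ts{l}_rmean"], self.buffers[f"ts{l}_rvar"],
                    training)
                cache["ts_bn"].append(bnc)
                x = np.maximum(h, 0.0)
                cache["ts_relu"].append(x)
        scores = cache["o"][-1]
        return scores, cache

    def backward_batch(self, cache, dscores):
        """Backpropagate ``dscores`` through TS, the gates and CA.

        Returns ``(grads, dC, dX)``: parameter-gradient dict keyed like
        ``self.params``, gradient with respect to the concept input and
        gradient with respect to the feature input.
        """
        L = self.n_layers
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        gates = cache["gates"]
        dgates = [None] * L

        dout = np.asarray(dscores, dtype=float)
        for l in range(L - 1, -1, -1):
            if l < L - 1:
                dh = dout * (cache["ts_relu"][l] > 0)
                do, dgamma, dbeta = _bn_backward(
                    dh, self.params[f"ts{l}_gamma"], cache["ts_bn"][l])
                grads[f"ts{l}_gamma"] += dgamma
                grads[f"ts{l}_beta"] += dbeta
            else:
                do = dout
            grads[f"ts{l}_W"] += do.T @ cache["z"][l]
            grads[f"ts{l}_b"] += do.sum(axis=0)
            dz = do @ self.params[f"ts{l}_W"]
            dgates[l] = dz * cache["x"][l]
            dout = dz * gates[l]
        dX = dout

        if cache["gate_override"] is not None:
            # gates were externally fixed; no gradient flows into CA
            return grads, np.zeros_like(cache["c_in"][0]), dX

        dc_next = None
        for l in range(L - 1, -1, -1):
            g = cache["g"][l]
            da = dgates[l] * g * (1.0 - g)
            if l < L - 1 and dc_next is not None:
                dh = dc_next * (cache["ca_relu"][l] > 0)
                da_bn, dgamma, dbeta = _bn_backward(
                    dh, self.params[f"ca{l}_gamma"], cache["ca_bn"][l])
                grads[f"ca{l}_gamma"] += dgamma
                grads[f"ca{l}_beta"] += dbeta
                da = da + da_bn
            grads[f"ca{l}_W"] += da.T @ cache["c_in"][l]
            grads[f"ca{l}_b"] += da.sum(axis=0)
            dc_next = da @ self.params[f"ca{l}_W"]
        dC = dc_next
        return grads, dC, dX

    # ---------------------------------------------------- user-facing API

    def forward(self, features, concept, capture=False, gate_override=None):
        """Single-sample evaluation-mode forward pass.

        Returns ``(decision, scores)`` or ``(decision, scores, trace)``
        when ``capture`` is set.  The decision is ``"Yes"`` when the Yes
        unit (index 1) strictly exceeds the No unit; ties resolve to
        ``"No"``.
        """
        features = np.asarray(features, dtype=float).reshape(1, -1)
        concept = np.asarray(concept, dtype=float).reshape(1, -1)
        scores, cache = self.forward_batch(
            features, concept, training=False, capture=capture,
            gate_override=gate_override)
        y = scores[0]
        decision = "Yes" if y[1] > y[0] else "No"
        if not capture:
            return decision, y
        trace = ActivationTrace(
            x=[v[0] for v in cache["x"]],
            z=[v[0] for v in cache["z"]],
            o=[v[0] for v in cache["o"]],
            g=[v[0] for v in cache["gates"]],
            c=[v[0] for v in cache["c_in"]],
            y=y,
        )
        return decision, y, trace

    def decide_batch(self, X, C):
        """Vectorized Yes/No decisions (True = Yes) in evaluation mode."""
        scores, _ = self.forward_batch(X, C, training=False)
        return scores[:, 1] > scores[:, 0]

    def input_gradient(self, features, concept, unit=1):
        """Gradient of one output unit's pre-softmax score w.r.t. features.

        ``unit=1`` targets the Yes score (used by the gated class
        activation maps); evaluation-mode normalization throughout.
        """
        X = np.asarray(features, dtype=float).reshape(1, -1)
        C = np.asarray(concept, dtype=float).reshape(1, -1)
        _, cache = self.forward_batch(X, C, training=False)
        dscores = np.zeros((1, 2))
        dscores[0, unit] = 1.0
        _, _, dX = self.backward_batch(cache, dscores)
        return dX[0]

    def ts_forward_only(self, X, training=False):
        """The ungated TS perceptron (all gates forced to one)."""
        ones = [np.ones(self.ts_sizes[l]) for l in range(self.n_layers)]
        scores, _ = self.forward_batch(
            np.asarray(X, dtype=float),
            np.zeros((np.asarray(X).shape[0], self.d_c)),
            training=training, gate_override=ones)
        return scores
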