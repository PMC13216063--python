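"""Triplet construction and the two-phase alternating training loop.

The classification task is posed over (feature, concept, label) triplets:
half of the samples are paired with their own category's concept vector and
the label Yes, the other half with a uniformly drawn non-corresponding
concept and the label No.  Training alternates, epoch by epoch, between

* a network-learning phase — concept vectors fixed, all CA and TS weights
  updated by cross-entropy backpropagation, and
* a concept-learning phase — network weights fixed, only the per-category
  concept vectors updated by the gradients arriving at the CA input.

Uniform noise in [-amplitude, amplitude] (default 0.1) is injected into
every concept element during both phases; evaluation is always noise-free.
A joint mode updates both parameter groups in a single loop for comparison.
Training stops after a fixed number of epochs (default 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    CatsNet,
    ConceptSet,
    ConfigurationError,
    softmax_cross_entropy,
)

__all__ = [
    "TripletSample",
    "TrainConfig",
    "TrainingDivergenceError",
    "AdamState",
    "build_triplets",
    "inject_noise",
    "train_network_phase",
    "train_concept_phase",
    "train_alternating",
    "evaluate_concepts",
]


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite; message names the epoch and batch."""


@dataclass(frozen=True)
class TripletSample:
    """One training unit: a feature vector, the concept it is judged
    against, the sample's true category and the Yes/No label."""

    features: np.ndarray
    concept_id: object
    true_id: object
    label: str  # "Yes" | "No"


@dataclass
class TrainConfig:
    epochs: int = 5
    noise_amplitude: float = 0.1
    negative_fraction: float = 0.5
    optimizer: str = "adam"
    lr_network: float = 1e-3
    lr_concept: float = 1e-2
    batch_size: int = 32
    seed: int = 0
    mode: str = "alternating"  # "alternating" | "joint"
    concept_init: str = "normal"  # "normal" | "uniform"
    resample_negatives: bool = True
    patience: int | None = None  # optional early stop on accuracy plateau

    def __post_init__(self):
        if not (0.0 <= self.negative_fraction < 1.0):
            raise ConfigurationError("negative_fraction must be in [0, 1)")
        if self.noise_amplitude < 0:
            raise ConfigurationError("noise_amplitude must be >= 0")
        if self.mode not in ("alternating", "joint"):
            raise ConfigurationError(f"unknown training mode {self.mode!r}")


class AdamState:
    """Minimal Adam optimizer over a dict of named numpy arrays."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            params[k] -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ------------------------------------------------------------- data layer

def build_triplets(features_by_class, concepts: ConceptSet,
                   negative_fraction=0.5, seed=0):
    """Pair every feature vector with a concept id and a Yes/No label.

    Exactly ``round(n * negative_fraction)`` samples (chosen uniformly)
    receive a uniformly drawn *different* category's concept and the
    label No; the rest keep their own concept with label Yes.
    """
    classes = list(features_by_class)
    if len(classes) < 2 and negative_fraction > 0:
        raise ConfigurationError(
            "negative sampling needs at least two classes")
    for cid in classes:
        if cid not in concepts:
            raise KeyError(f"class {cid!r} has no concept vector")
    rng = np.random.default_rng(seed)
    flat = [(np.asarray(f, dtype=float), cid)
            for cid in classes for f in features_by_class[cid]]
    n = len(flat)
    n_neg = int(round(n * negative_fraction))
    neg_mask = np.zeros(n, dtype=bool)
    neg_mask[rng.permutation(n)[:n_neg]] = True
    triplets = []
    for (feat, cid), is_neg in zip(flat, neg_mask):
        if is_neg:
            others = [c for c in classes if c != cid]
            wrong = others[rng.integers(len(others))]
            triplets.append(TripletSample(feat, wrong, cid, "No"))
        else:
            triplets.append(TripletSample(feat, cid, cid, "Yes"))
    return triplets


def inject_noise(values, amplitude, seed=None, rng=None):
    """Additive elementwise Uniform(-amplitude, amplitude) perturbation.

    Accepts a vector or a batch matrix; the input is never modified.
    """
    if amplitude < 0:
        raise ConfigurationError("noise amplitude must be >= 0")
    values = np.asarray(values, dtype=float)
    if amplitude == 0:
        return values.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return values + rng.uniform(-amplitude, amplitude, size=values.shape)


def _stack_triplets(triplets, concepts):
    X = np.stack([t.features for t in triplets])
    rows = np.array([concepts.row(t.concept_id) for t in triplets])
    y = np.array([1 if t.label == "Yes" else 0 for t in triplets])
    return X, rows, y


# ------------------------------------------------------------ the phases

def _run_phase(net: CatsNet, concepts: ConceptSet, triplets, config,
               rng, update_network, update_concepts,
               net_opt=None, concept_opt=None, epoch_tag=0):
    """One pass over the triplets updating the selected parameter group.

    The network group trains with batch statistics; a concepts-only pass
    runs the network in evaluation mode so every normalization buffer
    (part of the network state) stays bytewise unchanged.
    """
    if not triplets:
        return []
    X, rows, y = _stack_triplets(triplets, concepts)
    order = rng.permutation(len(triplets))
    losses = []
    training_mode = update_network
    bs = max(config.batch_size, 2) if training_mode else config.batch_size
    for start in range(0, len(order), bs):
        idx = order[start:start + bs]
        if training_mode and len(idx) < 2:
            continue  # a trailing singleton has degenerate batch statistics
        C = inject_noise(concepts.matrix[rows[idx]],
                         config.noise_amplitude, rng=rng)
        scores, cache = net.forward_batch(X[idx], C, training=training_mode)
        loss, dscores = softmax_cross_entropy(scores, y[idx])
        if not np.isfinite(loss):
            raise TrainingDivergenceError(
                f"non-finite loss at epoch {epoch_tag}, "
                f"batch {start // bs}")
        losses.append(float(loss))
        grads, dC, _ = net.backward_batch(cache, dscores)
        if update_network:
            net_opt.step(net.params, grads)
        if update_concepts:
            cgrad = np.zeros_like(concepts.matrix)
            np.add.at(cgrad, rows[idx], dC)
            concept_opt.step({"c": concepts.matrix}, {"c": cgrad})
    return losses


def train_network_phase(net, concepts, triplets, config, rng=None,
                        net_opt=None, epoch_tag=0):
    """Update all CA/TS weights with concept vectors held fixed.

    Returns the per-batch loss history; ``concepts`` is read-only here.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if net_opt is None:
        net_opt = AdamState(net.params, config.lr_network)
    return _run_phase(net, concepts, triplets, config, rng,
                      update_network=True, update_concepts=False,
                      net_opt=net_opt, epoch_tag=epoch_tag)


def train_concept_phase(net, concepts, triplets, config, rng=None,
                        concept_opt=None, epoch_tag=0):
    """Update only the concept vectors with all network weights fixed."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if concept_opt is None:
        concept_opt = AdamState({"c": concepts.matrix}, config.lr_concept)
    return _run_phase(net, concepts, triplets, config, rng,
                      update_network=False, update_concepts=True,
                      concept_opt=concept_opt, epoch_tag=epoch_tag)


def train_alternating(net, concepts, features_by_class, config,
                      eval_features_by_class=None):
    """Full training loop (alternating two-phase or joint single loop).

    Per epoch the triplet set is rebuilt with a fresh negative assignment
    (configurable), then one network phase and one concept phase run (or a
    single joint pass in ``mode="joint"``).  Returns a history dict with
    per-phase losses and, when an evaluation split is supplied, per-epoch
    held-out macro accuracy.
    """
    history = {"network_loss": [], "concept_loss": [], "joint_loss": [],
               "holdout_accuracy": []}
    if config.epochs == 0:
        return net, concepts, history
    rng = np.random.default_rng(config.seed)
    net_opt = AdamState(net.params, config.lr_network)
    concept_opt = AdamState({"c": concepts.matrix}, config.lr_concept)
    triplets = None
    best_acc, stall = -np.inf, 0
    for epoch in range(config.epochs):
        if triplets is None or config.resample_negatives:
            triplets = build_triplets(
                features_by_class, concepts, config.negative_fraction,
                seed=int(rng.integers(2 ** 31)))
        if config.mode == "alternating":
            history["network_loss"].append(_run_phase(
                net, concepts, triplets, config, rng,
                update_network=True, update_concepts=False,
                net_opt=net_opt, epoch_tag=epoch))
            history["concept_loss"].append(_run_phase(
                net, concepts, triplets, config, rng,
                update_network=False, update_concepts=True,
                concept_opt=concept_opt, epoch_tag=epoch))
        else:
            history["joint_loss"].append(_run_phase(
                net, concepts, triplets, config, rng,
                update_network=True, update_concepts=True,
                net_opt=net_opt, concept_opt=concept_opt, epoch_tag=epoch))
        if eval_features_by_class is not None:
            acc = evaluate_concepts(
                net, concepts, eval_features_by_class,
                seed=config.seed + 7)["macro"]
            history["holdout_accuracy"].append(acc)
            if config.patience is not None:
                if acc > best_acc + 1e-3:
                    best_acc, stall = acc, 0
                else:
                    stall += 1
                    if stall >= config.patience:
                        break
    return net, concepts, history


def evaluate_concepts(net, concepts, eval_features_by_class, seed=0,
                      noise_amplitude=0.0):
    """Balanced Yes/No accuracy per category (noise-free by default).

    For each category the probe set pairs every one of its evaluation
    samples with its own concept (expected Yes) and an equal number of
    samples drawn from the other categories with that same concept
    (expected No).  Returns a dict of per-category accuracies plus the
    macro mean under the key ``"macro"``.
    """
    rng = np.random.default_rng(seed)
    classes = list(eval_features_by_class)
    for cid in classes:
        if cid not in concepts:
            raise KeyError(f"category {cid!r} missing from the concept set")
    pools = {cid: np.stack([np.asarray(f, dtype=float)
                            for f in eval_features_by_class[cid]])
             for cid in classes}
    out = {}
    for cid in classes:
        pos = pools[cid]
        others = np.concatenate([pools[c] for c in classes if c != cid])
        neg = others[rng.choice(len(others), size=len(pos),
                                replace=len(others) < len(pos))]
        X = np.concatenate([pos, neg])
        concept = concepts.vector(cid)
        if noise_amplitude > 0:
            C = inject_noise(np.tile(concept, (len(X), 1)),
                             noise_amplitude, rng=rng)
        else:
            C = np.tile(concept, (len(X), 1))
        yes = net.decide_batch(X, C)
        correct = np.concatenate([yes[:len(pos)], ~yes[len(pos):]])
        out[cid] = float(np.mean(correct))
    out["macro"] = float(np.mean([out[c] for c in classes]))
    return out
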