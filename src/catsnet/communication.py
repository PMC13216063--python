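"""Teacher-to-student concept communication.

The protocol has three phases:

1. independent concept abstraction — a teacher network trains on all
   categories, a student trains with one category (D1) withheld;
2. concept-space alignment — the teacher's concept set is expanded (each
   category gets extra concept vectors optimized with the network frozen,
   under a repelling loss that keeps new vectors away from existing ones)
   and a feed-forward translation module is fitted to map teacher
   concepts onto student concepts over the shared D99 categories;
3. concept transmission — the teacher's D1 concept is passed through the
   translation module and the student performs Yes/No judgments on D1
   images using only that transferred vector.

The expansion loss is ``L = L_CE(x_new, Yes|C) + alpha * L_CE(x_old,
No|C) + beta * L_rep(C, C_old, tau)`` with ``L_rep = sum_i
exp(-|C_i - C|^2 / tau)``; reference hyperparameters alpha=0.5,
beta=0.001, tau=0.01, lr=0.01, 2 new shots and 1 shot per old category.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .core_model import CatsNet, CatsNetError, ConceptSet, ConfigurationError
from .concept_analysis import rdm_from_vectors
from .rsa_stats import spearman_rdm
from .training import AdamState, TrainConfig, train_alternating
from .core_model import softmax_cross_entropy

__all__ = [
    "DatasetSplit",
    "RepellingConfig",
    "TranslationConfig",
    "TranslationModel",
    "ProtocolViolationError",
    "OptimizationError",
    "repelling_loss",
    "desk_translation_config",
    "desk_scale_world",
    "expand_concepts",
    "fit_translation",
    "transmit_and_evaluate",
    "layer_rdm_preservation",
    "run_communication_rounds",
]


class ProtocolViolationError(CatsNetError):
    """The held-out category leaked into student training or translation."""


class OptimizationError(CatsNetError, RuntimeError):
    """Concept-expansion optimization diverged."""


@dataclass(frozen=True)
class DatasetSplit:
    """Student training classes (D99) and the single held-out class (D1)."""

    d99: tuple
    d1: object

    def __post_init__(self):
        if self.d1 in self.d99:
            raise ProtocolViolationError("held-out class inside D99")

    @classmethod
    def holding_out(cls, classes, d1):
        return cls(tuple(c for c in classes if c != d1), d1)


@dataclass
class RepellingConfig:
    tau: float = 0.01
    alpha: float = 0.5
    beta: float = 0.001
    lr: float = 0.01
    n_new_shots: int = 2
    n_old_shots_per_class: int = 1
    n_steps: int = 150

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")


@dataclass
class TranslationConfig:
    """Reference-scale defaults: 10 hidden layers of 500 ReLU units,
    dropout 0.3, MSE loss, Adam at 1e-4 halved every 10 epochs, 200
    epochs.  Reduced-scale runs override ``hidden_layers``/``hidden_width``."""

    hidden_layers: int = 10
    hidden_width: int = 500
    dropout: float = 0.3
    epochs: int = 200
    lr: float = 1e-4
    lr_decay: float = 0.5
    decay_every: int = 10
    batch_size: int = 32

    def __post_init__(self):
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must be in [0, 1)")


# -------------------------------------------------------- repelling loss

def repelling_loss(concept, old_concepts, tau):
    """``sum_i exp(-|C_i - C|^2 / tau)`` over the existing concepts.

    Zero for an empty set of old concepts.  Depends only on pairwise
    distances, so it is invariant to any rigid rotation of all vectors.
    """
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    c = np.asarray(concept, dtype=float)
    total = 0.0
    for ci in old_concepts:
        d2 = float(np.sum((np.asarray(ci, dtype=float) - c) ** 2))
        total += np.exp(-d2 / tau)
    return float(total)


def _repelling_grad(concept, old_mat, tau):
    if old_mat.size == 0:
        return np.zeros_like(concept)
    diff = old_mat - concept  # (m, d)
    w = np.exp(-np.sum(diff ** 2, axis=1) / tau)
    return (2.0 / tau) * (diff * w[:, None]).sum(axis=0)


# ----------------------------------------------------- concept expansion

def expand_concepts(net: CatsNet, concepts: ConceptSet, target_class,
                    new_shots, old_shots_by_class, config: RepellingConfig,
                    n_expanded, seed=0):
    """Optimize fresh concept vectors for one category, network frozen.

    Each of the ``n_expanded`` vectors starts from an independent standard
    normal init and minimizes the combined cross-entropy + repelling loss
    on the few-shot batches: the new-category shots labeled Yes and one
    shot per old category labeled No, both judged under the candidate
    concept.  Returns ``[(vector, final_loss), ...]``.
    """
    rng = np.random.default_rng(seed)
    new_X = np.stack([np.asarray(f, dtype=float) for f in new_shots])
    old_classes = [c for c in old_shots_by_class if c != target_class]
    old_X = np.stack([np.asarray(old_shots_by_class[c], dtype=float)
                      for c in old_classes]) if old_classes else \
        np.zeros((0, net.ts_sizes[0]))
    old_mat = np.stack([concepts.vector(c) for c in old_classes]) \
        if old_classes else np.zeros((0, concepts.d_c))
    y_new = np.ones(len(new_X), dtype=int)
    y_old = np.zeros(len(old_X), dtype=int)

    # all candidates are optimized in parallel: their losses are additive
    # and independent, so one stacked batch per step gives identical math
    m = int(n_expanded)
    C = rng.standard_normal((m, concepts.d_c))
    opt = AdamState({"c": C}, config.lr)
    n_new, n_old = len(new_X), len(old_X)
    Xn = np.tile(new_X, (m, 1))
    Yn = np.tile(y_new, m)
    Xo = np.tile(old_X, (m, 1)) if n_old else old_X
    Yo = np.tile(y_old, m)
    losses = np.full(m, np.nan)
    for step in range(config.n_steps):
        Cn = np.repeat(C, n_new, axis=0)
        s_new, cache_new = net.forward_batch(Xn, Cn, training=False)
        _, d_new = softmax_cross_entropy(s_new, Yn)
        _, dC_new, _ = net.backward_batch(cache_new, m * d_new)
        grad = dC_new.reshape(m, n_new, -1).sum(axis=1)
        per_sample = -np.log(_softmax_prob(s_new, Yn))
        losses = per_sample.reshape(m, n_new).mean(axis=1)
        if n_old:
            Co = np.repeat(C, n_old, axis=0)
            s_old, cache_old = net.forward_batch(Xo, Co, training=False)
            _, d_old = softmax_cross_entropy(s_old, Yo)
            _, dC_old, _ = net.backward_batch(cache_old, m * d_old)
            grad = grad + config.alpha * dC_old.reshape(
                m, n_old, -1).sum(axis=1)
            losses = losses + config.alpha * (-np.log(_softmax_prob(
                s_old, Yo))).reshape(m, n_old).mean(axis=1)
        if config.beta != 0:
            for i in range(m):
                losses[i] += config.beta * repelling_loss(
                    C[i], old_mat, config.tau)
                grad[i] += config.beta * _repelling_grad(
                    C[i], old_mat, config.tau)
        if not np.all(np.isfinite(losses)):
            raise OptimizationError(
                f"expansion diverged at step {step} for {target_class!r}")
        opt.step({"c": C}, {"c": grad})
    return [(C[i].copy(), float(losses[i])) for i in range(m)]


def _softmax_prob(scores, labels):
    shifted = scores - scores.max(axis=1, keepdims=True)
    exps = np.exp(shifted)
    probs = exps / exps.sum(axis=1, keepdims=True)
    return probs[np.arange(len(labels)), labels] + 1e-12


# ---------------------------------------------------- translation module

class TranslationModel:
    """Feed-forward ReLU regressor between two concept spaces.

    Dropout (inverted, seeded) is active only while fitting; layer
    activations can be captured for the layer-wise RDM analysis.
    """

    def __init__(self, d_in, d_out, config: TranslationConfig, seed=0):
        self.config = config
        sizes = [d_in] + [config.hidden_width] * config.hidden_layers + \
            [d_out]
        rng = np.random.default_rng(seed)
        self.weights = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.weights.append([
                rng.standard_normal((b, a)) * np.sqrt(2.0 / a),
                np.zeros(b)])
        self.trained_classes: tuple = ()
        self.history: list = []

    def _forward(self, X, training=False, rng=None, capture=False):
        acts = [X] if capture else None
        h = X
        caches = []
        L = len(self.weights)
        for i, (W, b) in enumerate(self.weights):
            o = h @ W.T + b
            if i < L - 1:
                h = np.maximum(o, 0.0)
                mask = None
                if training and self.config.dropout > 0:
                    keep = 1.0 - self.config.dropout
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                caches.append((o, mask))
                if capture:
                    acts.append(h)
            else:
                h = o
                if capture:
                    acts.append(h)
        return (h, caches, acts) if capture else (h, caches)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out, _ = self._forward(X, training=False)
        return out[0] if out.shape[0] == 1 and np.asarray(X).ndim == 1 \
            else out

    def layer_activations(self, X):
        """Input, every post-activation hidden layer, and the output."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, _, acts = self._forward(X, training=False, capture=True)
        return acts

    def fit(self, X, Y, seed=0):
        cfg = self.config
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        rng = np.random.default_rng(seed)
        params = {}
        for i, (W, b) in enumerate(self.weights):
            params[f"W{i}"], params[f"b{i}"] = W, b
        opt = AdamState(params, cfg.lr)
        for epoch in range(cfg.epochs):
            lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.decay_every)
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                out, caches = self._forward(X[idx], training=True, rng=rng)
                err = out - Y[idx]
                losses.append(float(np.mean(err ** 2)))
                grads = {}
                dout = 2.0 * err / err.size
                # backprop through the stored affine/ReLU/dropout chain
                acts_in = [X[idx]]
                for (o, mask) in caches:
                    h = np.maximum(o, 0.0)
                    if mask is not None:
                        h = h * mask
                    acts_in.append(h)
                for i in range(len(self.weights) - 1, -1, -1):
                    W, b = self.weights[i]
                    grads[f"W{i}"] = dout.T @ acts_in[i]
                    grads[f"b{i}"] = dout.sum(axis=0)
                    dh = dout @ W
                    if i > 0:
                        o, mask = caches[i - 1]
                        if mask is not None:
                            dh = dh * mask
                        dout = dh * (o > 0)
                opt.step(params, grads, lr=lr)
            self.history.append({"epoch": epoch, "lr": lr,
                                 "loss": float(np.mean(losses))})
        return self


def fit_translation(teacher_vectors_by_class, student_concepts: ConceptSet,
                    config: TranslationConfig | None = None, seed=0):
    """Fit the teacher-to-student concept map over the shared categories.

    ``teacher_vectors_by_class`` maps each D99 category to a list of
    teacher-space vectors (originally learned + expanded); every one of
    them regresses onto that category's single student concept vector.
    """
    config = TranslationConfig() if config is None else config
    t_classes = set(teacher_vectors_by_class)
    s_classes = set(student_concepts.ids)
    if t_classes != s_classes:
        raise ConfigurationError(
            f"class sets differ: {sorted(t_classes ^ s_classes)!r}")
    X, Y = [], []
    for cid in teacher_vectors_by_class:
        for vec in teacher_vectors_by_class[cid]:
            X.append(np.asarray(vec, dtype=float))
            Y.append(student_concepts.vector(cid))
    X = np.stack(X)
    Y = np.stack(Y)
    model = TranslationModel(X.shape[1], Y.shape[1], config, seed=seed)
    model.trained_classes = tuple(sorted(t_classes, key=str))
    model.fit(X, Y, seed=seed)
    return model


# -------------------------------------------------- transmission + eval

def transmit_and_evaluate(teacher_concepts: ConceptSet,
                          student_net: CatsNet, translation,
                          d1_class, eval_features_by_class, seed=0,
                          scramble=False):
    """Translate the teacher's held-out concept and score the student.

    The student judges a balanced probe set — every D1 evaluation sample
    (expected Yes) against an equal number of other-category samples
    (expected No) — using only the transferred vector.  ``translation``
    may be ``None`` for the degenerate identity protocol.  ``scramble``
    permutes the translated vector's dimensions (destroyed-mapping
    control).  Returns ``(accuracy, transferred_vector)``.
    """
    if translation is not None and d1_class in translation.trained_classes:
        raise ProtocolViolationError(
            f"held-out class {d1_class!r} was in the translation "
            "training set")
    vec = np.asarray(teacher_concepts.vector(d1_class), dtype=float)
    if translation is not None:
        vec = np.asarray(translation.predict(vec), dtype=float).ravel()
    rng = np.random.default_rng(seed)
    if scramble:
        vec = vec[rng.permutation(len(vec))]
    pos = np.stack([np.asarray(f, dtype=float)
                    for f in eval_features_by_class[d1_class]])
    others = np.concatenate([
        np.stack([np.asarray(f, dtype=float) for f in feats])
        for cid, feats in eval_features_by_class.items() if cid != d1_class])
    neg = others[rng.choice(len(others), size=len(pos),
                            replace=len(others) < len(pos))]
    X = np.concatenate([pos, neg])
    C = np.tile(vec, (len(X), 1))
    yes = student_net.decide_batch(X, C)
    correct = np.concatenate([yes[:len(pos)], ~yes[len(pos):]])
    return float(np.mean(correct)), vec


def layer_rdm_preservation(translation: TranslationModel, probe_concepts):
    """Layer-wise Euclidean RDMs of the translation module.

    Returns ``(rdms, spearman_to_input)`` over input, every hidden layer
    and the output, for >= 3 probe vectors.
    """
    probes = np.atleast_2d(np.asarray(probe_concepts, dtype=float))
    if probes.shape[0] < 3:
        raise ConfigurationError("need at least 3 probe concepts")
    acts = translation.layer_activations(probes)
    labels = [f"item_{i}" for i in range(probes.shape[0])]
    rdms = [rdm_from_vectors(
        {lab: a[i] for i, lab in enumerate(labels)}, metric="euclidean")
        for a in acts]
    corrs = [spearman_rdm(rdms[0], r) for r in rdms]
    return rdms, corrs


# ------------------------------------------------------ round orchestration

def desk_translation_config() -> TranslationConfig:
    """Reduced-scale translation profile: 3 hidden layers of 64 units.

    The learning schedule is re-based for the small anchor set (~200
    samples, a handful of minibatches per epoch): Adam at 3e-3 halved
    every 50 epochs.  The reference-scale schedule assumes hundreds of
    minibatches per epoch and underfits here.
    """
    return TranslationConfig(hidden_layers=3, hidden_width=64,
                             lr=3e-3, decay_every=50)


def desk_scale_world(seed=0, n_classes=20, feature_dim=64,
                     samples_per_class=80, n_eval=30):
    """The reduced-scale communication world.

    A 5-level hierarchy with geometrically shrinking displacement scales
    gives every class a close sibling — the superclass-like similarity
    structure that concept transfer relies on (a never-trained category is
    recognized through its trained semantic neighbors).  Returns
    ``(train_features, eval_features, truth_rdm, class_ids)``.
    """
    from .synthetic_data import SyntheticSpec, generate_class_features, \
        split_features
    spec = SyntheticSpec(
        n_classes=n_classes, feature_dim=feature_dim,
        samples_per_class=samples_per_class,
        level_scales=(3.0, 1.5, 0.8, 0.4, 0.2), within_class_sd=0.5,
        seed=seed)
    feats, truth, ids = generate_class_features(spec)
    train, evals = split_features(feats, n_eval)
    return train, evals, truth, ids

@dataclass
class CommunicationRoundResult:
    round_index: int
    d1_class: object
    transfer_accuracy: float
    scrambled_accuracy: float | None
    teacher_student_rdm_rho: float


def run_communication_rounds(features_by_class, eval_features_by_class,
                             n_rounds=20, d_c=10, ts_hidden=(32, 32),
                             repelling: RepellingConfig | None = None,
                             translation_config: TranslationConfig | None
                             = None,
                             n_expanded=8, train_config: TrainConfig | None
                             = None, seed=0, scrambled_control=True):
    """Run the full three-phase protocol for several held-out classes.

    Classes cycle through the D1 role; each round trains a fresh teacher
    (all classes) and student (D99 only), expands the teacher's concepts,
    fits the translation map on D99, and evaluates the transferred D1
    concept on the student.  Returns a list of
    :class:`CommunicationRoundResult`.
    """
    classes = list(features_by_class)
    feature_dim = np.asarray(
        next(iter(features_by_class.values()))[0]).shape[0]
    repelling = RepellingConfig() if repelling is None else repelling
    if translation_config is None:
        translation_config = desk_translation_config()
    if train_config is None:
        # small synthetic datasets need more epochs than the reference
        # 5-epoch schedule to reach their accuracy plateau
        train_config = TrainConfig(epochs=15)
    rng = np.random.default_rng(seed)
    results = []
    for rnd in range(n_rounds):
        d1 = classes[rnd % len(classes)]
        split = DatasetSplit.holding_out(classes, d1)
        base = int(rng.integers(2 ** 28))
        cfg = train_config
        ts_sizes = [feature_dim, *ts_hidden, 2]

        teacher = CatsNet(ts_sizes, d_c=d_c, seed=base)
        t_concepts = ConceptSet.random(classes, d_c, seed=base + 1)
        t_cfg = TrainConfig(**{**cfg.__dict__, "seed": base + 2})
        train_alternating(teacher, t_concepts, features_by_class, t_cfg)

        student = CatsNet(ts_sizes, d_c=d_c, seed=base + 3)
        s_concepts = ConceptSet.random(split.d99, d_c, seed=base + 4)
        s_feats = {c: features_by_class[c] for c in split.d99}
        s_cfg = TrainConfig(**{**cfg.__dict__, "seed": base + 5})
        train_alternating(student, s_concepts, s_feats, s_cfg)

        # teacher-side few-shot expansion over the shared categories
        shot_rng = np.random.default_rng(base + 6)
        old_shots = {c: features_by_class[c][
            shot_rng.integers(len(features_by_class[c]))]
            for c in classes}
        teacher_vectors = {}
        for cid in split.d99:
            pool = features_by_class[cid]
            new_idx = shot_rng.choice(len(pool),
                                      size=repelling.n_new_shots,
                                      replace=False)
            cid_tag = zlib.crc32(str(cid).encode()) % 1000
            expanded = expand_concepts(
                teacher, t_concepts, cid,
                [pool[i] for i in new_idx], old_shots, repelling,
                n_expanded=n_expanded, seed=base + 7 + cid_tag)
            teacher_vectors[cid] = [t_concepts.vector(cid)] + \
                [v for v, _ in expanded]

        translation = fit_translation(
            teacher_vectors, s_concepts, translation_config, seed=base + 8)

        acc, _ = transmit_and_evaluate(
            t_concepts, student, translation, d1,
            eval_features_by_class, seed=base + 9)
        scram = None
        if scrambled_control:
            scram, _ = transmit_and_evaluate(
                t_concepts, student, translation, d1,
                eval_features_by_class, seed=base + 10, scramble=True)

        shared = sorted(split.d99, key=str)
        t_rdm = rdm_from_vectors(
            {c: t_concepts.vector(c) for c in shared}, metric="cosine")
        s_rdm = rdm_from_vectors(
            {c: s_concepts.vector(c) for c in shared}, metric="cosine")
        rho = spearman_rdm(t_rdm, s_rdm)

        results.append(CommunicationRoundResult(
            round_index=rnd, d1_class=d1, transfer_accuracy=acc,
            scrambled_accuracy=scram, teacher_student_rdm_rho=rho))
    return results
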