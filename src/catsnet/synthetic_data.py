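"""Synthetic worlds for exercising the model and the RSA stack.

Two families of fixtures:

* backbone-like feature vectors — Gaussian class clusters whose means are
  placed by accumulating displacements along a binary hierarchy, so
  sibling classes sit closer together than cousins (a controllable
  between-class similarity structure, mimicking embeddings from a
  pretrained vision backbone), and
* RDM ensembles — subject-level and model-instance-level dissimilarity
  matrices generated as a shared signal RDM plus independent symmetric
  noise, the generative model assumed by the noise-ceiling estimator.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import ConfigurationError

__all__ = [
    "SyntheticSpec",
    "RdmEnsembleSpec",
    "generate_class_features",
    "generate_rdm_ensemble",
    "make_hypercategory_world",
    "split_features",
]


@dataclass
class SyntheticSpec:
    """Hierarchically clustered Gaussian feature world.

    ``level_scales`` gives the mean-displacement magnitude per hierarchy
    level, root first; deeper (later) entries separate ever-smaller
    sibling groups, so decreasing scales produce the sibling-closer-than-
    cousin structure.
    """

    n_classes: int = 8
    feature_dim: int = 64
    samples_per_class: int = 150
    level_scales: tuple = (4.0, 2.0, 1.0)
    within_class_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if any(s <= 0 for s in self.level_scales):
            raise ConfigurationError("displacement scales must be positive")
        if self.within_class_sd < 0:
            raise ConfigurationError("within_class_sd must be >= 0")


@dataclass
class RdmEnsembleSpec:
    """Shared-signal-plus-noise RDM ensemble."""

    n_items: int = 12
    n_subjects: int = 8
    noise_sd: float = 0.3
    n_model_instances: int = 6
    instance_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0 or self.instance_noise_sd < 0:
            raise ConfigurationError("noise sds must be >= 0")
        if self.n_items < 4:
            raise ConfigurationError("need at least 4 items")


def _class_means(spec: SyntheticSpec, rng):
    """Place class means by accumulating binary-tree level displacements."""
    n, d = spec.n_classes, spec.feature_dim
    depth = max(1, int(np.ceil(np.log2(n))))
    scales = list(spec.level_scales)
    while len(scales) < depth:
        scales.append(scales[-1] * 0.5)
    means = np.zeros((n, d))
    for level in range(depth):
        n_groups = 2 ** (level + 1)
        group_of = (np.arange(n) * n_groups) // n
        disp = rng.standard_normal((n_groups, d)) * scales[level]
        means += disp[group_of]
    return means


def generate_class_features(spec: SyntheticSpec):
    """Sample the feature world.

    Returns ``(features_by_class, truth_rdm, class_ids)`` where the truth
    RDM holds Euclidean distances between the class means (the analytic
    between-class structure a consistent estimator should recover).
    """
    rng = np.random.default_rng(spec.seed)
    means = _class_means(spec, rng)
    class_ids = [f"class_{i:02d}" for i in range(spec.n_classes)]
    features_by_class = {
        cid: means[i] + rng.standard_normal(
            (spec.samples_per_class, spec.feature_dim)) * spec.within_class_sd
        for i, cid in enumerate(class_ids)
    }
    diff = means[:, None, :] - means[None, :, :]
    truth_rdm = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(truth_rdm, 0.0)
    return features_by_class, truth_rdm, class_ids


def split_features(features_by_class, n_eval):
    """Split each class's samples into held-in and held-out subsets.

    The last ``n_eval`` samples per class form the evaluation split (the
    generators draw i.i.d. samples, so any fixed split is unbiased).
    """
    train, evals = {}, {}
    for cid, feats in features_by_class.items():
        feats = np.asarray(feats)
        if len(feats) <= n_eval:
            raise ConfigurationError(
                f"class {cid!r} has too few samples to hold out {n_eval}")
        train[cid] = feats[:-n_eval]
        evals[cid] = feats[-n_eval:]
    return train, evals


def _symmetric_noise(n, sd, rng):
    """Zero-diagonal symmetric noise built on the upper triangle."""
    noise = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    noise[iu] = rng.standard_normal(len(iu[0])) * sd
    return noise + noise.T


def generate_rdm_ensemble(spec: RdmEnsembleSpec, signal_rdm=None):
    """Draw subject and model-instance RDMs around a shared signal RDM.

    The signal RDM defaults to Euclidean distances between random points;
    each subject/instance adds independent symmetric upper-triangle noise,
    clipped to nonnegative with a zero diagonal.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_items
    if signal_rdm is None:
        pts = rng.standard_normal((n, 5))
        diff = pts[:, None, :] - pts[None, :, :]
        signal_rdm = np.sqrt((diff ** 2).sum(axis=-1))
    signal_rdm = np.asarray(signal_rdm, dtype=float)

    def _draw(sd):
        out = np.clip(signal_rdm + _symmetric_noise(n, sd, rng), 0.0, None)
        np.fill_diagonal(out, 0.0)
        return out

    subjects = [_draw(spec.noise_sd) for _ in range(spec.n_subjects)]
    instances = [_draw(spec.instance_noise_sd)
                 for _ in range(spec.n_model_instances)]
    return subjects, instances, signal_rdm


def make_hypercategory_world(n_hyper=2, classes_per_hyper=4,
                             feature_dim=64, samples_per_class=100,
                             hyper_scale=6.0, class_scale=1.5,
                             within_class_sd=0.5, seed=0):
    """Feature world whose top hierarchy level is the hyper-category.

    Returns ``(features_by_class, hyper_map, truth_rdm, class_ids)``;
    ``hyper_map`` is the two-column class -> hyper-category table the
    basis-specificity analysis requires.
    """
    if n_hyper < 1 or classes_per_hyper < 1:
        raise ConfigurationError("world sizes must be positive")
    rng = np.random.default_rng(seed)
    class_ids, hyper_map = [], {}
    means = {}
    for h in range(n_hyper):
        hyper_id = f"hyper_{h}"
        center = rng.standard_normal(feature_dim) * hyper_scale
        for c in range(classes_per_hyper):
            cid = f"h{h}_class{c}"
            class_ids.append(cid)
            hyper_map[cid] = hyper_id
            means[cid] = center + rng.standard_normal(feature_dim) * class_scale
    features_by_class = {
        cid: means[cid] + rng.standard_normal(
            (samples_per_class, feature_dim)) * within_class_sd
        for cid in class_ids
    }
    m = np.stack([means[c] for c in class_ids])
    diff = m[:, None, :] - m[None, :, :]
    truth_rdm = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(truth_rdm, 0.0)
    return features_by_class, hyper_map, truth_rdm, class_ids
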