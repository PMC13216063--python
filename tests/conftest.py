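"""Shared fixtures: synthetic worlds and trained model instances.

Everything is generated at run time from fixed seeds; the heavier trained
instances are session-scoped so the suite trains each of them once.
"""

import numpy as np
import pytest

import catsnet as cn


@pytest.fixture(scope="session")
def eight_class_world():
    """The default 8-class hierarchical feature world, split 100/50."""
    spec = cn.SyntheticSpec(seed=11)
    feats, truth, ids = cn.generate_class_features(spec)
    train, evals = cn.synthetic_data.split_features(feats, 50)
    return {"train": train, "eval": evals, "truth": truth, "ids": ids}


@pytest.fixture(scope="session")
def trained_instance(eight_class_world):
    """Alternating-trained network + concepts on the 8-class world."""
    w = eight_class_world
    net = cn.CatsNet([64, 32, 32, 2], d_c=20, seed=5)
    concepts = cn.ConceptSet.random(w["ids"], 20, seed=6)
    cfg = cn.TrainConfig(seed=7)
    _, _, history = cn.train_alternating(
        net, concepts, w["train"], cfg,
        eval_features_by_class=w["eval"])
    return {"net": net, "concepts": concepts, "history": history,
            "config": cfg, **w}


@pytest.fixture(scope="session")
def joint_instance(eight_class_world):
    """Joint-mode counterpart trained from the same initialization."""
    w = eight_class_world
    net = cn.CatsNet([64, 32, 32, 2], d_c=20, seed=5)
    concepts = cn.ConceptSet.random(w["ids"], 20, seed=6)
    cfg = cn.TrainConfig(seed=7, mode="joint")
    cn.train_alternating(net, concepts, w["train"], cfg)
    return {"net": net, "concepts": concepts, **w}


@pytest.fixture(scope="session")
def hyper_world():
    """2x4 hyper-category world plus a trained instance on it."""
    feats, hyper_map, truth, ids = cn.make_hypercategory_world(
        n_hyper=2, classes_per_hyper=4, samples_per_class=150, seed=31)
    train, evals = cn.synthetic_data.split_features(feats, 50)
    net = cn.CatsNet([64, 32, 32, 2], d_c=20, seed=32)
    concepts = cn.ConceptSet.random(ids, 20, seed=33)
    cn.train_alternating(net, concepts, train, cn.TrainConfig(seed=34))
    return {"train": train, "eval": evals, "hyper_map": hyper_map,
            "truth": truth, "ids": ids, "net": net, "concepts": concepts}


@pytest.fixture
def tiny_net():
    """Small untrained instance for shape/determinism checks."""
    return cn.CatsNet([16, 8, 8, 2], d_c=4, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
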