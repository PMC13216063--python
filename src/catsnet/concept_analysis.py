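"""Probes and statistics of the learned concept space.

Covers: functional entropy of per-class Yes counts, hyper-category
specificity of the one-hot basis vectors, representational dissimilarity
matrices over concept vectors, agglomerative (cosine/UPGMA) clustering,
best-match labeling of concept dimensions against an external reference
space, the critical Pearson-r significance threshold, and k-means grouping
of model RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as _t_dist
from sklearn.cluster import KMeans

from .core_model import (
    ConceptSet,
    ConfigurationError,
    DegenerateVectorError,
    DimensionError,
    InvalidInputError,
)

__all__ = [
    "ResponseCounts",
    "EntropyResult",
    "RDM",
    "functional_entropy",
    "yes_counts",
    "entropy_distribution",
    "parameter_space_entropy_baseline",
    "random_concept_sampler",
    "trained_space_sampler",
    "basis_specificity",
    "rdm_from_vectors",
    "hcluster_concepts",
    "best_match_dimensions",
    "critical_r",
    "kmeans_rdm_groups",
    "upper_triangle",
]


@dataclass
class ResponseCounts:
    """Per-class counts of Yes responses elicited by one concept vector."""

    class_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.class_ids) != len(self.counts):
            raise DimensionError("one count per class required")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be nonnegative")


@dataclass
class EntropyResult:
    e: float
    p: np.ndarray


@dataclass
class RDM:
    """Symmetric item x item dissimilarity matrix."""

    items: list
    d: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.items)
        if self.d.shape != (n, n):
            raise DimensionError("RDM must be square over the item list")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise InvalidInputError("RDM must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise InvalidInputError("RDM diagonal must be zero")


def upper_triangle(matrix):
    """Row-major upper triangle (diagonal excluded) as a flat vector."""
    matrix = np.asarray(matrix)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


# ------------------------------------------------------ functional entropy

def functional_entropy(counts: ResponseCounts) -> EntropyResult:
    """Shannon entropy (natural log) of the normalized Yes-count profile.

    ``e = -sum_i p_i ln p_i`` with ``p_i = c_i / sum_j c_j`` and the limit
    convention ``0 * ln 0 = 0``.  Low entropy means the concept vector is
    selective for few categories.  All-zero counts leave the distribution
    undefined and raise :class:`InvalidInputError`.
    """
    c = np.asarray(counts.counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise InvalidInputError(
            "entropy undefined: the concept elicited no Yes response")
    p = c / total
    nz = p > 0
    e = float(-(p[nz] * np.log(p[nz])).sum())
    return EntropyResult(e=e, p=p)


def yes_counts(net, concept_vector, eval_features_by_class) -> ResponseCounts:
    """Count Yes decisions per class when one concept probes every sample."""
    class_ids = list(eval_features_by_class)
    concept = np.asarray(concept_vector, dtype=float)
    counts = []
    for cid in class_ids:
        X = np.stack([np.asarray(f, dtype=float)
                      for f in eval_features_by_class[cid]])
        C = np.tile(concept, (len(X), 1))
        counts.append(int(net.decide_batch(X, C).sum()))
    return ResponseCounts(class_ids, np.array(counts))


def parameter_space_entropy_baseline(ts_sizes, d_c, eval_features_by_class,
                                     n_nets=5, points_per_net=20, seed=0,
                                     sampler_kind="normal"):
    """Entropy baseline from the task-solving *parameter* space.

    Samples several architecture-matched networks with random parameters
    and collects the functional entropies their responses assign to
    random concept vectors.  Pooling over parameter draws matters: a
    single random network can be decisively biased toward a few
    categories, but the ensemble is unselective.  Returns
    ``(entropies, n_dropped)`` pooled over all networks.
    """
    from .core_model import CatsNet
    rng = np.random.default_rng(seed)
    sampler = random_concept_sampler(d_c, kind=sampler_kind)
    entropies, dropped = [], 0
    for _ in range(n_nets):
        net = CatsNet(ts_sizes, d_c=d_c, seed=int(rng.integers(2 ** 31)))
        es, dr = entropy_distribution(
            net, sampler, eval_features_by_class, points_per_net,
            seed=int(rng.integers(2 ** 31)))
        entropies.extend(es)
        dropped += dr
    return entropies, dropped


def random_concept_sampler(d_c, kind="normal"):
    """Baseline sampler over concept space: standard normal or U(-1,1)."""
    if kind == "normal":
        return lambda n, rng: rng.standard_normal((n, d_c))
    if kind == "uniform":
        return lambda n, rng: rng.uniform(-1.0, 1.0, size=(n, d_c))
    raise ConfigurationError(f"unknown sampler kind {kind!r}")


def trained_space_sampler(concepts: ConceptSet):
    """Gaussian fit (mean + covariance) to the learned concept vectors."""
    mu = concepts.matrix.mean(axis=0)
    cov = np.cov(concepts.matrix, rowvar=False)
    cov = cov + 1e-8 * np.eye(len(mu))
    return lambda n, rng: rng.multivariate_normal(mu, cov, size=n)


def entropy_distribution(net, concepts_or_sampler, eval_features_by_class,
                         n_points, seed=0):
    """Sample concept vectors and collect their functional entropies.

    ``concepts_or_sampler`` is either a :class:`ConceptSet` (sampled via a
    Gaussian fit to the learned vectors) or a callable ``sampler(n, rng)``.
    Sampled points that elicit no Yes response anywhere (entropy
    undefined) are dropped; the return value is ``(entropies, n_dropped)``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(concepts_or_sampler, ConceptSet):
        sampler = trained_space_sampler(concepts_or_sampler)
    else:
        sampler = concepts_or_sampler
    points = sampler(n_points, rng)
    entropies, dropped = [], 0
    for vec in points:
        counts = yes_counts(net, vec, eval_features_by_class)
        if counts.counts.sum() == 0:
            dropped += 1
            continue
        entropies.append(functional_entropy(counts).e)
    return entropies, dropped


# ------------------------------------------------- basis-vector specificity

def basis_specificity(net, eval_features_by_class, hyper_map):
    """Yes counts per (basis dimension, hyper-category).

    Each of the ``d_c`` canonical one-hot vectors is fed as the concept;
    Yes decisions over the evaluation set are tallied by hyper-category.
    Returns ``(matrix of shape (d_c, n_hyper), hyper_ids)``.
    """
    missing = [c for c in eval_features_by_class if c not in hyper_map]
    if missing:
        raise ConfigurationError(
            f"classes missing from the hyper-category map: {missing}")
    hyper_ids = sorted(set(hyper_map[c] for c in eval_features_by_class))
    hcol = {h: j for j, h in enumerate(hyper_ids)}
    out = np.zeros((net.d_c, len(hyper_ids)), dtype=int)
    for dim in range(net.d_c):
        basis = np.zeros(net.d_c)
        basis[dim] = 1.0
        counts = yes_counts(net, basis, eval_features_by_class)
        for cid, cnt in zip(counts.class_ids, counts.counts):
            out[dim, hcol[hyper_map[cid]]] += int(cnt)
    return out, hyper_ids


# ----------------------------------------------------------------- RDMs

def rdm_from_vectors(vectors, metric="pearson") -> RDM:
    """RDM over labeled vectors.

    ``metric``: ``pearson`` (1 - Pearson correlation, entries in [0, 2]),
    ``cosine`` or ``euclidean``.  ``vectors`` is an ordered mapping
    label -> vector or a :class:`ConceptSet`.
    """
    if isinstance(vectors, ConceptSet):
        items = list(vectors.ids)
        mat = vectors.matrix
    else:
        items = list(vectors)
        mat = np.stack([np.asarray(vectors[k], dtype=float) for k in items])
    if len(items) < 3:
        raise ConfigurationError("need at least 3 items for an RDM")
    if mat.shape[1] < 2:
        raise ConfigurationError("vectors must have length >= 2")
    if metric == "pearson":
        sd = mat.std(axis=1)
        bad = np.where(sd == 0)[0]
        if len(bad):
            raise DegenerateVectorError(
                f"constant vector(s) under pearson: {[items[i] for i in bad]}")
        d = squareform(pdist(mat, metric="correlation"))
    elif metric == "cosine":
        norms = np.linalg.norm(mat, axis=1)
        bad = np.where(norms == 0)[0]
        if len(bad):
            raise DegenerateVectorError(
                f"zero vector(s) under cosine: {[items[i] for i in bad]}")
        d = squareform(pdist(mat, metric="cosine"))
    elif metric == "euclidean":
        d = squareform(pdist(mat, metric="euclidean"))
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return RDM(items=items, d=d, metric=metric)


def hcluster_concepts(concepts, threshold=None):
    """Agglomerative clustering of concept vectors.

    Cosine distance with unweighted average (UPGMA) linkage.  Items are
    sorted lexicographically by label before linkage so that distance
    ties resolve deterministically.  Returns ``(linkage matrix, ordered
    labels, flat cluster labels or None)``; flat clusters are cut at
    ``threshold`` cophenetic distance when given.
    """
    if isinstance(concepts, ConceptSet):
        mapping = {cid: concepts.vector(cid) for cid in concepts.ids}
    else:
        mapping = dict(concepts)
    if len(mapping) < 2:
        raise ConfigurationError("need at least 2 concepts to cluster")
    labels = sorted(mapping, key=str)
    mat = np.stack([np.asarray(mapping[k], dtype=float) for k in labels])
    if np.any(np.linalg.norm(mat, axis=1) == 0):
        raise DegenerateVectorError("zero vector has no cosine direction")
    link = _hier.linkage(mat, method="average", metric="cosine")
    flat = None
    if threshold is not None:
        flat = _hier.fcluster(link, t=threshold, criterion="distance")
    return link, labels, flat


def best_match_dimensions(reference_dims, concept_matrix):
    """Best-matching concept dimension for every reference dimension.

    Both arguments are items x dims matrices over the same item order.
    For each reference dimension, Pearson r against all concept dimensions
    is computed and the maximum (with its argmax index) retained.
    Returns a list of ``(best_r, best_dim_index)`` pairs.
    """
    ref = np.asarray(reference_dims, dtype=float)
    con = np.asarray(concept_matrix, dtype=float)
    if ref.ndim == 1:
        ref = ref[:, None]
    if ref.shape[0] != con.shape[0]:
        raise DimensionError("item counts differ between the two matrices")
    if ref.shape[0] < 3:
        raise ConfigurationError("need at least 3 items")
    for name, m in (("reference", ref), ("concept", con)):
        if np.any(m.std(axis=0) == 0):
            raise DegenerateVectorError(f"constant column in {name} matrix")
    rz = (ref - ref.mean(0)) / ref.std(0)
    cz = (con - con.mean(0)) / con.std(0)
    corr = rz.T @ cz / ref.shape[0]  # (R, d_c) Pearson correlations
    best = corr.argmax(axis=1)
    return [(float(corr[i, j]), int(j)) for i, j in enumerate(best)]


def critical_r(df, alpha=0.05, tails=2):
    """Critical Pearson correlation at the given degrees of freedom.

    ``r* = t* / sqrt(t*^2 + df)`` with ``t*`` the critical Student-t
    quantile (two-tailed by default); e.g. ``critical_r(330)`` is 0.107.
    """
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ConfigurationError("tails must be 1 or 2")
    t_star = _t_dist.ppf(1.0 - alpha / tails, df)
    return float(t_star / np.sqrt(t_star ** 2 + df))


def kmeans_rdm_groups(model_rdms, k=2, seed=0, n_init=10):
    """k-means grouping of RDMs on their vectorized upper triangles."""
    if len(model_rdms) < k:
        raise ConfigurationError("need at least k RDMs")
    mats = [r.d if isinstance(r, RDM) else np.asarray(r, dtype=float)
            for r in model_rdms]
    X = np.stack([upper_triangle(m) for m in mats])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(X)
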