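"""Representational-similarity statistics.

Spearman and partial Spearman correlation between RDMs, the Mantel
permutation test, Fisher-z aggregation with one-sample/paired group tests,
split-half group reliability with Spearman-Brown correction, and a noise
ceiling expressed in the Fisher-z domain:

    rel_s   = r^2(X_s, mean(X_-s)) / rel_group        (per subject)
    rel_model = back-transformed mean_z of leave-one-out instance rhos
    NC_z    = (1/S) sum_s atanh( sqrt(rel_s * rel_model) )

All RDM comparisons work on the row-major upper triangle (diagonal
excluded) with tie-averaged ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .concept_analysis import RDM, upper_triangle
from .core_model import ConfigurationError, DegenerateVectorError

__all__ = [
    "NoiseCeilingResult",
    "GroupTestResult",
    "spearman_rdm",
    "partial_spearman_rdm",
    "mantel_test",
    "fisher_z",
    "fisher_z_inverse",
    "split_half_reliability",
    "noise_ceiling",
    "nc_z_from_reliabilities",
    "group_level_tests",
]

_CLIP = 1.0 - 1e-7


def _as_matrix(rdm):
    return rdm.d if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)


def _utri(rdm):
    v = upper_triangle(_as_matrix(rdm))
    if len(v) < 3:
        raise ConfigurationError("need at least 4 items (6 pairs)")
    return v


def spearman_rdm(rdm_a, rdm_b):
    """Spearman rank correlation over the two upper-triangle vectors."""
    a, b = _utri(rdm_a), _utri(rdm_b)
    if len(a) != len(b):
        raise ConfigurationError("RDMs must share the same items")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateVectorError("constant RDM has no rank correlation")
    rho = _st.spearmanr(a, b).statistic
    return float(rho)


def partial_spearman_rdm(rdm_a, rdm_b, covariate_rdm):
    """First-order partial Spearman correlation controlling a covariate RDM.

    All three upper triangles are rank-transformed (average ranks), then
    the standard first-order partial Pearson formula is applied:
    ``r_ab.c = (r_ab - r_ac r_bc) / sqrt((1 - r_ac^2)(1 - r_bc^2))``.
    """
    vecs = [_utri(r) for r in (rdm_a, rdm_b, covariate_rdm)]
    if len({len(v) for v in vecs}) != 1:
        raise ConfigurationError("RDMs must share the same items")
    ra, rb, rc = (_st.rankdata(v) for v in vecs)
    for v in (ra, rb, rc):
        if np.std(v) == 0:
            raise DegenerateVectorError("constant ranks in an input RDM")
    r_ab = np.corrcoef(ra, rb)[0, 1]
    r_ac = np.corrcoef(ra, rc)[0, 1]
    r_bc = np.corrcoef(rb, rc)[0, 1]
    denom = (1 - r_ac ** 2) * (1 - r_bc ** 2)
    if denom <= 1e-14:
        raise DegenerateVectorError(
            "covariate collinear with an input RDM; partial undefined")
    return float((r_ab - r_ac * r_bc) / np.sqrt(denom))


def mantel_test(rdm_a, rdm_b, n_perm=10_000, seed=0, tails=1):
    """Mantel permutation test of RDM association.

    The observed statistic is the Spearman rho of the upper triangles.
    The null permutes item labels of the second RDM jointly on rows and
    columns.  ``p = (1 + #{null >= observed}) / (1 + n_perm)`` one-tailed;
    the two-tailed p doubles the smaller tail (capped at 1).
    """
    A, B = _as_matrix(rdm_a), _as_matrix(rdm_b)
    n = A.shape[0]
    if n < 4:
        raise ConfigurationError("Mantel test needs at least 4 items")
    if n_perm < 99:
        raise ConfigurationError("n_perm must be at least 99")
    # Pre-rank both matrices: a joint row/column permutation permutes the
    # upper-triangle multiset, so ranks computed once stay valid and each
    # null statistic is a plain Pearson correlation of rank vectors.
    iu = np.triu_indices(n, k=1)
    ra = _st.rankdata(A[iu])
    rb_mat = np.zeros((n, n))
    rb_mat[iu] = _st.rankdata(B[iu])
    rb_mat += rb_mat.T
    if np.std(ra) == 0 or np.std(rb_mat[iu]) == 0:
        raise DegenerateVectorError("constant RDM in Mantel test")

    za = (ra - ra.mean()) / ra.std()
    rb = rb_mat[iu]
    zb = (rb - rb.mean()) / rb.std()
    observed = float(np.mean(za * zb))

    rng = np.random.default_rng(seed)
    count_ge = 0
    count_le = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pb = rb_mat[np.ix_(perm, perm)][iu]
        zpb = (pb - pb.mean()) / pb.std()
        stat = np.mean(za * zpb)
        if stat >= observed - 1e-12:
            count_ge += 1
        if stat <= observed + 1e-12:
            count_le += 1
    p_greater = (1 + count_ge) / (1 + n_perm)
    if tails == 1:
        p = p_greater
    elif tails == 2:
        p_less = (1 + count_le) / (1 + n_perm)
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ConfigurationError("tails must be 1 or 2")
    return observed, float(p)


def fisher_z(rho):
    """Variance-stabilizing atanh transform, clipped at |rho| = 1 - 1e-7."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) > 1):
        raise ValueError("correlation must lie in [-1, 1]")
    out = np.arctanh(np.clip(rho, -_CLIP, _CLIP))
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def split_half_reliability(subject_rdms, n_splits=1000, seed=0):
    """Group-mean RDM reliability via random 50/50 subject splits.

    Each split correlates (Spearman) the two half-sample mean RDMs; the
    correlations are Fisher-z averaged across splits, back-transformed,
    and Spearman-Brown corrected (``r' = 2r / (1 + r)``).  With an odd
    subject count the extra subject is assigned at random per split.
    """
    mats = [_as_matrix(r) for r in subject_rdms]
    S = len(mats)
    if S < 4:
        raise ConfigurationError("need at least 4 subjects")
    stack = np.stack(mats)
    rng = np.random.default_rng(seed)
    zs = []
    for _ in range(n_splits):
        perm = rng.permutation(S)
        half = S // 2
        m1 = stack[perm[:half]].mean(axis=0)
        m2 = stack[perm[half:]].mean(axis=0)
        zs.append(fisher_z(spearman_rdm(m1, m2)))
    r = fisher_z_inverse(float(np.mean(zs)))
    return float(2.0 * r / (1.0 + r))


@dataclass
class NoiseCeilingResult:
    rel_group: float
    rel_s: np.ndarray
    rel_model: float
    nc_z: float


def nc_z_from_reliabilities(rel_s, rel_model):
    """z-domain ceiling from per-subject and model reliabilities.

    ``NC_z = (1/S) sum_s atanh(sqrt(rel_s * rel_model))`` with every
    reliability clipped to [0, 1 - 1e-7] first.
    """
    rel_s = np.clip(np.asarray(rel_s, dtype=float), 0.0, _CLIP)
    rel_model = float(np.clip(rel_model, 0.0, _CLIP))
    return float(np.mean(np.arctanh(
        np.clip(np.sqrt(rel_s * rel_model), 0.0, _CLIP))))


def noise_ceiling(subject_rdms, model_rdms, n_splits=1000, seed=0,
                  rel_s_override=None, rel_model_override=None):
    """Noise ceiling for subject-averaged Fisher-z model correlations.

    Subject reliability plugs the lower bound
    ``rel_s = r^2(X_s, mean(X_-s)) / rel_group`` in as a point estimate;
    model-instance reliability is the back-transformed Fisher-z mean of
    leave-one-out instance correlations.  Negative intermediate
    correlations clip at 0, reliabilities at [0, 1 - 1e-7].  The
    ``*_override`` hooks bypass estimation (used for worked examples).
    """
    subs = [_as_matrix(r) for r in subject_rdms]
    mods = [_as_matrix(r) for r in model_rdms]
    if rel_s_override is None and len(subs) < 3:
        raise ConfigurationError("need at least 3 subjects")
    if rel_model_override is None and len(mods) < 3:
        raise ConfigurationError("need at least 3 model instances")

    if rel_s_override is not None:
        rel_group = np.nan
        rel_s = np.clip(np.asarray(rel_s_override, dtype=float), 0.0, _CLIP)
    else:
        rel_group = split_half_reliability(subs, n_splits=n_splits, seed=seed)
        rel_group = float(np.clip(rel_group, 1e-12, _CLIP))
        stack = np.stack(subs)
        rel_s = []
        for s in range(len(subs)):
            loo = (stack.sum(axis=0) - stack[s]) / (len(subs) - 1)
            r = max(0.0, spearman_rdm(stack[s], loo))
            rel_s.append(r ** 2 / rel_group)
        rel_s = np.clip(np.asarray(rel_s), 0.0, _CLIP)

    if rel_model_override is not None:
        rel_model = float(np.clip(rel_model_override, 0.0, _CLIP))
    else:
        stack = np.stack(mods)
        zs = []
        for i in range(len(mods)):
            loo = (stack.sum(axis=0) - stack[i]) / (len(mods) - 1)
            zs.append(fisher_z(max(0.0, spearman_rdm(stack[i], loo))))
        rel_model = float(np.clip(
            fisher_z_inverse(float(np.mean(zs))), 0.0, _CLIP))

    return NoiseCeilingResult(
        rel_group=float(rel_group),
        rel_s=rel_s,
        rel_model=rel_model,
        nc_z=nc_z_from_reliabilities(rel_s, rel_model),
    )


@dataclass
class GroupTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    ci: tuple
    degenerate: bool = False


def group_level_tests(per_model_z, baseline=0.0, tails=1):
    """One-sample (or paired) t-test of Fisher-z values against a baseline.

    ``baseline`` may be a scalar (one-sample test) or a paired list of the
    same length (paired test on the differences).  Returns t, df, p,
    Cohen's d and the 95% CI of the (mean - baseline) difference.  Zero
    variance yields an explicit degenerate result rather than a silent NaN.
    """
    x = np.asarray(per_model_z, dtype=float)
    if x.size < 2:
        raise ConfigurationError("need at least 2 values")
    if np.ndim(baseline) > 0:
        b = np.asarray(baseline, dtype=float)
        if b.shape != x.shape:
            raise ConfigurationError("paired baseline must match in length")
        diffs = x - b
    else:
        diffs = x - float(baseline)
    n = diffs.size
    df = n - 1
    sd = diffs.std(ddof=1)
    mean = diffs.mean()
    if sd == 0:
        return GroupTestResult(t=np.nan, df=df, p=np.nan, cohen_d=np.nan,
                               ci=(mean, mean), degenerate=True)
    t_stat = mean / (sd / np.sqrt(n))
    if tails == 1:
        p = float(_st.t.sf(t_stat, df))
    elif tails == 2:
        p = float(2 * _st.t.sf(abs(t_stat), df))
    else:
        raise ConfigurationError("tails must be 1 or 2")
    half = _st.t.ppf(0.975, df) * sd / np.sqrt(n)
    return GroupTestResult(
        t=float(t_stat), df=df, p=p, cohen_d=float(mean / sd),
        ci=(float(mean - half), float(mean + half)))
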