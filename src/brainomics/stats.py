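"""Shared statistical primitives: rank tests, correlations, FDR, overlap
tests, PCA and Ward clustering.

These wrap the scipy/statsmodels routines a practitioner would reach for,
with the conventions fixed once here (exact small-sample rank tests,
continuity correction, BH step-up, deterministic PCA signs, Ward.D2
linkage) so every downstream stage shares them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "rank_sum_test",
    "spearman",
    "bh_adjust",
    "overlap_test",
    "pca",
    "ward_cluster",
]

EXACT_RANKSUM_MAX_N = 12  # exhaustive null enumeration up to this combined size


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    tail: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


_TAIL_TO_ALT = {"two-sided": "two-sided", "lower": "less", "upper": "greater"}


def rank_sum_test(x, y, tail: str = "two-sided") -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test of ``x`` against ``y``.

    ``tail='lower'`` tests that values in ``x`` tend to be smaller than in
    ``y``. Uses exhaustive enumeration of the null when the combined sample
    size is at most 12 and there are no ties, otherwise the normal
    approximation with mid-ranks, tie correction and continuity correction.
    Returns the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    if tail not in _TAIL_TO_ALT:
        raise ValueError(f"unknown tail {tail!r}")
    n = x.size + y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n
    if n <= EXACT_RANKSUM_MAX_N and not has_ties:
        method, label = "exact", "mann-whitney-exact"
    else:
        method, label = "asymptotic", "mann-whitney-normal"
    res = sps.mannwhitneyu(
        x, y, alternative=_TAIL_TO_ALT[tail], method=method, use_continuity=True
    )
    pvalue = float(res.pvalue)
    # U at the exact center of the null has two-sided p = 1 by symmetry;
    # the continuity-corrected normal approximation would report < 1 there
    if tail == "two-sided" and float(res.statistic) == x.size * y.size / 2.0:
        pvalue = 1.0
    return TestResult(float(res.statistic), pvalue, label, tail)


EXACT_SPEARMAN_MAX_N = 8
_spearman_null_cache: dict[int, np.ndarray] = {}


def _spearman_null_rhos(n: int) -> np.ndarray:
    """Exact null distribution of rho over all n! rank permutations."""
    if n not in _spearman_null_cache:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))), dtype=float)
        d2 = ((perms - np.arange(n)) ** 2).sum(axis=1)
        _spearman_null_cache[n] = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return _spearman_null_cache[n]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation.

    The two-sided p-value is exact (full permutation enumeration) for
    tie-free samples of at most 8 observations, and the usual
    t-approximation otherwise. A constant input vector leaves rho
    undefined: returns ``(nan, nan)`` with a warning rather than raising,
    so callers can drop the pair.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    n = x.size
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if tie_free and n <= EXACT_SPEARMAN_MAX_N:
        null = _spearman_null_rhos(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return float(rho), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_test(
    k: int, set_a_size: int, set_b_size: int, universe_size: int, method: str = "fisher"
) -> TestResult:
    """Test whether two sets drawn from a common universe overlap more than
    expected by chance.

    ``fisher`` gives the hypergeometric upper tail P(overlap >= k);
    ``chisq`` the 1-df chi-square on the 2x2 membership table (no Yates
    correction).
    """
    if not (0 <= k <= min(set_a_size, set_b_size)):
        raise ValueError("overlap k must satisfy 0 <= k <= min(set sizes)")
    if max(set_a_size, set_b_size) > universe_size:
        raise ValueError("set sizes cannot exceed the universe")
    d = universe_size - set_a_size - set_b_size + k
    if d < 0:
        raise ValueError("inconsistent counts: |A u B| exceeds the universe")
    if method == "fisher":
        p = float(sps.hypergeom.sf(k - 1, universe_size, set_a_size, set_b_size))
        return TestResult(float(k), min(p, 1.0), "fisher-exact", "upper")
    if method == "chisq":
        table = np.array(
            [[k, set_a_size - k], [set_b_size - k, d]], dtype=float
        )
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            return TestResult(0.0, 1.0, "chi-square", "upper")
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return TestResult(float(stat), float(p), "chi-square", "upper")
    raise ValueError(f"unknown method {method!r}")


def pca(matrix, n_components: int | None = None):
    """Principal components of a samples x features matrix.

    Features are mean-centered (not scaled); computed by SVD. Component
    signs are fixed so the largest-magnitude loading of each component is
    positive. Returns ``(scores, loadings, variance_fractions)`` where
    loadings is features x components.
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("pca expects a 2-D matrix")
    n, m = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps)) if s.size else 0
    k = min(n_components, s.size) if n_components is not None else s.size
    if n_components is not None and n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    total_var = np.sum(s**2)
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, loadings, var_frac


def ward_cluster(matrix, k: int | None = None, distance: str = "euclidean"):
    """Ward (D2) hierarchical clustering of the rows of ``matrix``.

    Returns ``(linkage_matrix, labels)``; labels are 1..k flat-cut
    assignments, or None when ``k`` is not given.
    """
    X = np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("ward_cluster requires at least 2 rows")
    if distance != "euclidean":
        raise ValueError("only Euclidean distance is supported")
    if np.any(~np.isfinite(X)):
        raise ValueError("NaN/inf in clustering input")
    Z = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") if k is not None else None
    return Z, labels
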