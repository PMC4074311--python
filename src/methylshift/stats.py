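"""Statistical primitives shared by every analysis stage.

The workhorse is the classical equal-variance (pooled) two-sample Student
t-test — used per cytosine in DMR calling, for global methylation contrasts
and for dimorphic-site selection — together with the Kolmogorov–Smirnov
two-sample test, Fisher's exact 2×2 test, hypergeometric overlap enrichment,
Pearson correlation matrices, and complete-linkage agglomerative clustering.

Conventions: p-values are two-sided except for overlap enrichment, which is
the upper tail P(X ≥ k) (right-tailed, as is standard for gene-set overlap).
A pooled SD of exactly zero yields t=0, p=1 when the means agree and a
signed infinite t with p=0 when they do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    delta: float  # mean(A) - mean(B)


@dataclass
class KsResult:
    d: float
    p: float


@dataclass
class OverlapEnrichment:
    k: int
    nA: int
    nB: int
    N: int
    p: float
    fold: float


# ---------------------------------------------------------------------------
# Pooled t
# ---------------------------------------------------------------------------

def _pooled_from_moments(
    mean_a: np.ndarray, var_a: np.ndarray, n_a: int,
    mean_b: np.ndarray, var_b: np.ndarray, n_b: int,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized t/df/p from group moments (``var`` with ddof=1)."""
    delta = mean_a - mean_b
    if equal_var:
        df = np.asarray(float(n_a + n_b - 2))
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        va, vb = var_a / n_a, var_b / n_b
        se = np.sqrt(va + vb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        df = np.where(np.isfinite(df), df, n_a + n_b - 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    # degenerate pooled SD: equal means -> t=0; unequal -> signed infinity
    zero_se = se == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (delta == 0), 0.0, t)
        t = np.where(zero_se & (delta != 0), np.sign(delta) * np.inf, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, np.broadcast_to(df, np.shape(t)).astype(float), p


def pooled_t(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample Student t-test with pooled variance (Welch optional).

    Both samples need n ≥ 2.  ``delta`` is mean(A) − mean(B) and shares its
    sign with ``t`` whenever the pooled SD is positive.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("pooled_t requires at least two values per group")
    t, df, p = _pooled_from_moments(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size,
        equal_var=equal_var,
    )
    return TTestResult(float(t), float(df), float(p), float(a.mean() - b.mean()))


def pooled_t_summary(
    mean_a: float, sem_a: float, n_a: int,
    mean_b: float, sem_b: float, n_b: int,
    equal_var: bool = True,
) -> TTestResult:
    """Pooled t from summary statistics (means, SEMs, group sizes).

    The group SD is reconstructed as SEM·√n, so published mean ± SEM tables
    can be tested directly.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("pooled_t_summary requires n >= 2 per group")
    var_a = (sem_a * np.sqrt(n_a)) ** 2
    var_b = (sem_b * np.sqrt(n_b)) ** 2
    t, df, p = _pooled_from_moments(
        np.asarray(float(mean_a)), np.asarray(var_a), n_a,
        np.asarray(float(mean_b)), np.asarray(var_b), n_b,
        equal_var=equal_var,
    )
    return TTestResult(float(t), float(df), float(p), float(mean_a - mean_b))


def pooled_t_arrays(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled t over two matrices of shape (n_sites, n_reps).

    Returns (t, p, delta) arrays; this is the vectorized path used for
    per-cytosine testing across whole methylomes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, _, p = _pooled_from_moments(
        a.mean(axis=1), a.var(axis=1, ddof=1), a.shape[1],
        b.mean(axis=1), b.var(axis=1, ddof=1), b.shape[1],
        equal_var=equal_var,
    )
    return t, p, a.mean(axis=1) - b.mean(axis=1)


# ---------------------------------------------------------------------------
# Distribution and count tests
# ---------------------------------------------------------------------------

def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov–Smirnov test: D = sup |ECDF_x − ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample requires nonempty samples")
    res = sps.ks_2samp(x, y, alternative="two-sided")
    return KsResult(float(res.statistic), float(res.pvalue))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2×2 count table (two-sided, probability order).

    Returns (odds_ratio, p).  The odds ratio is the sample cross ratio
    ad/bc (inf when bc = 0 and ad > 0).
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if tab.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return float(odds), float(p)


def hypergeom_overlap(k: int, nA: int, nB: int, N: int) -> OverlapEnrichment:
    """Upper-tail hypergeometric overlap test with fold enrichment.

    Drawing ``nA`` items from a universe of ``N`` containing ``nB`` marked
    items, ``p`` = P(X ≥ k) and ``fold`` = (k/nA)/(nB/N), the observed
    overlap relative to its chance expectation.
    """
    if not (0 <= k <= min(nA, nB)):
        raise ValueError(f"k={k} outside [0, min(nA={nA}, nB={nB})]")
    if max(nA, nB) > N:
        raise ValueError("set larger than universe")
    if k < max(0, nA + nB - N):
        raise ValueError("overlap below the deterministic minimum")
    p = float(sps.hypergeom.sf(k - 1, N, nB, nA))
    fold = (k / nA) / (nB / N) if nA > 0 and nB > 0 else 0.0
    return OverlapEnrichment(k, nA, nB, N, min(p, 1.0), fold)


# ---------------------------------------------------------------------------
# Correlation and clustering
# ---------------------------------------------------------------------------

def pearson_matrix(samples: Sequence[Sequence[float]]) -> np.ndarray:
    """Symmetric Pearson correlation matrix over aligned vectors.

    Zero-variance vectors make their pairwise correlations undefined; those
    entries are returned as NaN (the diagonal stays 1) rather than silently 0.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need >=2 aligned observations per vector")
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.atleast_2d(R)
    bad = sd == 0
    if bad.any():
        R[bad, :] = np.nan
        R[:, bad] = np.nan
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0, out=R)


def hier_cluster(
    X: Sequence[Sequence[float]], metric: str = "euclidean", linkage: str = "complete"
) -> tuple[np.ndarray, list[int]]:
    """Agglomerative clustering; returns (scipy linkage matrix, leaf order)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    D = pdist(X, metric=metric)
    if np.isnan(D).any():
        raise ValueError("NaN distances")
    Z = sch.linkage(D, method=linkage)
    return Z, list(sch.leaves_list(Z))
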