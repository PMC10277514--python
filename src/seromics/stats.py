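"""Self-contained statistical primitives.

Every routine here is a pure function validated in the test suite against an
independent brute-force oracle (full enumeration, literal step-up definitions,
binomial tail sums, exhaustive objective evaluation).  Conventions, stated
once because upstream software rarely states them:

* ties receive mid-ranks (Mann-Whitney and Spearman);
* all p-values are two-sided;
* the default multiple-testing procedure is the two-stage sharpened
  linear step-up FDR (Benjamini-Krieger-Yekutieli), with plain BH and BY
  available behind a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "FDRDecision",
    "mann_whitney",
    "chi_square_2xk",
    "spearman",
    "spearman_test",
    "bky_two_stage",
    "fdr_reject",
    "mcnemar",
    "ward_linkage",
    "cut_tree",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    exact: bool = False
    note: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class FDRDecision:
    """Result of a multiple-testing step-up procedure on one family."""

    p_values: np.ndarray
    q: float
    rejected: np.ndarray          # boolean, aligned with p_values
    method: str
    stage1_rejections: int | None = None
    adjusted: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def _tie_corrected_sd(pooled: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    if n <= 1:
        return 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def _exact_mw_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates every way of assigning n1 of the pooled observations to the
    first sample; mid-ranks are held fixed, so ties are handled exactly.
    """
    n = len(ranks)
    offset = n1 * (n1 + 1) / 2.0
    u_all = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in itertools.combinations(range(n), n1)),
        dtype=float,
    )
    eps = 1e-9
    p_le = np.mean(u_all <= u_obs + eps)
    p_ge = np.mean(u_all >= u_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test with mid-rank tie handling.

    Parameters
    ----------
    x, y : array-like
        The two samples; each must be nonempty.
    mode : {"auto", "exact", "asymptotic"}
        ``exact`` enumerates the permutation distribution of U (ties OK).
        ``asymptotic`` uses the tie-corrected normal approximation with a
        continuity correction.  ``auto`` picks exact when n+m <= 20 and the
        pooled sample has no ties.

    Returns
    -------
    TestResult with ``statistic`` = U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires both samples to be nonempty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    use_exact = mode == "exact" or (mode == "auto" and n1 + n2 <= 20 and not has_ties)
    if use_exact:
        p = _exact_mw_p(ranks, n1, u1)
        return TestResult(u1, p, "mann-whitney", exact=True)

    mean_u = n1 * n2 / 2.0
    sd = _tie_corrected_sd(pooled, n1, n2)
    if sd == 0.0:
        # all pooled values identical: no evidence either way
        return TestResult(u1, 1.0, "mann-whitney", note="degenerate: zero variance")
    z = max(abs(u1 - mean_u) - 0.5, 0.0) / sd
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(u1, p, "mann-whitney")


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------

def chi_square_2xk(table) -> TestResult:
    """Pearson chi-square on an r x k contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal row or column")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), "chi-square")


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Returns NaN for a constant input vector (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_test(x, y) -> TestResult:
    """Spearman rho with the t-approximation p-value."""
    rho = spearman(x, y)
    n = len(np.asarray(x))
    if math.isnan(rho):
        return TestResult(rho, float("nan"), "spearman", note="constant input")
    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, "spearman")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = min(1.0, 2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(rho, p, "spearman")


# ---------------------------------------------------------------------------
# False discovery rate
# ---------------------------------------------------------------------------

def _step_up_reject(p: np.ndarray, alpha: float, c_m: float = 1.0) -> np.ndarray:
    """Linear step-up (BH) rejection set at level alpha; c_m=harmonic for BY."""
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) / (m * c_m)) * alpha
    below = sorted_p <= thresholds
    rejected = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        rejected[order[: k + 1]] = True
    return rejected


def bky_two_stage(p, q: float = 0.05) -> FDRDecision:
    """Two-stage sharpened linear step-up FDR procedure.

    Stage 1 runs the linear step-up at q' = q/(1+q); with r1 rejections the
    number of true nulls is estimated as m0 = m - r1, and stage 2 reruns the
    step-up at q' * m / m0.  r1 = 0 rejects nothing; r1 = m rejects all.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    q_prime = q / (1.0 + q)
    stage1 = _step_up_reject(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        rejected = np.zeros(m, dtype=bool)
    elif r1 == m:
        rejected = np.ones(m, dtype=bool)
    else:
        m0 = m - r1
        rejected = _step_up_reject(p, q_prime * m / m0)
    return FDRDecision(p, q, rejected, "bky-two-stage", stage1_rejections=r1)


def _bh_adjusted(p: np.ndarray, c_m: float = 1.0) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def fdr_reject(p, q: float = 0.05, method: str = "bky") -> FDRDecision:
    """FDR decision with selectable procedure: ``bky`` (default), ``bh``, ``by``."""
    p_arr = np.asarray(p, dtype=float)
    if method == "bky":
        return bky_two_stage(p_arr, q)
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        c_m = 1.0
    elif method == "by":
        c_m = float(np.sum(1.0 / np.arange(1, p_arr.size + 1)))
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    rejected = _step_up_reject(p_arr, q, c_m)
    return FDRDecision(p_arr, q, rejected, method, adjusted=_bh_adjusted(p_arr, c_m))


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def mcnemar(b: int, c: int, mode: str = "exact", correction: bool = True) -> TestResult:
    """McNemar test on the two discordant counts of a paired design.

    ``exact`` is the two-sided binomial test of b successes out of b+c at
    probability 1/2; ``asymptotic`` is the chi-square on the discordant
    difference, by default with the continuity correction
    (|b-c|-1)^2/(b+c) — without it the approximation strays well past the
    exact tail for moderate counts.  ``correction=False`` gives the plain
    (b-c)^2/(b+c) statistic.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be nonnegative integers")
    n = b + c
    if n == 0:
        return TestResult(0.0, 1.0, "mcnemar", exact=mode == "exact",
                          note="no discordant pairs")
    if mode == "exact":
        k = max(b, c)
        p = min(1.0, 2.0 * sps.binom.sf(k - 1, n, 0.5))
        if b == c:
            p = 1.0
        return TestResult(float(b), p, "mcnemar", exact=True)
    if mode == "asymptotic":
        diff = max(abs(b - c) - 1, 0) if correction else abs(b - c)
        stat = diff**2 / n
        p = float(sps.chi2.sf(stat, df=1))
        return TestResult(float(stat), p, "mcnemar")
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Ward hierarchical clustering
# ---------------------------------------------------------------------------

def ward_linkage(data, *, is_distance: bool = False) -> np.ndarray:
    """Agglomerative Ward clustering on Euclidean distances.

    Greedy merging with the Lance-Williams Ward update on squared distances;
    ties in the minimum merge cost are broken by the lexicographically
    smallest (cluster id, cluster id) pair, so output is fully deterministic.

    Parameters
    ----------
    data : array
        Either an (n, p) observation matrix or, with ``is_distance=True``, an
        (n, n) symmetric Euclidean distance matrix.

    Returns
    -------
    (n-1, 4) linkage matrix in the usual format: merged ids, merge height
    (sqrt of twice the within-cluster variance increase), new cluster size.
    """
    arr = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in clustering input")
    if is_distance:
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        d2 = arr**2
        n = arr.shape[0]
    else:
        if arr.ndim != 2:
            raise ValueError("observations must form a 2-D matrix")
        n = arr.shape[0]
        sq = np.sum(arr**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * arr @ arr.T
        np.maximum(d2, 0.0, out=d2)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    np.fill_diagonal(d2, np.inf)
    active = np.ones(n, dtype=bool)
    ids = np.arange(n)            # position -> current cluster id
    sizes = np.ones(n)
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        sub = np.where(active)[0]
        block = d2[np.ix_(sub, sub)]
        dmin = block.min()
        # candidate positions with the minimal cost; break ties on cluster ids
        cand = np.argwhere(np.isclose(block, dmin, rtol=0.0, atol=0.0))
        pairs = []
        for a, b in cand:
            if a < b:
                i, j = sub[a], sub[b]
                lo, hi = sorted((ids[i], ids[j]))
                pairs.append((lo, hi, i, j))
        lo, hi, i, j = min(pairs)

        ni, nj = sizes[i], sizes[j]
        Z[step] = [lo, hi, math.sqrt(max(dmin, 0.0)), ni + nj]

        # Lance-Williams Ward update into slot i
        for k in np.where(active)[0]:
            if k == i or k == j:
                continue
            nk = sizes[k]
            new = ((ni + nk) * d2[i, k] + (nj + nk) * d2[j, k] - nk * dmin) / (
                ni + nj + nk
            )
            d2[i, k] = d2[k, i] = new
        active[j] = False
        d2[j, :] = np.inf
        d2[:, j] = np.inf
        sizes[i] = ni + nj
        ids[i] = n + step
    return Z


def cut_tree(Z: np.ndarray, k: int | None = None, height: float | None = None) -> np.ndarray:
    """Flat clusters from a linkage matrix, by cluster count or by height.

    Labels are integers 0..k-1, renumbered by first appearance in item order.
    """
    n = Z.shape[0] + 1
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if k is not None:
        if not (1 <= k <= n):
            raise ValueError(f"k={k} out of range [1, {n}]")
        n_merges = n - k
    else:
        n_merges = int(np.sum(Z[:, 2] <= height))

    parent = list(range(n + n_merges))
    members: dict[int, int] = {}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n_merges):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for item in range(n):
        root = find(item)
        if root not in seen:
            seen[root] = len(seen)
        labels[item] = seen[root]
    return labels
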