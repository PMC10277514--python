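"""Marker-driven patient subgroup discovery on an expression matrix.

Samples are Ward-clustered in the space of a small marker-gene panel, the
resulting clusters are compared pairwise for differentially expressed genes
(Welch test per gene with two-stage FDR), and the observed DEG counts are
calibrated against a null of randomly assembled clusters of the same sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import cut_tree, fdr_reject, ward_linkage

__all__ = [
    "SubgroupPartition",
    "PairwiseDEGCounts",
    "cluster_samples_on_markers",
    "pairwise_deg",
    "random_cluster_null",
    "deg_compartment_summary",
]


@dataclass
class SubgroupPartition:
    """A flat clustering of samples in marker space."""

    labels: pd.Series                  # sample id -> cluster label (0..k-1)
    markers: list[str]
    linkage: np.ndarray = field(repr=False)
    k: int = 0

    def __post_init__(self):
        if self.k == 0:
            self.k = int(self.labels.nunique())

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class PairwiseDEGCounts:
    """Symmetric cluster-pair DEG counts with per-pair gene lists."""

    counts: dict[tuple[int, int], int]
    genes: dict[tuple[int, int], list[str]]
    q: float
    skipped_clusters: list[int] = field(default_factory=list)

    def count(self, a: int, b: int) -> int:
        if a == b:
            return 0
        return self.counts[tuple(sorted((a, b)))]

    def gene_list(self, a: int, b: int) -> list[str]:
        if a == b:
            return []
        return self.genes[tuple(sorted((a, b)))]

    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    def as_matrix(self) -> pd.DataFrame:
        labels = sorted({c for pair in self.counts for c in pair})
        m = pd.DataFrame(0, index=labels, columns=labels)
        for (a, b), n in self.counts.items():
            m.loc[a, b] = m.loc[b, a] = n
        return m


def cluster_samples_on_markers(
    expr: pd.DataFrame, markers: list[str], k: int
) -> SubgroupPartition:
    """Ward/Euclidean clustering of samples restricted to marker columns."""
    missing = [m for m in markers if m not in expr.columns]
    if missing:
        raise KeyError(f"markers missing from expression matrix: {missing}")
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = expr[markers]
    if (sub.nunique() <= 1).all():
        warnings.warn("all markers constant across samples; degenerate tree",
                      stacklevel=2)
    Z = ward_linkage(sub.to_numpy())
    labels = pd.Series(cut_tree(Z, k=k), index=expr.index)
    return SubgroupPartition(labels, list(markers), Z, k)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def pairwise_deg(
    expr: pd.DataFrame,
    partition: SubgroupPartition,
    q: float = 0.05,
    min_cluster: int = 3,
    fdr_method: str = "bky",
) -> PairwiseDEGCounts:
    """Per cluster pair: Welch two-sample test per gene, FDR at q.

    Clusters smaller than ``min_cluster`` are skipped (recorded in
    ``skipped_clusters``).  Needs at least two eligible clusters.
    """
    labels = partition.labels.loc[expr.index]
    sizes = labels.value_counts()
    eligible = sorted(sizes.index[sizes >= min_cluster])
    skipped = sorted(sizes.index[sizes < min_cluster])
    if len(eligible) < 2:
        raise ValueError(
            f"only {len(eligible)} clusters with >= {min_cluster} samples"
        )
    arr = expr.to_numpy()
    gene_names = np.asarray(expr.columns)
    by_cluster = {c: arr[(labels == c).to_numpy()] for c in eligible}
    counts: dict[tuple[int, int], int] = {}
    genes: dict[tuple[int, int], list[str]] = {}
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            p = _welch_p(by_cluster[a], by_cluster[b])
            rejected = fdr_reject(p, q, method=fdr_method).rejected
            counts[(a, b)] = int(rejected.sum())
            genes[(a, b)] = gene_names[rejected].tolist()
    return PairwiseDEGCounts(counts, genes, q, skipped)


def random_cluster_null(
    expr: pd.DataFrame,
    sizes: list[int],
    n_permutations: int = 100,
    q: float = 0.05,
    seed: int = 0,
    min_cluster: int = 3,
    fdr_method: str = "bky",
) -> dict:
    """Null distribution of pairwise DEG counts under random cluster assembly.

    Each permutation assigns samples at random (without replacement) to
    clusters of the given sizes and records all pairwise DEG counts.
    Returns the per-permutation max counts, all counts, and the empirical
    50/95/99th percentiles of the max; reproducible under ``seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sizes = [int(s) for s in sizes]
    if any(s <= 0 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    n = expr.shape[0]
    if sum(sizes) > n:
        raise ValueError(f"cluster sizes sum to {sum(sizes)} > {n} samples")
    rng = np.random.default_rng(seed)
    max_counts = np.zeros(n_permutations, dtype=int)
    all_counts: list[int] = []
    for it in range(n_permutations):
        perm = rng.permutation(n)
        labels = np.full(n, -1)
        start = 0
        for ci, s in enumerate(sizes):
            labels[perm[start : start + s]] = ci
            start += s
        part = SubgroupPartition(
            pd.Series(labels, index=expr.index)[lambda s: s >= 0],
            markers=[], linkage=np.zeros((0, 4)), k=len(sizes),
        )
        assigned = expr.loc[part.labels.index]
        deg = pairwise_deg(assigned, part, q=q, min_cluster=min_cluster,
                           fdr_method=fdr_method)
        max_counts[it] = deg.max_count()
        all_counts.extend(deg.counts.values())
    return dict(
        max_counts=max_counts,
        all_counts=np.asarray(all_counts),
        percentiles={
            50: float(np.percentile(max_counts, 50)),
            95: float(np.percentile(max_counts, 95)),
            99: float(np.percentile(max_counts, 99)),
        },
        n_permutations=n_permutations,
        seed=seed,
    )


def deg_compartment_summary(
    gene_lists: dict, annotation: dict[str, str]
) -> dict:
    """Biotype frequency table per cluster pair.

    ``annotation`` maps gene -> biotype (e.g. protein_coding); genes absent
    from it are counted as "unknown".  Empty DEG lists yield empty tables.
    """
    if not annotation:
        raise ValueError("empty gene annotation")
    out = {}
    for pair, genes in gene_lists.items():
        if not genes:
            out[pair] = {}
            continue
        biotypes = pd.Series([annotation.get(g, "unknown") for g in genes])
        out[pair] = (biotypes.value_counts() / len(genes)).to_dict()
    return out
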