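"""Differential co-expression via residual Spearman matrices.

A per-group protein-protein Spearman matrix is computed, two groups are
contrasted by element-wise subtraction of coefficients, and the residual
matrix's rows (protein profiles) are Ward-clustered to extract blocks of
differentially co-expressed proteins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import NPXMatrix
from .stats import cut_tree, ward_linkage

__all__ = [
    "GroupCorrMatrix",
    "ResidualCorrMatrix",
    "group_correlation",
    "residual_matrix",
    "cluster_residuals",
    "cluster_enrichment_summary",
    "choose_k_by_height_gap",
]


@dataclass
class GroupCorrMatrix:
    """Protein x protein Spearman coefficients within one sample group."""

    corr: pd.DataFrame
    group: str
    n_samples: int
    constant_proteins: list[str] = field(default_factory=list)


@dataclass
class ResidualCorrMatrix:
    """Element-wise difference of two group correlation matrices."""

    values: pd.DataFrame
    contrast: str                      # e.g. "NASH-NAFL"
    corr_a: GroupCorrMatrix | None = None
    corr_b: GroupCorrMatrix | None = None
    cluster_labels: pd.Series | None = None
    linkage: np.ndarray | None = None
    note: str | None = None

    @property
    def clusters(self) -> list[list[str]]:
        """Cluster membership lists, largest first (ties by label order)."""
        if self.cluster_labels is None:
            raise ValueError("residual matrix has not been clustered")
        out = [
            list(self.cluster_labels.index[self.cluster_labels == lab])
            for lab in sorted(self.cluster_labels.unique())
        ]
        return sorted(out, key=len, reverse=True)


def group_correlation(matrix: NPXMatrix, meta: pd.DataFrame, group: str) -> GroupCorrMatrix:
    """Pairwise Spearman over all proteins for the samples of one group.

    Constant proteins get NaN off-diagonal entries and are listed in
    ``constant_proteins``; the diagonal is fixed at 1.
    """
    groups = meta.set_index("sample_id")["group"]
    ids = [s for s in matrix.samples if groups.get(s) == group]
    if len(ids) < 4:
        raise ValueError(f"group {group!r} has {len(ids)} samples; need >= 4")
    vals = matrix.values.loc[ids]
    ranks = vals.rank(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(ranks.T)
    constant = [p for p, v in zip(matrix.proteins, vals.nunique()) if v < 2]
    np.fill_diagonal(R, 1.0)
    corr = pd.DataFrame(R, index=matrix.proteins, columns=matrix.proteins)
    return GroupCorrMatrix(corr, group, len(ids), constant)


def residual_matrix(a: GroupCorrMatrix, b: GroupCorrMatrix) -> ResidualCorrMatrix:
    """Element-wise a - b; missing coefficients propagate as missing."""
    if list(a.corr.columns) != list(b.corr.columns):
        raise ValueError("correlation matrices cover different protein sets")
    diff = a.corr - b.corr
    return ResidualCorrMatrix(
        diff, contrast=f"{a.group}-{b.group}", corr_a=a, corr_b=b
    )


def choose_k_by_height_gap(Z: np.ndarray, k_min: int = 2, k_max: int | None = None) -> int:
    """Cluster count at the largest gap between successive merge heights."""
    n = Z.shape[0] + 1
    if k_max is None:
        k_max = max(k_min, n // 2)
    heights = Z[:, 2]
    best_k, best_gap = k_min, -1.0
    for i in range(n - 2):
        k = n - i - 1                 # clusters left after merges 0..i
        if not (k_min <= k <= k_max):
            continue
        gap = heights[i + 1] - heights[i]
        if gap > best_gap:
            best_gap, best_k = gap, k
    return best_k


def cluster_residuals(
    residual: ResidualCorrMatrix, k: int | None = None, height: float | None = None
) -> ResidualCorrMatrix:
    """Ward-cluster the residual matrix's protein row-profiles.

    Missing entries are imputed to 0 (conservative toward the null) with a
    warning.  When neither ``k`` nor ``height`` is given the cluster count
    is chosen at the largest merge-height gap.  Returns a new
    ResidualCorrMatrix carrying labels and the linkage.
    """
    vals = residual.values.copy()
    if vals.isna().any().any():
        warnings.warn(
            "missing residual entries imputed to 0 for clustering", stacklevel=2
        )
        vals = vals.fillna(0.0)
    note = None
    arr = vals.to_numpy()
    if np.allclose(arr, 0.0):
        note = "all-zero residual: single trivial cluster"
        labels = pd.Series(0, index=vals.index)
        Z = ward_linkage(arr)
        return ResidualCorrMatrix(
            residual.values, residual.contrast, residual.corr_a, residual.corr_b,
            cluster_labels=labels, linkage=Z, note=note,
        )
    Z = ward_linkage(arr)
    if height is not None:
        flat = cut_tree(Z, height=height)
    else:
        if k is None:
            k = choose_k_by_height_gap(Z)
        flat = cut_tree(Z, k=k)
    labels = pd.Series(flat, index=vals.index)
    return ResidualCorrMatrix(
        residual.values, residual.contrast, residual.corr_a, residual.corr_b,
        cluster_labels=labels, linkage=Z, note=note,
    )


def _rho_p(rho: float, n: int) -> float:
    if math.isnan(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return min(1.0, 2.0 * float(sps.t.sf(abs(t), n - 2)))


def cluster_enrichment_summary(
    clustered: ResidualCorrMatrix, top_n: int = 5
) -> list[dict]:
    """Per-cluster summary: members, mean within-cluster |residual|, and the
    top differential pairs with both groups' coefficients and p-values.

    Singleton clusters contribute no pairs.  Clusters are reported largest
    first.
    """
    if clustered.cluster_labels is None:
        raise ValueError("cluster the residual matrix first")
    vals = clustered.values
    out = []
    for members in clustered.clusters:
        pairs = []
        if len(members) > 1:
            for i, p1 in enumerate(members):
                for p2 in members[i + 1 :]:
                    r = vals.loc[p1, p2]
                    pairs.append((p1, p2, float(r)))
        abs_res = [abs(r) for _, _, r in pairs if not math.isnan(r)]
        mean_abs = float(np.mean(abs_res)) if abs_res else 0.0
        top = sorted(
            (p for p in pairs if not math.isnan(p[2])),
            key=lambda t: abs(t[2]),
            reverse=True,
        )[:top_n]
        top_pairs = []
        for p1, p2, r in top:
            entry = dict(pair=(p1, p2), residual=r)
            if clustered.corr_a is not None and clustered.corr_b is not None:
                ra = float(clustered.corr_a.corr.loc[p1, p2])
                rb = float(clustered.corr_b.corr.loc[p1, p2])
                entry.update(
                    rho_a=ra,
                    rho_b=rb,
                    p_a=_rho_p(ra, clustered.corr_a.n_samples),
                    p_b=_rho_p(rb, clustered.corr_b.n_samples),
                    group_a=clustered.corr_a.group,
                    group_b=clustered.corr_b.group,
                )
            top_pairs.append(entry)
        out.append(
            dict(
                members=members,
                size=len(members),
                mean_abs_residual=mean_abs,
                top_pairs=top_pairs,
            )
        )
    return out
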