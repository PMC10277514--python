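"""Group-wise differential protein abundance.

Per protein: a two-sided Mann-Whitney test, a median-based effect on the NPX
scale (with its linear-scale ratio 2^effect, since NPX is log2-like), and a
joint two-stage FDR decision across the whole tested panel.  Also provides
the per-protein heat-map normalization (division by a reference group's
linear-scale median) and covariate-stratified re-testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io import NPXMatrix
from .stats import fdr_reject, mann_whitney

__all__ = [
    "differential",
    "median_normalize_heatmap",
    "StratificationSpec",
    "stratified_differential",
    "by_fibrosis",
    "by_bmi",
    "by_boolean",
    "by_sex",
    "by_age_median",
]

TABLE_COLUMNS = [
    "protein", "median_a", "median_b", "effect", "ratio",
    "p_value", "rejected", "direction",
]


def _differential_on_ids(
    matrix: NPXMatrix,
    ids_a: list[str],
    ids_b: list[str],
    q: float,
    fdr_method: str,
    mw_mode: str,
) -> pd.DataFrame:
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    va = matrix.values.loc[ids_a]
    vb = matrix.values.loc[ids_b]
    rows = []
    for prot in matrix.proteins:
        a = va[prot].to_numpy()
        b = vb[prot].to_numpy()
        res = mann_whitney(a, b, mode=mw_mode)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        effect = med_a - med_b
        rows.append(
            dict(
                protein=prot,
                median_a=med_a,
                median_b=med_b,
                effect=effect,
                ratio=2.0**effect,
                p_value=res.p_value,
                direction="up" if effect > 0 else "down",
            )
        )
    table = pd.DataFrame(rows)
    decision = fdr_reject(table["p_value"].to_numpy(), q, method=fdr_method)
    table["rejected"] = decision.rejected
    return table[TABLE_COLUMNS]


def differential(
    matrix: NPXMatrix,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    q: float = 0.05,
    fdr_method: str = "bky",
    mw_mode: str = "auto",
) -> pd.DataFrame:
    """Volcano table for group_a vs group_b over all proteins in the matrix.

    ``effect`` is median(group_a) - median(group_b) in NPX units; ``ratio``
    is 2^effect on the linear scale.  The FDR decision is made jointly
    across all proteins of this one comparison.
    """
    groups = meta.set_index("sample_id")["group"]
    for g in (group_a, group_b):
        if g not in set(groups):
            raise ValueError(f"group {g!r} absent from metadata")
    ids_a = [s for s in matrix.samples if groups.get(s) == group_a]
    ids_b = [s for s in matrix.samples if groups.get(s) == group_b]
    return _differential_on_ids(matrix, ids_a, ids_b, q, fdr_method, mw_mode)


def median_normalize_heatmap(
    matrix: NPXMatrix, meta: pd.DataFrame, reference_group: str = "NAFL"
) -> pd.DataFrame:
    """Linear-scale matrix with each protein divided by the reference
    group's median.

    NPX values are linearized (2^NPX) first; after normalization every
    protein's reference-group median equals 1.
    """
    groups = meta.set_index("sample_id")["group"]
    ref_ids = [s for s in matrix.samples if groups.get(s) == reference_group]
    if not ref_ids:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    linear = np.power(2.0, matrix.values)
    return normalize_linear_by_reference(linear, ref_ids)


def normalize_linear_by_reference(
    linear: pd.DataFrame, reference_ids: list[str]
) -> pd.DataFrame:
    """Divide each column of an already-linear matrix by its reference median."""
    ref_median = linear.loc[reference_ids].median(axis=0)
    if (ref_median <= 0).any():
        bad = ref_median.index[ref_median <= 0].tolist()
        raise ValueError(f"non-positive reference medians for: {bad}")
    return linear / ref_median


# ---------------------------------------------------------------------------
# confounder stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratificationSpec:
    """A covariate-defined two-way split of the cohort.

    ``selector`` maps the metadata frame to a boolean Series indexed by
    sample id (True -> stratum A); samples with a null selector value are
    dropped from the comparison.
    """

    name: str
    label_a: str
    label_b: str
    selector: Callable[[pd.DataFrame], pd.Series]

    def split(self, meta: pd.DataFrame) -> tuple[list[str], list[str]]:
        flags = self.selector(meta)
        flags.index = meta["sample_id"]
        a = flags.index[flags == True].tolist()   # noqa: E712 (nullable bools)
        b = flags.index[flags == False].tolist()  # noqa: E712
        if not a or not b:
            raise ValueError(
                f"stratification {self.name!r} yields an empty stratum "
                f"({self.label_a}: {len(a)}, {self.label_b}: {len(b)})"
            )
        return a, b


def by_fibrosis() -> StratificationSpec:
    """Low (stage 0-1) vs significant (stage 2-4) fibrosis."""
    return StratificationSpec(
        "fibrosis", "stage 2-4", "stage 0-1",
        lambda m: m["fibrosis_stage"] >= 2,
    )


def by_bmi(cut: float = 25.0) -> StratificationSpec:
    return StratificationSpec(
        "bmi", f"BMI > {cut}", f"BMI <= {cut}", lambda m: m["bmi"] > cut
    )


def by_boolean(column: str) -> StratificationSpec:
    return StratificationSpec(
        column, column, f"no {column}", lambda m: m[column].astype(bool)
    )


def by_sex() -> StratificationSpec:
    return StratificationSpec("sex", "F", "M", lambda m: m["sex"] == "F")


def by_age_median() -> StratificationSpec:
    # the age grouping is a median split; any other cut is equally defensible
    return StratificationSpec(
        "age", "above median age", "at/below median age",
        lambda m: m["age"] > m["age"].median(),
    )


def stratified_differential(
    matrix: NPXMatrix,
    meta: pd.DataFrame,
    spec: StratificationSpec,
    q: float = 0.05,
    fdr_method: str = "bky",
    patients_only: bool = False,
) -> pd.DataFrame:
    """The differential machinery applied to a covariate-defined split."""
    use = meta[meta["group"] != "HC"] if patients_only else meta
    ids_a, ids_b = spec.split(use)
    ids_a = [s for s in ids_a if s in matrix.values.index]
    ids_b = [s for s in ids_b if s in matrix.values.index]
    return _differential_on_ids(matrix, ids_a, ids_b, q, fdr_method, "auto")
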