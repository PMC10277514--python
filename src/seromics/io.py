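"""Readers/writers for NPX expression data and sample metadata, plus the
detection-rate QC filter that reduces the measured panel to the analyzed one.

Formats
-------
wide TSV      samples as rows, proteins as columns, header row; an optional
              companion TSV of the same shape holds the below-LOD flags (0/1).
long CSV      one row per (sample, protein) measurement with columns
              ``sample_id, protein_id, npx, below_lod``.
metadata TSV  one row per sample; see REQUIRED_META_COLUMNS.

All files are UTF-8; the missing-value token is ``NA``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NPXMatrix",
    "GROUPS",
    "read_wide_npx",
    "write_wide_npx",
    "read_long_npx",
    "write_long_npx",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "filter_by_detection",
]

GROUPS = ("HC", "NAFL", "NASH")

LONG_COLUMNS = ("sample_id", "protein_id", "npx", "below_lod")

REQUIRED_META_COLUMNS = ("sample_id", "group")
OPTIONAL_META_COLUMNS = (
    "fibrosis_stage",
    "nas",
    "steatosis",
    "lobular_inflammation",
    "ballooning",
    "t2d",
    "hypertension",
    "bmi",
    "age",
    "sex",
)


class NPXMatrix:
    """Samples x proteins expression on the NPX (log2-like) scale.

    Carries a boolean mask of the same shape flagging measurements that fell
    below the assay's limit of detection (those values sit at the LOD floor).
    """

    def __init__(self, values: pd.DataFrame, below_lod: pd.DataFrame | None = None):
        values = values.astype(float)
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated protein ids: {dups}")
        if below_lod is None:
            below_lod = pd.DataFrame(
                False, index=values.index, columns=values.columns
            )
        else:
            if not below_lod.index.equals(values.index) or not below_lod.columns.equals(
                values.columns
            ):
                raise ValueError("below_lod mask does not align with values")
            below_lod = below_lod.astype(bool)
        measured = values.to_numpy(dtype=float)[~below_lod.to_numpy(dtype=bool)]
        if not np.all(np.isfinite(measured)):
            raise ValueError("non-finite NPX values outside the below-LOD mask")
        self.values = values
        self.below_lod = below_lod

    # -- basic introspection ------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def below_lod_fraction(self) -> pd.Series:
        """Per-protein fraction of samples below the limit of detection."""
        return self.below_lod.mean(axis=0)

    def subset(self, samples=None, proteins=None) -> "NPXMatrix":
        v = self.values
        m = self.below_lod
        if samples is not None:
            v = v.loc[samples]
            m = m.loc[samples]
        if proteins is not None:
            v = v[proteins]
            m = m[proteins]
        return NPXMatrix(v.copy(), m.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, NPXMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.below_lod.equals(
            other.below_lod
        )


# ---------------------------------------------------------------------------
# wide TSV
# ---------------------------------------------------------------------------

def read_wide_npx(path, lod_path=None) -> NPXMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    mask = None
    if lod_path is not None:
        mask = pd.read_csv(lod_path, sep="\t", index_col=0).astype(bool)
    return NPXMatrix(values, mask)


def write_wide_npx(matrix: NPXMatrix, path, lod_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    if lod_path is not None:
        matrix.below_lod.astype(int).to_csv(lod_path, sep="\t")


# ---------------------------------------------------------------------------
# long CSV (Olink-style)
# ---------------------------------------------------------------------------

def read_long_npx(path) -> NPXMatrix:
    """Read a long-format measurement file and pivot it to a wide matrix.

    Raises on missing columns, duplicated (sample, protein) pairs, and
    non-numeric NPX values.
    """
    df = pd.read_csv(path, na_values=["NA"])
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long-format file missing columns: {missing}")
    dup = df.duplicated(subset=["sample_id", "protein_id"], keep=False)
    if dup.any():
        first = df.loc[dup, ["sample_id", "protein_id"]].iloc[0]
        raise ValueError(
            "duplicated (sample, protein) pair: "
            f"({first['sample_id']}, {first['protein_id']})"
        )
    npx = pd.to_numeric(df["npx"], errors="coerce")
    bad = df["npx"].notna() & npx.isna()
    if bad.any():
        raise ValueError(f"non-numeric NPX values: {df.loc[bad, 'npx'].tolist()[:5]}")
    df = df.assign(npx=npx)
    values = df.pivot(index="sample_id", columns="protein_id", values="npx")
    mask = (
        df.pivot(index="sample_id", columns="protein_id", values="below_lod")
        .fillna(False)
        .astype(bool)
    )
    # preserve file order of samples and proteins
    sample_order = df["sample_id"].drop_duplicates().tolist()
    protein_order = df["protein_id"].drop_duplicates().tolist()
    values = values.loc[sample_order, protein_order]
    mask = mask.loc[sample_order, protein_order]
    values.index.name = None
    values.columns.name = None
    mask.index.name = None
    mask.columns.name = None
    return NPXMatrix(values, mask)


def write_long_npx(matrix: NPXMatrix, path) -> None:
    long = matrix.values.stack(future_stack=True).rename("npx").reset_index()
    long.columns = ["sample_id", "protein_id", "npx"]
    long["below_lod"] = matrix.below_lod.stack(future_stack=True).to_numpy().astype(int)
    long.to_csv(path, index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicated sample ids in metadata")
    bad_groups = set(meta["group"].dropna()) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    sub = ["steatosis", "lobular_inflammation", "ballooning"]
    if "nas" in meta.columns and all(c in meta.columns for c in sub):
        complete = meta[sub + ["nas"]].notna().all(axis=1)
        expected = meta.loc[complete, sub].sum(axis=1)
        mismatch = meta.loc[complete, "nas"] != expected
        if mismatch.any():
            rows = meta.loc[complete].loc[mismatch, "sample_id"].tolist()
            raise ValueError(f"NAS != steatosis+inflammation+ballooning for: {rows}")
    if "fibrosis_stage" in meta.columns:
        stages = meta["fibrosis_stage"].dropna()
        if not stages.isin([0, 1, 2, 3, 4]).all():
            raise ValueError("fibrosis stage outside 0..4")
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("t2d", "hypertension"):
        if col in meta.columns:
            meta[col] = meta[col].astype("boolean").astype(bool)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    for col in ("t2d", "hypertension"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# detection-rate QC filter
# ---------------------------------------------------------------------------

def filter_by_detection(
    matrix: NPXMatrix, max_below_lod_fraction: float = 0.10
) -> tuple[NPXMatrix, list[str]]:
    """Drop proteins whose below-LOD fraction strictly exceeds the threshold.

    A protein sitting exactly at the threshold is retained (the criterion is
    "more than", not "at least").  Returns the filtered matrix and the list
    of excluded proteins in input column order.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot filter an empty matrix")
    frac = matrix.below_lod_fraction()
    excluded = [p for p in matrix.proteins if frac[p] > max_below_lod_fraction]
    retained = [p for p in matrix.proteins if p not in excluded]
    return matrix.subset(proteins=retained), excluded
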