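"""End-to-end pipeline: filter -> differential -> stratified -> panel ->
co-expression -> subgroups, with per-stage TSV/JSON outputs and a run
manifest (parameters, derived seeds, output hashes) for auditability.

All randomness flows from one root seed via deterministic per-stage
offsets, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr as cx
from . import diffabund as da
from . import panel as pn
from . import subgroups as sg
from .io import (
    NPXMatrix,
    filter_by_detection,
    read_metadata,
    read_wide_npx,
    write_wide_npx,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

STAGE_SEED_OFFSETS = {"panel": 11, "subgroups": 23}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    npx_path: str | None = None
    lod_path: str | None = None
    metadata_path: str | None = None
    out_dir: str = "seromics_out"
    group_case: str = "NASH"
    group_control: str = "NAFL"
    q: float = 0.05
    fdr_method: str = "bky"
    max_below_lod_fraction: float = 0.10
    specificity_targets: tuple[float, ...] = (0.76, 0.90)
    panel_pool: list[str] | None = None    # default: FDR hits of the main contrast
    panel_max_size: int = 6
    contrasts: tuple[tuple[str, str], ...] = (
        ("NASH", "NAFL"), ("NASH", "HC"), ("NAFL", "HC"),
    )
    coexpr_k: int | None = None
    transcriptome_path: str | None = None
    subgroup_markers: list[str] | None = None
    subgroup_k: int = 8
    null_permutations: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")
        for t in self.specificity_targets:
            if not (0.0 < t < 1.0):
                raise ValueError("specificity targets must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "specificity_targets" in raw:
            raw["specificity_targets"] = tuple(raw["specificity_targets"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    matrix: NPXMatrix | None = None,
    meta: pd.DataFrame | None = None,
    transcriptome: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage and write its outputs under ``config.out_dir``.

    Inputs may be passed in memory or read from the configured paths.
    Returns a report dict with the in-memory stage results plus the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    report: dict = {}

    # ---- load ------------------------------------------------------------
    try:
        if matrix is None:
            matrix = read_wide_npx(config.npx_path, config.lod_path)
        if meta is None:
            meta = read_metadata(config.metadata_path)
        if transcriptome is None and config.transcriptome_path:
            transcriptome = pd.read_csv(
                config.transcriptome_path, sep="\t", index_col=0
            )
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # ---- detection filter ------------------------------------------------
    try:
        filtered, excluded = filter_by_detection(
            matrix, config.max_below_lod_fraction
        )
        p = out / "filtered_npx.tsv"
        write_wide_npx(filtered, p, out / "filtered_below_lod.tsv")
        outputs["filtered_npx"] = p
        outputs["filtered_below_lod"] = out / "filtered_below_lod.tsv"
        (out / "excluded_proteins.json").write_text(json.dumps(excluded, indent=2))
        outputs["excluded_proteins"] = out / "excluded_proteins.json"
        report["excluded_proteins"] = excluded
        report["n_retained"] = filtered.shape[1]
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # ---- differential ----------------------------------------------------
    try:
        tables = {}
        for a, b in config.contrasts:
            t = da.differential(filtered, meta, a, b, config.q, config.fdr_method)
            tables[f"{a}_vs_{b}"] = t
            p = out / f"differential_{a}_vs_{b}.tsv"
            _write_tsv(t, p)
            outputs[f"differential_{a}_vs_{b}"] = p
        report["differential"] = tables
        main = tables[f"{config.group_case}_vs_{config.group_control}"]
    except Exception as exc:
        raise PipelineError("differential", str(exc)) from exc

    # ---- stratified ------------------------------------------------------
    try:
        specs = [da.by_fibrosis(), da.by_boolean("hypertension"), da.by_bmi(),
                 da.by_boolean("t2d"), da.by_sex(), da.by_age_median()]
        strat = {}
        for spec in specs:
            try:
                t = da.stratified_differential(
                    filtered, meta, spec, config.q, config.fdr_method,
                    patients_only=spec.name == "fibrosis",
                )
            except ValueError:
                continue    # covariate missing or one-sided in this cohort
            strat[spec.name] = t
            p = out / f"stratified_{spec.name}.tsv"
            _write_tsv(t, p)
            outputs[f"stratified_{spec.name}"] = p
        report["stratified"] = strat
    except Exception as exc:
        raise PipelineError("stratified", str(exc)) from exc

    # ---- panel -----------------------------------------------------------
    try:
        pool = config.panel_pool
        if pool is None:
            pool = main.loc[main["rejected"], "protein"].tolist()
        report["panel_pool"] = pool
        if len(pool) >= 1:
            case_ids = meta.loc[meta["group"] == config.group_case, "sample_id"]
            ctrl_ids = meta.loc[meta["group"] == config.group_control, "sample_id"]
            ids = [s for s in filtered.samples
                   if s in set(case_ids) | set(ctrl_ids)]
            labels = pd.Series(
                [s in set(case_ids) for s in ids], index=ids, dtype=bool
            )
            directions = {
                row.protein: "greater" if row.effect > 0 else "less"
                for row in main.itertuples()
            }
            panel_report = {}
            for target in config.specificity_targets:
                tests = [
                    pn.derive_test(filtered, labels, prot, directions[prot], target)
                    for prot in pool
                ]
                rule = pn.evaluate_k_of_n(tests, filtered, labels)
                key = f"sp{int(round(target * 100))}"
                panel_report[key] = rule
                _write_tsv(rule.operating_points, out / f"panel_{key}_operating_points.tsv")
                outputs[f"panel_{key}_operating_points"] = (
                    out / f"panel_{key}_operating_points.tsv"
                )
                (out / f"panel_{key}_tests.json").write_text(
                    json.dumps([dataclasses.asdict(t) for t in tests], indent=2)
                )
                outputs[f"panel_{key}_tests"] = out / f"panel_{key}_tests.json"
            selected, probs, info = pn.select_subset_logistic(
                filtered, labels, pool, config.panel_max_size
            )
            info_out = {k: v for k, v in info.items() if k != "evaluated_scores"}
            (out / "panel_selected_subset.json").write_text(
                json.dumps(dict(selected=list(selected), **info_out), indent=2)
            )
            outputs["panel_selected_subset"] = out / "panel_selected_subset.json"
            panel_report["selected_subset"] = selected
            panel_report["selection_info"] = info
            report["panel"] = panel_report
    except Exception as exc:
        raise PipelineError("panel", str(exc)) from exc

    # ---- co-expression ---------------------------------------------------
    try:
        coexpr_report = {}
        for a, b in config.contrasts:
            ca = cx.group_correlation(filtered, meta, a)
            cb = cx.group_correlation(filtered, meta, b)
            res = cx.residual_matrix(ca, cb)
            clustered = cx.cluster_residuals(res, k=config.coexpr_k)
            name = f"{a}_minus_{b}"
            _write_tsv(clustered.values, out / f"residual_{name}.tsv", index=True)
            outputs[f"residual_{name}"] = out / f"residual_{name}.tsv"
            (out / f"residual_{name}_clusters.json").write_text(
                json.dumps(clustered.clusters, indent=2)
            )
            outputs[f"residual_{name}_clusters"] = (
                out / f"residual_{name}_clusters.json"
            )
            coexpr_report[name] = clustered
        report["coexpr"] = coexpr_report
    except Exception as exc:
        raise PipelineError("coexpr", str(exc)) from exc

    # ---- subgroups (optional; needs a transcriptome + markers) -----------
    if transcriptome is not None and config.subgroup_markers:
        try:
            part = sg.cluster_samples_on_markers(
                transcriptome, config.subgroup_markers, config.subgroup_k
            )
            deg = sg.pairwise_deg(transcriptome, part, config.q)
            null = sg.random_cluster_null(
                transcriptome,
                part.sizes().tolist(),
                n_permutations=config.null_permutations,
                q=config.q,
                seed=config.seed + STAGE_SEED_OFFSETS["subgroups"],
            )
            (out / "subgroup_partition.json").write_text(
                json.dumps(
                    {s: int(l) for s, l in part.labels.items()}, indent=2
                )
            )
            outputs["subgroup_partition"] = out / "subgroup_partition.json"
            _write_tsv(deg.as_matrix(), out / "subgroup_deg_counts.tsv", index=True)
            outputs["subgroup_deg_counts"] = out / "subgroup_deg_counts.tsv"
            (out / "subgroup_null.json").write_text(
                json.dumps(
                    dict(
                        percentiles=null["percentiles"],
                        max_counts=null["max_counts"].tolist(),
                        n_permutations=null["n_permutations"],
                    ),
                    indent=2,
                )
            )
            outputs["subgroup_null"] = out / "subgroup_null.json"
            report["subgroups"] = dict(partition=part, deg=deg, null=null)
        except Exception as exc:
            raise PipelineError("subgroups", str(exc)) from exc

    # ---- manifest --------------------------------------------------------
    manifest = dict(
        config={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        seed=config.seed,
        stage_seeds={k: config.seed + v for k, v in STAGE_SEED_OFFSETS.items()},
        outputs={k: dict(path=str(p), sha256=_sha256(p)) for k, p in outputs.items()},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report["manifest"] = manifest
    return report
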