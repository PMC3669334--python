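"""End-to-end orchestration: parse -> subset -> means -> score -> rank ->
intersect -> per-candidate ANOVA -> report.

The run report is a plain JSON-serializable dict; :data:`REPORT_SCHEMA`
declares its structure and :func:`validate_report` checks a report against
it. Given identical inputs the pipeline is deterministic and its TSV
outputs are byte-identical (stable mergesort everywhere, floats written
with 6 significant digits).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .crosspecies import (
    flag_platform_missing,
    intersect_top_ranked,
    read_ortholog_map,
    write_candidate_table,
)
from .datamodel import ExpressionDataset, TissueSampleMap, ValidationError
from .geo_io import parse_gds_soft, read_tissue_map, subset_by_tissue_map
from .specificity import (
    compute_tissue_means,
    rank_by_specificity,
    score_specificity,
    write_ranked_table,
)
from .summary_stats import ALPHA_DEFAULT, confirm_target_specificity, summarize

REPORT_SCHEMA = {
    "type": "object",
    "required": ["tool", "version", "parameters", "tissues"],
    "properties": {
        "tool": {"type": "string"},
        "version": {"type": "string"},
        "parameters": {"type": "object"},
        "tissues": {
            "type": "object",
            "additionalProperties": {
                "type": "object",
                "required": ["candidates", "rank_intersection", "platform_flags", "anova"],
                "properties": {
                    "candidates": {"type": "array"},
                    "rank_intersection": {"type": "array"},
                    "platform_flags": {"type": "array"},
                    "anova": {"type": "array"},
                },
            },
        },
    },
}


def validate_report(report: dict) -> None:
    """Check a run report against :data:`REPORT_SCHEMA` (minimal checker)."""

    def check(obj, schema, where):
        t = schema.get("type")
        if t == "object":
            if not isinstance(obj, dict):
                raise ValidationError(f"{where}: expected object")
            for key in schema.get("required", []):
                if key not in obj:
                    raise ValidationError(f"{where}: missing key {key!r}")
            props = schema.get("properties", {})
            extra = schema.get("additionalProperties")
            for key, val in obj.items():
                if key in props:
                    check(val, props[key], f"{where}.{key}")
                elif isinstance(extra, dict):
                    check(val, extra, f"{where}.{key}")
        elif t == "array":
            if not isinstance(obj, list):
                raise ValidationError(f"{where}: expected array")
        elif t == "string":
            if not isinstance(obj, str):
                raise ValidationError(f"{where}: expected string")

    check(report, REPORT_SCHEMA, "report")


@dataclass
class PipelineResult:
    """Run report plus the per-tissue tables backing it."""

    report: dict
    ranked: dict[tuple[str, str], pd.DataFrame]      # (species_label, tissue) -> table
    candidates: dict[str, pd.DataFrame]              # tissue -> confirmed candidates
    rank_intersection: dict[str, pd.DataFrame]       # tissue -> raw top-K intersection
    platform_flags: dict[str, pd.DataFrame]
    anova: dict[str, pd.DataFrame]


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _candidate_confirmation(dataset: ExpressionDataset, tmap: TissueSampleMap,
                            feature_id: str, target: str, alpha: float) -> dict | None:
    groups, labels = [], []
    for tissue, samples in tmap.assignments.items():
        vals = dataset.values.loc[feature_id, samples].dropna().to_list()
        if len(vals) < 2:
            return None  # single-replicate mode: variance-based tests not estimable
        groups.append(vals)
        labels.append(tissue)
    confirmed, overall, _ = confirm_target_specificity(
        summarize(groups, labels=labels), target, alpha=alpha
    )
    return {
        "F": overall.statistic, "df1": overall.df1, "df2": overall.df2,
        "pvalue": overall.pvalue, "method": overall.method,
        "confirmed": bool(confirmed),
    }


def run_pipeline(
    dataset_a: ExpressionDataset,
    map_a: TissueSampleMap,
    dataset_b: ExpressionDataset,
    map_b: TissueSampleMap,
    targets: list[str] | str = "all",
    top_k: int = 100,
    ortholog_map: dict[str, str] | None = None,
    labels: tuple[str, str] = ("A", "B"),
    out_dir: str | os.PathLike | None = None,
    confirm_alpha: float | None = ALPHA_DEFAULT,
    parameters: dict | None = None,
) -> PipelineResult:
    """Run every stage for the requested target tissues.

    The two tissue maps must cover the same tissue name set (checked before
    any computation). Per target tissue: both species are scored and ranked
    at gene level, the top-K lists intersected, and each intersected gene
    put through the statistical confirmation stage (one-way ANOVA plus
    protected LSD requiring the target tissue to be the significantly
    highest group, at ``confirm_alpha``, in both species). The final
    candidate table keeps confirmed genes; the raw rank intersection is
    retained alongside for audit. Confirmation is skipped — all intersected
    genes kept — when ``confirm_alpha`` is None or when a tissue has fewer
    than two usable replicates (published-means one-replicate inputs).
    """
    if map_a.tissue_names != map_b.tissue_names:
        if set(map_a.tissue_names) != set(map_b.tissue_names):
            raise ValidationError(
                "tissue maps disagree: "
                f"{map_a.tissue_names} vs {map_b.tissue_names}"
            )
        raise ValidationError("tissue maps list the same tissues in different order")
    tissues = map_a.tissue_names
    if targets == "all":
        targets = tissues
    unknown = [t for t in targets if t not in tissues]
    if unknown:
        raise ValidationError(f"unknown target tissue(s): {unknown}")

    sub_a = subset_by_tissue_map(dataset_a, map_a)
    sub_b = subset_by_tissue_map(dataset_b, map_b)
    means_a = compute_tissue_means(sub_a, map_a)
    means_b = compute_tissue_means(sub_b, map_b)

    ranked: dict[tuple[str, str], pd.DataFrame] = {}
    cand: dict[str, pd.DataFrame] = {}
    intersections: dict[str, pd.DataFrame] = {}
    flags: dict[str, pd.DataFrame] = {}
    anova: dict[str, pd.DataFrame] = {}
    report_tissues: dict[str, dict] = {}

    for tissue in targets:
        ra = rank_by_specificity(score_specificity(means_a, tissue), level="gene")
        rb = rank_by_specificity(score_specificity(means_b, tissue), level="gene")
        ranked[(labels[0], tissue)] = ra
        ranked[(labels[1], tissue)] = rb
        ct = intersect_top_ranked(ra, rb, top_k, ortholog_map)
        fl = flag_platform_missing(ra, rb, top_k, ortholog_map, labels)
        intersections[tissue] = ct
        flags[tissue] = fl

        probe_of = {
            lbl: dict(zip(t["gene_symbol"].str.upper(), t["feature_id"]))
            for lbl, t in ((labels[0], ra), (labels[1], rb))
        }
        stat_rows = []
        confirmed_per_gene: dict[str, bool | None] = {}
        for _, row in ct.iterrows():
            verdicts = []
            for lbl, ds, tm in ((labels[0], sub_a, map_a), (labels[1], sub_b, map_b)):
                fid = probe_of[lbl].get(row["gene_symbol"])
                if fid is None:
                    continue
                res = _candidate_confirmation(
                    ds, tm, fid, tissue, confirm_alpha or ALPHA_DEFAULT
                )
                if res is not None:
                    stat_rows.append({"gene_symbol": row["gene_symbol"],
                                      "species": lbl, "feature_id": fid, **res})
                    verdicts.append(res["confirmed"])
            confirmed_per_gene[row["gene_symbol"]] = (
                all(verdicts) if verdicts else None
            )
        anova[tissue] = pd.DataFrame(
            stat_rows,
            columns=["gene_symbol", "species", "feature_id", "F", "df1", "df2",
                     "pvalue", "method", "confirmed"],
        )
        if confirm_alpha is not None:
            keep = ct["gene_symbol"].map(
                lambda g: confirmed_per_gene.get(g) in (True, None)
            ).astype(bool)
            cand[tissue] = ct.loc[keep].reset_index(drop=True)
        else:
            cand[tissue] = ct
        report_tissues[tissue] = {
            "candidates": cand[tissue].to_dict(orient="records"),
            "rank_intersection": ct.to_dict(orient="records"),
            "platform_flags": fl.astype(object).where(fl.notna(), None)
                                .to_dict(orient="records"),
            "anova": anova[tissue].to_dict(orient="records"),
        }

    report = {
        "tool": "tissuespec",
        "version": __version__,
        "parameters": {
            "top_k": top_k,
            "confirm_alpha": confirm_alpha,
            "targets": list(targets),
            "species_labels": list(labels),
            "ortholog_map": ortholog_map is not None,
            **(parameters or {}),
        },
        "tissues": report_tissues,
    }
    validate_report(report)

    result = PipelineResult(report, ranked, cand, intersections, flags, anova)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(result: PipelineResult, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for (label, tissue), table in result.ranked.items():
        write_ranked_table(table, os.path.join(out_dir, f"ranked_{label}_{tissue}.tsv"))
    for tissue, table in result.candidates.items():
        write_candidate_table(table, os.path.join(out_dir, f"candidates_{tissue}.tsv"))
    for tissue, table in result.rank_intersection.items():
        write_candidate_table(table, os.path.join(out_dir, f"intersection_{tissue}.tsv"))
    for tissue, table in result.platform_flags.items():
        write_candidate_table(table, os.path.join(out_dir, f"platform_flags_{tissue}.tsv"))
    for tissue, table in result.anova.items():
        table.to_csv(os.path.join(out_dir, f"anova_{tissue}.tsv"), sep="\t",
                     index=False, float_format="%.6g")
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline_from_paths(
    soft_a, soft_b, tissues_a, tissues_b,
    targets="all", top_k: int = 100, ortholog_map_path=None,
    labels: tuple[str, str] = ("A", "B"), out_dir=None,
) -> PipelineResult:
    """Path-based wrapper around :func:`run_pipeline` recording input digests."""
    omap = read_ortholog_map(ortholog_map_path) if ortholog_map_path else None
    return run_pipeline(
        parse_gds_soft(soft_a, species_label=labels[0]),
        read_tissue_map(tissues_a),
        parse_gds_soft(soft_b, species_label=labels[1]),
        read_tissue_map(tissues_b),
        targets=targets, top_k=top_k, ortholog_map=omap, labels=labels,
        out_dir=out_dir,
        parameters={"input_digests": {
            "soft_a": _file_digest(soft_a), "soft_b": _file_digest(soft_b),
        }},
    )
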