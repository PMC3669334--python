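"""Ratio-based tissue-specificity scoring and ranking.

For a target tissue, each feature's per-tissue replicate means are turned
into ratios against the target mean. Two equivalent scores are kept:

``score_i``
    mean over non-target tissues of (tissue mean / target mean); low
    values indicate target-specific expression. This is the score the
    ranked lists are sorted by, ascending.
``score_v``
    target mean / mean of non-target tissue means; high values indicate
    target-specific expression. Exactly the reciprocal of ``score_i``
    (the mean of ratios against a common denominator equals the ratio of
    means), so the two sort orders coincide.

Both are dimensionless ratios of deposited intensities: no log transform
and no pseudocount is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, TissueSampleMap, ValidationError

#: Column order of ranked/score tables (ratio columns are inserted per tissue).
SCORE_COLUMNS = ["feature_id", "gene_symbol", "target_tissue", "score_i", "score_v"]

EXCLUDED_UNDEFINED_TARGET = "undefined target mean"
EXCLUDED_NONPOSITIVE_TARGET = "nonpositive target mean"
EXCLUDED_UNDEFINED_OTHER = "undefined non-target mean"


@dataclass
class TissueMeanMatrix:
    """Feature x tissue replicate-averaged means with replicate counts.

    ``means`` holds the arithmetic mean of the non-missing replicate values
    per feature per tissue (NaN where every replicate is missing);
    ``n_replicates`` the count actually averaged in each cell.
    """

    means: pd.DataFrame
    n_replicates: pd.DataFrame
    gene_symbols: pd.Series

    @property
    def feature_ids(self) -> list[str]:
        return list(self.means.index)

    @property
    def tissue_names(self) -> list[str]:
        return list(self.means.columns)


def compute_tissue_means(
    dataset: ExpressionDataset, tissue_map: TissueSampleMap
) -> TissueMeanMatrix:
    """Average replicate samples per tissue, skipping missing values."""
    missing = [s for s in tissue_map.sample_ids if s not in set(dataset.sample_ids)]
    if missing:
        raise ValidationError(f"sample ids absent from dataset: {missing}")
    means = {}
    counts = {}
    for tissue, samples in tissue_map.assignments.items():
        block = dataset.values[samples]
        means[tissue] = block.mean(axis=1, skipna=True)
        counts[tissue] = block.notna().sum(axis=1)
    return TissueMeanMatrix(
        means=pd.DataFrame(means),
        n_replicates=pd.DataFrame(counts),
        gene_symbols=dataset.gene_symbols,
    )


def score_specificity(means: TissueMeanMatrix, target: str) -> pd.DataFrame:
    """Score every feature for specificity to ``target``.

    Returns one row per feature with columns ``feature_id``,
    ``gene_symbol``, ``target_tissue``, ``score_i``, ``score_v``, one
    ``ratio_<tissue>`` column per tissue (tissue mean / target mean; 1 for
    the target itself), and ``excluded_reason`` (empty for scored rows).

    A feature is scored only if its target mean is defined and strictly
    positive and every non-target mean is defined; otherwise the scores
    are NaN and ``excluded_reason`` says why.
    """
    tissues = means.tissue_names
    if target not in tissues:
        raise ValidationError(f"unknown target tissue {target!r}; have {tissues}")
    if len(tissues) < 2:
        raise ValidationError("need at least 2 tissues to score specificity")
    others = [t for t in tissues if t != target]

    m = means.means
    target_mean = m[target]
    other = m[others]

    reason = pd.Series("", index=m.index, dtype=str)
    reason[other.isna().any(axis=1)] = EXCLUDED_UNDEFINED_OTHER
    reason[target_mean <= 0] = EXCLUDED_NONPOSITIVE_TARGET
    reason[target_mean.isna()] = EXCLUDED_UNDEFINED_TARGET
    ok = reason == ""

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = m.div(target_mean, axis=0)
    ratios = ratios.where(ok, np.nan)
    score_i = ratios[others].mean(axis=1)
    with np.errstate(divide="ignore"):
        score_v = target_mean / other.mean(axis=1)
    score_v = score_v.where(ok, np.nan)

    out = pd.DataFrame(
        {
            "feature_id": m.index.astype(str),
            "gene_symbol": means.gene_symbols.reindex(m.index).fillna("").astype(str).values,
            "target_tissue": target,
            "score_i": score_i.values,
            "score_v": score_v.values,
        },
        index=m.index,
    )
    for t in tissues:
        out[f"ratio_{t}"] = ratios[t].values
    out["excluded_reason"] = reason.values
    return out.reset_index(drop=True)


def rank_by_specificity(results: pd.DataFrame, level: str = "probe") -> pd.DataFrame:
    """Sort scored features ascending by ``score_i`` and assign 1-based ranks.

    Ties break by ascending gene symbol, then feature id. At
    ``level="gene"`` each symbol keeps only its best-ranked feature
    (unannotated features, empty symbol, are dropped at gene level).
    Excluded features are placed after all scored features and keep their
    positional ranks so the table remains a complete audit trail.
    """
    if level not in ("probe", "gene"):
        raise ValidationError(f"level must be 'probe' or 'gene', got {level!r}")
    targets = results["target_tissue"].unique()
    if len(targets) != 1:
        raise ValidationError(f"mixed target tissues in one ranking: {list(targets)}")

    df = results.copy()
    df["_excluded"] = df["excluded_reason"] != ""
    df = df.sort_values(
        ["_excluded", "score_i", "gene_symbol", "feature_id"],
        ascending=True,
        kind="mergesort",
    ).drop(columns="_excluded")

    if level == "gene":
        df = df[df["gene_symbol"] != ""]
        df = df.loc[~df["gene_symbol"].str.upper().duplicated(keep="first")]

    df = df.reset_index(drop=True)
    df.insert(len(SCORE_COLUMNS), "rank", np.arange(1, len(df) + 1))
    return df


def write_ranked_table(ranked: pd.DataFrame, path) -> None:
    """Write a ranked table as TSV with 6-significant-digit floats."""
    ranked.to_csv(path, sep="\t", index=False, float_format="%.6g")
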