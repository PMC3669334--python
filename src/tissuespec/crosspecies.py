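"""Cross-species intersection of top-ranked gene lists.

Genes are matched between species by case-normalized symbol (human
SLC34A1 vs mouse Slc34a1); an explicit two-column ortholog map can
override name-based matching. Candidates are genes inside the top-K of
both species' gene-level rankings; genes top-ranked in one species whose
symbol is entirely absent from the other platform's annotation are
reported separately with an ``only_in_*_platform`` flag (present-but-
lowly-ranked genes are not flagged).
"""

from __future__ import annotations

import os

import pandas as pd

from .datamodel import ValidationError

CANDIDATE_COLUMNS = [
    "gene_symbol", "rank_a", "score_v_a", "rank_b", "score_v_b", "flag",
]


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def read_ortholog_map(path: str | os.PathLike) -> dict[str, str]:
    """Load a two-column TSV (symbol_A, symbol_B) into a B->A translation."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{os.fspath(path)}: ortholog map needs two columns")
    return {
        normalize_symbol(b): normalize_symbol(a)
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def _scored(ranked: pd.DataFrame) -> pd.DataFrame:
    return ranked[ranked["excluded_reason"] == ""]


def _symbol_index(ranked: pd.DataFrame, translate: dict[str, str] | None) -> pd.DataFrame:
    df = _scored(ranked)[["gene_symbol", "rank", "score_v"]].copy()
    sym = df["gene_symbol"].map(normalize_symbol)
    if translate is not None:
        sym = sym.map(lambda s: translate.get(s, s))
    df["symbol"] = sym
    return df.drop_duplicates("symbol", keep="first").set_index("symbol")


def _check(ranked_a: pd.DataFrame, ranked_b: pd.DataFrame, k: int) -> None:
    if k < 1:
        raise ValidationError(f"top-K cutoff must be >= 1, got {k}")
    ta = ranked_a["target_tissue"].unique()
    tb = ranked_b["target_tissue"].unique()
    if len(ta) != 1 or len(tb) != 1 or ta[0] != tb[0]:
        raise ValidationError(
            f"ranked tables target different tissues: {list(ta)} vs {list(tb)}"
        )


def intersect_top_ranked(
    ranked_a: pd.DataFrame,
    ranked_b: pd.DataFrame,
    k: int = 100,
    ortholog_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Genes within the top ``k`` of both species' gene-level rankings.

    Returns a candidate table sorted by the sum of the two ranks (ties by
    symbol) with flag ``"both"``. ``ortholog_map`` translates species-B
    symbols into species-A symbol space before matching.
    """
    _check(ranked_a, ranked_b, k)
    a = _symbol_index(ranked_a, None)
    b = _symbol_index(ranked_b, ortholog_map)
    top_a = a[a["rank"] <= k]
    top_b = b[b["rank"] <= k]
    common = top_a.index.intersection(top_b.index)
    out = pd.DataFrame(
        {
            "gene_symbol": common,
            "rank_a": top_a.loc[common, "rank"].values,
            "score_v_a": top_a.loc[common, "score_v"].values,
            "rank_b": top_b.loc[common, "rank"].values,
            "score_v_b": top_b.loc[common, "score_v"].values,
            "flag": "both",
        }
    )
    out["_ranksum"] = out["rank_a"] + out["rank_b"]
    out = (
        out.sort_values(["_ranksum", "gene_symbol"], kind="mergesort")
        .drop(columns="_ranksum")
        .reset_index(drop=True)
    )
    return out


def flag_platform_missing(
    ranked_a: pd.DataFrame,
    ranked_b: pd.DataFrame,
    k: int = 100,
    ortholog_map: dict[str, str] | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Top-K genes of one species absent from the other platform entirely.

    A symbol counts as "on the platform" if it appears anywhere in the
    other species' full ranked table (scored or excluded), so genes that
    are merely lowly ranked are never flagged.
    """
    _check(ranked_a, ranked_b, k)

    def all_symbols(ranked: pd.DataFrame, translate) -> set[str]:
        syms = ranked["gene_symbol"].map(normalize_symbol)
        if translate is not None:
            syms = syms.map(lambda s: translate.get(s, s))
        return set(syms) - {""}

    a = _symbol_index(ranked_a, None)
    b = _symbol_index(ranked_b, ortholog_map)
    platform_a = all_symbols(ranked_a, None)
    platform_b = all_symbols(ranked_b, ortholog_map)

    rows = []
    for sym, row in a[a["rank"] <= k].iterrows():
        if sym not in platform_b:
            rows.append((sym, row["rank"], row["score_v"], pd.NA, pd.NA,
                         f"only_in_{labels[0]}_platform"))
    for sym, row in b[b["rank"] <= k].iterrows():
        if sym not in platform_a:
            rows.append((sym, pd.NA, pd.NA, row["rank"], row["score_v"],
                         f"only_in_{labels[1]}_platform"))
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return out.sort_values("gene_symbol", kind="mergesort").reset_index(drop=True)


def write_candidate_table(candidates: pd.DataFrame, path) -> None:
    candidates.to_csv(path, sep="\t", index=False, float_format="%.6g")
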