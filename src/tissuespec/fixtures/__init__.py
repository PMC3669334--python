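"""Packaged reference configurations and published expression summaries.

Ships the GSM-to-tissue rosters for the two GEO DataSets the pipeline was
built around (human GDS596, mouse GDS3142) and the published per-gene
mean +/- SEM expression values by tissue for the curated tissue-specific
gene panels, usable as worked-example inputs: as group summaries for the
summary-statistics layer, or as degenerate one-replicate-per-tissue
datasets for the specificity scorer.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..datamodel import DEFAULT_TISSUES, ExpressionDataset, TissueSampleMap, ValidationError
from ..geo_io import read_tissue_map
from ..specificity import TissueMeanMatrix
from ..summary_stats import GroupSummary

_SPECIES = ("human", "mouse")


def _path(name: str):
    return resources.files(__package__) / name


def tissue_roster(species: str) -> TissueSampleMap:
    """The published GSM roster for ``"human"`` (GDS596) or ``"mouse"`` (GDS3142)."""
    if species not in _SPECIES:
        raise ValidationError(f"species must be one of {_SPECIES}, got {species!r}")
    with resources.as_file(_path(f"{species}_tissues.yaml")) as p:
        return read_tissue_map(p)


def reference_means(species: str | None = None, target_tissue: str | None = None) -> pd.DataFrame:
    """Published per-gene mean/SEM by tissue, optionally filtered.

    Tidy columns: species, target_tissue (the tissue whose panel the gene
    belongs to), gene, tissue, mean, sem, p_printed.
    """
    with resources.as_file(_path("gds_reference_means.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"mean": float, "sem": float})
    if species is not None:
        df = df[df["species"] == species]
    if target_tissue is not None:
        df = df[df["target_tissue"] == target_tissue]
    return df.reset_index(drop=True)


def reference_summary(species: str, target_tissue: str, gene: str) -> GroupSummary:
    """One gene's published per-tissue mean/SEM/n as a :class:`GroupSummary`."""
    df = reference_means(species, target_tissue)
    df = df[df["gene"] == gene]
    if df.empty:
        raise ValidationError(f"no published row for {gene!r} ({species} {target_tissue})")
    roster = tissue_roster(species)
    df = df.set_index("tissue").loc[list(DEFAULT_TISSUES)]
    return GroupSummary(
        labels=list(DEFAULT_TISSUES),
        means=df["mean"].to_numpy(),
        sems=df["sem"].to_numpy(),
        ns=[roster.n_replicates(t) for t in DEFAULT_TISSUES],
    )


def reference_mean_matrix(species: str, target_tissue: str) -> TissueMeanMatrix:
    """The published panel for one species/tissue as a mean matrix."""
    df = reference_means(species, target_tissue)
    means = df.pivot(index="gene", columns="tissue", values="mean")[list(DEFAULT_TISSUES)]
    roster = tissue_roster(species)
    n = pd.DataFrame(
        {t: roster.n_replicates(t) for t in DEFAULT_TISSUES}, index=means.index
    )
    return TissueMeanMatrix(
        means=means,
        n_replicates=n,
        gene_symbols=pd.Series(means.index, index=means.index, name="IDENTIFIER"),
    )


def reference_dataset(species: str, target_tissue: str | None = None) -> tuple[ExpressionDataset, TissueSampleMap]:
    """Published means as a one-replicate-per-tissue dataset plus its map.

    Each tissue becomes a single pseudo-sample named ``MEAN_<tissue>``.
    Variance-based statistics are not meaningful on this dataset; it exists
    so the published values can flow through the full scoring pipeline.
    """
    df = reference_means(species, target_tissue)
    means = (
        df.groupby(["gene", "tissue"], sort=False)["mean"].first().unstack()
    )[list(DEFAULT_TISSUES)]
    means.columns = [f"MEAN_{t}" for t in means.columns]
    means.index.name = "ID_REF"
    tmap = TissueSampleMap({t: [f"MEAN_{t}"] for t in DEFAULT_TISSUES})
    ds = ExpressionDataset(
        species_label=f"{species}_published_means",
        values=means,
        gene_symbols=pd.Series(means.index, index=means.index, name="IDENTIFIER"),
        metadata=[f"^DATASET = {species}_published_means"],
    )
    return ds, tmap
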