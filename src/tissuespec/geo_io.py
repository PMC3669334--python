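"""Reading GDS-style SOFT files and tissue-sample configurations.

Only the ``!dataset_table_begin`` ... ``!dataset_table_end`` block of a GDS
full-SOFT file is interpreted: a tab-separated table whose header starts
with ``ID_REF`` and ``IDENTIFIER`` followed by one column per GSM. All
other header lines are kept verbatim as opaque metadata. Plain and
gzip-compressed files are supported.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
from typing import TextIO

import numpy as np
import pandas as pd
import yaml

from .datamodel import ExpressionDataset, SoftFormatError, TissueSampleMap, ValidationError

logger = logging.getLogger(__name__)

#: Cell tokens treated as missing values (compared case-insensitively).
MISSING_TOKENS = frozenset({"null", "--", "", "na"})

TABLE_BEGIN = "!dataset_table_begin"
TABLE_END = "!dataset_table_end"


def _open_text(path: str | os.PathLike) -> TextIO:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_gds_soft(path: str | os.PathLike, species_label: str | None = None) -> ExpressionDataset:
    """Parse a GDS full-SOFT file into an :class:`ExpressionDataset`.

    Feature ids come from the ``ID_REF`` column, gene symbols from
    ``IDENTIFIER``, samples from the remaining (GSM) columns. Non-numeric
    cells (``null``, ``--``, ``NA``, empty) become missing values; negative
    values are clamped to missing with a logged warning count.

    Raises
    ------
    SoftFormatError
        If the table delimiters or the header line are missing/malformed
        (the message names the offending line).
    ValidationError
        If ID_REF values are duplicated.
    """
    metadata: list[str] = []
    header: list[str] | None = None
    id_refs: list[str] = []
    symbols: list[str] = []
    rows: list[list[str]] = []
    in_table = False
    table_closed = False

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            low = line.strip().lower()
            if not in_table:
                if low == TABLE_BEGIN:
                    in_table = True
                else:
                    metadata.append(line)
                continue
            if low == TABLE_END:
                table_closed = True
                break
            if header is None:
                header = line.split("\t")
                if len(header) < 3 or header[0] != "ID_REF" or header[1] != "IDENTIFIER":
                    raise SoftFormatError(
                        f"line {lineno}: expected header starting with "
                        f"'ID_REF\\tIDENTIFIER', got: {line[:80]!r}"
                    )
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise SoftFormatError(
                    f"line {lineno}: expected {len(header)} columns, "
                    f"got {len(cells)}: {line[:80]!r}"
                )
            id_refs.append(cells[0])
            symbols.append(cells[1])
            rows.append(cells[2:])

    if not in_table:
        raise SoftFormatError(f"{os.fspath(path)}: no '{TABLE_BEGIN}' line found")
    if not table_closed:
        raise SoftFormatError(f"{os.fspath(path)}: missing '{TABLE_END}' line")
    if header is None:
        raise SoftFormatError(f"{os.fspath(path)}: dataset table has no header line")

    sample_ids = header[2:]
    index = pd.Index(id_refs, name="ID_REF")
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate ID_REF values: {dups[:5]}")

    def to_float(cell: str) -> float:
        # float() is correctly rounded, so emitted values re-parse exactly
        if cell.strip().lower() in MISSING_TOKENS:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            return np.nan

    values = pd.DataFrame(
        [[to_float(c) for c in row] for row in rows],
        index=index, columns=sample_ids, dtype=float,
    )

    negative = values.lt(0)
    n_neg = int(negative.to_numpy().sum())
    if n_neg:
        logger.warning(
            "%s: clamped %d negative intensity value(s) to missing", path, n_neg
        )
        values = values.mask(negative)

    if species_label is None:
        species_label = _infer_label(metadata) or os.path.basename(os.fspath(path))
    return ExpressionDataset(
        species_label=species_label,
        values=values,
        gene_symbols=pd.Series(symbols, index=index, name="IDENTIFIER"),
        metadata=metadata,
    )


def _infer_label(metadata: list[str]) -> str | None:
    for line in metadata:
        if line.lower().startswith("!dataset_organism"):
            _, _, val = line.partition("=")
            return val.strip() or None
    return None


def read_tissue_map(path: str | os.PathLike) -> TissueSampleMap:
    """Load a tissue->samples configuration from YAML or two-column TSV.

    YAML form: a mapping ``tissue: [GSM..., ...]``. TSV form: columns
    ``tissue`` and ``sample_id``, one row per sample, tissue order given by
    first appearance.
    """
    path = os.fspath(path)
    if path.endswith((".yaml", ".yml")):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a tissue->samples mapping")
        return TissueSampleMap({str(t): [str(s) for s in ss] for t, ss in data.items()})
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tissue", "sample_id"}.issubset(df.columns):
        raise ValidationError(f"{path}: TSV needs columns 'tissue' and 'sample_id'")
    assignments: dict[str, list[str]] = {}
    for tissue, sample in zip(df["tissue"], df["sample_id"]):
        assignments.setdefault(tissue, []).append(sample)
    return TissueSampleMap(assignments)


def subset_by_tissue_map(
    dataset: ExpressionDataset, tissue_map: TissueSampleMap
) -> ExpressionDataset:
    """Restrict a dataset to the mapped samples, grouped in tissue order.

    Column order of the result is tissue-major: all samples of the first
    tissue in map order, then the second, etc. Unknown sample ids raise a
    :class:`ValidationError` listing every missing id.
    """
    available = set(dataset.sample_ids)
    missing = [s for s in tissue_map.sample_ids if s not in available]
    if missing:
        raise ValidationError(
            f"sample ids absent from dataset {dataset.species_label!r}: {missing}"
        )
    ordered = tissue_map.sample_ids
    return ExpressionDataset(
        species_label=dataset.species_label,
        values=dataset.values.loc[:, ordered],
        gene_symbols=dataset.gene_symbols,
        metadata=list(dataset.metadata),
    )
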