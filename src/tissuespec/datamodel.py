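"""Core data containers for the cross-species tissue-specificity pipeline.

The pipeline operates on GEO DataSet (GDS) style expression matrices: one
row per platform feature (probe/spot), one column per GEO sample (GSM),
values are the deposited non-negative hybridization intensities. A
:class:`TissueSampleMap` assigns GSM columns to named tissues (by default
the six tissues kidney, liver, lung, heart, muscle, adipose).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical tissue panel, in reporting order.
DEFAULT_TISSUES: tuple[str, ...] = (
    "kidney", "liver", "lung", "heart", "muscle", "adipose",
)


class ValidationError(ValueError):
    """A dataset, map, or configuration violates a structural invariant."""


class SoftFormatError(ValueError):
    """A SOFT file does not contain a well-formed GDS dataset table."""


@dataclass
class ExpressionDataset:
    """A probe x sample expression matrix for one species.

    Parameters
    ----------
    species_label
        Free-text species/platform label (e.g. ``"human"``).
    values
        Float DataFrame indexed by unique feature ids (ID_REF) with unique
        sample-id columns (GSM names). Missing measurements are NaN; all
        stored numbers are finite and non-negative.
    gene_symbols
        Per-feature gene symbol (IDENTIFIER column), aligned to
        ``values.index``. May contain empty strings for unannotated spots.
    metadata
        Opaque SOFT header lines retained for provenance.
    """

    species_label: str
    values: pd.DataFrame
    gene_symbols: pd.Series
    metadata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.gene_symbols = self.gene_symbols.fillna("").astype(str)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        if not self.gene_symbols.index.equals(idx):
            raise ValidationError("gene_symbols index does not match values index")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("expression values must be finite")
        with np.errstate(invalid="ignore"):
            if (arr < 0).any():
                raise ValidationError("expression values must be non-negative")

    # -- accessors ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def equals(self, other: "ExpressionDataset") -> bool:
        """Numeric + annotation equality (NaNs compare equal)."""
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and bool(self.gene_symbols.eq(other.gene_symbols).all())
            and np.array_equal(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
        )


@dataclass
class TissueSampleMap:
    """Ordered assignment of sample ids (GSMs) to named tissues."""

    assignments: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.assignments = {t: list(s) for t, s in self.assignments.items()}
        self.validate()

    def validate(self) -> None:
        if not self.assignments:
            raise ValidationError("tissue map is empty")
        seen: dict[str, str] = {}
        for tissue, samples in self.assignments.items():
            if not samples:
                raise ValidationError(f"tissue {tissue!r} has no samples")
            for s in samples:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {tissue!r}"
                    )
                seen[s] = tissue

    @property
    def tissue_names(self) -> list[str]:
        return list(self.assignments)

    @property
    def sample_ids(self) -> list[str]:
        return [s for samples in self.assignments.values() for s in samples]

    def n_replicates(self, tissue: str) -> int:
        return len(self.assignments[tissue])
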