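"""Paired spike-in expression simulator with SOFT emission.

Generates two species-like GDS-style datasets over the same gene panel:
per-gene log-normal baselines shared between species (up to an independent
per-species scale factor), multiplicative log-normal replicate noise at a
configured coefficient of variation, and a chosen number of spiked genes
per tissue whose expected expression in exactly one target tissue is
elevated by a fold-change. Spikes are conserved across species with a
configurable probability, and genes can drop out of one species' platform
annotation entirely, mimicking probes present on only one array design.

Replicate structure mirrors a two-subject-per-tissue species A (human-like)
and a three-subject-per-tissue species B with four muscle subjects
(mouse-like). Species A symbols are uppercase, species B title-case, to
exercise cross-species symbol normalization.

Everything is reproducible from the configured seed; the module draws no
global randomness.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_TISSUES, ExpressionDataset, TissueSampleMap, ValidationError


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the real study design: 6 tissues, 2 replicates per
    tissue in species A, 3 per tissue in species B with 4 for muscle;
    baselines log-normal around ~100 intensity units; 10% multiplicative
    noise; 5 spiked genes per tissue at 100-fold.
    """

    n_genes: int = 5000
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    replicates_a: int | dict[str, int] = 2
    replicates_b: int | dict[str, int] | None = None  # default: 3, muscle 4
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    species_scale_log_sd: float = 0.3
    noise_cv: float = 0.1
    spikes_per_tissue: int = 5
    spike_fold: float | tuple[float, float] = 100.0
    conservation_prob: float = 1.0
    platform_dropout_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates_b is None:
            self.replicates_b = {t: (4 if t == "muscle" else 3) for t in self.tissue_names}
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if len(self.tissue_names) < 2:
            raise ValidationError("need at least 2 tissues")
        if self.spikes_per_tissue < 0:
            raise ValidationError("spikes_per_tissue must be >= 0")
        if self.spikes_per_tissue * len(self.tissue_names) > self.n_genes:
            raise ValidationError("more spiked genes requested than genes")
        lo, hi = self._fold_range()
        if lo <= 0 or hi <= 0:
            raise ValidationError("spike fold-change must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for p, name in ((self.conservation_prob, "conservation_prob"),
                        (self.platform_dropout_prob, "platform_dropout_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for reps in (self._reps("a"), self._reps("b")):
            if any(r < 1 for r in reps.values()):
                raise ValidationError("replicate counts must be >= 1")

    def _fold_range(self) -> tuple[float, float]:
        if isinstance(self.spike_fold, (tuple, list)):
            return float(self.spike_fold[0]), float(self.spike_fold[1])
        return float(self.spike_fold), float(self.spike_fold)

    def _reps(self, species: str) -> dict[str, int]:
        spec = self.replicates_a if species == "a" else self.replicates_b
        if isinstance(spec, dict):
            missing = [t for t in self.tissue_names if t not in spec]
            if missing:
                raise ValidationError(f"replicate counts missing tissues: {missing}")
            return {t: int(spec[t]) for t in self.tissue_names}
        return {t: int(spec) for t in self.tissue_names}


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: one row per generated gene.

    Columns: ``gene`` (canonical uppercase symbol), ``target_tissue``
    (empty for unspiked genes), ``spiked_a`` / ``spiked_b`` (is the spike
    realized in each species), ``fold`` (realized fold-change), ``in_a_platform``
    / ``in_b_platform`` (annotation presence flags).
    """

    table: pd.DataFrame

    def conserved_spiked(self, tissue: str) -> set[str]:
        """Symbols spiked in ``tissue`` in both species and on both platforms."""
        t = self.table
        sel = (
            (t["target_tissue"] == tissue)
            & t["spiked_a"] & t["spiked_b"]
            & t["in_a_platform"] & t["in_b_platform"]
        )
        return set(t.loc[sel, "gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def tissue_sample_maps(config: SimulationConfig) -> tuple[TissueSampleMap, TissueSampleMap]:
    """The deterministic GSM layout that :func:`generate_pair` emits."""
    maps = []
    for species, offset in (("a", 100000), ("b", 200000)):
        reps = config._reps(species)
        counter = offset
        assignments: dict[str, list[str]] = {}
        for tissue in config.tissue_names:
            ids = [f"GSM{counter + i}" for i in range(reps[tissue])]
            counter += reps[tissue]
            assignments[tissue] = ids
        maps.append(TissueSampleMap(assignments))
    return maps[0], maps[1]


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise at coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sdlog = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sdlog * sdlog / 2.0, sigma=sdlog, size=shape)


def generate_pair(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionDataset, ExpressionDataset, SyntheticTruth]:
    """Generate the two species datasets and their ground-truth manifest.

    ``seed`` overrides ``config.seed``; one of the two must be set.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValidationError("a seed is required (config.seed or the seed argument)")
    rng = np.random.default_rng(int(seed))

    n = config.n_genes
    tissues = list(config.tissue_names)
    symbols_upper = np.array([f"GENE{i:05d}" for i in range(1, n + 1)])
    symbols_title = np.array([s.title() for s in symbols_upper])

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    # spike assignment: disjoint gene sets per tissue
    target = np.array([""] * n, dtype=object)
    spike_idx = rng.choice(n, size=config.spikes_per_tissue * len(tissues), replace=False)
    for ti, tissue in enumerate(tissues):
        block = spike_idx[ti * config.spikes_per_tissue:(ti + 1) * config.spikes_per_tissue]
        target[block] = tissue
    lo, hi = config._fold_range()
    fold = np.ones(n)
    spiked = target != ""
    fold[spiked] = lo if lo == hi else rng.uniform(lo, hi, size=int(spiked.sum()))

    conserved = rng.random(n) < config.conservation_prob
    spiked_a = spiked.copy()
    spiked_b = spiked & conserved

    drop = rng.random(n) < config.platform_dropout_prob
    drop_species = rng.integers(0, 2, size=n)  # 0 -> drop from A, 1 -> drop from B
    in_a = ~(drop & (drop_species == 0))
    in_b = ~(drop & (drop_species == 1))

    map_a, map_b = tissue_sample_maps(config)
    datasets = []
    for species, tmap, syms, spiked_here, present in (
        ("a", map_a, symbols_upper, spiked_a, in_a),
        ("b", map_b, symbols_title, spiked_b, in_b),
    ):
        scale = rng.lognormal(0.0, config.species_scale_log_sd, size=n)
        expected = np.tile((baseline * scale)[:, None], (1, len(tissues)))
        for ti, tissue in enumerate(tissues):
            boost = spiked_here & (target == tissue)
            expected[boost, ti] *= fold[boost]
        cols = {}
        for ti, tissue in enumerate(tissues):
            for gsm in tmap.assignments[tissue]:
                cols[gsm] = expected[:, ti] * _lognormal_noise(rng, config.noise_cv, n)
        values = pd.DataFrame(cols, index=pd.Index(
            [f"PR{species.upper()}{i:05d}" for i in range(1, n + 1)], name="ID_REF"))
        ds = ExpressionDataset(
            species_label=f"synthetic_species_{species}",
            values=values.loc[present],
            gene_symbols=pd.Series(syms, index=values.index, name="IDENTIFIER").loc[present],
            metadata=[
                f"^DATASET = synthetic_species_{species}",
                f"!dataset_title = synthetic spike-in dataset (seed={seed})",
            ],
        )
        datasets.append(ds)

    truth = SyntheticTruth(pd.DataFrame({
        "gene": symbols_upper,
        "target_tissue": target.astype(str),
        "spiked_a": spiked_a,
        "spiked_b": spiked_b,
        "fold": np.where(spiked, fold, 1.0),
        "in_a_platform": in_a,
        "in_b_platform": in_b,
    }))
    return datasets[0], datasets[1], truth


def emit_soft_files(dataset: ExpressionDataset, path: str | os.PathLike) -> str:
    """Write a dataset as a GDS-dialect SOFT file that the parser inverts.

    Values are written with 17 significant digits so the emit -> parse
    round trip is numerically exact; missing values become ``null``.
    """
    path = os.fspath(path)
    values = dataset.values
    with open(path, "w", encoding="utf-8") as fh:
        for line in dataset.metadata:
            fh.write(line + "\n")
        if not dataset.metadata:
            fh.write(f"^DATASET = {dataset.species_label}\n")
        fh.write("!dataset_table_begin\n")
        fh.write("ID_REF\tIDENTIFIER\t" + "\t".join(values.columns) + "\n")
        arr = values.to_numpy()
        symbols = dataset.gene_symbols.to_numpy()
        for i, fid in enumerate(values.index):
            cells = [
                "null" if np.isnan(v) else format(v, ".17g") for v in arr[i]
            ]
            fh.write(f"{fid}\t{symbols[i]}\t" + "\t".join(cells) + "\n")
        fh.write("!dataset_table_end\n")
    return path
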