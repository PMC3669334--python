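# Methods

## Data model and input handling

The pipeline consumes GEO DataSet (GDS) full-SOFT files. Only the
`!dataset_table_begin` … `!dataset_table_end` block is interpreted — a
tab-separated table with `ID_REF` (platform feature), `IDENTIFIER` (gene
symbol) and one column per GSM sample; every other header line is carried
along as opaque metadata. This is sufficient for curated GDS records and
keeps the parser small and auditable. The cell tokens `null`, `--`, `NA`
and the empty string (case-insensitive) are treated as missing. Deposited
values are consumed as-is (no renormalization, no background correction):
whatever value type the DataSet stores is what the ratios are computed on.
Negative parsed values are clamped to missing with a logged warning count,
because the ratio statistic below assumes positive intensities and a
negative intensity has no physical meaning on this scale. Cell values are
parsed with correctly-rounded float conversion so that files written by
the package's own emitter re-parse to bit-identical matrices.

A tissue–sample map (YAML mapping or two-column TSV) assigns GSM columns
to named tissues; the package ships the rosters used with GDS596 (human,
2 subjects per tissue) and GDS3142 (mouse, 3 per tissue, 4 for muscle —
19 samples). Subsetting reorders columns tissue-major and rejects unknown
sample ids before any computation.

## Specificity scoring

Per feature and tissue, replicate samples are averaged arithmetically over
the non-missing values (a cell with no usable replicate has an undefined
mean). For a target tissue, each feature receives

- `score_i` — the mean over non-target tissues of (tissue mean / target
  mean); lower ⇒ more target-specific; rankings sort by it ascending;
- `score_v` — target mean / mean of non-target tissue means; higher ⇒
  more target-specific;
- a per-tissue ratio profile (tissue mean / target mean, 1 at the target).

Since the mean of ratios against a common denominator equals the ratio of
the means, `score_v = 1/score_i` exactly wherever both are defined; the
test suite asserts this to 1e-9 and asserts the identity of the two sort
orders on random matrices. Both scores are dimensionless ratios of raw
deposited values — deliberately no log transform and no pseudocount.

A feature is scored only if its target mean is defined and strictly
positive and *all* non-target means are defined. Scoring on fewer tissues
would silently change the statistic's meaning and break reciprocity, so
incomplete features are excluded with an explicit reason instead. Ties in
the ranking break by ascending gene symbol, then feature id, making ranks
deterministic. At gene level each symbol keeps its best-ranked probe
(best-rank collapsing preserves the winning probe's identity; averaging
probes would mix measurements of different transcript regions);
unannotated probes (empty symbol) cannot participate in cross-species
matching and are dropped from gene-level tables.

## Cross-species candidate selection

Gene-level rankings of the two species are intersected at a rank cutoff K
(default 100 — the screen targets roughly the one-to-two-hundred
strongest signature genes per tissue; configurable). Symbols are matched
after uppercasing, which handles the human/mouse casing convention; an
explicit two-column ortholog map overrides name matching where symbol
identity is wrong or missing. Candidates are ordered by the sum of their
two ranks. Separately, a top-K gene whose symbol is entirely absent from
the other platform's annotation is reported with an
`only_in_<species>_platform` flag — such a gene cannot appear in the
intersection through no fault of its biology (genes merely ranked below K
in the other species are not flagged).

## Statistical confirmation

Rank intersection alone admits chance overlaps: with G genes and cutoff K
the expected number of coincidental two-species overlaps per tissue is
roughly K²/G (≈ 2 per tissue at G = 5000, K = 100), so a screen of this
shape needs its confirmation stage. Each intersected gene is therefore
tested, in each species, with a per-gene one-way ANOVA across tissues
followed by Fisher's protected LSD: the gene is confirmed when the
overall F is significant (α = 0.05), the target tissue has the strictly
largest mean, and every target-versus-other pairwise comparison on the
pooled ANOVA error is significant. The final candidate table keeps
confirmed genes; the raw intersection is written alongside for audit.
The tissue-distribution design gives each tissue its own subjects, so no
random subject effect is estimable and a fixed-effect one-way ANOVA is
the model the data support; the method label in the output records this.

ANOVA can be computed from raw replicates or reconstructed exactly from
published mean ± SEM ± n summaries (sd = SEM·√n recovers the within-group
sum of squares), which makes printed tables first-class test inputs. With
only group summaries and n = 1 per group (the packaged published-means
datasets), variance-based confirmation is impossible and the pipeline
keeps all intersected genes, noting the mode in the report. Post-hoc
machinery: Fisher's LSD is pairwise t on the pooled MSE with its df;
Tukey's HSD uses the studentized range on the same pooled MSE with the
Tukey–Kramer standard error for unequal n. Two-group comparisons use the
pooled-variance Student t test (Welch optional). p-values are reported
uncorrected, matching the screen's original design; a Benjamini–Hochberg
helper exists but is off by default. Reference-gene normalization
(e.g. to cyclophilin for qPCR-style relative expression) divides each
sample by its reference value, averaging probes if the reference symbol
maps to several, and refuses nonpositive or missing reference values.

Degenerate cases are pinned down explicitly: identical groups give
F = 0, p = 1; zero within-group variance with distinct means gives
F = ∞, p = 0; zero mean differences give post-hoc p = 1.

## Spike-in simulator

The generator emulates the paired two-platform design: a shared gene
panel; per-gene baselines drawn log-normally (median ≈ 100 intensity
units, log-sd 1 — the spread seen in deposited single-channel
intensities), multiplied by an independent per-species, per-gene scale
factor (log-sd 0.3) to mimic platform differences (the ratio statistic is
invariant to it); replicate values are the expected value times mean-one
log-normal noise at a configurable coefficient of variation (default
0.1, a typical between-replicate CV for curated arrays). Replicates
default to the real study's design: 2 per tissue in species A, 3 in
species B with 4 for muscle. Each tissue receives a configurable number
of spiked genes (default 5) whose expectation in exactly one target
tissue is multiplied by a fold-change (default 100, the order of
separation the published tissue panels show); a spike is realized in both
species with probability `conservation_prob` (default 1), and any gene
can be dropped from one species' annotation with probability
`platform_dropout_prob` (default 0) to exercise the single-platform
flags. Species A symbols are uppercase and species B title-case so the
cross-species matching is genuinely tested. All randomness flows from one
required seed; the emitted SOFT files round-trip through the parser
bit-exactly (values written with 17 significant digits, missing cells as
`null`).

What the simulator does not emulate: probe-level cross-hybridization,
spatial array artifacts, correlated noise between tissues, multi-probe
genes, and platform-specific value types. Passing the synthetic
acceptance checks therefore demonstrates the pipeline's correctness and
power under clean multiplicative noise, not performance on real arrays
with those artifacts.

## Problem sizes and determinism

The simulation-based checks run at 5,000 genes (the scale at which
per-tissue chance overlap is still material) with the default design, and
the chance-level control at fold-change 1 repeats the full pipeline over
20 seeds; property tests use smaller matrices (20–1,000 features). Reports
and TSVs are byte-stable across reruns: stable mergesorts everywhere,
explicit tie-breaks, floats formatted at 6 significant digits in TSV
output.

## Known limitations

- Symbol-based orthology is approximate; paralog families with divergent
  naming need an explicit ortholog map.
- The published screen's final gene counts involved manual curation
  against the literature, which is out of scope here; the pipeline
  reproduces the computational selection, not the curation.
- Scores are undefined for genes absent from a tissue (nonpositive or
  missing target mean) — genuinely silent genes in the target tissue are
  excluded rather than given infinite specificity in the other direction.
- One-replicate inputs (published means) support scoring and ranking but
  not variance-based confirmation; summary-ANOVA requires SEMs and n ≥ 2.
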