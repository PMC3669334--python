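# tissuespec

Cross-species discovery of tissue-specific genes from public microarray
expression data.

`tissuespec` reimplements, as a tested pipeline, a comparative strategy for
finding genes expressed specifically in one of six tissues (kidney, liver,
lung, heart, muscle, adipose): take one human and one mouse GEO DataSet
(the approach was developed around GDS596 for human and GDS3142 for mouse),
average the replicate samples per tissue, score every gene by a ratio-based
specificity statistic, rank, intersect the top-ranked genes across the two
species by symbol, and confirm each candidate statistically. A spike-in
simulator generates paired species-like datasets with known tissue-specific
genes in the same SOFT dialect the parser reads, so the whole pipeline is
verifiable without downloading anything.

It is intended for computational biologists who want a reproducible,
scriptable version of this kind of cross-species screen, or a ground-truth
test bed for tissue-specificity scoring.

## The statistic

For a target tissue with per-tissue replicate means m_1, ..., m_T (target
mean m_tgt), each gene gets two equivalent scores:

- **score_i** = mean over non-target tissues t of (m_t / m_tgt) — low values
  mean target-specific; ranked lists are sorted by score_i ascending.
- **score_v** = m_tgt / mean over non-target tissues of m_t — high values
  mean target-specific.

Because both use the same denominator structure, score_v = 1/score_i
exactly, and the two orderings coincide; the package keeps both so either
published presentation can be reproduced. Genes in the top K (default 100)
of both species' rankings, matched by case-normalized symbol (human SLC34A1
vs mouse Slc34a1) or an explicit ortholog map, become candidates; each
candidate is then confirmed by a per-gene one-way ANOVA across tissues
followed by Fisher's protected LSD requiring the target tissue to be the
significantly highest group (α = 0.05) in both species. Genes top-ranked in
one species but entirely absent from the other platform's annotation are
flagged `only_in_<species>_platform` instead of being silently lost.

## Worked example

The package ships the published per-gene mean ± SEM tables for both
species' tissue panels. Scoring the mouse kidney panel:

```python
from tissuespec import score_specificity, rank_by_specificity
from tissuespec.fixtures import reference_mean_matrix

mm = reference_mean_matrix("mouse", "kidney")
ranked = rank_by_specificity(score_specificity(mm, "kidney"), level="gene")
print(ranked[["gene_symbol", "score_v", "rank"]].head(3).to_string(index=False))
```

```
gene_symbol   score_v  rank
      FXYD2 80.344828     1
    SLC34A1 76.035565     2
         KL 23.805970     3
```

FXYD2's score_v = 80.34 means its kidney mean (9786 intensity units) is
80-fold the average of its five non-kidney means (121.8 units) — the
hallmark of a kidney-specific gene. A full synthetic run from the shell:

```
tissuespec simulate --seed 7 --out sim/
tissuespec run --soft-a sim/species_a.soft --soft-b sim/species_b.soft \
    --tissues-a sim/tissues_a.tsv --tissues-b sim/tissues_b.tsv \
    --target all --top-k 100 --out results/
```

which writes per-tissue ranked tables, candidate tables, platform flags,
ANOVA results and a JSON run report; `sim/truth.tsv` holds the spike-in
ground truth to compare against.

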