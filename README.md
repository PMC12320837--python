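# ugityper

Contamination-controlled analysis and community typing of low-biomass
upper-gastrointestinal (uGI) 16S rRNA microbiota profiles.

Saliva, gastric and duodenal samples carry so little microbial biomass
that reagent and laboratory contaminants can dominate their amplicon
profiles, and the taxa that are *present* (16S rRNA gene / DNA) are not
necessarily the taxa that are *transcriptionally active* (16S rRNA
transcript / cDNA). `ugityper` is a pipeline for genus-level (SILVA L6)
count tables from paired DNA/RNA uGI amplicon studies. It is written for
microbiome researchers who already have denoised, genus-collapsed count
tables (e.g. from QIIME 2) and want the downstream statistics:

- **Contamination gate** — compare blank extraction/amplification
  controls to biological samples by library size (pairwise Wilcoxon,
  BH-corrected), clr-PCA with 95% confidence ellipses, and PLS-DA VIP
  ranking of discriminative taxa; exclude biological samples that are
  compositionally indistinguishable from controls.
- **Diversity** — Shannon index, Bray-Curtis dissimilarity on rarefied
  relative abundances, PCoA, and a seed-deterministic ANOSIM permutation
  test; within-subject between-location dissimilarities and shared-taxa
  fractions.
- **Activity profiling** — per-taxon linear mixed models on clr values
  (`clr ~ location * amplicon + (1 | subject)`), estimated marginal mean
  contrasts, and volcano classification by
  `log2(mean RNA / mean DNA)` with cutoffs ±0.6 at BH q < 0.1, after
  phantom-taxon and prevalence filtering.
- **Community typing** — Spearman co-occurrence clustering
  (distance `1 − rho`, dendrogram cut at height 1, silhouette-validated)
  and the cluster-dominance rule: a sample is **Prevotella 7 type** when
  the cumulative relative abundance of the Prevotella 7 cluster is at
  least 2.5-fold that of the Neisseria cluster, with a *low-both* flag
  when both fall below 10%. The two reference salivary member lists
  (10 + 13 genera) ship with the package.
- **Associations** — HACEK-group and Fusobacterium burdens by type,
  normality-gated group tests, cytokine (e.g. TNF-α) correlations, and a
  logistic-regression covariate confounding check.
- **Synthetic cohorts** — a logistic-normal generator that plants
  co-occurrence blocks, community types, RNA/DNA activity effects,
  contaminant-dominated controls and cytokine gradients, with full ground
  truth for recovery testing.

## The statistics at the core

For a sample with genus proportions `p`, the centered log-ratio is
`clr(p)_i = ln(p_i / g(p))` with `g` the geometric mean. Per-taxon
activity is tested with the mixed model above; the volcano coordinate is
`log2(Σp̄_RNA / Σp̄_DNA)` per taxon (ratio of arithmetic means). Typing
uses cumulative abundances of the two cluster member lists `C_P7`, `C_N`:

```
type(s) = Prevotella7   iff   Σ_{i∈C_P7} p_i(s) ≥ 2.5 · Σ_{i∈C_N} p_i(s)
low_both(s) = [Σ_{C_P7} p_i < 0.10] ∧ [Σ_{C_N} p_i < 0.10]
```

ANOSIM reports `R = (r̄_between − r̄_within)/(M/2)` over the ranks of the
`M = n(n−1)/2` pairwise dissimilarities, with permutation p-values floored
by the +1 correction. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

Generate a small synthetic cohort and type its salivary DNA profiles with
the packaged reference clusters:

```python
from ugityper.config import AnalysisConfig
from ugityper.core_tables import to_relative
from ugityper.community_typing import reference_clusters, type_cohort
from ugityper.synthetic import SyntheticSpec, generate_cohort

table, meta, truth = generate_cohort(SyntheticSpec(n_subjects=6, seed=42))
rel = to_relative(table, pseudocount=0)
ref = reference_clusters()
records = type_cohort(rel, meta, ref["Prevotella 7"], ref["Neisseria"],
                      AnalysisConfig())
dna = records[(records.amplicon == "DNA") & (records.location == "saliva")]
print(dna[["sample_id", "p7_cum", "neis_cum", "ratio", "type"]].round(3))
```

prints

```
         sample_id  p7_cum  neis_cum  ratio        type
subj000_saliva_DNA   0.125     0.741  0.169       other
subj001_saliva_DNA   0.830     0.045 18.370 Prevotella7
subj002_saliva_DNA   0.877     0.032 27.345 Prevotella7
subj003_saliva_DNA   0.028     0.872  0.033       other
subj004_saliva_DNA   0.023     0.889  0.026       other
subj005_saliva_DNA   0.926     0.013 71.753 Prevotella7
```

`p7_cum`/`neis_cum` are the cumulative relative abundances of the two
cluster member lists; subjects 1, 2 and 5 exceed the 2.5-fold dominance
ratio and are assigned the Prevotella 7 type — exactly the three subjects
the generator planted as that type (`truth.subject_type`). All six
subjects keep a consistent type across saliva, stomach and duodenum
(`cross_site_consistency(records)` reports 0 switches).

The same analysis runs from the shell:

```bash
ugityper synth --seed 42 --out cohort/
ugityper run --table cohort/feature_table.tsv --meta cohort/metadata.tsv --out results/
ugityper run --table t.tsv --meta m.tsv --out out/ \
    --clusters src/ugityper/data/reference_clusters.json   # fixed reference lists
```

`run` writes per-stage TSV/JSON reports (exclusion list with reason
codes, alpha/beta diversity, per-location volcano tables, typing records,
association tests) plus a `run_manifest.json` with the config snapshot,
input digests and per-stage counts; reruns on identical inputs are
byte-identical. An external species-level count table is brought into the
typing dialect with `ugityper reimagine-import --species-table ... --genus-map ...`.

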