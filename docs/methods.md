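# Methods

## The problem

Upper-gastrointestinal (uGI) samples — saliva, gastric and duodenal
aspirates, murine esophagus/stomach/duodenum tissue — carry low microbial
biomass, so reagent and environment contaminants can dominate their 16S
rRNA amplicon profiles. `ugityper` implements a contamination-controlled
analysis of genus-level (SILVA L6) count tables: it gates samples against
blank extraction/amplification controls, compares 16S rRNA gene (DNA) with
transcript (RNA/cDNA) profiles to classify transcriptional activity,
discovers co-occurring taxon blocks, and types subjects by the dominance
ratio of the Prevotella 7 over the Neisseria cluster.

All stages consume a `FeatureTable` (genus × sample non-negative integer
counts, TSV or BIOM 2.1) plus a per-sample metadata registry (subject,
host, location, amplicon, biological/control class, control type, optional
nucleic-acid yield and `cytokine_*` columns).

## Core transforms

- **Rarefaction** subsamples each sample without replacement to a fixed
  depth (defaults 2907 reads for human, 3404 for mouse, selected by the
  metadata `host` field); shallower samples are dropped and reported.
  Each sample draws from its own RNG stream keyed on `(seed,
  crc32(sample_id))`, so results are independent of sample order.
- **Relative abundance**: a pseudocount (default 1) is added to zero
  *count* cells only, then columns are normalised to 1. Adding to counts
  keeps non-zero values untouched; the scale choice is exposed in
  `AnalysisConfig.pseudocount`.
- **clr**: ln(x / geometric mean) per sample; columns sum to 0 and the
  transform is invariant to per-sample rescaling.
- **Prevalence filter**: keep taxa with relative abundance strictly
  > 0.1% in ≥ 3 samples; retained values are *not* renormalised by default
  so they stay directly interpretable as fractions of the whole sample
  (`renormalize=True` available).

## Contamination gate

Controls are compared to biological samples three ways: pairwise
two-sided Wilcoxon rank-sum tests on library sizes (BH-adjusted across
pairs); PCA of clr profiles with per-class 95% confidence ellipses
(chi-square quantile of the fitted 2-D Gaussian); and PLS-DA (PLS2 on a
one-hot class matrix) with taxa ranked by VIP score (normalised so the
mean squared VIP is 1). A biological sample is excluded when its PC1/PC2
coordinate falls inside the controls' 95% ellipse **or** its cumulative
relative abundance over the contaminant taxon set exceeds
`exclusion_fraction` (default 0.25). There is no canonical quantitative
exclusion rule for this judgement; the ellipse-OR-fraction rule
operationalises "indistinguishable from controls", both knobs sit in the
config, and the
report lists per-criterion outcomes so users can re-gate. Low extraction
yield (below `yield_floor_ng_ul`, default 1 ng/µl) is recorded as a
corroborating annotation only, never a sole cause. When no contaminant
list is supplied, the pipeline derives one as the top-VIP taxa that are
also control-enriched on the clr scale (VIP alone also ranks taxa that
mark biological samples).

## Diversity

Shannon index in bits (base 2 — the common toolkit convention; the log
base is configurable), Bray-Curtis dissimilarity on rarefied relative
abundances, classical PCoA (double-centering eigendecomposition; negative
eigenvalues reported; axis signs fixed so the largest-|value| coordinate
is positive), and ANOSIM with `R = (mean between-group rank − mean
within-group rank)/(M/2)` over the `M = n(n−1)/2` distance ranks. The
permutation p-value uses the +1 correction, `p = (1 + #{R* ≥ R})/(1 +
n_perm)`, so 999 permutations floor at p = 0.001. ANOSIM is implemented
in-package because it must be deterministic under a caller-supplied seed;
the test suite cross-checks the statistic against scikit-bio.
`shared_taxa_fraction` counts the detected (> `shared_taxa_min_rel`,
default any non-zero) taxa of a source sample that recur in a target
sample.

## DNA/RNA activity profiling

Phantom taxa — above 1% relative abundance in at least one RNA sample yet
zero in every DNA sample — are removed as reverse-transcription/
amplification artifacts (the threshold is read on the percent scale — a
fraction-scale 1.0 would remove nothing). After the
prevalence filter, pseudocounted clr values are modelled per taxon with a
linear mixed model `clr ~ location * amplicon + (1 | subject)` fitted by
REML — the Gaussian identity-link case of a GLMM; a singular interaction
fit falls back to the additive model, and non-converging taxa are
reported untested. Estimated marginal means are computed per
location × amplicon cell; the DNA-vs-RNA contrast per location is reported
raw and with a single-step max-|z| (Tukey-family) adjustment across the
taxon's contrast set, computed exactly from the joint normal rectangle
probability of the contrast correlation matrix. Across taxa, the raw
contrast p-values are BH-adjusted within each location (volcano plots are
per-location). Marginal/conditional R² use the variance-partition
formulation (fixed / total, fixed+random / total).

The volcano ratio is `log2(mean RNA relative abundance / mean DNA
relative abundance)` with arithmetic means over the location's samples —
the ratio of means, not the mean of ratios. Classification:
`active` iff log2 ratio ≥ +0.6 and q < 0.1; `inactive` iff ≤ −0.6 and
q < 0.1; else `ns`. Taxa with zero mean DNA abundance after filtering are
excluded with a reason.

## Co-occurrence clustering and community typing

Per location/amplicon, Spearman correlations are computed between taxa
occurring in ≥ 5 samples (constant taxa dropped — their rank correlation
is undefined). Hierarchical clustering uses distance `d = 1 − rho`
(range [0, 2]; an absolute-correlation distance would wrongly merge the
two mutually anti-correlated anchor blocks) with complete linkage by
default — with cut height 1 it guarantees every within-cluster pair has
rho > 0; `average` and `ward` are configurable. Flat clusters come from
cutting the dendrogram at height 1; merges at exactly the cut height are
kept (distance-criterion semantics), covered by a boundary test. Cluster
validity is scored by silhouette widths on `d`; singletons score 0 by
convention. An anchor cluster is the anchor genus's cluster restricted to
members with silhouette width > 0 (the anchor itself always included).

Typing: per sample, `p7_cum` and `neis_cum` are the cumulative relative
abundances of the two cluster member lists (missing members contribute
0). The sample is type `Prevotella7` iff `p7_cum ≥ 2.5 × neis_cum` ("at
least" — the boundary counts); `low_both` flags samples with both
cumulative abundances below 10%. With `neis_cum = 0` the ratio is
undefined: the call falls back to `p7_cum > 0` and the record is flagged
degenerate. Cluster definitions are portable: a run may re-discover
clusters from the cohort or load a fixed member list; the package ships
the reference salivary lists (10 Prevotella 7-cluster and 13
Neisseria-cluster genera) in `ugityper/data/reference_clusters.json`,
which is what re-typing an external species-level cohort (via
`reimagine_adapter`, which aggregates species counts to genus by
summation and buckets unmapped species) requires.

## Associations

HACEK burden is the cumulative relative abundance over the five HACEK
genera (Haemophilus, Aggregatibacter, Cardiobacterium, Eikenella,
Kingella), matched by genus-name prefix to tolerate SILVA label suffixes;
the prefix list is user-editable. Two-group comparisons gate on
normality: Welch's t-test only when *both* Anderson-Darling and
Shapiro-Wilk fail to reject (α = 0.05) in *both* groups, otherwise the
two-sided Wilcoxon rank-sum test (exact for small tie-free samples via
scipy's method="auto"); multiple endpoints are BH-adjusted. Cytokine
associations are Spearman correlations between a cluster's per-subject
cumulative abundance and serum cytokine level (pairwise missing-data
deletion, ≥ 5 complete pairs). The covariate confounding check is a
binary logistic regression of type on host covariates (the two-level case
of the multinomial model), reporting per-covariate odds ratios with 95%
CIs; constant covariates are dropped with a note and complete separation
is flagged rather than silently fitted.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with full planted truth for recovery tests.

- **Latent model**: logistic-normal — per subject × location a latent
  log-abundance vector is drawn and softmaxed to a composition. A
  logistic-normal was chosen over a Dirichlet because the analysis is
  clr-based and needs controllable correlation blocks.
- **Co-occurrence blocks**: the Prevotella 7 (10 genera) and Neisseria
  (13 genera) blocks load on two shared factors with loading √0.7, giving
  within-block taxon correlation 0.7; the factors are anti-correlated so
  between-block correlation is −0.4. Subject-level factors are mixed with
  location-level noise (weight 0.85) so profiles cohere across sites.
- **Planted types**: half the subjects (default) are Prevotella 7-type;
  the dominant block's log-abundance moves up and the other block's down
  by log(planted_fold) each (default fold 4), so the expected cumulative
  ratio between the planted groups is ≈ fold² ≈ 16 — consistent with the
  observed bimodality of per-subject ratios (well below 1.5 vs well above
  3.0) and safely above the 2.5 typing threshold. The latent per-taxon
  noise sd (0.7) was set so the generator meets its own contracts —
  planted-type samples exceed the typing threshold in ≥ 90% of draws and
  ≥ 95% of within/between-block pairs carry the planted correlation
  signs.
- **Carriage**: each subject hosts a random subset (prob 0.7) of the
  facultative (non-cluster, non-contaminant) taxa at all of their
  locations, giving the subject-specific detection structure behind the
  shared-taxa-fraction analyses.
- **Activity effects**: RNA samples multiply selected taxa by
  2^effect on the latent scale before renormalisation; DNA/RNA pairs
  share the same latent draw plus small amplicon noise (sd 0.3), so the
  null is exact when no effect is planted.
- **Contamination**: biological compositions contain no contaminant
  genera; every sample is mixed with a Dirichlet contaminant profile at
  weight `w = c/(c + biomass)` (c = 300), encoding that contamination
  inflates as biomass drops. Library sizes are lognormal (mean 3×10⁴
  biological, 3×10² controls, sigma 0.4); counts are multinomial, so
  column totals equal the drawn biomass exactly. Blank controls draw from
  control-type-specific sub-profiles (DNA-extraction vs RNA-isolate
  contaminants differ). `n_low_biomass` plants biological samples at
  control biomass (w ≈ 0.5) for gate-recovery tests.
- **Cytokines**: per-subject TNF-α = intercept + slope × (duodenal
  Prevotella 7 cumulative abundance) + Gaussian noise, slope −20 pg/ml
  per unit abundance, so the negative correlation is recoverable at
  cohort scale.

What the generator does **not** emulate: sequencing error, chimeras, 16S
copy-number variation, cDNA synthesis efficiency differences,
overdispersion beyond the logistic-normal (no per-taxon multinomial
overdispersion), taxonomic misclassification, or realistic zero inflation
beyond carriage. Passing recovery tests therefore demonstrate the
*statistical machinery* (gating, testing, clustering, typing) under the
assumed data-generating structure, not performance on real amplicon data.

## Problem sizes and runtime choices

Recovery and calibration runs use: typing and cluster recovery, 25
replicates of the default 40-subject cohort; activity calibration, 25
null and 25 planted-effect replicates at 19 subjects, one location, 60
taxa with 10 planted |log2| = 1.5 effects (each replicate fits one mixed
model per retained taxon); ANOSIM uniformity, 500 shuffled-label
replicates at 99 permutations; oracle-equivalence, 50 random ≤ 8-sample
tables checked to 1e-12; contamination gating, 25 replicates of a
40-biological-sample cohort with 5 planted low-biomass samples plus 18
controls. These sizes are the package's choice of a thorough-but-quick
default; all are parameters of the corresponding functions.

## Numerical conventions and degenerate inputs

Floating-point stage outputs are written as plain `pandas.to_csv` text;
determinism under a fixed seed is byte-level and covered by tests.
Duplicate taxon rows merge by summation with a warning. PCoA reports
negative eigenvalues rather than clipping silently. `fcluster` keeps
merges at exactly the cut height. Silhouette of singleton clusters is 0.
Empty samples, constant covariates/cytokines, single-class PLS-DA,
degenerate ANOSIM groupings, zero-Neisseria typing and zero-mean-DNA
activity records all raise or flag explicitly rather than propagating
NaNs.

## Known limitations

- The exclusion gate's ellipse criterion needs ≥ 3 control samples and
  assumes approximately Gaussian control scores on the first two PCs.
- Mixed-model inference uses normal-approximation Wald tests (no
  Kenward-Roger small-sample correction); with very few subjects the
  contrast p-values are anti-conservative.
- The sparse PLS-DA variant is a soft-thresholded loading filter and is
  flagged experimental.
- Re-typing an external species-level cohort requires a user-supplied
  species→genus mapping into the reference label dialect; unmapped
  species are bucketed, not guessed.
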