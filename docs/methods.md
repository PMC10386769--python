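# Methods

This note documents the statistical procedures txplore implements, the
defaults it ships, and the choices made where the design was genuinely
open. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Normalization

Counts `c(g, s)` for gene `g` with length `ℓ(g)` bp in sample `s` with
library size `N(s)` (always the column sum of the supplied matrix —
aligner-reported totals are never consulted, so results depend only on
the input file):

* CPM: `10⁶ · c / N`
* RPKM (= FPKM on output labeling): `10⁹ · c / (N · ℓ)`
* TPM: `10⁶ · (c/ℓ) / Σ_g (c/ℓ)` — every column sums to 10⁶ by
  construction; equivalently TPM is RPKM rescaled per column.
* log transform: `log2(x + pseudocount)`, pseudocount default 1.0
  (counts-scale convention; it must be positive when zeros are present).

All three normalizations refuse input whose declared unit is not
`counts`: renormalizing an already-normalized matrix is a silent error
we prefer to make loud. Zero-library columns are hard errors naming the
sample.

## Differential expression

Two classical per-gene location tests, computed on normalized values:

* **Welch's t**: `t = (x̄_A − x̄_B) / √(s²_A/n_A + s²_B/n_B)` with n−1
  variances and Satterthwaite degrees of freedom; two-sided p from the
  t distribution. Degenerate conventions: both variances zero with
  equal means → (t = 0, p = 1); with unequal means → p = 0 plus a
  runtime warning.
* **Wilcoxon rank-sum**: statistic is the mid-rank sum of group A.
  When both groups have ≤ 25 samples and the pooled values are untied,
  the exact null distribution of the rank sum is computed by dynamic
  programming over subset-sum counts (identical to enumerating all
  label assignments; counts stay below 2⁵³ so int64 arithmetic is
  exact), and the two-sided p doubles the smaller tail (the untied null
  is symmetric). Ties, or larger groups, route to the normal
  approximation with the tie-corrected variance and a 0.5 continuity
  correction; zero tie-corrected variance (all values identical) gives
  p = 1. The 25-per-group cutoff balances exactness against the
  quadratic-in-N cost of the exact table.

Effect size is `log2((mean_A + c)/(mean_B + c))` with a shared
pseudocount `c` (default 1.0); the pseudocount is a surfaced flag, not a
hidden constant. Multiple testing uses the Benjamini–Hochberg step-up
rule across all genes actually tested. Genes at zero in every sample of
both groups are dropped and counted. Counts-unit input is refused —
normalize first. Volcano thresholds (|log2FC| ≥ 1, q < 0.05) are
emitted as metadata only, never applied as filters.

Rank tests behave identically on CPM and log2(CPM) (ranks are monotone
invariant); Welch is better calibrated on the log scale for skewed
expression data, which is how the calibration check runs it.

## Biomarker discovery

For a target group versus the union of the other groups, each gene gets

* `rank_fc` — 1 for the largest log2 fold change toward the target;
* `rank_cv` — 1 for the smallest *maximal within-group CV*, the max
  over all groups (target included) of sd/mean on the normalized,
  non-log scale. Taking the max across every group encodes that a
  marker must be stably expressed everywhere, not merely high on
  average; a gene wildly variable in any one group is a poor marker.
  All-zero genes have CV 0 by convention.

The default `cv_fc` ordering sorts by `rank_fc + rank_cv`; `welch` and
`wilcoxon` order by ascending p then descending |log2FC|; `combined`
adds the p-value rank to the pair. All rank ties and ordering ties
break by ascending gene identifier, so output tables are byte-stable.
Only genes with positive fold change toward the target are eligible as
its markers; down-regulated genes stay in the table flagged ineligible.
The one-vs-rest panel runs the ranking once per group and merges each
gene at its best position, mirroring how marker panels feed heatmaps
and embeddings.

## Pre-ranked GSEA

The ranked list sorts genes by a statistic (log2 fold change by
default), descending, ties by identifier. For a set S of size n in a
list of N genes, walking the list accumulates `+|r_g|^w / Σ_{S}|r|^w`
on members and `−1/(N − n)` on non-members (weight `w` default 1.0; if
all member statistics are zero the hit increments fall back to `1/n`).
The enrichment score is the walk's signed extreme. When the largest
positive and negative deviations tie in magnitude (possible with
rational step sizes, e.g. weight 0, or symmetric hit configurations),
the sign of the walk's mean decides, then positive by convention; the
tie comparison uses a 10⁻⁹ tolerance to absorb summation-order float
noise. The leading edge is the members at or before the extremum
(at or after it, for negative ES).

The null is gene sampling: for each set, `n_permutations` random
position assignments of the same size drawn from the observed ranked
statistics, evaluated with exactly the same running-sum definition.
Each set's random substream is seeded by (run seed, CRC-32 of the set
name), making results reproducible and invariant to set-member and
collection ordering, and keeping each set's Monte-Carlo error
independent (a pool shared across sets would shift all p-values
coherently). Significance is one-tailed within sign,

    p = (1 + #{null of same sign with |ES'| ≥ |ES|}) / (1 + #{null of same sign}),

so the resolution floor is 1/(n_permutations + 1); NES divides ES by
the mean |null ES| of the same sign. BH runs across all tested sets,
both signs in one family. Set-size bounds default to 5–500 (common
practice); filtered and non-overlapping sets are counted, not silently
dropped. At least 100 permutations are required. This is the plain
quadratic-cost permutation engine — no multilevel p-value refinement —
which is accurate at desk scale and exactly testable against a
brute-force running-sum oracle.

## Over-representation and set-level comparison

ORA is the hypergeometric upper tail P(X ≥ k) for the overlap k between
a query list and a set, both intersected with a stated universe; the
query must be contained in the universe. Expected overlap is
`|query|·|set∩universe|/|universe|`.

The set-level comparison reduces each member gene (≥ 3 required) to its
within-group mean expression and applies the unpaired rank-sum test to
the two per-gene mean vectors, reporting direction as the group with
the higher median and the per-gene values for plotting. The per-gene
pairing would also admit a signed-rank test; the unpaired rank-sum is
the documented choice, and on duplicated groups the tie-corrected
variance is zero so p = 1.

## Embeddings and heatmap ordering

Samples are the observations, genes the features (a transpose flag
embeds genes). PCA centers features (optionally scales to unit
variance, dropping constant features with a count) and decomposes by
SVD; explained-variance fractions are singular values squared over
their total; each component's sign is fixed so its largest-|loading|
entry is positive, making coordinates platform-stable. Classical MDS
double-centers `B = −½ J D² J`, embeds with the top-k nonnegative
eigenpairs, and reports the negative-eigenvalue mass as a distortion
fraction (zero for exact Euclidean input). t-SNE and UMAP are delegated
to scikit-learn and umap-learn with a contract of output shape and
determinism given the seed; perplexity/neighbor defaults (30 / 15) are
surfaced flags and must be below the number of observations.
Non-log input triggers a warning, not an error. Heatmap leaf ordering is
average or complete linkage on correlation (1 − Pearson r; constant
rows at distance 1 to everything) or Euclidean distances.

## Synthetic studies

The generator emulates small grouped bulk RNA-seq designs of the kind
found in public immune-cell compendia: log-normal per-gene baseline
means (location log 100, scale 1), a shared negative-binomial
dispersion of 0.25 (variance μ + 0.25 μ², background within-group CV
around 0.5 at moderate expression), uniform gene lengths 500–5000 bp,
and three groups of four libraries by default. Planted structure:

* 10 markers per group at 8-fold, drawn at reduced dispersion and
  rejection-resampled (≤ 200 tries, then a warning) until the
  empirical within-group CV is ≤ 0.2 in *every* group; marker baseline
  means are floored at 50 counts because the CV cap is unattainable at
  lower means (a mean-5 gene has Poisson CV ≈ 0.45 alone).
* 50 DE genes between groups A and B at |log2 effect| 2, signs
  alternating, recorded signed in the truth table.
* five enriched 30-gene sets drawing 80% of members from up-regulated
  DE genes (optionally plus pure-background null sets).

Everything derives from one seed; identical specs are byte-identical.
The generator does **not** model batch effects, library-preparation
artifacts, gene–gene correlation, length-dependent counting bias, or
read-level noise — so passing recovery tests demonstrate correctness of
the ranking and testing machinery under clean overdispersed counts, not
robustness to confounded real-world designs.

## Verification scale and numerical choices

The recovery and calibration checks run at desk scale, chosen to keep
the whole suite under a minute while leaving no ambiguity in outcomes:
500-gene/12-sample fixtures over 50 seeds for marker recovery (1500
marker slots), 2000 null genes at 10 + 10 samples for test calibration,
1000-gene ranked lists with 1000 permutations for GSEA, exhaustive
universes ≤ 30 for ORA. Exactness tolerances: 10⁻¹² against brute-force
oracles (enumeration, plain-loop running sums, closed-form
combinatorics), 10⁻⁸ for decomposition oracles, 10⁻⁶ relative for TPM
column sums. Expression tables serialize floats via `repr` (shortest
round-trip representation), so write∘read is exact. CLI provenance
headers carry version, parameters, and seed but never timestamps or
absolute paths, making reruns byte-identical.

## Known limitations

* No dispersion-model DE (edgeR/DESeq2-class engines are out of scope
  by design); with very few replicates the rank-sum p floors high
  (2/70 at 4 vs 4) and Welch is underpowered.
* GSEA p-values cannot go below 1/(n_permutations + 1); no multilevel
  refinement.
* GO structure is ignored: sets are flat gene lists as supplied, with
  no is_a/part_of propagation.
* Identifier matching is exact and case-sensitive; ortholog or alias
  mapping belongs upstream.
* The ES sign is ambiguous on exactly tied extremes of self-symmetric
  walks; the documented tie rule is deterministic, and sign
  antisymmetry under statistic negation holds on tie-free instances
  (magnitude antisymmetry always).
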