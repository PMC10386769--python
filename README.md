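# txplore

A headless bulk RNA-seq exploration toolkit for biologists' everyday
questions: *which genes differ between my sample groups, which genes
mark one group, and which pathways move?* It implements the analytical
engine behind interactive expression-browser workflows — normalization,
group-wise differential expression, biomarker ranking, gene-set
statistics, and embeddings — as a plain Python library plus a `txplore`
command-line tool that reads and writes delimited text. There is no GUI,
no web service, and no network access: gene sets come in as GMT files,
expression as gene × sample tables.

## What it computes

* **Normalization** — CPM, RPKM/FPKM, and TPM from raw counts
  (library size = column sum), plus a `log2(x + pseudocount)`
  transform. TPM is the per-length read rate rescaled so every sample
  sums to 10⁶: `TPM_g = 10⁶ · (c_g/ℓ_g) / Σ_j (c_j/ℓ_j)`.
* **Differential expression** — per-gene Welch's unequal-variance
  *t*-test or the Wilcoxon rank-sum test between two groups, effect
  size `log2((mean_A + c)/(mean_B + c))`, and Benjamini–Hochberg
  q-values. The Wilcoxon null is exact (enumeration-equivalent dynamic
  programming) up to 25 samples per group without ties.
* **Biomarker discovery** — one-vs-rest marker ranking combining the
  rank of descending fold change with the rank of ascending maximal
  within-group coefficient of variation (CV = sd/mean), so a marker
  must be both high in its group and stable in every group; Welch /
  Wilcoxon p-value orderings are available as alternatives.
* **Gene-set statistics** — pre-ranked GSEA (weighted running-sum
  enrichment score, gene-sampling permutation null, NES, BH q-values,
  leading edge), hypergeometric over-representation, and a set-level
  Wilcoxon comparison of all member genes' group means.
* **Embeddings** — native PCA (SVD, fixed sign convention) and
  classical MDS (double-centering + eigendecomposition); t-SNE and
  UMAP delegated to scikit-learn / umap-learn; hierarchical leaf
  ordering for heatmaps.
* **Synthetic studies** — a seeded negative-binomial generator that
  plants markers, DE genes, and enriched sets with truth tables, so the
  whole pipeline is testable without downloads.

## Worked example

```python
import txplore as tx

bundle = tx.generate_dataset(tx.SyntheticSpec(seed=7))   # 500 genes, groups A/B/C x 4
matrix = tx.cpm(bundle.matrix)

de = tx.run_differential_expression(matrix, bundle.groups, "B", "A", test="wilcoxon")
print(de.table.nsmallest(3, "q_value")[["gene", "log2_fold_change", "p_value", "q_value"]])

markers = tx.discover_biomarkers(matrix, bundle.groups, "C", method="cv_fc", top_k=5)
print(markers.top_genes)

ranked = tx.make_ranked_list(de)
gsea = tx.preranked_gsea(ranked, bundle.sets, n_permutations=1000, seed=1)
print(gsea.table.head(3)[["name", "es", "nes", "p_value", "q_value"]])
```

prints

```
  gene  log2_fold_change  p_value  q_value
G00001         -3.021949 0.028571 0.223214
G00002         -3.083133 0.028571 0.223214
G00003         -2.959870 0.028571 0.223214
['G00029', 'G00025', 'G00021', 'G00023', 'G00022']
      name       es      nes  p_value  q_value
SET_ENR_01 0.880406 2.691385 0.002604 0.002681
SET_ENR_02 0.897648 2.800069 0.002415 0.002681
SET_ENR_03 0.876919 2.757432 0.002494 0.002681
```

The three lowest-q genes are markers planted for group A (hence
negative fold change toward B; with n = 4 vs 4 the exact Wilcoxon
two-sided p floors at 2/70 ≈ 0.029, so q stays modest). The group-C
marker list recovers planted C markers, and the planted gene sets reach
the permutation p-value floor region with strongly positive NES.

The same chain runs from the shell:

```sh
txplore simulate --out-dir fix --seed 7
txplore normalize --matrix fix/matrix.tsv --unit cpm --out cpm.tsv
txplore de --matrix cpm.tsv --groups fix/groups.tsv --a B --b A --test wilcoxon --out de.tsv
txplore gsea --ranked de.tsv --gmt fix/sets.gmt --nperm 1000 --seed 1 --out gsea.tsv
txplore pca --matrix cpm.tsv --unit CPM --k 2 --out pca.tsv
```

Outputs are plot-ready tables with a `#` provenance header (tool
version, parameters, seed — no timestamps, so reruns are
byte-identical).

## Scope

Identifier matching is exact and case-sensitive; delimiters are explicit
(default tab). The toolkit does not download from GEO/MSigDB/GO, does
not parse GTF/GFF (gene lengths come as a two-column table), does not
re-implement negative-binomial DE engines (edgeR/DESeq2-style), and
emits tables rather than rendered figures. See `docs/methods.md` for the
statistical details and design choices.
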