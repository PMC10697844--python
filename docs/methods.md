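# Methods

This note documents the models implemented in `scevolink`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions adopted where the underlying procedures are
commonly described ambiguously.

## Single-cell preprocessing

A `CellMatrix` holds genes × cells UMI counts with per-cell sample, sex and
cluster annotations. QC keeps cells with mitochondrial fraction ≤ 0.40,
500 ≤ nUMI ≤ 60,000 and 250 ≤ nGene ≤ 3,000 (all bounds inclusive; the
permissive mito ceiling reflects tissues where healthy cells carry high
mitochondrial content), then keeps genes detected in ≥ 3 retained cells.
The filter order is fixed: cells first, then genes. An optional
cluster-level pre-filter drops whole clusters in which a strict majority
(> 50%) of cells violate (mito ≥ 0.40 OR nUMI < 1,000); OR is the default
combination because it is the conservative reading of a rule stated with an
ambiguous conjunction, and both are exposed.

Normalization is `value = ln(1 + count / nUMI × 10⁴)` (scale factor and
pseudocount configurable; 10⁴ is the de-facto standard for droplet data).
Cluster summaries report `avg_exp` — the mean of `exp(value) − 1` over a
cluster's cells, i.e. de-logged normalized expression — and `pct_exp`, the
fraction of cells with a nonzero raw count. A conservation identity
(cluster means weighted by cluster sizes equal the global mean) is tested.

## Marker detection

Per cluster-vs-rest comparison, genes pass the detection filter when
`max(pct_in, pct_out) ≥ min.pct` (0.2); the test is the two-sided Wilcoxon
rank-sum on normalized values — exact for tie-free groups of ≤ 8, otherwise
the tie-corrected normal approximation with continuity correction
(`scipy.stats.mannwhitneyu`, vectorized across genes). P-values are
BH-adjusted across all tests of all clusters, and the returned table keeps
positive fold changes (one-sided interest) at adjusted p < 0.05.

`avg_log2FC = log2((mean_in + c) / (mean_out + c))` on de-logged means with
pseudocount c = 1, the mean-ratio convention of current single-cell
toolkits; the pseudocount is configurable because toolkit versions differ.
"Highly enriched" (neuron-specific) genes are markers whose maximum
avg_log2FC is ≥ 1 and that mark ≤ 5 clusters, both bounds inclusive.

## Bulk tissue specificity

TPM is computed per sample as
`rate_g = count_g × mean_read_length / CDS_g`, `TPM_g = 10⁶ rate_g / Σ rate`,
so each sample sums to 10⁶ exactly; replicates are averaged per tissue
*after* TPM (per-sample normalization then averaging is the
order that keeps each replicate equally weighted). τ is computed on raw
replicate-averaged TPM — the index is scale invariant, so the choice of
unit is immaterial, but no log transform is applied (a log changes τ).
A gene is tissue specific when τ > 0.8 strictly; the argmax tissue breaks
ties by first index; all-zero genes have undefined τ and are never specific.

## Duplication timing

Gene trees are rooted, with leaf labels `SPECIES|gene` (delimiter
configurable). Duplications are detected by species overlap: an internal
node is a duplication iff two of its children have intersecting species
sets. This is the minimal topology-only rule — no branch lengths, no
reconciliation costs — and it is exact on single-duplication trees without
losses. Multifurcations are not binarized; each pair of children sharing
species is treated as one event at that node.

Scenarios are an ordered, strictly nested list of named clades configured
against the species tree (default: focal species H1 ⊂ spiders H2 ⊂
spiders+scorpions H3 ⊂ arachnids H4 ⊂ spiders+insects H5, over a six-taxon
desk-scale tree `((((Hgra,Aka),Cscu),Ture),(Dmel,Amel))`). A duplication is
assigned the smallest clade containing the union of species below it;
species absent from every clade leave the event `unassigned` (warning, not
an error). Keeping the clade list in a config file rather than hard-coding
it lets users express groupings (e.g. a spider+scorpion ancestor) whose
exact taxon support varies between studies. Paralog pairs are all
cross-child pairs of focal-species genes at each duplication node; since a
pair's MRCA is exactly the node it is emitted at, nested duplications never
produce duplicate pairs. Both properties are tested against brute-force
all-pairs MRCA oracles.

## Paralog expression divergence

Four per-pair statistics:

1. **Same cell type** — the pair's enriched-cluster sets intersect, where a
   gene's enriched clusters are those with `pct_exp > 0.25` and
   `avg_exp > 2` (strict). Pairs with an empty set on either side are
   excluded from the denominator and counted separately.
2. **Expression correlation** — Pearson r of `ln(1 + count)` across all
   cells (a per-cluster-mean mode exists; per-cell is the default since it
   uses the full data). Zero-variance genes give an undefined r, reported
   as missing.
3. **Shared top regulators** — |top-k ∩ top-k| of the two genes'
   regulator-weight columns, k = 25, ties at rank k broken by regulator id
   for reproducibility.
4. **Regulator-weight correlation** — Spearman ρ of the full weight columns.

Regulator weights are consumed from an external regulator × target TSV
(e.g. a random-forest importance matrix produced elsewhere). When none is
supplied, a clearly-labelled co-expression stand-in is available —
|Spearman| of cluster-mean profiles — which is *not* equivalent to a
network-inference importance and is tagged `correlation_standin` in every
output.

**Resampling null.** Each scenario's summary (mean, or fraction for the
boolean statistic) is compared against `n_perm` permutations, each drawing
the same number of uniform random gene pairs (distinct genes within a pair)
from the analysis universe; `p = (1 + #{null ≥ observed}) / (n_perm + 1)`,
never exactly 0. For the same-cell-type statistic the null universe is
restricted to genes the enrichment rule can evaluate (≥ 1 enriched
cluster), mirroring the observed denominator. Permutations whose summary is
undefined are redrawn with a capped retry. Calibration is verified: with
observed pairs drawn from the null itself, empirical p-values are uniform
(KS test) and never zero.

## Cross-species cluster correspondence

Profiles are compared on BRH-linked genes that are markers in both species.
Spearman correlation is computed between de-logged cluster mean profiles
(rank-based, hence invariant to monotone transforms); marker-set similarity
is the Jaccard index of orthology-mapped marker sets, with both sides
restricted to the BRH-covered universe so the measure is symmetric under
swapping species and inverting the map. Jaccard is adopted as the minimal
symmetric set-overlap measure; the metric is pluggable.

Ordering uses classical Ward (ward.D): Lance–Williams agglomeration on
*unsquared* Euclidean distances, implemented directly because the common
library routine is the squared-distance ward.D2 variant; it is verified
against R's `hclust(method = "ward.D")`. Merge ties break on the smaller
cluster-id pair, so leaf orders are deterministic.

A gene-label shuffling null (permute the B side of the BRH pairing, record
the matrix maximum, 200 permutations) provides the significance reference
for mutual best hits.

## Gene sets, sex bias, module scores, peptidergic cells

- **Enrichment mapping**: strict `pct_exp > 0.25` and `avg_exp > 2`;
  thresholds are recorded in the output and monotonicity (raising a
  threshold never adds a cluster) is tested.
- **Group comparison**: two-sided Pearson chi-square on 2×2 counts, df = 1,
  no Yates correction by default (a continuity flag exists); a zero
  marginal is degenerate and returns chi2 = 0 with a warning rather than an
  exception.
- **Sex-biased genes**: every (male sample, female sample) pair is tested
  separately (Wilcoxon, min.pct 0.25, BH within comparison); a gene is
  sex-biased only if significant with a consistent direction in *all*
  pairs. Direction consistency is required in addition to significance to
  make "male-biased" well defined; the all-pairs rule is what rejects
  single-sample batch artefacts, and that rejection is tested explicitly.
- **Module score**: mean normalized expression of the set minus the mean of
  control genes sampled (seeded) from the set genes' global-mean-expression
  bins (25 equal-frequency bins, 100 controls per set gene). This is the
  difference-of-means score; it is not the rank-based AUC statistic some
  packages compute under a similar name.
- **Peptidergic cells**: a cell is peptidergic when its summed raw UMIs over
  the neuropeptide list strictly exceed 100. Sum (not mean) is the default
  aggregation — the natural reading of a per-cell neuropeptide nUMI — and
  both the aggregation and threshold are configurable.

## Synthetic data

All generators are deterministic given the config seed and return explicit
truth tables. Counts are gamma-Poisson (negative binomial,
Var = μ + φμ², shared dispersion φ = 0.3) — the standard UMI noise model;
no ambient RNA, doublets, batch effects or realistic sequence evolution are
simulated, so passing tests demonstrate correctness of the statistics and
their power under clean planted signal, not robustness to those artefacts.

- **Atlas fixture**: 5 samples (2 male / 3 female) × 600 cells, 12
  clusters, 2,000 genes, 10 markers per cluster at 8× fold change over a
  0.5 UMI/gene baseline. Sized for rank-sum power (≈ 250 cells per cluster)
  while generating in seconds.
- **Bulk panel**: 8 tissues × 3 replicates; 10% of genes tissue specific at
  500 expression units (leakage configurable, default 0) over a flat
  50-unit background; specific genes are planted in equal numbers per
  tissue and share a common CDS length so the noise-free limit recovers τ
  exactly (τ = 1 at zero leakage; τ = 1 − leakage in general).
- **Gene trees**: the species tree with exactly one duplication grafted at
  the named clade's subtree (both copies then follow the species tree);
  one event per tree keeps the truth label unambiguous. Losses drop leaves
  independently at a configured rate (default 0).
- **Paralog expression**: 40 pairs per scenario with divergence level d
  rising with duplication age (0.05, 0.25, 0.45, 0.65, 0.85). Gene B shares
  gene A's home cluster and per-cell gamma noise with weight 1 − d. The
  panel's baseline is 0.2 UMI/gene — below the NB detection fraction the
  pct > 0.25 enrichment threshold implies — with a 10× home-cluster fold,
  so enriched-cluster sets track the planted home clusters; 40 pairs per
  scenario keeps the standard error of a scenario mean (~0.025) well under
  the gaps between adjacent scenario means.
- **Two species**: 8 clusters each, 1,000 BRH-paired genes, 120 cells per
  cluster. Every cluster carries a lognormal per-gene expression signature
  (log-sd 0.5); homologous cluster pairs share their signature through the
  BRH alignment — the generative analogue of homologous cell types
  correlating transcriptome-wide — plus a shared 12-gene marker block,
  while non-homologous clusters draw independent signatures and private
  marker blocks.

## Numerical conventions and degenerate inputs

- Empirical p-values use the +1 correction and are never 0.
- Argmax ties (top tissue, top-k regulators) break deterministically by
  first index / lexicographic id.
- All-zero genes: τ undefined (NaN), never "specific"; zero-variance genes:
  correlations undefined, excluded from scenario means and reported as
  missing.
- A missing mitochondrial gene list makes the mito filter a logged no-op
  rather than an error.
- QC raising an empty result names the first filter that exhausted the
  cells.

## Problem sizes

The test suite and the acceptance script run the fixtures described above:
3,000-cell atlas, 200 gene trees, 200 paralog pairs (+ background genes),
two 960-cell species atlases, 300-replicate null calibration at 199
permutations. These sizes were chosen so every recovery statistic has
comfortable power at desk scale; all are fields of `SimConfig` and scale up
directly.

## Known limitations

- The species-overlap rule over-calls duplications under heavy gene loss or
  incomplete lineage sorting; no reconciliation-cost correction is applied.
- The correlation stand-in for regulator weights measures co-expression,
  not regulatory importance.
- The marker-similarity Jaccard is one reasonable operationalization of
  marker-set overlap; fold-change-weighted variants are not implemented.
- Exact tests for sparse 2×2 tables are out of scope; the chi-square
  comparison refuses degenerate tables instead.
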