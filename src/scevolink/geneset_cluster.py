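"""Mapping evolutionary gene sets onto clusters and tissues.

Selection-candidate gene lists (positively selected / rapidly evolving
genes, neuropeptides, transcription factors) are mapped to the cell
clusters where they are enriched (fraction of expressing cells > 0.25 and
de-logged mean expression > 2, both strict), brain-bias fractions are
computed against the bulk tau specificity calls, group differences are
tested with a two-sided Pearson chi-square, sex-biased genes are called by
an all-sample-pairs rank-sum rule, gene modules are scored per cell against
expression-matched background genes, and peptidergic cells are counted by
their summed neuropeptide UMIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .core_model import CellMatrix, GeneSet, NormalizedMatrix, ClusterSummary
from .specificity import SpecificityResult, _rank_sum_matrix

logger = logging.getLogger("scevolink")


# ---------------------------------------------------------------------------
# Cluster enrichment of gene sets
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentMap:
    """Per-gene set of clusters passing the pct/avg enrichment thresholds."""

    clusters_by_gene: dict  # gene -> frozenset of clusters
    pct_min: float
    avg_min: float
    missing_genes: tuple = ()

    def __getitem__(self, gene: str):
        return self.clusters_by_gene[gene]

    def get(self, gene: str, default=frozenset()):
        return self.clusters_by_gene.get(gene, default)


def enriched_clusters(
    gs: GeneSet, cs: ClusterSummary, pct_min: float = 0.25, avg_min: float = 2.0
) -> EnrichmentMap:
    """Clusters where each set gene has pct_exp > pct_min AND avg_exp > avg_min.

    Both thresholds are strict.  Set genes absent from the summary are
    reported (not an error); genes enriched nowhere keep an empty set.
    """
    known = set(cs.avg_exp.columns)
    present = sorted(g for g in gs.genes if g in known)
    missing = tuple(sorted(gs.genes - known))
    if missing:
        logger.warning("%d gene(s) of set %s absent from summary", len(missing), gs.name)
    out = {}
    for g in present:
        ok = (cs.pct_exp[g] > pct_min) & (cs.avg_exp[g] > avg_min)
        out[g] = frozenset(cs.avg_exp.index[ok])
    return EnrichmentMap(out, pct_min, avg_min, missing)


def cluster_group_fraction(em: EnrichmentMap, group) -> tuple:
    """Fraction of enriched genes whose cluster set intersects ``group``.

    The denominator is the genes with at least one enriched cluster; genes
    enriched nowhere are excluded and counted.  Returns
    (fraction, n_in_group, n_evaluable, n_excluded).
    """
    group = set(group)
    if not group:
        raise ValueError("cluster group is empty")
    evaluable = {g: c for g, c in em.clusters_by_gene.items() if c}
    excluded = len(em.clusters_by_gene) - len(evaluable)
    n_in = sum(1 for c in evaluable.values() if c & group)
    frac = n_in / len(evaluable) if evaluable else float("nan")
    return frac, n_in, len(evaluable), excluded


def brain_bias_fraction(gs: GeneSet, sr: SpecificityResult, brain_label: str) -> tuple:
    """Fraction of set genes that are tissue specific with argmax = brain.

    Returns (fraction, n_brain_specific, n_evaluable, n_missing); genes
    absent from the specificity table are excluded from the denominator.
    """
    table = sr.table
    known_tissues = set(sr.tissues) or _tissues_of(table)
    if brain_label not in known_tissues:
        raise ValueError(f"{brain_label!r} is not a tissue in the specificity result")
    present = sorted(g for g in gs.genes if g in table.index)
    missing = len(gs.genes) - len(present)
    if not present:
        return float("nan"), 0, 0, missing
    sub = table.loc[present]
    n_brain = int((sub["specific"] & (sub["top_tissue"] == brain_label)).sum())
    return n_brain / len(present), n_brain, len(present), missing


def _tissues_of(table: pd.DataFrame) -> set:
    return set(table["top_tissue"].dropna().unique())


# ---------------------------------------------------------------------------
# Two-sided chi-square group comparison
# ---------------------------------------------------------------------------


@dataclass
class BiasComparison:
    table: np.ndarray  # 2x2 counts: rows = sets, cols = (in-category, not)
    chi2: float
    p: float
    df: int = 1
    corrected: bool = False


def compare_bias(
    set1_counts, set2_counts, continuity: bool = False
) -> BiasComparison:
    """Two-sided Pearson chi-square on a 2x2 table (no Yates correction
    by default).

    ``set1_counts``/``set2_counts`` are (in-category, not-in-category)
    pairs.  A zero marginal makes the statistic degenerate; chi2 = 0 and
    p = 1 are returned with a warning.
    """
    a, b = map(int, set1_counts)
    c, d = map(int, set2_counts)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("empty table")
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        logger.warning("degenerate 2x2 table (zero marginal); chi2 = 0")
        return BiasComparison(table.astype(int), 0.0, 1.0, 1, continuity)
    det = a * d - b * c
    if continuity:
        det = max(abs(det) - n / 2.0, 0.0)
        chi2 = n * det**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    else:
        chi2 = n * det**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(st.chi2.sf(chi2, df=1))
    return BiasComparison(table.astype(int), float(chi2), p, 1, continuity)


# ---------------------------------------------------------------------------
# Sex-biased genes: the all-sample-pairs rule
# ---------------------------------------------------------------------------


def sex_biased_genes(
    nm: NormalizedMatrix,
    m: CellMatrix,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
):
    """Genes differentially expressed in EVERY male-vs-female sample pair.

    For each (male sample, female sample) pair a two-sided Wilcoxon
    rank-sum test is run per gene on the normalized values (genes detected
    in >= ``min_pct`` of either group), BH-adjusted within the comparison.
    A gene is male-biased iff it is significant with a male-higher fold
    change in all pairs (symmetrically female-biased); requiring a
    consistent direction in every pair is what rejects single-sample batch
    effects.  Returns (male GeneSet | None, female GeneSet | None, detail
    DataFrame with one row per gene x comparison).
    """
    meta = m.cell_meta
    male_samples = sorted(meta.loc[meta["sex"] == "male", "sample"].unique())
    female_samples = sorted(meta.loc[meta["sex"] == "female", "sample"].unique())
    if not male_samples or not female_samples:
        raise ValueError("need at least one sample of each sex")
    dense = nm.dense()
    delog = np.expm1(dense)
    detected = dense > 0
    genes = np.asarray(nm.gene_ids, dtype=object)

    records = []
    for ms in male_samples:
        m_mask = ((meta["sample"] == ms) & (meta["sex"] == "male")).to_numpy()
        if m_mask.sum() < 10:
            logger.warning("male sample %s has <10 cells", ms)
        for fs in female_samples:
            f_mask = ((meta["sample"] == fs) & (meta["sex"] == "female")).to_numpy()
            if f_mask.sum() < 10:
                logger.warning("female sample %s has <10 cells", fs)
            pct_m = detected[:, m_mask].mean(axis=1)
            pct_f = detected[:, f_mask].mean(axis=1)
            test = np.maximum(pct_m, pct_f) >= min_pct
            if not test.any():
                continue
            pvals = _rank_sum_matrix(dense[test][:, m_mask].T, dense[test][:, f_mask].T)
            padj = multipletests(pvals, method="fdr_bh")[1]
            lfc = np.log2(
                (delog[test][:, m_mask].mean(axis=1) + pseudocount)
                / (delog[test][:, f_mask].mean(axis=1) + pseudocount)
            )
            records.append(
                pd.DataFrame(
                    {
                        "gene": genes[test],
                        "male_sample": ms,
                        "female_sample": fs,
                        "avg_log2FC": lfc,
                        "p_value": pvals,
                        "p_adj": padj,
                    }
                )
            )
    detail = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(
            columns=["gene", "male_sample", "female_sample", "avg_log2FC", "p_value", "p_adj"]
        )
    )
    n_comparisons = len(male_samples) * len(female_samples)

    male_genes, female_genes = [], []
    for gene, grp in detail.groupby("gene"):
        if len(grp) < n_comparisons:
            continue  # not even tested in every comparison
        sig = (grp["p_adj"] < alpha).all()
        if not sig:
            continue
        if (grp["avg_log2FC"] > 0).all():
            male_genes.append(gene)
        elif (grp["avg_log2FC"] < 0).all():
            female_genes.append(gene)
    male_set = GeneSet("male_biased", frozenset(male_genes), "sex_bias") if male_genes else None
    female_set = (
        GeneSet("female_biased", frozenset(female_genes), "sex_bias") if female_genes else None
    )
    return male_set, female_set, detail


# ---------------------------------------------------------------------------
# Module score
# ---------------------------------------------------------------------------


def module_score(
    nm: NormalizedMatrix,
    gs: GeneSet,
    n_bins: int = 25,
    ctrl_per_gene: int = 100,
    seed: int = 0,
    clusters: pd.Series = None,
):
    """Per-cell module score against expression-bin-matched background genes.

    score(cell) = mean normalized expression of the set genes minus the mean
    over control genes, where each set gene contributes ``ctrl_per_gene``
    controls sampled (seeded, with replacement) from its global
    mean-expression bin (``n_bins`` equal-frequency bins).  Returns
    (per-cell Series, per-cluster mean Series or None).
    """
    genes = list(nm.gene_ids)
    gene_index = {g: i for i, g in enumerate(genes)}
    set_genes = sorted(g for g in gs.genes if g in gene_index)
    if not set_genes:
        raise ValueError(f"no gene of set {gs.name} present in the matrix")
    if len(set_genes) < 2:
        logger.warning("gene set %s has <2 genes in the matrix", gs.name)
    rng = np.random.default_rng(seed)
    dense = nm.dense()
    global_mean = dense.mean(axis=1)
    bins = pd.qcut(pd.Series(global_mean, index=genes), q=n_bins, duplicates="drop")

    ctrl_idx = []
    for g in set_genes:
        pool = bins.index[(bins == bins[g]).to_numpy()]
        picks = rng.choice(pool, size=ctrl_per_gene, replace=True)
        ctrl_idx.extend(gene_index[p] for p in picks)
    set_idx = [gene_index[g] for g in set_genes]
    score = dense[set_idx].mean(axis=0) - dense[ctrl_idx].mean(axis=0)
    per_cell = pd.Series(score, index=list(nm.cell_ids), name=f"{gs.name}_score")
    per_cluster = None
    if clusters is not None:
        per_cluster = per_cell.groupby(pd.Series(clusters).to_numpy()).mean()
    return per_cell, per_cluster


# ---------------------------------------------------------------------------
# Peptidergic cells
# ---------------------------------------------------------------------------


def peptidergic_cells(
    m: CellMatrix, np_set: GeneSet, umi_threshold: float = 100, agg: str = "sum"
):
    """Cells whose raw neuropeptide UMIs exceed the threshold (strict >).

    ``agg='sum'`` totals UMIs over the neuropeptide list per cell (default
    reading of "nUMI of neuropeptides > 100"); ``agg='mean'`` averages
    instead.  Returns (cell ids, count, proportion).
    """
    if not np_set.genes:
        raise ValueError("neuropeptide set is empty")
    present = set(m.gene_ids)
    missing = sorted(np_set.genes - present)
    if missing:
        raise ValueError(f"neuropeptide genes absent from matrix: {missing[:10]}")
    mask = np.isin(m.gene_ids, sorted(np_set.genes))
    totals = np.asarray(m.counts[mask].sum(axis=0)).ravel().astype(float)
    if agg == "mean":
        totals = totals / mask.sum()
    elif agg != "sum":
        raise ValueError("agg must be 'sum' or 'mean'")
    is_pep = totals > umi_threshold
    cells = list(np.asarray(m.cell_ids)[is_pep])
    return cells, int(is_pep.sum()), float(is_pep.mean())
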