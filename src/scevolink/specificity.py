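"""Bulk-tissue specificity (TPM, tau) and single-cell marker detection.

Two notions of "specific" are computed here.  For bulk tissue panels the
tau index summarizes how concentrated a gene's expression profile is across
tissues (0 = uniform, 1 = single tissue); genes with tau > 0.8 and maximal
expression in a tissue of interest are called tissue specific.  For
single-cell data, per-cluster markers come from a cluster-vs-rest two-sided
Wilcoxon rank-sum test on log-normalized values, and "highly enriched"
genes are markers with high fold change in few clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .core_model import GeneSet, NormalizedMatrix, ValidationError

logger = logging.getLogger("scevolink")


@dataclass
class TissueMatrix:
    """Replicate-averaged gene x tissue TPM with CDS lengths."""

    tpm: pd.DataFrame  # genes x tissues (replicate-averaged)
    tpm_per_sample: pd.DataFrame  # genes x samples
    cds_length: pd.Series
    mean_read_length: float

    @property
    def tissues(self) -> list:
        return list(self.tpm.columns)


# ---------------------------------------------------------------------------
# TPM and tau
# ---------------------------------------------------------------------------


def compute_tpm(
    counts: pd.DataFrame,
    cds_length: pd.Series,
    mean_read_length: float,
    sample_tissue=None,
) -> TissueMatrix:
    """Length-normalized TPM, then replicate means per tissue.

    rate[g] = count[g] * mean_read_length / cds_length[g];
    TPM[g] = rate[g] / sum_j rate[j] * 1e6, per sample, so each sample's
    TPM column sums to 1e6.  ``sample_tissue`` maps sample names to tissue
    labels; by default the tissue is the sample name up to the last ``_``
    (e.g. ``brain_1`` -> ``brain``).
    """
    cds = cds_length.reindex(counts.index)
    if cds.isna().any():
        missing = list(cds.index[cds.isna()][:5])
        raise ValidationError(f"genes without CDS length: {missing}")
    if (cds <= 0).any():
        raise ValidationError("CDS lengths must be positive")
    rates = counts.mul(float(mean_read_length), axis=0).div(cds, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"sample(s) with zero total counts: {list(zero)}")
    tpm_samples = rates.div(totals, axis=1) * 1e6

    if sample_tissue is None:
        sample_tissue = {s: str(s).rsplit("_", 1)[0] for s in counts.columns}
    tissues = pd.Series({s: sample_tissue[s] for s in counts.columns})
    tpm = tpm_samples.T.groupby(tissues).mean().T
    return TissueMatrix(tpm, tpm_samples, cds, float(mean_read_length))


def tau_index(x) -> float:
    """Tissue-specificity index tau = sum_i (1 - x_i / max(x)) / (n - 1).

    Ranges over [0, 1]: 0 for a uniform profile, 1 for expression confined
    to a single tissue.  Undefined (NaN) for an all-zero profile.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau requires a 1-d profile over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("tau requires nonnegative expression")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


@dataclass
class SpecificityResult:
    """Per-gene tau, argmax tissue and the tau > threshold call."""

    table: pd.DataFrame  # columns: tau, top_tissue, specific
    threshold: float
    tissues: tuple = ()

    def brain_specific(self, tissue_label: str) -> pd.Index:
        t = self.table
        return t.index[t["specific"] & (t["top_tissue"] == tissue_label)]


def classify_specific(tm: TissueMatrix, threshold: float = 0.8) -> SpecificityResult:
    """Call tissue-specific genes: tau strictly > threshold.

    ``top_tissue`` is the argmax of replicate-averaged TPM with first-index
    tie-break; all-zero genes get tau = NaN, specific = False and a missing
    top tissue.
    """
    vals = tm.tpm.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    taus = np.array([tau_index(row) if row.max() > 0 else np.nan for row in vals])
    top_idx = vals.argmax(axis=1)
    top = np.array(tm.tpm.columns, dtype=object)[top_idx]
    top = np.where(np.isnan(taus), None, top)
    specific = np.where(np.isnan(taus), False, taus > threshold)
    table = pd.DataFrame(
        {"tau": taus, "top_tissue": top, "specific": specific.astype(bool)},
        index=tm.tpm.index,
    )
    return SpecificityResult(table, threshold, tuple(tm.tpm.columns))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum marker detection
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact for tie-free samples with both sizes <= 8, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    if len(x) <= 8 and len(y) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(st.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _rank_sum_matrix(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values, one per column (gene)."""
    n1, n2 = x_in.shape[0], x_out.shape[0]
    if n1 <= 8 and n2 <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = st.mannwhitneyu(x_in, x_out, alternative="two-sided", method=method, axis=0)
    return np.atleast_1d(res.pvalue)


def find_markers(
    nm: NormalizedMatrix,
    clusters: pd.Series,
    min_pct: float = 0.2,
    only_pos: bool = True,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    counts=None,
) -> pd.DataFrame:
    """Cluster-vs-rest marker detection (Wilcoxon rank-sum, BH-adjusted).

    For every cluster, genes detected (value > 0) in at least ``min_pct``
    of cells in either group are tested cluster-vs-rest; p-values are
    BH-adjusted across all tests of all clusters; the table is restricted
    to positive fold changes when ``only_pos`` and to adjusted p < alpha.

    avg_log2FC = log2((mean_in(exp(value)-1) + c) / (mean_out(exp(value)-1) + c))
    with pseudocount c (default 1), matching the de-logged mean-ratio
    convention of the standard single-cell toolkits.

    Returns a DataFrame with columns gene, cluster, avg_log2FC, pct_in,
    pct_out, p_value, p_adj.
    """
    clusters = pd.Series(clusters)
    labels = [c for c in sorted(clusters.dropna().unique(), key=str)]
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters for marker detection")

    dense = nm.dense()  # genes x cells
    delog = np.expm1(dense)
    detected = dense > 0
    genes = np.asarray(nm.gene_ids, dtype=object)

    rows = []
    for cl in labels:
        mask = (clusters == cl).to_numpy()
        n_in = int(mask.sum())
        n_out = int((~mask).sum())
        if n_in < 2:
            logger.warning("cluster %s has <2 cells; skipped", cl)
            continue
        pct_in = detected[:, mask].mean(axis=1)
        pct_out = detected[:, ~mask].mean(axis=1)
        test_mask = np.maximum(pct_in, pct_out) >= min_pct
        if not test_mask.any():
            continue
        x_in = dense[test_mask][:, mask].T  # cells x genes
        x_out = dense[test_mask][:, ~mask].T
        pvals = _rank_sum_matrix(x_in, x_out)
        mean_in = delog[test_mask][:, mask].mean(axis=1)
        mean_out = delog[test_mask][:, ~mask].mean(axis=1)
        lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        sub = pd.DataFrame(
            {
                "gene": genes[test_mask],
                "cluster": cl,
                "avg_log2FC": lfc,
                "pct_in": pct_in[test_mask],
                "pct_out": pct_out[test_mask],
                "p_value": pvals,
            }
        )
        rows.append(sub)

    if not rows:
        return pd.DataFrame(
            columns=["gene", "cluster", "avg_log2FC", "pct_in", "pct_out", "p_value", "p_adj"]
        )
    table = pd.concat(rows, ignore_index=True)
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    if only_pos:
        table = table[table["avg_log2FC"] > 0]
    table = table[table["p_adj"] < alpha].reset_index(drop=True)
    return table


def select_highly_enriched(
    markers: pd.DataFrame, min_max_lfc: float = 1.0, max_clusters: int = 5,
    name: str = "highly_enriched",
) -> GeneSet:
    """Neuron-specific gene selection from a marker table.

    A gene is kept iff its maximum avg_log2FC over all its marker records is
    >= ``min_max_lfc`` (inclusive) and it appears as a marker in at most
    ``max_clusters`` distinct clusters (inclusive).
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    by_gene = markers.groupby("gene").agg(
        max_lfc=("avg_log2FC", "max"), n_clusters=("cluster", "nunique")
    )
    keep = by_gene[(by_gene["max_lfc"] >= min_max_lfc) & (by_gene["n_clusters"] <= max_clusters)]
    if keep.empty:
        raise ValueError("no genes pass the highly-enriched thresholds")
    return GeneSet(name, frozenset(keep.index), provenance="marker")


def markers_by_cluster(markers: pd.DataFrame) -> dict:
    """Marker table -> {cluster: set of marker genes}."""
    return {cl: set(grp["gene"]) for cl, grp in markers.groupby("cluster")}
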