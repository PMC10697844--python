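"""Homology-aware cluster correspondence between two species' atlases.

Cluster pairs are compared on the genes covered by 1:1 best-reciprocal-hit
(BRH) orthology that are markers in both species: Spearman correlation of
mean expression profiles, and a Jaccard similarity of orthology-mapped
per-cluster marker sets.  Rows/columns of the resulting matrix can be
ordered by classical Ward agglomeration on unsquared Euclidean distances
(the 'ward.D' variant; implemented here because the common library routine
is the squared-distance 'ward.D2' variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .core_model import ClusterSummary, OrthologyMap

logger = logging.getLogger("scevolink")


@dataclass
class CorrespondenceMatrix:
    """Clusters_A x clusters_B similarity values."""

    values: pd.DataFrame
    metric: str  # 'spearman_corr' or 'marker_similarity'
    common_gene_count: int = 0


def intersect_brh_markers(
    markers_a, markers_b, om: OrthologyMap, species_a: str = "A", species_b: str = "B"
) -> list:
    """1:1 BRH pairs whose genes are markers in both species.

    ``markers_a`` / ``markers_b`` are iterables of marker gene ids (e.g. the
    union over clusters of a marker table).  Raises when the intersection is
    empty, since the downstream correlation would be meaningless.
    """
    set_a, set_b = set(markers_a), set(markers_b)
    if not set_a or not set_b:
        raise ValueError("marker sets must be non-empty")
    mapping = om.mapping(species_a, species_b)
    pairs = [(a, b) for a, b in mapping.items() if a in set_a and b in set_b]
    if not pairs:
        raise ValueError(
            "no BRH pair is a marker in both species; consider relaxing marker thresholds"
        )
    return sorted(pairs)


def _rank_z(x: np.ndarray) -> tuple:
    """Row-wise rank-standardized matrix and a per-row definedness mask."""
    ranks = st.rankdata(x, axis=1)
    mu = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    defined = sd.ravel() > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (ranks - mu) / sd, 0.0)
    return z, defined


def cluster_correlation(
    cs_a: ClusterSummary, cs_b: ClusterSummary, common_pairs
) -> CorrespondenceMatrix:
    """Spearman rho of mean expression profiles on the common BRH genes.

    Profiles are de-logged cluster means (avg_exp) restricted to the common
    gene pairs, with the species-A gene order defining the pairing.  A
    cluster whose restricted profile has zero variance yields a missing
    row/column (warned).
    """
    common_pairs = list(common_pairs)
    if len(common_pairs) < 3:
        raise ValueError("need >= 3 common gene pairs for rank correlation")
    genes_a = [a for a, _ in common_pairs]
    genes_b = [b for _, b in common_pairs]
    xa = cs_a.avg_exp[genes_a].to_numpy(dtype=float)
    xb = cs_b.avg_exp[genes_b].to_numpy(dtype=float)
    za, def_a = _rank_z(xa)
    zb, def_b = _rank_z(xb)
    if not def_a.all() or not def_b.all():
        logger.warning(
            "%d cluster profile(s) with zero variance set to missing",
            int((~def_a).sum() + (~def_b).sum()),
        )
    rho = za @ zb.T / len(common_pairs)
    rho[~def_a, :] = np.nan
    rho[:, ~def_b] = np.nan
    values = pd.DataFrame(rho, index=cs_a.avg_exp.index, columns=cs_b.avg_exp.index)
    return CorrespondenceMatrix(values, "spearman_corr", len(common_pairs))


def marker_similarity(
    markers_by_cluster_a: dict,
    markers_by_cluster_b: dict,
    om: OrthologyMap,
    species_a: str = "A",
    species_b: str = "B",
) -> CorrespondenceMatrix:
    """Jaccard index of orthology-mapped per-cluster marker sets.

    Both sides are restricted to the BRH-covered gene universe before the
    Jaccard index, which keeps the measure symmetric under swapping species
    and inverting the map.  Cluster pairs where both restricted sets are
    empty score 0.
    """
    mapping = om.mapping(species_a, species_b)
    mapped_b_universe = set(mapping.values())
    rows = sorted(markers_by_cluster_a, key=str)
    cols = sorted(markers_by_cluster_b, key=str)
    out = np.zeros((len(rows), len(cols)))
    for i, ca in enumerate(rows):
        ma = {mapping[g] for g in markers_by_cluster_a[ca] if g in mapping}
        for j, cb in enumerate(cols):
            mb = set(markers_by_cluster_b[cb]) & mapped_b_universe
            union = ma | mb
            if not union:
                logger.warning("clusters %s/%s share no BRH-covered markers", ca, cb)
                out[i, j] = 0.0
            else:
                out[i, j] = len(ma & mb) / len(union)
    return CorrespondenceMatrix(pd.DataFrame(out, index=rows, columns=cols),
                                "marker_similarity")


def mutual_best_hits(values: pd.DataFrame) -> list:
    """Cluster pairs that are each other's row/column argmax."""
    arr = values.to_numpy(dtype=float)
    hits = []
    for i in range(arr.shape[0]):
        row = arr[i]
        if np.isnan(row).all():
            continue
        j = int(np.nanargmax(row))
        col = arr[:, j]
        if not np.isnan(col).all() and int(np.nanargmax(col)) == i:
            hits.append((values.index[i], values.columns[j]))
    return hits


def correlation_shuffle_null(
    cs_a: ClusterSummary, cs_b: ClusterSummary, common_pairs,
    n_perm: int = 200, seed: int = 0,
) -> np.ndarray:
    """Gene-label shuffling null for the correspondence matrix.

    Each permutation shuffles the B-side of the BRH pairing (destroying any
    true orthologous signal) and records the maximum Spearman value over the
    whole matrix; the 95th percentile of these maxima is the usual
    significance reference for mutual best hits.
    """
    rng = np.random.default_rng(seed)
    common_pairs = list(common_pairs)
    genes_b = [b for _, b in common_pairs]
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        perm_b = list(rng.permutation(genes_b))
        shuffled = [(a, pb) for (a, _), pb in zip(common_pairs, perm_b)]
        cm = cluster_correlation(cs_a, cs_b, shuffled)
        maxima[i] = np.nanmax(cm.values.to_numpy())
    return maxima


# ---------------------------------------------------------------------------
# Classical Ward (ward.D) agglomeration
# ---------------------------------------------------------------------------


def ward_d_linkage(x: np.ndarray) -> np.ndarray:
    """Agglomerative linkage with the classical Ward update on unsquared
    Euclidean distances (the 'ward.D' variant).

    Returns a linkage matrix in the usual (id1, id2, height, size) format
    with original observations 0..n-1 and merged clusters n, n+1, ...
    Merge ties are broken by the smaller cluster-id pair, so the result is
    deterministic.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 observations")
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(x[i] - x[j]))
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (s, t), d_st = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        z[step] = (s, t, d_st, size[s] + size[t])
        new = next_id
        next_id += 1
        active -= {s, t}
        for v in sorted(active):
            d_vs = dist.pop((min(v, s), max(v, s)))
            d_vt = dist.pop((min(v, t), max(v, t)))
            total = size[v] + size[s] + size[t]
            dist[(v, new)] = (
                (size[v] + size[s]) * d_vs
                + (size[v] + size[t]) * d_vt
                - size[v] * d_st
            ) / total
        del dist[(s, t)]
        size[new] = size[s] + size[t]
        active.add(new)
    return z


def linkage_leaf_order(z: np.ndarray) -> list:
    """Left-to-right leaf order of a linkage matrix."""
    n = z.shape[0] + 1

    def leaves(node: int) -> list:
        if node < n:
            return [node]
        row = z[node - n]
        return leaves(int(row[0])) + leaves(int(row[1]))

    return leaves(2 * n - 2) if n > 1 else [0]


@dataclass
class HierarchicalOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def hierarchical_order(cm: CorrespondenceMatrix) -> HierarchicalOrder:
    """Ward.D ordering of rows then columns of a correspondence matrix.

    Rows/columns containing missing values are dropped with a warning
    before clustering; with fewer than 2 rows (or columns) the identity
    ordering is returned for that axis.
    """
    values = cm.values
    row_ok = ~values.isna().any(axis=1)
    col_ok = ~values.isna().any(axis=0)
    if not row_ok.all() or not col_ok.all():
        logger.warning(
            "dropping %d row(s) / %d column(s) with missing values before clustering",
            int((~row_ok).sum()), int((~col_ok).sum()),
        )
    sub = values.loc[row_ok, col_ok]

    def order(frame: pd.DataFrame):
        if frame.shape[0] < 2:
            return list(frame.index), np.zeros((0, 4))
        zz = ward_d_linkage(frame.to_numpy())
        return [frame.index[i] for i in linkage_leaf_order(zz)], zz

    rows, zr = order(sub)
    cols, zc = order(sub.T)
    return HierarchicalOrder(rows, cols, zr, zc)
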