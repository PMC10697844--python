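"""Seeded generators for every input the pipeline consumes.

The generators emulate the shapes of a spider-brain single-cell study at
desk scale: a handful of samples (2 male / 3 female) of a few hundred cells
each, partitioned into tens of clusters with planted marker genes; an
8-tissue x 3-replicate bulk panel with planted tissue-specific genes; gene
trees carrying exactly one duplication grafted onto a named ancestral
branch; and a two-species pair of atlases sharing a subset of homologous
clusters through a 1:1 best-reciprocal-hit gene map.

Counts follow a negative-binomial (gamma-Poisson) model with a shared
dispersion — the standard UMI noise assumption, stated here as the module's
own modelling choice.  All generators are deterministic given the config
seed, and every planted signal is returned as an explicit truth table so
downstream recovery can be scored.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_model import CellMatrix, OrthologyMap
from .dup_timing import GeneTree, SpeciesTree, default_species_tree


class ConfigError(ValueError):
    """Simulation configuration is infeasible or inconsistent."""


def _default_dup_plan() -> dict:
    # one duplication per tree; divergence_level rises with duplication age,
    # mirroring the expectation that older paralogs have drifted further apart
    return {
        "H1": (40, 0.05),
        "H2": (40, 0.25),
        "H3": (40, 0.45),
        "H4": (40, 0.65),
        "H5": (40, 0.85),
    }


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Single-cell defaults give the desk-scale fixture: 5 samples (2 male /
    3 female) x 600 cells, 12 clusters, 2,000 genes, 10 markers per cluster
    at 8-fold enrichment over a baseline mean of 0.5 UMI/gene — large enough
    for rank-sum power, small enough to generate in seconds.
    """

    seed: int = 0
    # single-cell atlas
    n_samples: int = 5
    sex_split: tuple = (2, 3)  # (male, female) samples
    n_cells_per_sample: int = 600
    n_clusters: int = 12
    n_genes: int = 2000
    n_markers_per_cluster: int = 10
    marker_fold_change: float = 8.0
    nb_dispersion: float = 0.3
    baseline_mean: float = 0.5
    # bulk tissue panel
    n_tissues: int = 8
    n_reps: int = 3
    tissue_specific_fraction: float = 0.1
    bulk_base_level: float = 50.0
    bulk_specific_level: float = 500.0
    bulk_leakage: float = 0.0
    bulk_dispersion: float = 0.1  # <= 0 -> noise-free deterministic counts
    mean_read_length: float = 150.0
    # gene trees
    dup_plan: dict = field(default_factory=_default_dup_plan)
    loss_rate: float = 0.0
    # two-species comparison
    n_clusters_xs: int = 8
    n_genes_xs: int = 1000
    n_cells_per_cluster_xs: int = 120
    n_markers_per_cluster_xs: int = 12
    xs_signature_sd: float = 0.5  # log-sd of the per-cluster expression signature
    homologous_cluster_map: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.homologous_cluster_map is None:
            self.homologous_cluster_map = {f"a{i}": f"b{i}" for i in range(5)}
        self.validate()

    def validate(self) -> None:
        positive = [
            "n_samples", "n_cells_per_sample", "n_clusters", "n_genes",
            "n_tissues", "n_reps", "n_clusters_xs", "n_genes_xs",
            "n_cells_per_cluster_xs",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if sum(self.sex_split) != self.n_samples:
            raise ConfigError("sex_split must sum to n_samples")
        if self.n_markers_per_cluster * self.n_clusters > self.n_genes:
            raise ConfigError("marker plan infeasible: n_markers x n_clusters > n_genes")
        if self.n_markers_per_cluster > 0 and self.marker_fold_change < 1:
            raise ConfigError("marker fold_change must be >= 1")
        if self.n_tissues < 2:
            raise ConfigError("need >= 2 tissues")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        for scen, (n, d) in self.dup_plan.items():
            if n < 0 or not (0.0 <= d <= 1.0):
                raise ConfigError(f"dup_plan entry {scen} invalid: {(n, d)}")
        if not (0.0 <= self.loss_rate < 1.0):
            raise ConfigError("loss_rate must be in [0, 1)")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Single-cell atlas
# ---------------------------------------------------------------------------


def simulate_cell_matrix(cfg: SimConfig, rng=None):
    """Simulate a CellMatrix with planted cluster markers.

    Marker gene g of cluster k has NB mean baseline * fold_change in k's
    cells and baseline elsewhere; marker blocks are disjoint across
    clusters.  Returns (CellMatrix, truth) where truth has columns gene,
    cluster, fold_change.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    n_cells = cfg.n_samples * cfg.n_cells_per_sample
    genes = np.array([f"g{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    cells = np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)

    sample = np.repeat([f"sample_{i + 1}" for i in range(cfg.n_samples)],
                       cfg.n_cells_per_sample)
    sex_of_sample = ["male"] * cfg.sex_split[0] + ["female"] * cfg.sex_split[1]
    sex = np.repeat(sex_of_sample, cfg.n_cells_per_sample)
    base_labels = np.array(
        [f"c{i % cfg.n_clusters}" for i in range(n_cells)], dtype=object
    )
    cluster = rng.permutation(base_labels)

    mu = np.full((cfg.n_genes, n_cells), cfg.baseline_mean)
    truth_rows = []
    for k in range(cfg.n_clusters):
        start = k * cfg.n_markers_per_cluster
        idx = np.arange(start, start + cfg.n_markers_per_cluster)
        in_k = cluster == f"c{k}"
        mu[np.ix_(idx, in_k)] = cfg.baseline_mean * cfg.marker_fold_change
        if cfg.marker_fold_change > 1:
            for g in idx:
                truth_rows.append((genes[g], f"c{k}", cfg.marker_fold_change))

    counts = _nb_counts(rng, mu, cfg.nb_dispersion)
    meta = pd.DataFrame({"sample": sample, "sex": sex, "cluster": cluster}, index=cells)
    m = CellMatrix(sp.csr_matrix(counts), genes, cells, meta)
    truth = pd.DataFrame(truth_rows, columns=["gene", "cluster", "fold_change"])
    return m, truth


# ---------------------------------------------------------------------------
# Bulk tissue panel
# ---------------------------------------------------------------------------


@dataclass
class TissueCounts:
    """Raw bulk counts (genes x samples) plus what TPM needs."""

    counts: pd.DataFrame
    cds_length: pd.Series
    mean_read_length: float
    sample_tissue: dict


def simulate_tissue_matrix(cfg: SimConfig, rng=None):
    """Bulk counts with planted tissue-specific genes.

    Each specific gene is expressed at ``bulk_specific_level`` in exactly
    one tissue and at ``bulk_leakage`` x that level elsewhere; non-specific
    genes have a flat profile at ``bulk_base_level``.  Specific genes are
    planted in equal numbers per tissue and share a common CDS length so
    that, in the noise-free limit, per-sample totals match exactly and tau
    is recovered in closed form.
    Returns (TissueCounts, truth) with truth a per-gene Series holding the
    planted tissue (NaN for uniform genes).
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 1)
    tissues = ["brain"] + [f"tissue_{i}" for i in range(1, cfg.n_tissues)]
    n_spec = int(cfg.n_genes * cfg.tissue_specific_fraction)
    n_spec -= n_spec % cfg.n_tissues  # equal planting per tissue
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    level = np.full((cfg.n_genes, cfg.n_tissues), cfg.bulk_base_level)
    truth = pd.Series([None] * cfg.n_genes, index=genes, dtype=object, name="tissue")
    for i in range(n_spec):
        t = i % cfg.n_tissues
        level[i, :] = cfg.bulk_leakage * cfg.bulk_specific_level
        level[i, t] = cfg.bulk_specific_level
        truth.iloc[i] = tissues[t]

    cds = pd.Series(rng.integers(300, 3001, size=cfg.n_genes), index=genes, name="cds_length")
    cds.iloc[:n_spec] = 1500  # common length keeps noise-free totals equal
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(cfg.n_reps)]
    sample_tissue = {s: s.rsplit("_", 1)[0] for s in samples}
    mean_counts = (
        level[:, np.repeat(np.arange(cfg.n_tissues), cfg.n_reps)]
        * cds.to_numpy()[:, None]
        / cfg.mean_read_length
    )
    if cfg.bulk_dispersion > 0:
        counts = _nb_counts(rng, mean_counts, cfg.bulk_dispersion)
    else:
        counts = np.round(mean_counts).astype(int)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return TissueCounts(df, cds, cfg.mean_read_length, sample_tissue), truth


# ---------------------------------------------------------------------------
# Gene trees with planted duplications
# ---------------------------------------------------------------------------


def _tree_struct(node):
    if node.is_leaf():
        return node.taxon.label
    return [_tree_struct(c) for c in node.child_nodes()]


def _leafset(struct) -> frozenset:
    if isinstance(struct, str):
        return frozenset({struct})
    out = frozenset()
    for child in struct:
        out |= _leafset(child)
    return out


def _graft_duplication(struct, clade: frozenset):
    """Replace the subtree whose leaf set equals ``clade`` with two copies."""
    if _leafset(struct) == clade:
        return [copy.deepcopy(struct), copy.deepcopy(struct)], True
    if isinstance(struct, str):
        return struct, False
    new_children = []
    done = False
    for child in struct:
        if not done:
            child, done_here = _graft_duplication(child, clade)
            done = done or done_here
        new_children.append(child)
    return new_children, done


def _relabel(struct, counter: dict, tree_tag: str, delimiter: str):
    if isinstance(struct, str):
        sp_name = struct
        counter[sp_name] = counter.get(sp_name, 0) + 1
        return f"{sp_name}{delimiter}{sp_name}_{tree_tag}g{counter[sp_name]}"
    return [_relabel(c, counter, tree_tag, delimiter) for c in struct]


def _apply_losses(struct, rng, loss_rate: float):
    """Drop leaves independently; returns None if everything is lost."""
    if isinstance(struct, str):
        return None if rng.random() < loss_rate else struct
    kept = [c for c in (_apply_losses(ch, rng, loss_rate) for ch in struct) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return kept


def _to_newick(struct) -> str:
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(_to_newick(c) for c in struct) + ")"


def simulate_gene_trees(
    species_tree: SpeciesTree = None,
    dup_plan: dict = None,
    seed: int = 0,
    loss_rate: float = 0.0,
    delimiter: str = "|",
):
    """Gene trees each carrying exactly one duplication at a named clade.

    For each scenario in ``dup_plan`` (clade name -> (n_trees, level)), the
    gene tree is the species tree with the scenario clade's subtree
    duplicated in place; both daughter copies then follow the species tree.
    Leaf labels are '<SPECIES>|<gene>'.  With ``loss_rate`` > 0 each leaf is
    independently dropped (trees degenerating below 2 leaves are skipped).
    Returns (list of GeneTree, truth list of scenario labels, pairs between
    copies are recoverable downstream).
    """
    st = species_tree or default_species_tree()
    dup_plan = dup_plan if dup_plan is not None else _default_dup_plan()
    rng = np.random.default_rng(seed)
    base = _tree_struct(st.tree.seed_node)
    tree_species = st.species()

    trees, labels = [], []
    idx = 0
    for scenario, spec_entry in dup_plan.items():
        n_trees = spec_entry[0] if isinstance(spec_entry, (tuple, list)) else int(spec_entry)
        clade = st.named_clades.get(scenario)
        if clade is None:
            raise ConfigError(f"scenario {scenario} not among named clades")
        clade = clade & tree_species
        if not clade:
            raise ConfigError(f"scenario {scenario} has no species in the species tree")
        for _ in range(n_trees):
            struct, done = _graft_duplication(copy.deepcopy(base), clade)
            if not done:
                raise ConfigError(
                    f"clade {scenario} ({sorted(clade)}) is not a subtree of the species tree"
                )
            if loss_rate > 0:
                struct = _apply_losses(struct, rng, loss_rate)
                if struct is None or isinstance(struct, str):
                    continue
            labeled = _relabel(struct, {}, f"t{idx}", delimiter)
            trees.append(GeneTree.from_newick(_to_newick(labeled) + ";", delimiter))
            labels.append(scenario)
            idx += 1
    return trees, labels


# ---------------------------------------------------------------------------
# Paralog-pair expression with planted divergence
# ---------------------------------------------------------------------------


def simulate_paralog_expression(cfg: SimConfig, n_cells: int = 600, n_clusters: int = 6,
                                fold_change: float = 10.0, baseline: float = 0.2,
                                rng=None):
    """Expression for paralog pairs whose divergence is planted per scenario.

    For each scenario in ``cfg.dup_plan`` with divergence level d in [0, 1],
    gene A follows the NB model with a cluster-specific mean (one "home"
    cluster at ``fold_change`` x baseline); gene B shares A's home cluster
    and per-cell gamma noise with weight (1 - d) and uses an independent
    home cluster / noise with weight d.  Higher d therefore yields lower
    expression correlation and less same-cell-type co-enrichment.

    The baseline (0.2 UMI/gene) sits below the detection fraction the
    enrichment rule thresholds at (pct > 0.25), while home-cluster means
    (2 UMI) sit well above it, so enriched-cluster sets track the planted
    home clusters.

    Returns (CellMatrix, pairs) where pairs has columns gene_a, gene_b,
    scenario, divergence, home_a, home_b.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 2)
    cluster = rng.permutation(
        np.array([f"c{i % n_clusters}" for i in range(n_cells)], dtype=object)
    )
    cluster_idx = np.array([int(c[1:]) for c in cluster])
    disp = cfg.nb_dispersion
    base = baseline

    gene_rows, gene_ids, pair_rows = [], [], []
    gi = 0
    for scenario, (n_pairs, d) in cfg.dup_plan.items():
        for p in range(n_pairs):
            home_a = p % n_clusters
            if rng.random() < d:
                others = [k for k in range(n_clusters) if k != home_a]
                home_b = int(rng.choice(others))
            else:
                home_b = home_a
            mu_a = np.where(cluster_idx == home_a, base * fold_change, base)
            mu_b = np.where(cluster_idx == home_b, base * fold_change, base)
            z_shared = rng.gamma(1.0 / disp, disp, size=n_cells)
            z_indep = rng.gamma(1.0 / disp, disp, size=n_cells)
            z_b = (1.0 - d) * z_shared + d * z_indep
            ga, gb = f"p{gi:04d}a", f"p{gi:04d}b"
            gene_rows.append(rng.poisson(mu_a * z_shared))
            gene_rows.append(rng.poisson(mu_b * z_b))
            gene_ids += [ga, gb]
            pair_rows.append((ga, gb, scenario, d, f"c{home_a}", f"c{home_b}"))
            gi += 1
    # background genes so random pairs are drawn from a realistic universe
    n_bg = max(200, 2 * gi)
    for b in range(n_bg):
        home = b % n_clusters
        mu = np.where(cluster_idx == home, base * fold_change, base)
        gene_rows.append(_nb_counts(rng, mu, disp))
        gene_ids.append(f"bg{b:04d}")

    counts = np.vstack(gene_rows)
    cells = np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {"sample": "sample_1", "sex": "unknown", "cluster": cluster}, index=cells
    )
    m = CellMatrix(sp.csr_matrix(counts), np.array(gene_ids, dtype=object), cells, meta)
    pairs = pd.DataFrame(
        pair_rows,
        columns=["gene_a", "gene_b", "scenario", "divergence", "home_a", "home_b"],
    )
    return m, pairs


# ---------------------------------------------------------------------------
# Two-species atlases with shared homologous clusters
# ---------------------------------------------------------------------------


def simulate_two_species(cfg: SimConfig, rng=None):
    """Two single-cell atlases sharing homologous clusters through a BRH map.

    Gene i of species A is the best reciprocal hit of gene i of species B.
    Each cluster has a lognormal per-gene expression signature; homologous
    cluster pairs (cfg.homologous_cluster_map) share their signature through
    the BRH index alignment, while every other cluster draws its own —
    homologous clusters therefore correlate across the whole BRH gene set,
    not just at markers.  On top of the signature, each homologous pair
    shares one block of marker gene indices and non-homologous clusters get
    disjoint, species-private marker blocks.

    Returns (CellMatrix A, CellMatrix B, OrthologyMap, truth) with truth a
    list of (cluster_a, cluster_b) planted homolog pairs.
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed + 3)
    k, nm = cfg.n_clusters_xs, cfg.n_markers_per_cluster_xs
    hom = dict(cfg.homologous_cluster_map)
    clusters_a = [f"a{i}" for i in range(k)]
    clusters_b = [f"b{i}" for i in range(k)]
    bad = (set(hom) - set(clusters_a)) | (set(hom.values()) - set(clusters_b))
    if bad:
        raise ConfigError(f"homologous_cluster_map references missing clusters: {sorted(bad)}")
    # marker blocks: homologous pairs consume shared blocks first, then each
    # species' non-homologous clusters get private blocks
    needed = (len(hom) + 2 * (k - len(hom))) * nm
    if needed > cfg.n_genes_xs:
        raise ConfigError("n_genes_xs too small for the marker plan")

    blocks = iter(range(0, cfg.n_genes_xs, nm))
    marker_idx_a, marker_idx_b = {}, {}
    for ca, cb in hom.items():
        start = next(blocks)
        idx = np.arange(start, start + nm)
        marker_idx_a[ca] = idx
        marker_idx_b[cb] = idx
    for ca in clusters_a:
        if ca not in marker_idx_a:
            start = next(blocks)
            marker_idx_a[ca] = np.arange(start, start + nm)
    for cb in clusters_b:
        if cb not in marker_idx_b:
            start = next(blocks)
            marker_idx_b[cb] = np.arange(start, start + nm)

    # per-cluster lognormal signatures, shared across homologous pairs
    sig_a, sig_b = {}, {}
    for ca, cb in sorted(hom.items()):
        s = rng.lognormal(0.0, cfg.xs_signature_sd, cfg.n_genes_xs)
        sig_a[ca], sig_b[cb] = s, s
    for ca in clusters_a:
        if ca not in sig_a:
            sig_a[ca] = rng.lognormal(0.0, cfg.xs_signature_sd, cfg.n_genes_xs)
    for cb in clusters_b:
        if cb not in sig_b:
            sig_b[cb] = rng.lognormal(0.0, cfg.xs_signature_sd, cfg.n_genes_xs)

    def _species_matrix(tag: str, cluster_labels, marker_idx, sig) -> CellMatrix:
        n_cells = k * cfg.n_cells_per_cluster_xs
        cluster = rng.permutation(
            np.array([cluster_labels[i % k] for i in range(n_cells)], dtype=object)
        )
        mu = np.empty((cfg.n_genes_xs, n_cells))
        for cl in cluster_labels:
            in_cl = cluster == cl
            mu[:, in_cl] = cfg.baseline_mean * sig[cl][:, None]
            mu[np.ix_(marker_idx[cl], in_cl)] *= cfg.marker_fold_change
        counts = _nb_counts(rng, mu, cfg.nb_dispersion)
        genes = np.array([f"g{tag}_{i:05d}" for i in range(cfg.n_genes_xs)], dtype=object)
        cells = np.array([f"{tag}_cell_{i:05d}" for i in range(n_cells)], dtype=object)
        meta = pd.DataFrame(
            {"sample": f"{tag}_1", "sex": "unknown", "cluster": cluster}, index=cells
        )
        return CellMatrix(sp.csr_matrix(counts), genes, cells, meta)

    m_a = _species_matrix("A", clusters_a, marker_idx_a, sig_a)
    m_b = _species_matrix("B", clusters_b, marker_idx_b, sig_b)
    brh = pd.DataFrame(
        {
            "species_a": "A",
            "gene_a": m_a.gene_ids,
            "species_b": "B",
            "gene_b": m_b.gene_ids,
        }
    )
    om = OrthologyMap(brh)
    truth = sorted(hom.items())
    return m_a, m_b, om, truth
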