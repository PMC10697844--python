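"""Core containers and I/O for the expression pipeline.

The central object is :class:`CellMatrix`, a genes x cells UMI count matrix
with per-cell annotations (sample, sex, cluster) and an optional set of
mitochondrial genes.  Everything downstream — QC, log-normalization,
per-cluster summaries, marker detection, gene-set mapping — operates on it
or on objects derived from it.

Counts are stored as a ``scipy.sparse.csr_matrix`` in genes x cells
orientation (the orientation used for gene-wise statistics throughout the
package); per-cell annotations live in a :class:`pandas.DataFrame` indexed
by barcode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("scevolink")

SEXES = ("male", "female", "unknown")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


class EmptyResultError(RuntimeError):
    """A filtering step removed every cell or gene."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Genes x cells UMI counts with per-cell annotations.

    Attributes
    ----------
    counts:
        Sparse nonnegative integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids:
        Unique string identifiers for rows / columns.
    cell_meta:
        DataFrame indexed by ``cell_ids`` with columns ``sample``, ``sex``
        (one of ``male``/``female``/``unknown``) and ``cluster`` (string or
        missing).
    mito_genes:
        Subset of ``gene_ids`` counted as mitochondrial for QC.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    mito_genes: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.mito_genes = frozenset(self.mito_genes)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"id lengths ({len(self.gene_ids)}, {len(self.cell_ids)}) do not "
                f"match matrix shape {self.counts.shape}"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValidationError("counts must be integers")
        missing = [c for c in ("sample", "sex", "cluster") if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns: {missing}")
        if not np.array_equal(self.cell_meta.index.to_numpy(dtype=object), self.cell_ids):
            raise ValidationError("cell_meta index does not match cell_ids")
        bad_sex = set(self.cell_meta["sex"].dropna()) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        clusters = self.cell_meta["cluster"].dropna()
        if (clusters.astype(str).str.len() == 0).any():
            raise ValidationError("empty cluster labels present")
        extra = self.mito_genes - set(self.gene_ids)
        if extra:
            raise ValidationError(f"mito_genes not in gene_ids: {sorted(extra)[:5]}")

    # -- derived per-cell statistics -------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def numi(self) -> np.ndarray:
        """Total UMI count per cell (nUMI)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def ngene(self) -> np.ndarray:
        """Number of detected genes per cell (nGene)."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's UMIs from mitochondrial genes.

        With no mitochondrial genes configured the fraction is 0 everywhere,
        which makes the mito QC filter a no-op (logged as a warning).
        """
        total = self.numi().astype(float)
        total[total == 0] = np.nan
        if not self.mito_genes:
            logger.warning("no mitochondrial genes configured; mito fraction is 0 for all cells")
            return np.zeros(self.n_cells)
        mask = np.isin(self.gene_ids, list(self.mito_genes))
        mito = np.asarray(self.counts[mask].sum(axis=0)).ravel()
        out = mito / total
        return np.nan_to_num(out)

    # -- subsetting -------------------------------------------------------

    def subset(self, gene_mask=None, cell_mask=None) -> "CellMatrix":
        gm = np.arange(self.n_genes) if gene_mask is None else np.where(np.asarray(gene_mask))[0]
        cm = np.arange(self.n_cells) if cell_mask is None else np.where(np.asarray(cell_mask))[0]
        counts = self.counts[gm][:, cm]
        gene_ids = self.gene_ids[gm]
        cell_ids = self.cell_ids[cm]
        meta = self.cell_meta.iloc[cm].copy()
        mito = frozenset(g for g in self.mito_genes if g in set(gene_ids))
        return CellMatrix(counts, gene_ids, cell_ids, meta, mito)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: value = ln(1 + count / nUMI * scale_factor)."""

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float = 1e4
    base: str = "natural"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")

    def dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class ClusterSummary:
    """Per-cluster expression summary.

    ``avg_exp`` holds the de-logged mean normalized expression
    (mean of ``exp(value) - 1`` over the cluster's cells) and ``pct_exp``
    the fraction of the cluster's cells with a nonzero raw count — the two
    quantities thresholded by the downstream gene-set enrichment rule.
    """

    avg_exp: pd.DataFrame  # clusters x genes
    pct_exp: pd.DataFrame  # clusters x genes, in [0, 1]
    n_cells: pd.Series  # per-cluster cell counts

    def __post_init__(self) -> None:
        if not self.avg_exp.index.equals(self.pct_exp.index):
            raise ValidationError("avg_exp / pct_exp cluster index mismatch")
        if not self.avg_exp.columns.equals(self.pct_exp.columns):
            raise ValidationError("avg_exp / pct_exp gene columns mismatch")
        if (self.pct_exp.to_numpy() < -1e-12).any() or (self.pct_exp.to_numpy() > 1 + 1e-12).any():
            raise ValidationError("pct_exp outside [0, 1]")
        if (self.avg_exp.to_numpy() < -1e-12).any():
            raise ValidationError("negative avg_exp")

    @property
    def clusters(self) -> list:
        return list(self.avg_exp.index)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids with a free-text provenance tag."""

    name: str
    genes: frozenset
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OrthologyMap:
    """Cross-species 1:1 best-reciprocal-hit pairs plus orthogroup membership."""

    brh_pairs: pd.DataFrame  # columns: species_a, gene_a, species_b, gene_b
    orthogroups: dict = field(default_factory=dict)  # og_id -> set of (species, gene)

    def __post_init__(self) -> None:
        cols = ["species_a", "gene_a", "species_b", "gene_b"]
        if list(self.brh_pairs.columns) != cols:
            self.brh_pairs = self.brh_pairs[cols]
        for (sa, sb), grp in self.brh_pairs.groupby(["species_a", "species_b"]):
            if grp["gene_a"].duplicated().any() or grp["gene_b"].duplicated().any():
                raise ValidationError(f"BRH pairs not 1:1 within species pair ({sa}, {sb})")
        seen: dict = {}
        for og, members in self.orthogroups.items():
            for member in members:
                if member in seen:
                    raise ValidationError(
                        f"gene {member} in orthogroups {seen[member]} and {og}"
                    )
                seen[member] = og

    def mapping(self, species_from: str, species_to: str) -> dict:
        """Gene-id mapping between two species, inverted on demand."""
        fwd = self.brh_pairs[
            (self.brh_pairs["species_a"] == species_from)
            & (self.brh_pairs["species_b"] == species_to)
        ]
        out = dict(zip(fwd["gene_a"], fwd["gene_b"]))
        rev = self.brh_pairs[
            (self.brh_pairs["species_a"] == species_to)
            & (self.brh_pairs["species_b"] == species_from)
        ]
        out.update(dict(zip(rev["gene_b"], rev["gene_a"])))
        return out

    def orthogroup_of(self, species: str, gene: str):
        for og, members in self.orthogroups.items():
            if (species, gene) in members:
                return og
        return None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_cell_matrix(
    mtx_path,
    features_path,
    barcodes_path,
    cell_meta_path=None,
    mito_prefix: str = "MT-",
    mito_list=None,
) -> CellMatrix:
    """Read a MatrixMarket triplet + features/barcodes TSV into a CellMatrix.

    ``cell_meta_path`` is a TSV with header ``barcode sample sex cluster``;
    a missing sex column defaults every cell to ``unknown`` with a logged
    warning, and cells present in only one of matrix/meta are reported.
    Mitochondrial genes are those whose id starts with ``mito_prefix``, or
    an explicit iterable/one-per-line file via ``mito_list``.
    """
    try:
        counts = mmread(str(mtx_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    counts = sp.csr_matrix(counts)

    gene_ids = pd.read_csv(features_path, sep="\t", header=None, dtype=str)[0].to_numpy(object)
    cell_ids = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].to_numpy(object)
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix shape {counts.shape} inconsistent with {len(gene_ids)} features "
            f"and {len(cell_ids)} barcodes"
        )
    if len(set(cell_ids)) != len(cell_ids):
        raise ValidationError("duplicate barcodes in barcodes file")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate gene ids in features file")

    if cell_meta_path is not None:
        meta = pd.read_csv(cell_meta_path, sep="\t", dtype=str)
        if "barcode" not in meta.columns:
            raise FormatError("cell metadata must have a 'barcode' column")
        if meta["barcode"].duplicated().any():
            raise ValidationError("duplicate barcodes in cell metadata")
        meta = meta.set_index("barcode")
        if "sex" not in meta.columns:
            logger.warning("metadata has no 'sex' column; setting sex=unknown for all cells")
            meta["sex"] = "unknown"
        if "sample" not in meta.columns:
            logger.warning("metadata has no 'sample' column; setting sample=unknown")
            meta["sample"] = "unknown"
        if "cluster" not in meta.columns:
            meta["cluster"] = pd.NA
        only_meta = set(meta.index) - set(cell_ids)
        only_matrix = set(cell_ids) - set(meta.index)
        if only_meta:
            logger.warning("%d cells in metadata but not in matrix", len(only_meta))
        if only_matrix:
            logger.warning("%d cells in matrix but not in metadata", len(only_matrix))
        meta = meta.reindex(cell_ids)
        meta["sex"] = meta["sex"].fillna("unknown")
        meta["sample"] = meta["sample"].fillna("unknown")
    else:
        meta = pd.DataFrame(
            {"sample": "unknown", "sex": "unknown", "cluster": pd.NA}, index=cell_ids
        )
    meta = meta[["sample", "sex", "cluster"]]

    if mito_list is not None:
        if isinstance(mito_list, (str, Path)):
            with open(mito_list) as fh:
                mito = frozenset(line.strip() for line in fh if line.strip())
        else:
            mito = frozenset(mito_list)
        mito = frozenset(g for g in mito if g in set(gene_ids))
    else:
        mito = frozenset(g for g in gene_ids if str(g).startswith(mito_prefix))

    return CellMatrix(counts, gene_ids, cell_ids, meta, mito)


def write_cell_matrix(m: CellMatrix, out_dir) -> dict:
    """Write matrix.mtx, features.tsv, barcodes.tsv and cell_meta.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "cell_meta.tsv",
    }
    mmwrite(str(paths["mtx"]), sp.coo_matrix(m.counts.astype(int)))
    pd.Series(m.gene_ids).to_csv(paths["features"], sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    meta = m.cell_meta.reset_index(names="barcode")
    meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_gene_set(path, name=None, provenance: str = "") -> GeneSet:
    """Read a one-id-per-line gene list."""
    path = Path(path)
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GeneSet(name or path.stem, frozenset(genes), provenance)


def read_gene_sets_tsv(path) -> dict:
    """Read a two-column (set_name, gene) TSV into {name: GeneSet}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"], dtype=str)
    return {
        name: GeneSet(name, frozenset(grp["gene"])) for name, grp in df.groupby("set")
    }


def read_orthology(brh_path, orthogroups_path=None) -> OrthologyMap:
    """Read BRH pairs (species_a, gene_a, species_b, gene_b) and optional
    orthogroup membership (orthogroup_id, species, gene) TSVs."""
    brh = pd.read_csv(
        brh_path, sep="\t", header=None,
        names=["species_a", "gene_a", "species_b", "gene_b"], dtype=str,
    )
    ogs: dict = {}
    if orthogroups_path is not None:
        og_df = pd.read_csv(
            orthogroups_path, sep="\t", header=None,
            names=["orthogroup", "species", "gene"], dtype=str,
        )
        for og, grp in og_df.groupby("orthogroup"):
            ogs[og] = set(zip(grp["species"], grp["gene"]))
    return OrthologyMap(brh, ogs)


def write_orthology(om: OrthologyMap, brh_path, orthogroups_path=None) -> None:
    om.brh_pairs.to_csv(brh_path, sep="\t", header=False, index=False)
    if orthogroups_path is not None:
        rows = [
            (og, sp_, g) for og, members in om.orthogroups.items() for sp_, g in sorted(members)
        ]
        pd.DataFrame(rows).to_csv(orthogroups_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# QC, normalization, summaries
# ---------------------------------------------------------------------------


def apply_qc_filters(
    m: CellMatrix,
    mito_max: float = 0.40,
    umi_min: int = 500,
    umi_max: int = 60000,
    ngene_min: int = 250,
    ngene_max: int = 3000,
    min_cells_per_gene: int = 3,
    cluster_qc: bool = False,
    cluster_qc_rule: str = "or",
    cluster_qc_mito: float = 0.40,
    cluster_qc_umi: int = 1000,
) -> CellMatrix:
    """Apply per-cell then per-gene QC filters.

    Cells are kept when mito fraction <= ``mito_max``,
    ``umi_min`` <= nUMI <= ``umi_max`` and ``ngene_min`` <= nGene <=
    ``ngene_max`` (all bounds inclusive); genes detected in fewer than
    ``min_cells_per_gene`` retained cells are then dropped.

    ``cluster_qc`` additionally drops, first, any whole cluster in which a
    strict majority (>50%) of cells violate the per-cluster rule — mito
    fraction >= ``cluster_qc_mito`` OR/AND nUMI < ``cluster_qc_umi``,
    combined per ``cluster_qc_rule``.
    """
    keep_cells = np.ones(m.n_cells, dtype=bool)

    if cluster_qc:
        mito = m.mito_fraction()
        numi = m.numi()
        bad_mito = mito >= cluster_qc_mito
        low_umi = numi < cluster_qc_umi
        if cluster_qc_rule == "or":
            violates = bad_mito | low_umi
        elif cluster_qc_rule == "and":
            violates = bad_mito & low_umi
        else:
            raise ValueError(f"cluster_qc_rule must be 'or' or 'and', got {cluster_qc_rule!r}")
        clusters = m.cell_meta["cluster"]
        for cl in clusters.dropna().unique():
            mask = (clusters == cl).to_numpy()
            if violates[mask].mean() > 0.5:
                logger.info("cluster-level QC drops cluster %s (%d cells)", cl, mask.sum())
                keep_cells &= ~mask
        if not keep_cells.any():
            raise EmptyResultError("cluster-level QC removed every cell")

    stages = [
        ("mito fraction", m.mito_fraction() <= mito_max),
        ("nUMI", (m.numi() >= umi_min) & (m.numi() <= umi_max)),
        ("nGene", (m.ngene() >= ngene_min) & (m.ngene() <= ngene_max)),
    ]
    for name, mask in stages:
        keep_cells &= mask
        if not keep_cells.any():
            raise EmptyResultError(f"QC filter on {name} removed every cell")

    filtered = m.subset(cell_mask=keep_cells)
    detected = np.asarray((filtered.counts > 0).sum(axis=1)).ravel()
    keep_genes = detected >= min_cells_per_gene
    if not keep_genes.any():
        raise EmptyResultError("gene-detection filter removed every gene")
    return filtered.subset(gene_mask=keep_genes)


def log_normalize(m: CellMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """value[g, c] = ln(1 + count[g, c] / nUMI[c] * scale_factor)."""
    numi = m.numi().astype(float)
    zero = np.where(numi == 0)[0]
    if len(zero):
        raise ValidationError(
            f"cells with zero total counts cannot be normalized: "
            f"{list(m.cell_ids[zero[:5]])}"
        )
    # scale each column by scale_factor / nUMI, then log1p on stored values
    scaled = sp.csr_matrix(m.counts.astype(float).multiply(scale_factor / numi))
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(scaled, m.gene_ids, m.cell_ids, scale_factor)


def summarize_clusters(nm: NormalizedMatrix, m: CellMatrix) -> ClusterSummary:
    """Per-cluster mean de-logged expression and expressing-cell fraction.

    avg_exp[k, g] = mean over cells in k of exp(value) - 1;
    pct_exp[k, g] = fraction of cells in k with raw count > 0.
    """
    clusters = m.cell_meta["cluster"]
    n_unlabeled = int(clusters.isna().sum())
    if n_unlabeled:
        raise ValidationError(f"{n_unlabeled} cells lack a cluster label")
    labels = sorted(clusters.unique(), key=str)

    delog = nm.values.copy()
    delog.data = np.expm1(delog.data)
    detected = (m.counts > 0).astype(float)

    avg_rows, pct_rows, sizes = [], [], []
    for cl in labels:
        mask = (clusters == cl).to_numpy()
        n = int(mask.sum())
        sizes.append(n)
        avg_rows.append(np.asarray(delog[:, mask].sum(axis=1)).ravel() / n)
        pct_rows.append(np.asarray(detected[:, mask].sum(axis=1)).ravel() / n)

    genes = list(m.gene_ids)
    avg = pd.DataFrame(avg_rows, index=labels, columns=genes)
    pct = pd.DataFrame(pct_rows, index=labels, columns=genes)
    return ClusterSummary(avg, pct, pd.Series(sizes, index=labels, name="n_cells"))
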