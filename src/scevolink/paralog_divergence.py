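"""Paralog expression-divergence statistics with random-gene-pair nulls.

Four per-pair statistics quantify how far two paralogs have diverged:

1. whether the pair is enriched in at least one shared cell cluster
   (operationalized through the pct > 0.25 / avg > 2 enrichment rule);
2. Pearson correlation of ln(1 + count) across single cells;
3. the number of shared regulators among each gene's top-k regulator
   weights;
4. Spearman correlation of the two genes' full regulator-weight columns.

Each scenario-level summary (mean, or fraction for the boolean statistic)
is compared against a resampling null built from uniformly drawn random
gene pairs, with a +1-corrected empirical p-value that is never exactly 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .core_model import CellMatrix, GeneSet, NormalizedMatrix

logger = logging.getLogger("scevolink")


@dataclass
class RegulatorWeights:
    """Nonnegative regulator x target weight matrix."""

    weights: pd.DataFrame  # regulators x targets
    source: str = "external_file"

    def __post_init__(self) -> None:
        vals = self.weights.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("regulator weights must be finite")
        if (vals < 0).any():
            raise ValueError("regulator weights must be nonnegative")
        # a regulator targeting itself carries no divergence information
        shared = [r for r in self.weights.index if r in self.weights.columns]
        for r in shared:
            self.weights.loc[r, r] = 0.0

    @property
    def regulators(self) -> pd.Index:
        return self.weights.index

    @property
    def targets(self) -> pd.Index:
        return self.weights.columns


def read_weights_tsv(path) -> RegulatorWeights:
    """Regulator x target weight matrix from TSV (regulators in rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RegulatorWeights(df, source="external_file")


# ---------------------------------------------------------------------------
# The four statistics
# ---------------------------------------------------------------------------


def same_celltype_frequency(pairs, enriched_map: dict):
    """Fraction of pairs whose enriched-cluster sets intersect.

    Pairs where either gene has an empty enriched set are excluded from the
    denominator and reported separately.  Returns
    (fraction, per-pair booleans aligned to the evaluable pairs, n_excluded).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    flags, excluded = [], 0
    for a, b in pairs:
        ca = enriched_map.get(a, set())
        cb = enriched_map.get(b, set())
        if not ca or not cb:
            excluded += 1
            flags.append(None)
        else:
            flags.append(bool(ca & cb))
    evaluable = [f for f in flags if f is not None]
    frac = float(np.mean(evaluable)) if evaluable else float("nan")
    return frac, flags, excluded


class PairCorrelator:
    """Vectorized Pearson correlation of ln(1 + count) between gene pairs.

    Standardizes every gene's log1p count vector once so that the
    correlation of a pair is a single dot product — cheap enough for the
    resampling null.  ``mode='cluster'`` correlates per-cluster mean
    profiles instead of per-cell vectors.
    """

    def __init__(self, m: CellMatrix, mode: str = "cell"):
        x = np.log1p(m.counts.toarray().astype(float))
        if mode == "cluster":
            clusters = m.cell_meta["cluster"]
            labels = sorted(clusters.dropna().unique(), key=str)
            x = np.column_stack([
                x[:, (clusters == cl).to_numpy()].mean(axis=1) for cl in labels
            ])
        elif mode != "cell":
            raise ValueError("mode must be 'cell' or 'cluster'")
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self._z = (x - mu) / sd
        self._defined = (sd.ravel() > 0)
        self._n = x.shape[1]
        self._index = {g: i for i, g in enumerate(m.gene_ids)}

    def corr(self, gene_a: str, gene_b: str) -> float:
        ia, ib = self._index[gene_a], self._index[gene_b]
        if not (self._defined[ia] and self._defined[ib]):
            return float("nan")
        return float(self._z[ia] @ self._z[ib] / self._n)

    def corr_many(self, pairs) -> np.ndarray:
        ia = np.array([self._index[a] for a, _ in pairs])
        ib = np.array([self._index[b] for _, b in pairs])
        out = np.einsum("ij,ij->i", self._z[ia], self._z[ib]) / self._n
        bad = ~(self._defined[ia] & self._defined[ib])
        out[bad] = np.nan
        return out


def pair_expression_correlation(pairs, m: CellMatrix, mode: str = "cell") -> pd.Series:
    """Per-pair Pearson r of log1p counts; NaN when either gene is constant."""
    pc = PairCorrelator(m, mode=mode)
    vals = pc.corr_many(list(pairs))
    idx = pd.MultiIndex.from_tuples([(a, b) for a, b in pairs], names=["gene_a", "gene_b"])
    return pd.Series(vals, index=idx, name="pearson_r")


def correlation_standin_weights(
    nm: NormalizedMatrix, m: CellMatrix, tf_set: GeneSet
) -> RegulatorWeights:
    """|Spearman| of cluster-mean profiles as a regulator-weight stand-in.

    A deliberately simple co-expression surrogate used when no external
    regulator-weight file (e.g. a random-forest importance matrix) is
    supplied; the two are not equivalent and the ``source`` tag records
    which one a report was built from.
    """
    clusters = m.cell_meta["cluster"]
    labels = sorted(clusters.dropna().unique(), key=str)
    if len(labels) < 3:
        raise ValueError("cluster-profile correlations need >= 3 clusters")
    dense = nm.dense()
    profiles = np.column_stack(
        [dense[:, (clusters == cl).to_numpy()].mean(axis=1) for cl in labels]
    )
    ranks = st.rankdata(profiles, axis=1)
    mu = ranks.mean(axis=1, keepdims=True)
    sd = ranks.std(axis=1, keepdims=True)
    defined = sd.ravel() > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (ranks - mu) / sd, 0.0)
    tfs = sorted(g for g in tf_set.genes)
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    missing = [g for g in tfs if g not in gene_index]
    if missing:
        raise ValueError(f"TFs absent from matrix: {missing[:5]}")
    tf_rows = np.array([gene_index[g] for g in tfs])
    w = np.abs(z[tf_rows] @ z.T / z.shape[1])
    w[~defined[tf_rows]] = 0.0
    w[:, ~defined] = 0.0  # undefined correlations stored as 0
    weights = pd.DataFrame(w, index=tfs, columns=list(nm.gene_ids))
    return RegulatorWeights(weights, source="correlation_standin")


def shared_top_regulators(pair, w: RegulatorWeights, k: int = 25) -> int:
    """|top-k(A) ∩ top-k(B)| with rank-k ties broken by regulator id."""
    a, b = pair
    if a not in w.targets or b not in w.targets:
        raise KeyError(f"pair {pair} not among weight targets")
    n_reg = len(w.regulators)
    if n_reg < k:
        logger.warning("only %d regulators; clipping k=%d", n_reg, k)
        k = n_reg

    def topk(gene: str) -> set:
        col = w.weights[gene]
        order = sorted(col.index, key=lambda r: (-col[r], str(r)))
        return set(order[:k])

    return len(topk(a) & topk(b))


def tf_weight_correlation(pair, w: RegulatorWeights) -> float:
    """Spearman correlation of the two genes' full regulator-weight columns."""
    a, b = pair
    xa = w.weights[a].to_numpy(dtype=float)
    xb = w.weights[b].to_numpy(dtype=float)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(st.spearmanr(xa, xb).statistic)


# ---------------------------------------------------------------------------
# Resampling null
# ---------------------------------------------------------------------------


@dataclass
class NullResult:
    observed: float
    null_sample: np.ndarray
    p_value: float
    n_perm: int
    alternative: str
    seed: int


def random_pair_null(
    statistic_fn,
    universe,
    n_obs_pairs: int,
    observed: float,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    max_retries: int = 10,
) -> NullResult:
    """Empirical p-value of an observed pair summary against random pairs.

    Each permutation draws ``n_obs_pairs`` uniform gene pairs (distinct
    genes within a pair, drawn with replacement across pairs) from
    ``universe`` and applies ``statistic_fn`` (a list of (gene_a, gene_b)
    -> scalar summary).  The +1-corrected empirical p is
    (1 + #{null >= observed}) / (n_perm + 1) for ``alternative='greater'``
    (or <= for 'less'), so it is never exactly 0.  A permutation whose
    summary is undefined (NaN) is redrawn up to ``max_retries`` times.
    """
    universe = list(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_obs_pairs < 1:
        raise ValueError("need >= 1 observed pair")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if not np.isfinite(observed):
        raise ValueError("observed summary is undefined")
    rng = np.random.default_rng(seed)
    n_genes = len(universe)
    uni = np.asarray(universe, dtype=object)

    null = np.empty(n_perm)
    for i in range(n_perm):
        for attempt in range(max_retries + 1):
            ia = rng.integers(n_genes, size=n_obs_pairs)
            ib = rng.integers(n_genes, size=n_obs_pairs)
            clash = ia == ib
            while clash.any():
                ib[clash] = rng.integers(n_genes, size=int(clash.sum()))
                clash = ia == ib
            val = statistic_fn(list(zip(uni[ia], uni[ib])))
            if np.isfinite(val):
                null[i] = val
                break
        else:
            raise RuntimeError(
                f"statistic undefined after {max_retries} redraws at permutation {i}"
            )
    if alternative == "greater":
        exceed = int((null >= observed).sum())
    else:
        exceed = int((null <= observed).sum())
    p = (1 + exceed) / (n_perm + 1)
    return NullResult(float(observed), null, float(p), n_perm, alternative, seed)


def mean_correlation_statistic(pc: PairCorrelator):
    """Pair-list -> mean Pearson r summary (NaN if >50% pairs undefined)."""

    def stat(pairs) -> float:
        vals = pc.corr_many(pairs)
        if np.isnan(vals).mean() > 0.5:
            return float("nan")
        return float(np.nanmean(vals))

    return stat


def same_celltype_statistic(enriched_map: dict):
    """Pair-list -> fraction sharing an enriched cluster (NaN if >50% excluded)."""

    def stat(pairs) -> float:
        frac, flags, excluded = same_celltype_frequency(pairs, enriched_map)
        if excluded > 0.5 * len(flags):
            return float("nan")
        return frac

    return stat


# ---------------------------------------------------------------------------
# Per-scenario report
# ---------------------------------------------------------------------------


@dataclass
class DivergenceReport:
    per_pair: pd.DataFrame
    per_scenario: pd.DataFrame
    nulls: dict = field(default_factory=dict)  # statistic -> {scenario: NullResult}
    n_perm: int = 0
    seed: int = 0


def divergence_report(
    pairs: pd.DataFrame,
    m: CellMatrix,
    enriched_map: dict = None,
    weights: RegulatorWeights = None,
    n_perm: int = 199,
    seed: int = 0,
    k_top: int = 25,
    corr_mode: str = "cell",
) -> DivergenceReport:
    """All four divergence statistics per pair, scenario summaries, and nulls.

    ``pairs`` needs columns gene_a, gene_b, scenario.  The enrichment-map
    and regulator-weight statistics are only computed when their inputs are
    supplied.  Null p-values are one-sided 'greater' — paralog pairs are
    expected to be more similar than random pairs.
    """
    per_pair = pairs[["gene_a", "gene_b", "scenario"]].copy()
    pc = PairCorrelator(m, mode=corr_mode)
    pair_list = list(zip(per_pair["gene_a"], per_pair["gene_b"]))
    per_pair["expr_correlation"] = pc.corr_many(pair_list)

    if enriched_map is not None:
        _, flags, _ = same_celltype_frequency(pair_list, enriched_map)
        per_pair["same_celltype"] = flags
    if weights is not None:
        per_pair["shared_top_tfs"] = [
            shared_top_regulators(p, weights, k_top) for p in pair_list
        ]
        per_pair["tf_weight_correlation"] = [
            tf_weight_correlation(p, weights) for p in pair_list
        ]

    summaries, nulls = [], {}
    universe = list(m.gene_ids)
    for scenario, grp in per_pair.groupby("scenario", sort=False):
        grp_pairs = list(zip(grp["gene_a"], grp["gene_b"]))
        row = {"scenario": scenario, "n_pairs": len(grp)}
        obs_corr = float(np.nanmean(grp["expr_correlation"]))
        row["mean_expr_correlation"] = obs_corr
        res = random_pair_null(
            mean_correlation_statistic(pc), universe, len(grp_pairs), obs_corr,
            n_perm=n_perm, seed=seed, alternative="greater",
        )
        nulls.setdefault("expr_correlation", {})[scenario] = res
        row["expr_correlation_p"] = res.p_value
        if enriched_map is not None:
            frac, _, excl = same_celltype_frequency(grp_pairs, enriched_map)
            row["same_celltype_fraction"] = frac
            row["same_celltype_excluded"] = excl
            # random pairs for the boolean statistic are drawn from genes the
            # enrichment rule can evaluate, mirroring the observed denominator
            universe_sc = [g for g in universe if enriched_map.get(g)]
            if np.isfinite(frac) and len(universe_sc) >= 2:
                res = random_pair_null(
                    same_celltype_statistic(enriched_map), universe_sc, len(grp_pairs),
                    frac, n_perm=n_perm, seed=seed + 1, alternative="greater",
                )
                nulls.setdefault("same_celltype", {})[scenario] = res
                row["same_celltype_p"] = res.p_value
        if weights is not None:
            row["mean_shared_top_tfs"] = float(np.mean(grp["shared_top_tfs"]))
            row["mean_tf_weight_correlation"] = float(
                np.nanmean(grp["tf_weight_correlation"])
            )
        summaries.append(row)

    return DivergenceReport(per_pair, pd.DataFrame(summaries), nulls, n_perm, seed)
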