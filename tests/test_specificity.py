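"""TPM/tau oracles, Wilcoxon exact-enumeration oracle, marker selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from scevolink import core_model as cm
from scevolink import specificity as spc


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------


class TestTPM:
    def test_hand_example(self):
        counts = pd.DataFrame({"s_1": [100, 300]}, index=["ga", "gb"])
        cds = pd.Series([1000, 1500], index=["ga", "gb"])
        tm = spc.compute_tpm(counts, cds, mean_read_length=150)
        # rates (15, 30) -> TPM (1/3, 2/3) of 1e6
        np.testing.assert_allclose(
            tm.tpm_per_sample["s_1"].to_numpy(), [1e6 / 3, 2e6 / 3], rtol=1e-9
        )

    def test_single_expressed_gene_gets_million(self):
        counts = pd.DataFrame({"s_1": [40, 0]}, index=["ga", "gb"])
        cds = pd.Series([500, 900], index=["ga", "gb"])
        tm = spc.compute_tpm(counts, cds, 100)
        assert tm.tpm_per_sample.loc["ga", "s_1"] == pytest.approx(1e6)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s_1": rng.integers(1, 100, 10)})
        cds = pd.Series(rng.integers(300, 3000, 10), index=counts.index)
        a = spc.compute_tpm(counts, cds, 150).tpm_per_sample
        b = spc.compute_tpm(counts * 10, cds, 150).tpm_per_sample
        pd.testing.assert_frame_equal(a, b)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 500, (30, 6)),
            columns=[f"t{i}_{r}" for i in range(3) for r in (1, 2)],
        )
        counts.iloc[0] += 1  # no all-zero sample
        cds = pd.Series(rng.integers(300, 3000, 30), index=counts.index)
        tm = spc.compute_tpm(counts, cds, 150)
        np.testing.assert_allclose(tm.tpm_per_sample.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_sample_error_names_sample(self):
        counts = pd.DataFrame({"good_1": [5], "bad_1": [0]})
        cds = pd.Series([1000], index=counts.index)
        with pytest.raises(cm.ValidationError, match="bad_1"):
            spc.compute_tpm(counts, cds, 150)

    def test_replicates_averaged_after_tpm(self):
        counts = pd.DataFrame(
            {"br_1": [10, 10], "br_2": [30, 10]}, index=["ga", "gb"]
        )
        cds = pd.Series([100, 100], index=counts.index)
        tm = spc.compute_tpm(counts, cds, 100)
        expected = (tm.tpm_per_sample["br_1"] + tm.tpm_per_sample["br_2"]) / 2
        np.testing.assert_allclose(tm.tpm["br"].to_numpy(), expected.to_numpy())


# ---------------------------------------------------------------------------
# tau
# ---------------------------------------------------------------------------


class TestTau:
    @pytest.mark.parametrize(
        "profile, expected",
        [((1, 0, 0), 1.0), ((5, 5, 5), 0.0), ((8, 2, 2), 0.75)],
    )
    def test_hand_profiles(self, profile, expected):
        assert spc.tau_index(profile) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_undefined(self):
        assert np.isnan(spc.tau_index([0, 0, 0]))

    def test_too_few_tissues(self):
        with pytest.raises(ValueError):
            spc.tau_index([1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        profile=hst.lists(hst.floats(0, 1e6), min_size=2, max_size=10),
        scale=hst.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_range(self, profile, scale):
        x = np.asarray(profile)
        if x.max() == 0:
            return
        t = spc.tau_index(x)
        assert -1e-12 <= t <= 1 + 1e-12
        assert spc.tau_index(x * scale) == pytest.approx(t, abs=1e-9)

    def test_raising_zero_tissue_decreases_tau(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.uniform(1, 10, 5)
            x[0] = 0
            base = spc.tau_index(x)
            for frac in (0.25, 0.5, 1.0):
                y = x.copy()
                y[0] = frac * x.max()
                assert spc.tau_index(y) <= base + 1e-12


class TestClassifySpecific:
    def _tm(self, tpm):
        df = pd.DataFrame(tpm, columns=["brain", "legs", "silk"])
        return spc.TissueMatrix(df, df, pd.Series(1, index=df.index), 150.0)

    def test_threshold_strict(self):
        # tau((1, 0.2, 0.2)) = 0.8 exactly -> NOT specific
        sr = self._tm([[1.0, 0.2, 0.2]])
        res = spc.classify_specific(sr)
        assert res.table["tau"].iloc[0] == pytest.approx(0.8, rel=1e-12)
        assert not res.table["specific"].iloc[0]

    def test_specific_with_top_tissue(self):
        res = spc.classify_specific(self._tm([[1.0, 0.1, 0.1]]))
        row = res.table.iloc[0]
        assert row["specific"] and row["top_tissue"] == "brain"

    def test_all_zero_gene(self):
        res = spc.classify_specific(self._tm([[0.0, 0.0, 0.0]]))
        row = res.table.iloc[0]
        assert not row["specific"] and row["top_tissue"] is None


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def exact_two_sided_rank_sum(x, y) -> float:
    """Oracle: exact two-sided p by enumerating all group assignments."""
    combined = np.concatenate([x, y])
    n1 = len(x)
    from scipy.stats import rankdata

    ranks = rankdata(combined)
    obs = ranks[:n1].sum()
    sums = np.array(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(combined)), n1)]
    )
    p_low = np.mean(sums <= obs)
    p_high = np.mean(sums >= obs)
    return float(min(1.0, 2 * min(p_low, p_high)))


class TestWilcoxon:
    def test_textbook_groups(self):
        assert spc.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, rel=1e-9)

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 5), (5, 8), (8, 8)])
    def test_matches_exact_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            data = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = data[:n1], data[n1:]
            assert spc.wilcoxon_rank_sum(x, y) == pytest.approx(
                exact_two_sided_rank_sum(x, y), rel=1e-9
            )


# ---------------------------------------------------------------------------
# Marker detection and highly-enriched selection
# ---------------------------------------------------------------------------


def _nm_from_values(values, gene_ids, cell_ids):
    import scipy.sparse as sp

    return cm.NormalizedMatrix(sp.csr_matrix(values), np.array(gene_ids, dtype=object),
                               np.array(cell_ids, dtype=object))


class TestFindMarkers:
    def test_avg_log2fc_convention(self):
        # de-logged means 3 in-cluster, 1 outside -> log2(4/2) = 1
        n = 30
        vals = np.zeros((2, 2 * n))
        vals[0, :n] = np.log(4.0)  # expm1 -> 3
        vals[0, n:] = np.log(2.0)  # expm1 -> 1
        vals[1] = np.log(2.0)
        nm = _nm_from_values(vals, ["hit", "flat"], [f"c{i}" for i in range(2 * n)])
        clusters = pd.Series(["in"] * n + ["out"] * n, index=nm.cell_ids)
        table = spc.find_markers(nm, clusters, min_pct=0.1)
        row = table[(table["gene"] == "hit") & (table["cluster"] == "in")]
        assert row["avg_log2FC"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_flat_gene_not_reported(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([np.log1p(rng.poisson(5, 60)), np.full(60, 1.0)])
        nm = _nm_from_values(vals, ["noisy", "flat"], [f"c{i}" for i in range(60)])
        clusters = pd.Series(["a"] * 30 + ["b"] * 30, index=nm.cell_ids)
        table = spc.find_markers(nm, clusters, min_pct=0.1)
        assert "flat" not in set(table["gene"])

    def test_planted_marker_recall(self, atlas, atlas_markers):
        _, truth = atlas
        found = set(zip(atlas_markers["gene"], atlas_markers["cluster"]))
        recall = np.mean([pair in found for pair in zip(truth["gene"], truth["cluster"])])
        assert recall >= 0.9

    def test_no_markers_without_signal(self):
        from scevolink import synthetic_data as syn

        cfg = syn.SimConfig(seed=11, n_samples=1, sex_split=(0, 1),
                            n_cells_per_sample=300, n_clusters=3, n_genes=300,
                            marker_fold_change=1.0)
        m, truth = syn.simulate_cell_matrix(cfg)
        assert truth.empty
        nm = cm.log_normalize(m)
        table = spc.find_markers(nm, m.cell_meta["cluster"])
        # BH at 5%: essentially nothing should survive on pure noise
        assert len(set(table["gene"])) <= 0.05 * m.n_genes


class TestSelectHighlyEnriched:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cluster", "avg_log2FC"]).assign(
            pct_in=0.5, pct_out=0.1, p_value=1e-6, p_adj=1e-5
        )

    def test_boundaries(self):
        rows = (
            [("six", f"k{i}", 3.0) for i in range(6)]  # 6 clusters -> excluded
            + [("edge", "k0", 1.0), ("edge", "k1", 0.5)]  # max LFC exactly 1 -> kept
            + [("weak", "k0", 0.8)]  # max LFC < 1 -> excluded
            + [("five", f"k{i}", 2.0) for i in range(5)]  # 5 clusters -> kept
        )
        gs = spc.select_highly_enriched(self._table(rows))
        assert gs.genes == {"edge", "five"}

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            spc.select_highly_enriched(self._table([]).iloc[0:0])
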