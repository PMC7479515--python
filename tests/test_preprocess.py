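"""Transforms and QC filters against their stated rules and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scprograms import preprocess
from scprograms.matrix import ExpressionMatrix


def tpm_matrix(arr, cells=None, genes=None, groups=None):
    arr = np.asarray(arr, dtype=float)
    cells = cells or [f"c{i}" for i in range(arr.shape[0])]
    genes = genes or [f"g{j}" for j in range(arr.shape[1])]
    grp = pd.Series(groups, index=cells) if groups is not None else None
    return ExpressionMatrix(pd.DataFrame(arr, index=cells, columns=genes), "tpm", grp)


class TestLogTransform:
    @pytest.mark.parametrize("tpm,expected", [(0.0, 0.0), (10.0, 1.0), (70.0, 3.0)])
    def test_known_values(self, tpm, expected):
        m = tpm_matrix([[tpm]])
        assert preprocess.log_transform(m).values.iloc[0, 0] == pytest.approx(expected)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 500, (20, 30))
        out = preprocess.log_transform(tpm_matrix(arr)).values.to_numpy()
        oracle = np.array(
            [[np.log2(x / 10 + 1) for x in row] for row in arr]
        )
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_rejects_wrong_scale(self):
        m = tpm_matrix([[1.0]])
        logged = preprocess.log_transform(m)
        with pytest.raises(ValueError, match="scale"):
            preprocess.log_transform(logged)


class TestSmartseqQC:
    def make(self, n_detected, hk_tpm, n_genes=3000):
        """One cell detecting ``n_detected`` genes, housekeeping at ``hk_tpm``."""
        row = np.zeros(n_genes)
        row[:n_detected] = 50.0
        row[:5] = hk_tpm  # first five genes are housekeeping
        return tpm_matrix([row]), [f"g{j}" for j in range(5)]

    def test_cell_below_gene_threshold_removed(self):
        m, hk = self.make(1999, hk_tpm=100.0)
        filtered, report = preprocess.qc_filter_smartseq(m, hk)
        assert filtered.n_cells == 0
        assert report.table["reason"].iloc[0].startswith("detected_genes")

    def test_cell_below_housekeeping_threshold_removed(self):
        # E = 2.4 -> TPM = (2^2.4 - 1) * 10
        hk_tpm = (2**2.4 - 1) * 10
        m, hk = self.make(2500, hk_tpm=hk_tpm)
        filtered, report = preprocess.qc_filter_smartseq(m, hk)
        assert filtered.n_cells == 0
        assert "housekeeping" in report.table["reason"].iloc[0]

    def test_good_cells_untouched_and_counts_reconcile(self):
        hk_tpm = (2**3.0 - 1) * 10  # E = 3
        rows = np.zeros((4, 3500))
        rows[:, :3000] = 40.0
        rows[:, :5] = hk_tpm
        m = tpm_matrix(rows)
        filtered, report = preprocess.qc_filter_smartseq(m, [f"g{j}" for j in range(5)])
        assert filtered.n_cells == 4
        assert report.n_passed + report.n_removed == m.n_cells

    def test_empty_housekeeping_rejected(self):
        m = tpm_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError, match="housekeeping"):
            preprocess.qc_filter_smartseq(m, [])


class TestGeneFilter:
    def test_prevalence_boundary(self):
        arr = np.zeros((12, 3))
        arr[:9, 0] = 20.0  # 9 cells above 10 -> removed
        arr[:10, 1] = 20.0  # 10 cells -> retained
        m = tpm_matrix(arr)
        kept = preprocess.filter_genes(m)
        assert list(kept.gene_ids) == ["g1"]

    def test_exactly_min_tpm_does_not_count(self):
        arr = np.full((12, 1), 10.0)  # TPM == 10 is not "> 10"
        assert preprocess.filter_genes(tpm_matrix(arr)).n_genes == 0


class TestAggregateExpression:
    def test_constant_gene(self):
        m = tpm_matrix(np.full((5, 1), 10.0))
        assert preprocess.aggregate_expression(m)["g0"] == pytest.approx(np.log2(11))

    def test_zero_gene_and_oracle(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 200, (20, 30))
        arr[:, 0] = 0.0
        ea = preprocess.aggregate_expression(tpm_matrix(arr))
        assert ea["g0"] == 0.0
        oracle = [np.log2(np.mean(arr[:, j]) + 1) for j in range(30)]
        np.testing.assert_allclose(ea.to_numpy(), oracle, atol=1e-12)

    def test_empty_matrix_rejected(self):
        m = tpm_matrix(np.zeros((0, 3)))
        with pytest.raises(ValueError, match="empty"):
            preprocess.aggregate_expression(m)


class TestCentering:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_groupwise_mean_zero_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 300, (10, 6))
        m = preprocess.log_transform(
            tpm_matrix(arr, groups=["a"] * 5 + ["b"] * 5)
        )
        er = preprocess.center_expression(m)
        for grp in ("a", "b"):
            block = er.values[er.cell_groups == grp]
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-8)
        again = preprocess.center_expression(er)
        np.testing.assert_allclose(
            again.values.to_numpy(), er.values.to_numpy(), atol=1e-10
        )

    def test_single_cell_group_goes_to_zero(self):
        m = preprocess.log_transform(tpm_matrix([[10.0, 70.0]], groups=["solo"]))
        er = preprocess.center_expression(m)
        np.testing.assert_array_equal(er.values.to_numpy(), 0.0)

    def test_pan_group_recentering_ignores_groups(self):
        arr = np.array([[0.0, 10.0], [10.0, 0.0], [70.0, 70.0], [0.0, 0.0]])
        m = preprocess.log_transform(tpm_matrix(arr, groups=["a", "a", "b", "b"]))
        er = preprocess.center_expression(m, by_group=False)
        np.testing.assert_allclose(er.values.mean(axis=0), 0.0, atol=1e-8)


class TestUmiQC:
    def make(self, detected_counts, mito_umis=None, n_genes=100):
        n = len(detected_counts)
        arr = np.zeros((n, n_genes))
        for i, d in enumerate(detected_counts):
            arr[i, :d] = 1.0
        genes = [f"MT-{j}" if j < 2 else f"g{j}" for j in range(n_genes)]
        if mito_umis is not None:
            for i, mu in enumerate(mito_umis):
                arr[i, 0] = mu
        df = pd.DataFrame(arr, index=[f"c{i}" for i in range(n)], columns=genes)
        return ExpressionMatrix(df, "umi")

    def test_mito_fraction_boundary(self):
        # total 1000 UMIs; mito 51 -> 5.1% removed, 50 -> kept
        arr = np.zeros((2, 100))
        arr[:, 1:50] = 1000 / 49.0
        base = arr[0, 1:].sum()
        arr[0, 0] = 0.051 / (1 - 0.051) * base
        arr[1, 0] = 0.05 / (1 - 0.05) * base
        df = pd.DataFrame(arr, columns=[f"MT-0"] + [f"g{j}" for j in range(1, 100)])
        m = ExpressionMatrix(df, "umi")
        filtered, report = preprocess.qc_filter_umi(m)
        assert list(filtered.cell_ids) == [1]
        assert report.table.loc[0, "reason"].startswith("mito")

    def test_detected_gene_window(self):
        # mean detected = 50; 0.4*mean = 20 removed, exactly mean kept
        m = self.make([20, 50, 80])
        filtered, _ = preprocess.qc_filter_umi(m)
        assert "c1" in list(filtered.cell_ids)
        assert "c0" not in list(filtered.cell_ids)

    def test_no_mito_genes_warns_and_skips_rule(self):
        arr = np.ones((3, 10))
        m = ExpressionMatrix(pd.DataFrame(arr, columns=[f"g{j}" for j in range(10)]), "umi")
        with pytest.warns(UserWarning, match="mitochondrial"):
            filtered, _ = preprocess.qc_filter_umi(m)
        assert filtered.n_cells == 3
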