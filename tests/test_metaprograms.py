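"""Overdispersion ranking, NMF behavior, program clustering and merging."""

import numpy as np
import pandas as pd
import pytest

from scprograms import metaprograms as mp
from scprograms import preprocess
from scprograms.matrix import ExpressionMatrix


def log_matrix(arr, genes=None):
    genes = genes or [f"g{j:03d}" for j in range(np.shape(arr)[1])]
    return ExpressionMatrix(pd.DataFrame(np.asarray(arr, float), columns=genes), "log")


class TestOverdispersedGenes:
    def test_n_at_least_gene_count_returns_all(self):
        m = log_matrix(np.random.default_rng(0).uniform(0, 3, (10, 15)))
        assert set(mp.overdispersed_genes(m, n=100)) == set(m.gene_ids)

    def test_planted_variable_genes_outrank_flat_genes(self, genome, cohort, cohort_pipeline):
        m, truth, _ = cohort
        sample_cells = truth.index[
            (truth["sample_id"] == "S0") & (truth["cell_class"] == "malignant")
        ]
        e = cohort_pipeline["E"].subset_cells(sample_cells)
        top = mp.overdispersed_genes(e, n=300)
        module_genes = set(genome.modules["P1"]) | set(genome.modules["P2"])
        # program modules differ between cells of different programs, so they
        # are the most over-dispersed genes of a mixed malignant sample
        assert len(module_genes & set(top)) / len(module_genes) > 0.8

    def test_constant_gene_never_selected_when_alternatives_exist(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 3, (12, 20))
        arr[:, 5] = 2.0  # constant
        m = log_matrix(arr)
        assert "g005" not in mp.overdispersed_genes(m, n=19)

    def test_invalid_n_rejected(self):
        m = log_matrix(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            mp.overdispersed_genes(m, n=0)


class TestRunNMF:
    def rank2(self):
        """Two disjoint 10-gene modules on two disjoint cell groups."""
        arr = np.zeros((30, 40))
        arr[:15, :10] = 3.0
        arr[15:, 10:20] = 3.0
        rng = np.random.default_rng(2)
        arr += rng.uniform(0, 0.05, arr.shape)
        return ExpressionMatrix(
            pd.DataFrame(arr, columns=[f"g{j:03d}" for j in range(40)]), "centered"
        )

    def test_rank2_recovery_of_planted_modules(self):
        er = self.rank2()
        programs, _ = mp.run_nmf(er, k=2, sample_id="t")
        mod_a = {f"g{j:03d}" for j in range(10)}
        mod_b = {f"g{j:03d}" for j in range(10, 20)}
        for prog in programs:
            top10 = set(mp.top_genes(prog.weights, 10))
            jac = max(
                len(top10 & mod) / len(top10 | mod) for mod in (mod_a, mod_b)
            )
            assert jac >= 0.8

    def test_k1_factor_is_scaled_mean_profile(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 2, (20, 30))
        er = ExpressionMatrix(
            pd.DataFrame(arr, columns=[f"g{j:03d}" for j in range(30)]), "centered"
        )
        programs, _ = mp.run_nmf(er, k=1)
        w = programs[0].weights.to_numpy()
        mean_profile = arr.mean(axis=0)
        corr = np.corrcoef(w, mean_profile)[0, 1]
        assert corr > 0.99

    def test_reconstruction_error_monotone_nonincreasing(self):
        er = self.rank2()
        _, errors = mp.run_nmf(er, k=3, max_iter=200, tol=0.0)
        assert (np.diff(errors) <= 1e-9).all()

    def test_rerun_is_bit_identical(self):
        er = self.rank2()
        a, _ = mp.run_nmf(er, k=2, seed=0)
        b, _ = mp.run_nmf(er, k=2, seed=0)
        for pa, pb in zip(a, b):
            assert (pa.weights.to_numpy() == pb.weights.to_numpy()).all()

    def test_k_larger_than_matrix_rejected(self):
        er = self.rank2()
        with pytest.raises(ValueError):
            mp.run_nmf(er, k=1000)

    def test_agrees_with_sklearn_on_planted_structure(self):
        """Independent solver cross-check: same modules recovered."""
        from sklearn.decomposition import NMF

        er = self.rank2()
        ours, _ = mp.run_nmf(er, k=2)
        sk = NMF(n_components=2, init="nndsvda", max_iter=500, random_state=0)
        sk.fit(np.clip(er.values.to_numpy(), 0, None))
        sk_tops = [
            set(pd.Series(comp, index=er.gene_ids).nlargest(10).index)
            for comp in sk.components_
        ]
        our_tops = [set(mp.top_genes(p.weights, 10)) for p in ours]
        for ot in our_tops:
            assert max(len(ot & st) / len(ot | st) for st in sk_tops) >= 0.8


class TestClusterPrograms:
    def scores(self, cols):
        rng = np.random.default_rng(4)
        return pd.DataFrame(
            {name: vec for name, vec in cols.items()},
            index=[f"c{i}" for i in range(len(next(iter(cols.values()))))],
        )

    def test_duplicated_program_forms_one_cluster(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=100)
        cols = {"a": v, "b": v.copy(), "c": rng.normal(size=100)}
        clusters = mp.cluster_programs(pd.DataFrame(cols))
        assert ["a", "b"] in clusters
        assert not any("c" in cl for cl in clusters)

    def test_orthogonal_programs_yield_nothing_without_whitelist(self):
        rng = np.random.default_rng(6)
        cols = pd.DataFrame({f"p{i}": rng.normal(size=200) for i in range(5)})
        assert mp.cluster_programs(cols) == []
        white = mp.cluster_programs(cols, whitelist=["p2"])
        assert ["p2"] in white

    def test_result_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=150)
        cols = pd.DataFrame(
            {
                "x": v + rng.normal(0, 0.1, 150),
                "y": v + rng.normal(0, 0.1, 150),
                "z": rng.normal(size=150),
                "w": rng.normal(size=150),
            }
        )
        a = mp.cluster_programs(cols)
        b = mp.cluster_programs(cols[["w", "z", "y", "x"]])
        assert a == b

    def test_fewer_than_two_programs_rejected(self):
        with pytest.raises(ValueError):
            mp.cluster_programs(pd.DataFrame({"only": np.arange(5.0)}))


class TestMerge:
    def programs(self, weight_rows, genes):
        return [
            mp.NMFProgram("s", i, pd.Series(row, index=genes))
            for i, row in enumerate(weight_rows)
        ]

    def test_single_member_returns_its_top30(self):
        rng = np.random.default_rng(8)
        genes = [f"g{j:03d}" for j in range(50)]
        progs = self.programs([rng.uniform(0, 1, 50)], genes)
        meta = mp.merge_to_metaprogram(progs, "MP1")
        assert meta.top_genes == progs[0].top_genes

    def test_identical_members_same_top30(self):
        rng = np.random.default_rng(9)
        genes = [f"g{j:03d}" for j in range(50)]
        w = rng.uniform(0, 1, 50)
        meta = mp.merge_to_metaprogram(self.programs([w, w.copy()], genes), "MP1")
        assert meta.top_genes == mp.top_genes(pd.Series(w, index=genes))

    def test_asymmetric_members_match_average_and_sort_oracle(self):
        rng = np.random.default_rng(10)
        genes = [f"g{j:03d}" for j in range(60)]
        rows = [rng.uniform(0, 1, 60) for _ in range(3)]
        meta = mp.merge_to_metaprogram(self.programs(rows, genes), "MP1")
        avg = {g: float(np.mean([r[j] for r in rows])) for j, g in enumerate(genes)}
        oracle = [g for g, _ in sorted(avg.items(), key=lambda kv: (-kv[1], kv[0]))][:30]
        assert meta.top_genes == oracle

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            mp.merge_to_metaprogram([], "MP1")


class TestSignatureGenes:
    def test_planted_module_recovered_and_filters_enforced(self, genome, cohort, cohort_pipeline):
        m, truth, _ = cohort
        e = cohort_pipeline["E"]
        mal = truth["cell_class"] == "malignant"
        assignments = truth.loc[mal, "program"]
        sigs = mp.signature_genes(assignments, e.subset_cells(assignments.index))
        recovered = set(sigs["P1"]) & set(genome.modules["P1"])
        assert len(recovered) / len(genome.modules["P1"]) >= 0.8

    def test_identical_populations_give_empty_signature(self):
        rng = np.random.default_rng(11)
        arr = rng.uniform(0, 3, (40, 30))
        m = log_matrix(arr)
        assignments = pd.Series(["a"] * 20 + ["b"] * 20, index=m.cell_ids)
        sigs = mp.signature_genes(assignments, m)
        assert sigs["a"] == [] and sigs["b"] == []

    def test_low_expression_fraction_rejected(self):
        # gene hugely up in population 'a' but expressed in only 40% of its cells
        arr = np.zeros((40, 10))
        arr[:, 1:] = np.random.default_rng(12).uniform(1, 2, (40, 9))
        arr[:8, 0] = 8.0  # 8 of 20 'a' cells
        m = log_matrix(arr)
        assignments = pd.Series(["a"] * 20 + ["b"] * 20, index=m.cell_ids)
        sigs = mp.signature_genes(assignments, m)
        assert "g000" not in sigs["a"]

    def test_tiny_population_skipped_with_warning(self):
        m = log_matrix(np.random.default_rng(13).uniform(0, 2, (10, 5)))
        assignments = pd.Series(["a"] * 2 + ["b"] * 8, index=m.cell_ids)
        with pytest.warns(UserWarning, match="too few"):
            sigs = mp.signature_genes(assignments, m)
        assert "a" not in sigs
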