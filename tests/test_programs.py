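"""Consensus NMF, rank selection, module scores and meta-program assembly."""

import numpy as np
import pandas as pd
import pytest

from creglink.programs import (
    ProgramSignature,
    kl_divergence,
    meta_programs,
    module_score,
    nmf_consensus,
    nmf_mu_kl,
    program_signature,
    relative_expression,
    select_k,
)


class TestRelativeExpression:
    def _counts(self, rng, n_genes=20, n_cells=30):
        return rng.poisson(3.0, size=(n_genes, n_cells)).astype(float) + 1

    def test_min_cells_gate_is_strict(self, rng):
        counts = self._counts(rng, n_cells=11)
        genes = pd.Index([f"G{i}" for i in range(20)])
        cells = [f"C{i}" for i in range(11)]
        samples = np.array(["S1"] * 5 + ["S2"] * 6)
        tumor = np.ones(11, dtype=bool)
        rel = relative_expression(counts, genes, cells, samples, tumor, min_cells=5)
        assert set(rel) == {"S2"}  # S1 has exactly 5 tumor cells: skipped

    def test_constant_gene_becomes_zero_row(self, rng):
        counts = self._counts(rng, n_cells=12)
        counts[0] = counts[1:].sum(axis=0) / 9.0  # a fixed fraction of depth
        genes = pd.Index([f"G{i}" for i in range(20)])
        cells = [f"C{i}" for i in range(12)]
        rel = relative_expression(counts, genes, cells,
                                  np.array(["S1"] * 12), np.ones(12, bool), min_cells=5)
        np.testing.assert_allclose(rel["S1"].loc["G0"], 0.0, atol=1e-9)

    def test_toy_center_and_clip(self):
        counts = np.array([[1.0, 3.0, 1.0, 3.0], [2.0, 2.0, 2.0, 2.0]])
        genes = pd.Index(["A", "B"])
        rel = relative_expression(counts, genes, list("wxyz"),
                                  np.array(["S"] * 4), np.ones(4, bool), min_cells=2)
        X = rel["S"].to_numpy()
        from creglink.preprocess import log_normalize
        import scipy.sparse as sp

        ln = np.asarray(log_normalize(sp.csr_matrix(counts)).todense())
        expected = np.clip(ln - ln.mean(axis=1, keepdims=True), 0, None)
        np.testing.assert_allclose(X, expected, atol=1e-12)

    def test_no_qualifying_sample_raises(self, rng):
        counts = self._counts(rng, n_cells=4)
        genes = pd.Index([f"G{i}" for i in range(20)])
        with pytest.raises(ValueError):
            relative_expression(counts, genes, list("abcd"),
                                np.array(["S"] * 4), np.ones(4, bool), min_cells=500)


class TestNMF:
    def test_planted_factorization_recovered(self, rng):
        W0 = rng.uniform(0, 1, size=(40, 3))
        H0 = rng.uniform(0, 1, size=(3, 25))
        V = W0 @ H0
        W, H, obj = nmf_mu_kl(V, 3, max_iter=500, tol=1e-9, seed=0)
        rel_err = np.linalg.norm(V - W @ H) / np.linalg.norm(V)
        assert rel_err < 1e-3

    def test_objective_non_increasing(self, rng):
        V = rng.gamma(1.0, 2.0, size=(30, 20))
        _, _, _, trace = nmf_mu_kl(V, 4, max_iter=60, tol=0, seed=1,
                                   track_objective=True)
        diffs = np.diff(trace)
        assert (diffs <= 1e-8).all()

    def test_nonnegativity_and_negative_input_rejected(self, rng):
        V = rng.gamma(1.0, 1.0, size=(10, 8))
        W, H, _ = nmf_mu_kl(V, 2, seed=0)
        assert (W >= 0).all() and (H >= 0).all()
        with pytest.raises(ValueError):
            nmf_mu_kl(-V, 2)

    def test_objective_competitive_with_sklearn(self, rng):
        from sklearn.decomposition import NMF

        V = rng.gamma(1.0, 2.0, size=(50, 30))
        W, H, obj = nmf_mu_kl(V, 4, max_iter=400, tol=1e-9, seed=0)
        sk = NMF(4, solver="mu", beta_loss="kullback-leibler", init="random",
                 max_iter=400, random_state=0, tol=1e-9)
        Wk = sk.fit_transform(V)
        obj_sk = kl_divergence(V, Wk @ sk.components_)
        assert obj <= obj_sk * 1.05

    def test_consensus_of_separable_clusters(self, rng):
        # two disjoint gene blocks over two cell groups
        V = np.zeros((20, 30))
        V[:10, :15] = rng.uniform(1, 2, size=(10, 15))
        V[10:, 15:] = rng.uniform(1, 2, size=(10, 15))
        res = nmf_consensus(V, 2, nrun=8, seed=0)
        assert res.cophenetic > 0.99
        assert res.consensus.shape == (30, 30)
        np.testing.assert_allclose(np.diag(res.consensus), 1.0)
        np.testing.assert_allclose(res.consensus, res.consensus.T)


class TestSelectK:
    def test_max_drop_example(self):
        coph = {2: 0.99, 3: 0.98, 4: 0.80, 5: 0.79, 6: 0.78}
        # largest decrease is 3 -> 4; the k preceding it is 3
        assert select_k(coph) == 3

    def test_equal_drops_pick_smallest(self):
        coph = {2: 1.0, 3: 0.9, 4: 0.8, 5: 0.7, 6: 0.6}
        assert select_k(coph) == 2

    def test_monotone_increase_warns_and_picks_largest(self):
        coph = {2: 0.5, 3: 0.6, 4: 0.7, 5: 0.8, 6: 0.9}
        with pytest.warns(UserWarning):
            assert select_k(coph) == 6


class TestProgramSignature:
    def test_fewer_genes_than_requested(self, rng):
        W = pd.DataFrame(rng.uniform(size=(3, 2)), index=["a", "b", "c"])
        with pytest.warns(UserWarning):
            sig = program_signature(W, 0, top_n=100)
        assert len(sig.genes) == 3

    def test_dominant_gene_ranks_first(self, rng):
        W = pd.DataFrame(rng.uniform(0, 1, size=(50, 2)),
                         index=[f"g{i}" for i in range(50)])
        W.iloc[7, 0] = 10.0
        sig = program_signature(W, 0, top_n=10)
        assert sig.genes[0] == "g7"

    def test_matches_full_sort_oracle(self, rng):
        genes = [f"g{i:03d}" for i in range(500)]
        W = pd.DataFrame(rng.uniform(size=(500, 1)), index=genes)
        sig = program_signature(W, 0, top_n=100)
        oracle = sorted(genes, key=lambda g: (-W.loc[g, 0], g))[:100]
        assert sig.genes == oracle


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(np.full((30, 10), 2.5),
                            index=[f"g{i}" for i in range(30)])
        score = module_score(expr, ["g1", "g5"], seed=0)
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_random_sets_mean_near_zero(self, rng):
        expr = pd.DataFrame(rng.gamma(2.0, 1.0, size=(200, 60)),
                            index=[f"g{i}" for i in range(200)])
        means = []
        for i in range(100):
            genes = [f"g{j}" for j in rng.choice(200, size=10, replace=False)]
            means.append(module_score(expr, genes, seed=i).mean())
        assert abs(np.mean(means)) < 0.05

    def test_toy_two_bins_by_hand(self, rng):
        # 6 genes, 2 bins (3 genes each by average expression), controls drawn
        # with a known seed are reproducible, so compute expectation directly
        expr = pd.DataFrame(
            np.array([
                [1.0, 2.0], [1.2, 2.2], [1.4, 2.4],   # low bin
                [5.0, 6.0], [5.2, 6.2], [5.4, 6.4],   # high bin
            ]),
            index=list("abcdef"),
        )
        got = module_score(expr, ["a"], n_bins=2, n_ctrl=4, seed=7)
        rng2 = np.random.default_rng(7)
        pool = np.array([1, 2])  # bin of 'a' excluding nothing: indices 0,1,2
        avg = expr.to_numpy().mean(axis=1)
        order = np.argsort(avg, kind="stable")
        bins = np.empty(6, dtype=int)
        bins[order] = (np.arange(6) * 2) // 6
        pool = np.flatnonzero(bins == bins[0])
        ctrl = rng2.choice(pool, size=4, replace=True)
        expected = expr.to_numpy()[[0]].mean(axis=0) - expr.to_numpy()[ctrl].mean(axis=0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_empty_intersection_raises(self):
        expr = pd.DataFrame(np.ones((5, 3)), index=list("abcde"))
        with pytest.raises(ValueError):
            module_score(expr, ["zzz"])


class TestMetaPrograms:
    def _signature(self, sample, program, genes):
        return ProgramSignature(sample, program, list(genes), np.ones(len(genes)))

    def test_identical_programs_pair_across_samples(self, rng):
        genes = [f"g{i}" for i in range(60)]
        set_a, set_b = genes[:20], genes[20:40]
        W = pd.DataFrame(np.zeros((60, 2)), index=genes)
        W.iloc[:20, 0] = 1.0
        W.iloc[20:40, 1] = 1.0
        expr = {}
        for s in ("S1", "S2"):
            X = rng.gamma(1.0, 0.3, size=(60, 80))
            cells_a = np.arange(40)
            X[np.ix_(np.arange(20), cells_a)] += 2.0        # program A cells
            X[np.ix_(np.arange(20, 40), np.arange(40, 80))] += 2.0  # program B
            expr[s] = pd.DataFrame(X, index=genes)
        sigs = [
            self._signature("S1", 0, set_a), self._signature("S1", 1, set_b),
            self._signature("S2", 0, set_a), self._signature("S2", 1, set_b),
        ]
        W_by = {"S1": W, "S2": W}
        out = meta_programs(sigs, expr, W_by, seed=0)
        assert len(out) == 2
        for mp in out:
            assert {s for s, _ in mp.members} == {"S1", "S2"}

    def test_low_coverage_cluster_dropped(self, rng):
        genes = [f"g{i}" for i in range(90)]
        sets = [genes[:20], genes[30:50], genes[60:80]]
        expr = {}
        for si, s in enumerate(("S1", "S2", "S3")):
            X = rng.gamma(1.0, 0.3, size=(90, 60))
            X[np.ix_(np.arange(0, 20), np.arange(30))] += 2.0
            X[np.ix_(np.arange(30, 50), np.arange(30, 60))] += 2.0
            if s == "S1":  # the third program exists only in sample S1
                X[np.ix_(np.arange(60, 80), np.arange(20, 40))] += 3.0
            expr[s] = pd.DataFrame(X, index=genes)
        W = pd.DataFrame(np.zeros((90, 3)), index=genes)
        W.iloc[0:20, 0] = 1.0
        W.iloc[30:50, 1] = 1.0
        W.iloc[60:80, 2] = 1.0
        sigs = []
        for s in ("S1", "S2", "S3"):
            sigs.append(self._signature(s, 0, sets[0]))
            sigs.append(self._signature(s, 1, sets[1]))
        sigs.append(self._signature("S1", 2, sets[2]))
        W_by = {s: W for s in ("S1", "S2", "S3")}
        out = meta_programs(sigs, expr, W_by, seed=0)
        covered = [mp.samples for mp in out]
        assert all(len(c) >= 2 for c in covered)  # 1-of-3 cluster disregarded

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            meta_programs([], {"S1": pd.DataFrame()}, {}, seed=0)
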