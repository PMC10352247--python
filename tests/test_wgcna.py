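import numpy as np
import pandas as pd
import pytest

from _oracles import naive_tom
from nephrotalk import wgcna
from nephrotalk.cluster import ClusterLabeling
from test_cluster import make_norm


def labeled_norm(values, conditions, clusters):
    norm = make_norm(values, conditions=conditions)
    labels = ClusterLabeling(
        cell_to_cluster=pd.Series(
            clusters, index=pd.Index(norm.cell_ids, name="cell_id"), dtype=int
        )
    )
    return norm, labels


class TestPseudocells:
    def test_group_size_one_identity(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 2, size=(8, 4))
        norm, labels = labeled_norm(X, ["control"] * 4 + ["case"] * 4, [0] * 8)
        obs = wgcna.aggregate_pseudocells(norm, labels, group_size=1, seed=0)
        assert obs.shape == (8, 4)
        rows = {tuple(np.round(r, 12)) for r in obs.to_numpy()}
        assert rows == {tuple(np.round(r, 12)) for r in X}

    def test_twenty_cells_group_ten(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 2, size=(20, 3))
        norm, labels = labeled_norm(X, ["control"] * 20, [0] * 20)
        obs = wgcna.aggregate_pseudocells(norm, labels, group_size=10, seed=0)
        assert obs.shape == (2, 3)
        # every cell lands in exactly one of the two observations, so their
        # pooled mean equals the grand mean
        assert np.allclose(obs.to_numpy().mean(axis=0), X.mean(axis=0), atol=1e-9)

    def test_partial_groups_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 2, size=(25, 3))
        norm, labels = labeled_norm(X, ["control"] * 25, [0] * 25)
        obs = wgcna.aggregate_pseudocells(norm, labels, group_size=10, seed=0)
        assert obs.shape[0] == 2

    def test_small_stratum_dropped(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 2, size=(14, 3))
        norm, labels = labeled_norm(X, ["control"] * 14, [0] * 10 + [1] * 4)
        obs = wgcna.aggregate_pseudocells(norm, labels, group_size=10, seed=0)
        assert list(obs.attrs["obs_meta"]["cluster"]) == [0]

    def test_obs_meta_strata(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 2, size=(20, 3))
        norm, labels = labeled_norm(
            X, (["control"] * 5 + ["case"] * 5) * 2, [0] * 10 + [1] * 10
        )
        obs = wgcna.aggregate_pseudocells(norm, labels, group_size=5, seed=0)
        meta = obs.attrs["obs_meta"]
        assert sorted(zip(meta["cluster"], meta["condition"])) == [
            (0, "case"), (0, "control"), (1, "case"), (1, "control")
        ]

    def test_bad_group_size(self):
        rng = np.random.default_rng(5)
        norm, labels = labeled_norm(rng.uniform(size=(4, 2)), ["control"] * 4, [0] * 4)
        with pytest.raises(ValueError, match="group_size"):
            wgcna.aggregate_pseudocells(norm, labels, group_size=0)


class TestSoftThreshold:
    def test_singleton_candidate(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(30, 12)))
        assert wgcna.pick_soft_threshold(expr, candidate_powers=[6]) == 6

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(40, 20)))
        assert wgcna.pick_soft_threshold(expr) == wgcna.pick_soft_threshold(expr)

    def test_scale_free_fit_regression_oracle(self):
        rng = np.random.default_rng(8)
        k = rng.pareto(2.0, size=200) + 0.5
        got = wgcna.scale_free_fit(k, n_bins=10)
        # replicate the equal-width binning and log-log regression by hand
        edges = np.linspace(k.min(), k.max(), 11)
        xs, ys = [], []
        for b in range(10):
            lo, hi = edges[b], edges[b + 1]
            if b < 9:
                members = k[(k >= lo) & (k < hi)]
            else:
                members = k[(k >= lo) & (k <= hi)]
            if members.size < 2:
                continue
            xs.append(np.log10(members.mean()))
            ys.append(np.log10(members.size / k.size))
        slope, intercept = np.polyfit(xs, ys, 1)
        pred = slope * np.array(xs) + intercept
        r2 = 1 - ((np.array(ys) - pred) ** 2).sum() / (
            (np.array(ys) - np.mean(ys)) ** 2
        ).sum()
        assert got == pytest.approx(-np.sign(slope) * r2, abs=1e-9)

    def test_scale_free_fit_degenerate(self):
        assert wgcna.scale_free_fit(np.array([2.0, 2.0, 2.0])) == 0.0
        assert wgcna.scale_free_fit(np.array([0.0])) == 0.0

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            wgcna.pick_soft_threshold(pd.DataFrame([[1.0, 2.0]]))


class TestAdjacency:
    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 10)
        expr = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": -x})
        A = wgcna.adjacency(expr, beta=6)
        assert A.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)
        assert A.loc["a", "c"] == pytest.approx(1.0, abs=1e-12)

    def test_power_arithmetic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 6))
        expr = pd.DataFrame(X, columns=list("abcdef"))
        A6 = wgcna.adjacency(expr, beta=6).to_numpy()
        C = np.abs(np.corrcoef(X, rowvar=False))
        expect = C**6
        np.fill_diagonal(expect, 1.0)
        assert np.allclose(A6, expect, atol=1e-12)
        # cor 0.5 at beta 6 -> 0.015625
        assert 0.5**6 == 0.015625

    def test_beta_one_is_abs_correlation(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 5))
        A = wgcna.adjacency(pd.DataFrame(X), beta=1).to_numpy()
        C = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(C, 1.0)
        assert np.allclose(A, C, atol=1e-12)

    def test_constant_gene_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="constant gene"):
            wgcna.adjacency(expr, beta=2)

    def test_bad_beta(self):
        with pytest.raises(ValueError, match="beta"):
            wgcna.adjacency(pd.DataFrame({"a": [1.0, 2.0]}), beta=0)


class TestTOM:
    def two_gene(self, a12):
        A = np.array([[1.0, a12], [a12, 1.0]])
        return wgcna.tom_similarity(
            pd.DataFrame(A, index=["a", "b"], columns=["a", "b"])
        )

    def test_two_gene_full_overlap(self):
        assert self.two_gene(1.0).loc["a", "b"] == pytest.approx(1.0)

    def test_two_gene_no_overlap(self):
        assert self.two_gene(0.0).loc["a", "b"] == pytest.approx(0.0)

    def test_triple_loop_oracle_8_genes(self):
        rng = np.random.default_rng(11)
        C = rng.uniform(0, 1, size=(8, 8))
        A = (C + C.T) / 2
        np.fill_diagonal(A, 1.0)
        T = wgcna.tom_similarity(pd.DataFrame(A)).to_numpy()
        assert np.allclose(T, naive_tom(A), atol=1e-10)

    def test_bounds_symmetry_diag_random_fixtures(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 10))
            A = wgcna.adjacency(pd.DataFrame(X), beta=4)
            T = wgcna.tom_similarity(A).to_numpy()
            assert np.allclose(T, T.T, atol=1e-12)
            assert np.allclose(np.diag(T), 1.0)
            assert T.min() >= 0.0 and T.max() <= 1.0


def block_expression(seed=0, sizes=(40, 40), n_obs=60, within=0.9):
    """Observations x genes with planted correlated blocks."""
    rng = np.random.default_rng(seed)
    cols = {}
    truth = {}
    noise_sd = np.sqrt(1 / within**2 - 1)
    for b, size in enumerate(sizes):
        latent = rng.normal(size=n_obs)
        for j in range(size):
            cols[f"B{b}G{j}"] = latent + rng.normal(0, noise_sd, size=n_obs)
            truth[f"B{b}G{j}"] = b
    return pd.DataFrame(cols), truth


class TestModules:
    def test_two_planted_blocks_recovered(self):
        expr, truth = block_expression()
        T = wgcna.tom_similarity(wgcna.adjacency(expr, beta=6))
        assign, _ = wgcna.detect_modules(T)
        mods = {m for m in assign.values() if m != wgcna.GREY}
        assert len(mods) == 2
        for b in (0, 1):
            labels = {assign[g] for g, blk in truth.items() if blk == b}
            assert len(labels) == 1 and labels != {wgcna.GREY}

    def test_min_size_boundary_all_grey(self):
        expr, _ = block_expression(sizes=(20, 20))
        T = wgcna.tom_similarity(wgcna.adjacency(expr, beta=6))
        assign, _ = wgcna.detect_modules(T, min_module_size=100)
        assert set(assign.values()) == {wgcna.GREY}

    def test_module_ids_ordered_by_size(self):
        expr, _ = block_expression(sizes=(50, 35))
        T = wgcna.tom_similarity(wgcna.adjacency(expr, beta=6))
        assign, _ = wgcna.detect_modules(T)
        sizes = pd.Series(list(assign.values())).value_counts()
        assert sizes["M1"] == 50 and sizes["M2"] == 35

    def test_gene_order_invariance(self):
        expr, _ = block_expression(seed=3)
        T = wgcna.tom_similarity(wgcna.adjacency(expr, beta=6))
        perm = expr.sample(frac=1, axis=1, random_state=5)
        Tp = wgcna.tom_similarity(wgcna.adjacency(perm, beta=6))
        a1, _ = wgcna.detect_modules(T)
        a2, _ = wgcna.detect_modules(Tp)
        parts1 = {
            frozenset(g for g, m in a1.items() if m == mod) for mod in set(a1.values())
        }
        parts2 = {
            frozenset(g for g, m in a2.items() if m == mod) for mod in set(a2.values())
        }
        assert parts1 == parts2


class TestEigengene:
    def test_identical_genes_rank_one(self):
        rng = np.random.default_rng(12)
        profile = rng.normal(size=30)
        expr = pd.DataFrame({f"g{j}": profile for j in range(5)})
        e = wgcna.module_eigengene(expr, list(expr.columns))
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0, abs=1e-12)
        assert np.corrcoef(e, expr.mean(axis=1))[0, 1] >= 0

    def test_pc1_optimality(self):
        rng = np.random.default_rng(13)
        expr = pd.DataFrame(rng.normal(size=(40, 8)))
        expr.columns = [f"g{j}" for j in range(8)]
        e = wgcna.module_eigengene(expr, list(expr.columns))
        X = expr.to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        for _ in range(20):
            u = rng.normal(size=8)
            u /= np.linalg.norm(u)
            assert np.var(e) >= np.var(Z @ u) - 1e-9

    def test_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(14)
        expr = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        e = wgcna.module_eigengene(expr, list("abcdef"))
        X = expr.to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        w, V = np.linalg.eigh(Z.T @ Z)
        v1 = V[:, np.argmax(w)]
        scores = Z @ v1
        if np.corrcoef(scores, X.mean(axis=1))[0, 1] < 0:
            scores = -scores
        assert np.allclose(e.to_numpy(), scores, atol=1e-8)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wgcna.module_eigengene(pd.DataFrame({"a": [1.0, 2.0]}), [])

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            wgcna.module_eigengene(pd.DataFrame({"a": [1.0]}), ["a"])


class TestModuleTrait:
    def test_eigengene_equal_to_trait(self):
        ind = pd.Series([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        eig = pd.DataFrame({"M1": ind})
        traits = pd.DataFrame({"t": ind, "const": 1.0})
        r, p = wgcna.module_trait_correlation(eig, traits)
        assert r.loc["M1", "t"] == pytest.approx(1.0)
        assert p.loc["M1", "t"] < 1e-3
        assert np.isnan(r.loc["M1", "const"])

    def test_orthogonal_trait(self):
        eig = pd.DataFrame({"M1": [1.0, -1.0, 1.0, -1.0]})
        traits = pd.DataFrame({"t": [1.0, 1.0, 0.0, 0.0]})
        r, _ = wgcna.module_trait_correlation(eig, traits)
        assert r.loc["M1", "t"] == pytest.approx(0.0, abs=1e-9)

    def test_trait_indicators(self):
        meta = pd.DataFrame(
            {"cluster": [0, 0, 1], "condition": ["case", "control", "case"]},
            index=pd.Index(["a", "b", "c"], name="obs"),
        )
        ind = wgcna.trait_indicators(meta)
        assert ind.loc["a", "cluster0_case"] == 1.0
        assert ind.loc["b", "cluster0_case"] == 0.0
        assert ind.to_numpy().sum() == 3.0  # each obs in exactly one trait


class TestHubs:
    def test_brute_force_sort(self):
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(
            rng.normal(size=(30, 12)), columns=[f"g{j:02d}" for j in range(12)]
        )
        e = wgcna.module_eigengene(expr, list(expr.columns))
        ranking = wgcna.hub_genes(expr, e, list(expr.columns), top_k=5)
        kme = {g: float(np.corrcoef(expr[g], e)[0, 1]) for g in expr.columns}
        expect = sorted(kme.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        assert [g for g, _ in ranking.genes] == [g for g, _ in expect]
        for (g1, v1), (g2, v2) in zip(ranking.genes, expect):
            assert v1 == pytest.approx(v2, abs=1e-12)

    def test_truncation_bound(self):
        rng = np.random.default_rng(16)
        expr = pd.DataFrame(rng.normal(size=(20, 10)))
        expr.columns = [f"g{j}" for j in range(10)]
        e = wgcna.module_eigengene(expr, list(expr.columns))
        ranking = wgcna.hub_genes(expr, e, list(expr.columns), top_k=25)
        assert len(ranking.genes) == 10

    def test_default_top_k_is_25(self):
        assert wgcna.DEFAULT_TOP_K_HUBS == 25


class TestRunModuleAnalysis:
    def test_end_to_end_contracts(self):
        expr, _ = block_expression(seed=18, sizes=(35, 35), n_obs=80)
        rng = np.random.default_rng(17)
        bg = pd.DataFrame(
            rng.normal(size=(80, 30)), columns=[f"bg{j}" for j in range(30)]
        )
        X = pd.concat([expr, bg], axis=1).to_numpy()
        X = X - X.min() + 0.01
        conds = (["control"] * 20 + ["case"] * 20) * 2
        clusters = [0] * 40 + [1] * 40
        norm, labels = labeled_norm(X, conds, clusters)
        norm.gene_ids = list(expr.columns) + list(bg.columns)
        ms, used = wgcna.run_module_analysis(norm, labels, group_size=2, seed=0)
        # every gene mapped, eigengene contracts hold
        assert set(ms.gene_to_module) == set(norm.gene_ids)
        for m in ms.modules:
            genes = ms.genes_of(m)
            assert len(genes) >= wgcna.DEFAULT_MIN_MODULE_SIZE
            e = ms.eigengenes[m]
            assert np.corrcoef(e, used[genes].mean(axis=1))[0, 1] >= 0
        assert ms.module_trait_r.abs().max().max() <= 1.0 + 1e-12
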