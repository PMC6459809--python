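"""Network construction: similarity, soft threshold, TOM, module
detection, eigengenes, connectivity and hub-module scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import braincoex as bc
from braincoex.network import (GREY, adjacency, detect_modules,
                               hub_module_scores,
                               intramodular_connectivity_and_hubs,
                               module_eigengene, pick_soft_threshold,
                               scale_free_fit_index, signed_similarity,
                               topological_overlap)


def random_similarity(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 20))
    return signed_similarity(pd.DataFrame(
        x, index=[f"g{i}" for i in range(n)]))


def block_expression(sizes, loading, noise_sd, n_samples, seed,
                     n_background=0) -> tuple[pd.DataFrame, pd.Series]:
    """Planted latent-factor blocks plus optional background noise genes."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b, size in enumerate(sizes):
        f = rng.standard_normal(n_samples)
        rows.append(loading * f
                    + noise_sd * rng.standard_normal((size, n_samples)))
        labels += [f"block{b}"] * size
    if n_background:
        rows.append(rng.standard_normal((n_background, n_samples)))
        labels += ["background"] * n_background
    x = np.vstack(rows)
    genes = [f"g{i:04d}" for i in range(x.shape[0])]
    return (pd.DataFrame(x, index=genes),
            pd.Series(labels, index=genes))


class TestSignedSimilarity:
    def test_perfect_correlation_bounds(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 4.0, 6.0, 8.0],       # cor +1
                      [4.0, 3.0, 2.0, 1.0]])      # cor -1 with row 0
        s = signed_similarity(pd.DataFrame(x))
        assert s.iloc[0, 1] == pytest.approx(1.0)
        assert s.iloc[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_adjacency_at_beta_12(self):
        s = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        a = adjacency(s, 12)
        assert a.iloc[0, 1] == pytest.approx(2.4414e-4, rel=1e-3)
        assert a.iloc[0, 0] == 1.0

    def test_zero_variance_gene_gets_half_similarity(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = signed_similarity(pd.DataFrame(x))
        assert s.iloc[0, 1] == pytest.approx(0.5)

    def test_mask_aware_pairwise_complete(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 10))
        df = pd.DataFrame(x)
        df.iloc[0, 0] = np.nan
        s = signed_similarity(df)
        expected = (1 + np.corrcoef(x[0, 1:], x[1, 1:])[0, 1]) / 2
        assert s.iloc[0, 1] == pytest.approx(expected)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="3 samples"):
            signed_similarity(pd.DataFrame(np.zeros((3, 2))))


class TestSoftThreshold:
    def _power_law_similarity(self, beta, n=400, seed=0):
        # construct S so that S^beta has connectivity ~ a planted
        # power-law degree sequence
        rng = np.random.default_rng(seed)
        k = rng.pareto(1.5, size=n) + 1.0
        k = np.clip(k, None, n / 4)
        w = np.outer(k, k) / k.sum()
        np.fill_diagonal(w, 0.0)
        w = np.clip(w, 1e-12, 0.999)
        s = np.power(w, 1.0 / beta)
        np.fill_diagonal(s, 1.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(s, index=genes, columns=genes)

    def test_planted_power_law_reaches_high_fit_at_matching_beta(self):
        s = self._power_law_similarity(beta=6)
        a = np.power(s.to_numpy(), 6)
        np.fill_diagonal(a, 0.0)
        idx, slope = scale_free_fit_index(a.sum(axis=1))
        assert idx > 0.8  # clears the default scale-free target
        assert slope < 0

    def test_picks_a_beta_reaching_target_on_power_law(self):
        s = self._power_law_similarity(beta=6)
        res = pick_soft_threshold(s, candidate_betas=(2, 4, 6, 8),
                                  target_r2=0.8)
        assert res.reached_target
        assert res.fit_table.loc[
            res.fit_table["beta"] == res.beta, "fit_index"].iloc[0] >= 0.8

    def test_falls_back_near_argmax_with_warning(self):
        s = random_similarity(60, seed=1)
        with pytest.warns(UserWarning, match="no candidate beta"):
            res = pick_soft_threshold(s, candidate_betas=(2, 4),
                                      target_r2=0.999)
        assert not res.reached_target
        best = res.fit_table["fit_index"].max()
        chosen = res.fit_table.loc[
            res.fit_table["beta"] == res.beta, "fit_index"].iloc[0]
        assert chosen >= best - 0.1  # largest beta on the near-max plateau
        plateau = res.fit_table[res.fit_table["fit_index"] >= best - 0.1]
        assert res.beta == plateau["beta"].max()

    def test_single_candidate_returned_unconditionally(self):
        s = random_similarity(40, seed=2)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pick_soft_threshold(s, candidate_betas=(12,))
        assert res.beta == 12
        assert len(res.fit_table) == 1

    def test_constant_connectivity_raises(self):
        with pytest.raises(ValueError, match="constant"):
            scale_free_fit_index(np.full(50, 3.0))

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(random_similarity(10, 0), candidate_betas=())


class TestTopologicalOverlap:
    def test_three_clique_is_all_ones(self):
        a = pd.DataFrame(np.ones((3, 3)))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom.to_numpy(), 1.0)

    def test_identity_adjacency_gives_zero_overlap(self):
        tom = topological_overlap(pd.DataFrame(np.eye(4)))
        off = tom.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetric_and_bounded_on_random_adjacency(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(pd.DataFrame(a))

    def test_hand_computed_chain(self):
        # path graph 0-1-2 with weight w: l_02 = w^2,
        # TOM_02 = (w^2 + 0)/(w + 1 - 0)
        w = 0.6
        a = np.eye(3)
        a[0, 1] = a[1, 0] = w
        a[1, 2] = a[2, 1] = w
        tom = topological_overlap(pd.DataFrame(a))
        assert tom.iloc[0, 2] == pytest.approx(w * w / (w + 1.0))


class TestDetectModules:
    def test_two_perfect_blocks_exactly_recovered(self):
        expr, truth = block_expression([100, 100], loading=0.95,
                                       noise_sd=0.2, n_samples=60, seed=0)
        net = bc.build_network(expr, beta=12, min_module_size=80)
        labels = net.labels
        assert (labels == GREY).sum() == 0
        assert set(labels.unique()) == {"turquoise", "blue"}
        # each detected module is exactly one planted block
        for color in ("turquoise", "blue"):
            blocks = truth[labels.index[labels == color]].unique()
            assert len(blocks) == 1

    def test_block_below_minimum_size_goes_grey(self):
        # study-like coexpression strength (within-module correlation 0.64)
        expr, truth = block_expression([50], loading=0.8, noise_sd=0.6,
                                       n_samples=168, seed=1,
                                       n_background=150)
        net = bc.build_network(expr, beta=12, min_module_size=80)
        block_genes = truth.index[truth == "block0"]
        assert (net.labels[block_genes] == GREY).all()

    def test_pure_noise_is_mostly_grey(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(300, 50)),
                            index=[f"g{i}" for i in range(300)])
        net = bc.build_network(expr, beta=12, min_module_size=30)
        assert (net.labels == GREY).mean() >= 0.9

    def test_min_size_above_gene_count_warns_all_grey(self):
        expr, _ = block_expression([40], 0.9, 0.3, 30, seed=3)
        s = signed_similarity(expr)
        tom = topological_overlap(adjacency(s, 12))
        with pytest.warns(UserWarning, match="grey"):
            det = detect_modules(tom, min_module_size=100)
        assert (det.labels == GREY).all()

    def test_deterministic(self, benchmark_network):
        tom = benchmark_network["tom"]
        det1 = detect_modules(tom)
        det2 = detect_modules(tom)
        pd.testing.assert_series_equal(det1.labels, det2.labels)

    def test_color_names_follow_size_ranking(self):
        expr, _ = block_expression([120, 90], loading=0.95, noise_sd=0.2,
                                   n_samples=60, seed=4)
        net = bc.build_network(expr, beta=12, min_module_size=80)
        sizes = net.detection.module_sizes()
        assert sizes.index[0] == "turquoise" and sizes.iloc[0] == 120
        assert sizes.index[1] == "blue" and sizes.iloc[1] == 90


class TestEigengene:
    def test_identical_profiles_fully_explained(self):
        x = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (5, 1))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(5)])
        labels = pd.Series("turquoise", index=expr.index)
        eig, ve = module_eigengene(expr, labels)
        assert ve["turquoise"] == pytest.approx(1.0)
        zx = (x[0] - x[0].mean()) / x[0].std()
        e = eig.loc["turquoise"].to_numpy()
        np.testing.assert_allclose(e / np.linalg.norm(e),
                                   zx / np.linalg.norm(zx), atol=1e-10)

    def test_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(30, 12)),
                            index=[f"g{i}" for i in range(30)])
        labels = pd.Series(["turquoise"] * 15 + ["blue"] * 15,
                           index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        for color in ("turquoise", "blue"):
            e = eig.loc[color].to_numpy()
            assert np.linalg.norm(e) == pytest.approx(1.0)
            sub = expr.loc[labels == color].to_numpy()
            z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
            assert np.corrcoef(e, z.mean(0))[0, 1] >= 0

    def test_latent_factor_recovered(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(100)
        expr = pd.DataFrame(0.8 * f + 0.6 * rng.normal(size=(40, 100)),
                            index=[f"g{i}" for i in range(40)])
        labels = pd.Series("turquoise", index=expr.index)
        eig, _ = module_eigengene(expr, labels)
        assert abs(np.corrcoef(eig.loc["turquoise"], f)[0, 1]) > 0.9


class TestConnectivityAndHubs:
    def _uniform_module(self, n, a_val):
        a = np.full((n, n), a_val)
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=genes, columns=genes)
        labels = pd.Series("turquoise", index=genes)
        return adj, labels

    def test_uniform_five_gene_module(self):
        adj, labels = self._uniform_module(5, 0.5)
        kin, hubs = intramodular_connectivity_and_hubs(adj, labels, 0.2)
        np.testing.assert_allclose(kin, 2.0)
        assert hubs["turquoise"] == ["g0"]  # ceil(1) hub, lexicographic tie

    def test_isolated_gene_zero_kin(self):
        adj, labels = self._uniform_module(4, 0.0)
        kin, _ = intramodular_connectivity_and_hubs(adj, labels)
        np.testing.assert_allclose(kin, 0.0)

    def test_hub_count_ceiling(self):
        adj, labels = self._uniform_module(10, 0.3)
        _, hubs = intramodular_connectivity_and_hubs(adj, labels, 0.2)
        assert len(hubs["turquoise"]) == 2

    def test_misaligned_labels_rejected(self):
        adj, labels = self._uniform_module(4, 0.5)
        with pytest.raises(ValueError, match="align"):
            intramodular_connectivity_and_hubs(adj, labels.iloc[::-1])


class TestHubModuleScores:
    def _two_block_adjacency(self, cross=0.0, seed=0):
        rng = np.random.default_rng(seed)
        n = 40
        a = np.zeros((n, n))
        a[:20, :20] = rng.uniform(0.5, 0.9, (20, 20))
        a[20:, 20:] = rng.uniform(0.5, 0.9, (20, 20))
        a[:20, 20:] = cross
        a = np.triu(a, 1)
        a = a + a.T
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        labels = pd.Series(["turquoise"] * 20 + ["blue"] * 20, index=genes)
        return pd.DataFrame(a, index=genes, columns=genes), labels

    def test_disconnected_modules_score_zero(self):
        adj, labels = self._two_block_adjacency(cross=0.0)
        scores = hub_module_scores(adj, labels, edge_density=0.2)
        assert (scores["score_all"] == 0).all()

    def test_size_normalization_is_invariant_to_duplication(self):
        adj, labels = self._two_block_adjacency(cross=0.0, seed=1)
        # add a third module bridging both blocks
        rng = np.random.default_rng(2)
        extra = rng.uniform(0.92, 0.99, size=(10, 40))
        block = rng.uniform(0.92, 0.99, size=(10, 10))
        n = 50
        a = np.zeros((n, n))
        a[:40, :40] = adj.to_numpy()
        a[40:, :40] = extra
        a[:40, 40:] = extra.T
        a[40:, 40:] = (block + block.T) / 2
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        labels = pd.Series(["turquoise"] * 20 + ["blue"] * 20
                           + ["brown"] * 10, index=genes)
        adj3 = pd.DataFrame(a, index=genes, columns=genes)
        scores = hub_module_scores(adj3, labels, edge_density=0.3)
        assert scores.index[0] == "brown"
        assert bool(scores.loc["brown", "is_hub_module"])

    def test_degenerate_threshold_raises(self):
        n = 10
        a = np.full((n, n), 0.5)
        np.fill_diagonal(a, 1.0)
        genes = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=genes, columns=genes)
        labels = pd.Series(["turquoise"] * 5 + ["blue"] * 5, index=genes)
        with pytest.raises(ValueError, match="equal"):
            hub_module_scores(adj, labels)

    def test_needs_two_modules(self):
        adj, labels = self._two_block_adjacency()
        with pytest.raises(ValueError, match="two"):
            hub_module_scores(adj, pd.Series("turquoise",
                                             index=labels.index))


class TestInvariants:
    def test_beta_monotonicity(self):
        s = random_similarity(30, seed=5)
        offdiag = ~np.eye(30, dtype=bool)
        prev = adjacency(s, 2).to_numpy()
        for beta in (4, 8, 16):
            cur = adjacency(s, beta).to_numpy()
            assert (cur[offdiag] <= prev[offdiag] + 1e-15).all()
            prev = cur

    def test_similarity_adjacency_tom_bounds(self, benchmark_network):
        for key in ("similarity", "adjacency", "tom"):
            m = benchmark_network[key].to_numpy()
            assert np.allclose(m, m.T)
            assert m.min() >= 0.0 and m.max() <= 1.0
            assert np.allclose(np.diag(m), 1.0)
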