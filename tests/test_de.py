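"""Differential expression: moderated t, hyperparameter estimation,
chi-square excess-DEG test, BH FDR and t-value clustering."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import braincoex as bc
from braincoex.de import (bh_fdr, cluster_t_values, degs_vs_chance,
                          estimate_prior, moderated_t_test,
                          trigamma_inverse)
from conftest import two_group_dataset


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_i = min over p_(j) >= p_(i) of
    min(1, n p_(j) / j)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, n * p[i] / (rank + 1))
        q[i] = running
    return np.minimum(q, 1.0)


class TestModeratedT:
    def test_pooled_t_hand_example_with_zero_prior_df(self):
        # (1,2,3) vs (4,5,6): pooled t = -3.674 on 4 df, p ~ 0.0213
        ds = two_group_dataset(np.array([[1.0, 2.0, 3.0]]),
                               np.array([[4.0, 5.0, 6.0]]))
        res = moderated_t_test(ds, "R", prior_df=0)
        row = res.table.iloc[0]
        assert row["moderated_t"] == pytest.approx(-3.674, abs=1e-3)
        assert row["df"] == 4
        assert row["p"] == pytest.approx(0.0213, abs=1e-3)
        assert row["direction"] == "down"

    def test_identical_groups_give_t_zero_p_one(self):
        x = np.tile(np.array([[1.0, 2.0, 5.0]]), (3, 1))
        ds = two_group_dataset(x, x.copy())
        res = moderated_t_test(ds, "R")
        assert np.allclose(res.table["moderated_t"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_zero_prior_df_reproduces_ordinary_t(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=(1000, 8))
        x2 = rng.normal(size=(1000, 8))
        ds = two_group_dataset(x1, x2)
        res = moderated_t_test(ds, "R", prior_df=0)
        t = res.table["moderated_t"].to_numpy()
        ref = stats.ttest_ind(x1, x2, axis=1).statistic
        np.testing.assert_allclose(t, ref, rtol=1e-10)
        np.testing.assert_allclose(res.table["ordinary_t"], ref, rtol=1e-10)

    def test_infinite_prior_df_gives_z_statistic_with_prior_sd(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=(200, 6)), rng.normal(size=(200, 6))
        ds = two_group_dataset(x1, x2)
        res = moderated_t_test(ds, "R", prior_df=np.inf)
        delta = x1.mean(axis=1) - x2.mean(axis=1)
        expected = delta / np.sqrt(res.prior_variance * (2 / 6))
        np.testing.assert_allclose(res.table["moderated_t"], expected,
                                   rtol=1e-10)
        assert np.isinf(res.table["df"]).all()

    def test_shared_variance_makes_prior_df_large_and_ranks_agree(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(0, 0.7, size=(5000, 12))
        x2 = rng.normal(0, 0.7, size=(5000, 12))
        ds = two_group_dataset(x1, x2)
        res = moderated_t_test(ds, "R")
        assert res.prior_df > 50  # single true variance -> heavy shrinkage
        rho = stats.spearmanr(np.abs(res.table["moderated_t"]),
                              np.abs(res.table["ordinary_t"])).statistic
        assert rho > 0.97  # per-gene s_g sampling noise perturbs near-ties

    def test_sign_of_t_matches_sign_of_delta(self):
        rng = np.random.default_rng(3)
        ds = two_group_dataset(rng.normal(size=(300, 5)),
                               rng.normal(size=(300, 5)))
        res = moderated_t_test(ds, "R")
        t = res.table["moderated_t"]
        assert (np.sign(t) == np.sign(res.table["delta"])).all()

    def test_masked_values_adjust_degrees_of_freedom(self):
        rng = np.random.default_rng(4)
        ds = two_group_dataset(rng.normal(size=(10, 6)),
                               rng.normal(size=(10, 6)))
        mask = pd.DataFrame(False, index=ds.genes, columns=ds.samples)
        mask.iloc[0, 0] = True
        res = moderated_t_test(ds.with_mask(mask), "R", prior_df=0)
        assert res.table["df"].iloc[0] == 9   # 11 values, 2 groups
        assert res.table["df"].iloc[1] == 10

    def test_small_group_raises(self):
        ds = two_group_dataset(np.zeros((3, 1)), np.zeros((3, 4)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t_test(ds, "R")

    def test_fold_change_convention(self):
        ds = two_group_dataset(np.array([[3.0, 3.0], [1.0, 1.0]]),
                               np.array([[1.0, 1.0], [3.0, 3.0]]))
        res = moderated_t_test(ds, "R", prior_df=0)
        fc = res.table["fold_change"]
        assert fc.iloc[0] == pytest.approx(4.0)    # delta +2 -> FC 4
        assert fc.iloc[1] == pytest.approx(-4.0)   # delta -2 -> FC -4

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        rng = np.random.default_rng(5)
        sd = np.exp(rng.normal(-0.5, 0.5, 300))[:, None]
        x = rng.normal(0, 1, (300, 12)) * sd
        x[:20, :6] += 1.0
        ds = two_group_dataset(x[:, :6], x[:, 6:])
        res = moderated_t_test(ds, "R")
        ds.values.to_csv(tmp_path / "x.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1))\n'
            'design <- cbind(1, c(rep(1,6), rep(0,6)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n'
            '                  d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path}/r.tsv", sep="\\t", quote=FALSE)\n')
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert res.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert res.prior_variance == pytest.approx(ref["s02"].iloc[0],
                                                   rel=1e-6)
        np.testing.assert_allclose(res.table["moderated_t"], ref["t"],
                                   rtol=1e-8)
        np.testing.assert_allclose(res.table["p"], ref["p"], rtol=1e-8)


class TestPriorEstimation:
    def test_trigamma_inverse_round_trip(self):
        from scipy import special
        for x in (0.1, 0.5, 1.0, 5.0, 50.0):
            y = special.polygamma(1, x)
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_homogeneous_variances_give_infinite_prior(self):
        # variance spread below sampling noise -> d0 = inf branch
        df = np.full(500, 10.0)
        s2 = np.full(500, 0.25)
        d0, s0 = estimate_prior(s2, df)
        assert np.isinf(d0)
        assert s0 > 0


class TestChiSquare:
    def test_observed_equals_expected(self):
        stat, p = degs_vs_chance(500, 10_000, alpha=0.05)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_excess_degs(self):
        stat, p = degs_vs_chance(1000, 10_000, alpha=0.05)
        assert stat == pytest.approx(526.32, abs=0.01)
        assert p < 1e-100

    def test_deficit_degs(self):
        stat, _ = degs_vs_chance(0, 1000, alpha=0.05)
        assert stat == pytest.approx(52.63, abs=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            degs_vs_chance(1, 0)
        with pytest.raises(ValueError):
            degs_vs_chance(11, 10)


class TestBHFDR:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert bh_fdr([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    def test_matches_brute_force_step_up_exactly(self, pvals):
        p = np.asarray(pvals)
        np.testing.assert_array_equal(bh_fdr(p), brute_force_bh(p))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        np.testing.assert_allclose(bh_fdr(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)


class TestClusterTValues:
    def test_two_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 0.2, size=(30, 4))
        b = rng.normal(-5, 0.2, size=(30, 4))
        tm = pd.DataFrame(np.vstack([a, b]),
                          index=[f"g{i}" for i in range(60)])
        labels, centers = cluster_t_values(tm, k=2, seed=0)
        assert len(set(labels.iloc[:30])) == 1
        assert len(set(labels.iloc[30:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_equals_one(self):
        tm = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 3)))
        labels, _ = cluster_t_values(tm, k=1, seed=0)
        assert set(labels) == {0}

    def test_duplicate_rows_co_clustered(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 3))
        tm = pd.DataFrame(np.vstack([base, base[0:1]]),
                          index=[f"g{i}" for i in range(9)])
        labels, _ = cluster_t_values(tm, k=3, seed=0)
        assert labels.loc["g0"] == labels.loc["g8"]

    def test_fewer_rows_than_k_raises(self):
        tm = pd.DataFrame(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="rows"):
            cluster_t_values(tm, k=5)

    def test_significance_prefilter(self):
        rng = np.random.default_rng(3)
        ds = two_group_dataset(rng.normal(size=(100, 12)),
                               rng.normal(size=(100, 12)))
        res = {"R": moderated_t_test(ds, "R")}
        tm = bc.t_value_matrix(res)
        sig = set(res["R"].table.index[res["R"].table["p"] < 0.5])
        labels, _ = cluster_t_values(tm, results=res, k=1, p_cut=0.5, seed=0)
        assert set(labels.index) == sig
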