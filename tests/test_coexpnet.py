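"""Co-expression networks: adjacency, TOM, modules, eigengenes, preservation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pcdnet.coexpnet import (ModuleAssignment, adjacency, center_within_groups,
                             detect_modules, module_eigengene,
                             module_preservation, pick_soft_threshold, tom,
                             wgcna_input_filter)
from tests.conftest import factor_expression


def exact_cor_pair(rho):
    """Two 4-sample genes with exactly the requested Pearson correlation."""
    x = np.array([1.0, -1.0, 1.0, -1.0])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    g2 = rho * x + np.sqrt(1 - rho ** 2) * y
    return pd.DataFrame([x, g2], index=["a", "b"])


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        expr = exact_cor_pair(1.0 - 1e-15)
        for mode in ("signed", "unsigned"):
            assert adjacency(expr, 6, mode).loc["a", "b"] == pytest.approx(1.0)

    def test_perfect_anticorrelation_signed_gives_zero(self):
        expr = exact_cor_pair(-1.0 + 1e-15)
        assert adjacency(expr, 6, "signed").loc["a", "b"] == pytest.approx(
            0.0, abs=1e-12)

    def test_half_correlation_signed_power_six(self):
        expr = exact_cor_pair(0.5)
        # ((1 + 0.5)/2)^6
        assert adjacency(expr, 6, "signed").loc["a", "b"] == pytest.approx(
            0.177978515625, abs=1e-12)

    def test_zero_variance_gene_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                            index=["flat", "ok"])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(expr, 6)

    def test_bounds_symmetry_unit_diagonal(self):
        expr = factor_expression(30, 12, range(10), 1.0, 0.5, seed=5)
        a = adjacency(expr, 6).values
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1
        assert np.allclose(np.diag(a), 1.0)


def tom_naive(a):
    """O(n^3) double-loop reference implementation."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u != i and u != j)
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    def test_complete_graph_is_all_ones(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                         columns=list("abc"))
        assert np.allclose(tom(a).values, 1.0)

    def test_empty_graph_has_zero_overlap(self):
        a = pd.DataFrame(np.eye(4))
        t = tom(a).values
        assert np.allclose(t[~np.eye(4, dtype=bool)], 0.0)

    @pytest.mark.parametrize("n", [4, 17, 50])
    def test_matches_naive_oracle(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        got = tom(pd.DataFrame(a)).values
        expected = tom_naive(a)
        assert np.abs(got - expected).max() < 1e-12

    def test_asymmetric_rejected(self):
        a = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom(a)


class TestDetectModules:
    @staticmethod
    def _two_blocks(seed, n_block=100, n_noise=300, rho=0.8):
        """Two independent factor blocks at within-correlation ~rho."""
        rng = np.random.default_rng(seed)
        n = 2 * n_block + n_noise
        s = 60
        lam = np.sqrt(rho / (1 - rho))  # loading so cor = lam^2/(lam^2+1)
        x = rng.normal(0, 1, (n, s))
        for b in range(2):
            f = rng.normal(0, 1, s)
            rows = slice(b * n_block, (b + 1) * n_block)
            x[rows] += lam * f
        labels = np.array([1] * n_block + [2] * n_block + [0] * n_noise)
        return pd.DataFrame(x, index=[f"g{i:04d}" for i in range(n)]), labels

    def test_recovers_planted_partition(self):
        # cut below the background-overlap level so noise stays unassigned
        aris = []
        for seed in range(10):
            expr, truth = self._two_blocks(seed)
            dis = 1 - tom(adjacency(expr, 12))
            mods = detect_modules(dis, expr, cut_height=0.9)
            found = pd.Categorical(mods.labels).codes
            aris.append(adjusted_rand_score(truth, found))
            assert len(mods.modules()) == 2
        assert np.mean(aris) > 0.9

    def test_pure_noise_leaves_all_unassigned(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (200, 30)),
                            index=[f"g{i}" for i in range(200)])
        mods = detect_modules(1 - tom(adjacency(expr, 12)), expr,
                              cut_height=0.98)
        assert mods.modules() == []
        assert (mods.labels == "unassigned").all()

    def test_correlated_subblocks_are_merged(self):
        # one factor split into two half-modules sharing most variance:
        # eigengene correlation ~0.9 > 1 - merge_height
        rng = np.random.default_rng(1)
        s = 60
        shared = rng.normal(0, 1, s)
        x = rng.normal(0, 0.35, (120, s))
        x[:60] += shared + 0.25 * rng.normal(0, 1, s)
        x[60:120] += shared + 0.25 * rng.normal(0, 1, s)
        expr = pd.DataFrame(np.vstack([x, rng.normal(0, 1, (200, s))]),
                            index=[f"g{i:04d}" for i in range(320)])
        mods = detect_modules(1 - tom(adjacency(expr, 12)), expr,
                              cut_height=0.98, merge_height=0.25)
        labels = {mods.labels[f"g{i:04d}"] for i in range(120)}
        assert len(labels) == 1 and labels != {"unassigned"}

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="min_size"):
            detect_modules(pd.DataFrame(np.zeros((3, 3))), min_size=1)

    def test_deterministic(self):
        expr, _ = self._two_blocks(3)
        dis = 1 - tom(adjacency(expr, 12))
        a = detect_modules(dis, expr, cut_height=0.98)
        b = detect_modules(dis, expr, cut_height=0.98)
        pd.testing.assert_series_equal(a.labels, b.labels)


class TestEigengene:
    def test_single_gene_module_is_its_profile(self):
        expr = factor_expression(5, 20, [], 0, 1.0, seed=2)
        e = module_eigengene(expr, ["g0001"])
        prof = expr.loc["g0001"]
        z = (prof - prof.mean()) / prof.std()
        cor = np.corrcoef(e, z)[0, 1]
        assert abs(cor) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_two_identical_genes(self):
        rng = np.random.default_rng(3)
        prof = rng.normal(0, 1, 15)
        expr = pd.DataFrame([prof, prof], index=["a", "b"])
        e = module_eigengene(expr, ["a", "b"])
        assert np.corrcoef(e, prof)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(4)
        f = rng.normal(0, 1, 50)
        x = 1.0 * f + rng.normal(0, 0.3, (10, 50))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(10)])
        e = module_eigengene(expr, list(expr.index))
        assert abs(np.corrcoef(e, f)[0, 1]) > 0.95

    def test_sign_follows_mean_expression(self):
        expr = factor_expression(20, 30, range(20), 1.0, 0.3, seed=6)
        e = module_eigengene(expr, list(expr.index))
        assert np.corrcoef(e, expr.mean(axis=0))[0, 1] > 0

    def test_empty_module_rejected(self):
        expr = factor_expression(5, 10, [], 0, 1.0, seed=7)
        with pytest.raises(ValueError, match="empty"):
            module_eigengene(expr, [])


class TestSoftThreshold:
    def test_zero_target_returns_smallest_power(self):
        expr = factor_expression(50, 20, range(10), 1.0, 0.5, seed=8)
        assert pick_soft_threshold(expr, r2_target=0.0) == 1

    def test_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(0, 1, (150, 30)),
                            index=[f"g{i}" for i in range(150)])
        with pytest.warns(UserWarning, match="falling back"):
            assert pick_soft_threshold(expr, r2_target=0.95) == 12

    def test_hub_structure_reaches_target_at_moderate_power(self):
        # heavy-tailed loadings give approximately scale-free connectivity
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lead = np.clip((rng.pareto(2.0, 300) + 0.1) / 3, 0.05, 1.2)
            x = np.outer(lead, rng.normal(0, 1, 40)) \
                + rng.normal(0, 1, (300, 40))
            expr = pd.DataFrame(x, index=[f"g{i}" for i in range(300)])
            chosen.append(pick_soft_threshold(expr, r2_target=0.8))
        assert np.median(chosen) <= 8

    def test_too_small_input_rejected(self):
        expr = factor_expression(5, 10, [], 0, 1.0, seed=10)
        with pytest.raises(ValueError, match="genes"):
            pick_soft_threshold(expr)


class TestInputFilterAndCentering:
    def test_read_filter_rule(self):
        counts = pd.DataFrame(
            {"s1": [12, 12, 3], "s2": [11, 9, 3], "s3": [15, 12, 3],
             "s4": [20, 12, 3], "s5": [10, 12, 3]},
            index=["pass", "four_of_five", "low"])
        kept = wgcna_input_filter(counts)
        assert list(kept) == ["pass", "four_of_five"]

    def test_centering_removes_group_means(self):
        expr = factor_expression(10, 8, [], 0, 1.0, seed=11)
        groups = ["a"] * 4 + ["b"] * 4
        out = center_within_groups(expr, groups)
        assert np.allclose(out.iloc[:, :4].mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.iloc[:, 4:].mean(axis=1), 0, atol=1e-12)


class TestPreservation:
    @staticmethod
    def _assignment(universe, members, label="mod"):
        labels = pd.Series("unassigned", index=universe, dtype=object)
        labels[members] = label
        return ModuleAssignment(labels=labels)

    def test_self_preservation_is_strong(self):
        expr = factor_expression(400, 40, range(100), 1.0, 0.5, seed=12)
        mods = self._assignment(expr.index, expr.index[:100])
        rep = module_preservation(expr, expr, mods, n_perm=50, seed=0)
        assert rep.table.loc["mod", "zsummary"] > 10

    def test_random_module_is_not_preserved(self):
        zs = []
        for seed in range(10):
            expr = factor_expression(300, 40, [], 0, 1.0, seed=100 + seed)
            test = factor_expression(300, 40, [], 0, 1.0, seed=200 + seed)
            rng = np.random.default_rng(seed)
            members = expr.index[rng.choice(300, 50, replace=False)]
            mods = self._assignment(expr.index, members)
            rep = module_preservation(expr, test, mods, n_perm=50,
                                      seed=seed)
            zs.append(rep.table.loc["mod", "zsummary"])
        assert -2 < np.mean(zs) < 2

    @staticmethod
    def _hetero_module(n, s, size, scale, seed):
        """Module with heterogeneous loadings (so connectivity is informative)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 0.6, (n, s))
        # loadings are a gene property: identical in every dataset drawn
        lead = scale * np.random.default_rng(77).uniform(0.7, 1.3, size)
        x[:size] += np.outer(lead, rng.normal(0, 1, s))
        return pd.DataFrame(x, index=[f"g{i:04d}" for i in range(n)])

    def test_zsummary_grows_with_module_strength(self):
        means = []
        for scale in (0.3, 0.65, 1.2):
            zs = []
            for seed in range(20):
                ref = self._hetero_module(600, 40, 60, scale, 300 + seed)
                tst = self._hetero_module(600, 40, 60, scale, 900 + seed)
                mods = self._assignment(ref.index, ref.index[:60])
                rep = module_preservation(ref, tst, mods, n_perm=50,
                                          seed=seed)
                zs.append(rep.table.loc["mod", "zsummary"])
            means.append(np.mean(zs))
        assert means[0] < means[1] < means[2]

    def test_zero_permutations_rejected(self):
        expr = factor_expression(50, 10, [], 0, 1.0, seed=13)
        mods = self._assignment(expr.index, expr.index[:10])
        with pytest.raises(ValueError, match="n_perm"):
            module_preservation(expr, expr, mods, n_perm=0)

    def test_module_larger_than_universe_rejected(self):
        expr = factor_expression(50, 10, [], 0, 1.0, seed=14)
        labels = pd.Series("mod", index=[f"x{i}" for i in range(60)],
                           dtype=object)
        with pytest.raises(ValueError):
            module_preservation(
                expr, expr, ModuleAssignment(labels=labels), n_perm=10)
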