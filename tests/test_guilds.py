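"""Guild clustering, IndVal, NB Wald test, dual criterion, ordination."""

import numpy as np
import pandas as pd
import pytest

from guildscan import synthetic as syn
from guildscan.core_io import CountMatrix, GuildscanError, NoStructureError
from guildscan.guilds import (all_pairwise_da, cluster_guilds,
                              define_guild_enzymes, indval,
                              indval_exhaustive, nb_pairwise_da, ordinate)
from guildscan.profiling import ProfileMatrix, percent_of_cazy, stabilize, \
    size_factors


def cm(arr, features=None, genomes=None):
    arr = np.asarray(arr)
    features = features or [f"f{i}" for i in range(arr.shape[0])]
    genomes = genomes or [f"g{j}" for j in range(arr.shape[1])]
    return CountMatrix(counts=pd.DataFrame(arr, index=features,
                                           columns=genomes))


def series(values, index):
    return pd.Series(values, index=index)


class TestClusterGuilds:
    def test_disjoint_blocks_recovered_exactly(self):
        # genomes 0-2 use families 0-1; genomes 3-5 use families 2-3
        arr = np.zeros((4, 6), dtype=int)
        arr[:2, :3] = 5
        arr[2:, 3:] = 7
        labels = cluster_guilds(percent_of_cazy(cm(arr)), 2)
        assert labels.iloc[:3].nunique() == 1
        assert labels.iloc[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_identical_columns_rejected_as_structureless(self):
        arr = np.tile([[3], [5]], (1, 4))
        with pytest.raises(NoStructureError):
            cluster_guilds(percent_of_cazy(cm(arr)), 2)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(GuildscanError):
            cluster_guilds(ProfileMatrix(
                percent=pd.DataFrame([[100.0, 100.0]], index=["f"],
                                     columns=["a", "b"])), 3)

    def test_default_simulation_recovers_labels(self):
        """ARI >= 0.9 against planted guilds across seeds."""
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for seed in range(10):
            m, truth, _ = syn.simulate_cazy_counts(
                syn.GuildSimParams(seed=seed))
            got = cluster_guilds(percent_of_cazy(m), 3)
            aris.append(adjusted_rand_score(truth, got[truth.index]))
        assert np.mean(aris) >= 0.9


class TestIndVal:
    def test_perfect_indicator_scores_100(self):
        arr = np.zeros((1, 9), dtype=int)
        arr[0, :3] = 4  # present in every genome of guild A only
        labels = series(list("AAABBBCCC"), [f"g{j}" for j in range(9)])
        res = indval(cm(arr), labels, n_perm=99, seed=0)
        assert res.table.loc["f0", "indval_A"] == pytest.approx(100.0)
        assert res.table.loc["f0", "best_guild"] == "A"

    def test_uniform_family_scores_one_third(self):
        arr = np.full((1, 9), 5, dtype=int)
        labels = series(list("AAABBBCCC"), [f"g{j}" for j in range(9)])
        res = indval(cm(arr), labels, n_perm=99, seed=0)
        assert res.table.loc["f0", "stat"] == pytest.approx(100 / 3)

    def test_all_zero_family_flagged(self):
        arr = np.array([[0] * 6, [1, 2, 3, 4, 5, 6]])
        labels = series(list("AAABBB"), [f"g{j}" for j in range(6)])
        res = indval(cm(arr), labels, n_perm=99, seed=0)
        assert res.table.loc["f0", "all_zero"]
        assert res.table.loc["f0", "p"] == 1.0
        assert res.table.loc["f0", "stat"] == 0.0

    def test_scaling_one_genome_changes_A_not_B(self):
        """Multiplying one genome's counts changes specificity (A) only;
        occupancy (B) is scale-free."""
        rng = np.random.default_rng(1)
        arr = rng.integers(1, 10, size=(5, 8))
        labels = series(list("AAAABBBB"), [f"g{j}" for j in range(8)])
        r1 = indval(cm(arr), labels, n_perm=99, seed=0)
        arr2 = arr.copy()
        arr2[:, 0] *= 7
        r2 = indval(cm(arr2), labels, n_perm=99, seed=0)
        for g in ("A", "B"):
            pd.testing.assert_series_equal(r1.table[f"B_{g}"],
                                           r2.table[f"B_{g}"])
        assert not np.allclose(r1.table["A_A"], r2.table["A_A"])

    def test_matches_exhaustive_enumeration(self):
        """Statistic identical and permutation p within binomial error of
        the exact enumeration on a small two-group matrix."""
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 12, size=(10, 8))
        labels = series(list("AAAABBBB"), [f"g{j}" for j in range(8)])
        m = cm(arr)
        stat_ex, p_ex = indval_exhaustive(m, labels)
        res = indval(m, labels, n_perm=999, seed=1)
        assert np.allclose(res.table["stat"], stat_ex)
        se = np.sqrt(p_ex * (1 - p_ex) / 999)
        assert (np.abs(res.table["p"] - p_ex)
                <= 4 * se + 2 / 999).all()

    def test_null_pvalues_valid_and_calibrated(self):
        """Permutation p-values under a null matrix are valid (never
        anticonservative at any level) and not degenerate.

        With integer counts the max-indval statistic depends on group
        count sums, which collide heavily across relabellings; the null
        is therefore a coarse lattice and p-values are super-uniform
        (P(p <= a) <= a) rather than exactly uniform — the correct
        behaviour for a discrete permutation test."""
        rng = np.random.default_rng(4)
        arr = rng.poisson(6, size=(200, 12))
        labels = series(list("AAAAAA") + list("BBBBBB"),
                        [f"g{j}" for j in range(12)])
        res = indval(cm(arr), labels, n_perm=999, seed=2)
        p = res.table["p"]
        for a in (0.01, 0.05, 0.1, 0.2, 0.5):
            se = np.sqrt(a * (1 - a) / len(p))
            assert (p <= a).mean() <= a + 3 * se, a
        assert (p <= 0.5).mean() >= 0.25  # not degenerate


class TestNBPairwise:
    def test_antisymmetry_under_pair_swap(self):
        m, labels, _ = syn.simulate_cazy_counts(syn.GuildSimParams(seed=6))
        r12 = nb_pairwise_da(m, labels, ("alpha_glucan", "plant_glycan"))
        r21 = nb_pairwise_da(m, labels, ("plant_glycan", "alpha_glucan"))
        assert np.allclose(r12.table["lfc"], -r21.table["lfc"])
        assert np.allclose(r12.table["p"], r21.table["p"])

    def test_all_zero_family_excluded(self):
        arr = np.vstack([np.zeros(8, dtype=int),
                         np.random.default_rng(0).poisson(5, 8)])
        labels = series(list("AAAABBBB"), [f"g{j}" for j in range(8)])
        res = nb_pairwise_da(cm(arr), labels, ("A", "B"))
        assert res.excluded == ["f0"]
        assert "f0" not in res.table.index

    def test_small_group_rejected(self):
        arr = np.random.default_rng(0).poisson(5, size=(3, 4))
        labels = series(list("AAAB"), [f"g{j}" for j in range(4)])
        with pytest.raises(GuildscanError):
            nb_pairwise_da(cm(arr), labels, ("A", "B"))

    def test_type_one_error_calibrated(self):
        """Null 10+10 at dispersion 0.3: empirical size near nominal."""
        rng = np.random.default_rng(0)
        size = 1 / 0.3
        c = rng.negative_binomial(size, size / (size + 6.0),
                                  size=(200, 20))
        labels = series(["A"] * 10 + ["B"] * 10,
                        [f"g{j}" for j in range(20)])
        res = nb_pairwise_da(cm(c), labels, ("A", "B"))
        assert 0.02 <= (res.table["p"] <= 0.05).mean() <= 0.08


class TestDualCriterion:
    def _toy(self):
        m, labels, defining = syn.simulate_cazy_counts(
            syn.GuildSimParams(seed=1))
        iv = indval(m, labels, n_perm=299, seed=1)
        da = all_pairwise_da(m, labels)
        return m, labels, defining, iv, da

    def test_monotone_in_alpha(self):
        m, labels, _, iv, da = self._toy()
        strict = define_guild_enzymes(iv, da, labels, alpha=0.01)
        loose = define_guild_enzymes(iv, da, labels, alpha=0.05)
        for g in loose.defining:
            assert strict.defining[g] <= loose.defining[g]

    def test_no_false_positive_defining_families(self):
        """Everything retained by the dual criterion was planted."""
        for seed in range(5):
            m, labels, defining = syn.simulate_cazy_counts(
                syn.GuildSimParams(seed=seed))
            iv = indval(m, labels, n_perm=299, seed=seed)
            da = all_pairwise_da(m, labels)
            gd = define_guild_enzymes(iv, da, labels)
            for g, fams in gd.defining.items():
                assert fams <= defining[g], (seed, g, fams - defining[g])

    def test_intersection_excludes_indval_only_families(self):
        """A family with a strong indicator signal but no pairwise
        enrichment against one alternative guild is excluded."""
        # f0: enriched in A vs B but identical A vs C
        arr = np.array([
            [20, 20, 20, 20, 2, 2, 2, 2, 20, 20, 20, 20],
            [9, 8, 9, 10, 9, 8, 10, 9, 9, 8, 10, 9],
        ])
        labels = series(list("AAAABBBBCCCC"),
                        [f"g{j}" for j in range(12)])
        iv = indval(cm(arr), labels, n_perm=299, seed=0)
        da = all_pairwise_da(cm(arr), labels)
        gd = define_guild_enzymes(iv, da, labels, alpha=0.05)
        assert "f0" not in gd.defining["A"]

    def test_missing_pair_rejected(self):
        m, labels, _, iv, da = self._toy()
        da.pop(sorted(da)[0])
        with pytest.raises(GuildscanError):
            define_guild_enzymes(iv, da, labels)


class TestOrdinate:
    def test_separated_clouds_split_on_pc1(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 0.1, (5, 6)),
                       rng.normal(8, 0.1, (5, 6))])
        coords, var = ordinate(pd.DataFrame(x))
        pc1 = coords["PC1"]
        assert (pc1.iloc[:5].max() < pc1.iloc[5:].min()) or \
               (pc1.iloc[5:].max() < pc1.iloc[:5].min())
        assert var.sum() <= 1.0 + 1e-12

    def test_matches_eigendecomposition(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(10, 20)))
        coords, var = ordinate(x)
        c = x.to_numpy() - x.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(c.T @ c)
        order = np.argsort(evals)[::-1]
        expected = np.abs(c @ evecs[:, order[:2]])
        assert np.allclose(np.abs(coords.to_numpy()), expected,
                           atol=1e-8)
        assert np.allclose(var, evals[order[:2]] / evals.sum())

    def test_constant_matrix_rejected(self):
        with pytest.raises(GuildscanError):
            ordinate(pd.DataFrame(np.ones((4, 3))))

    def test_stabilized_pipeline_input_works(self):
        m, _, _ = syn.simulate_cazy_counts(syn.GuildSimParams(seed=0))
        coords, var = ordinate(stabilize(m, size_factors(m)).T)
        assert coords.shape == (30, 2)
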