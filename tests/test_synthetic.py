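"""Generators: determinism, analytic moments, planted-truth integrity."""

import numpy as np
import pandas as pd
import pytest

from guildscan import synthetic as syn
from guildscan.core_io import GuildscanError


class TestCazyCounts:
    def test_seed_determinism(self):
        a, la, da = syn.simulate_cazy_counts(syn.GuildSimParams(seed=5))
        b, lb, db = syn.simulate_cazy_counts(syn.GuildSimParams(seed=5))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert da == db

    def test_default_guild_sizes(self):
        _, labels, _ = syn.simulate_cazy_counts(syn.GuildSimParams())
        assert labels.value_counts().to_dict() == {
            "alpha_glucan": 13, "plant_glycan": 12, "host_glycan": 5}

    def test_defining_family_mean_is_enriched(self):
        """Sample mean of a defining family in its guild ~ 3x background,
        within 3 standard errors of the analytic NB mean/variance."""
        p = syn.GuildSimParams(seed=11)
        m, labels, defining = syn.simulate_cazy_counts(p)
        mu = p.baseline_mean * p.enrichment_factor
        var = mu + p.nb_dispersion * mu ** 2
        for guild, fams in defining.items():
            cols = labels.index[labels == guild]
            se = np.sqrt(var / len(cols))
            for fam in fams:
                got = m.counts.loc[fam, cols].mean()
                assert abs(got - mu) < 3 * se, (guild, fam, got)

    def test_null_params_give_poisson_no_signal(self):
        p = syn.GuildSimParams(nb_dispersion=0.0, enrichment_factor=1.0,
                               seed=3)
        m, labels, defining = syn.simulate_cazy_counts(p)
        arr = m.counts.to_numpy()
        # Poisson: variance ~ mean across the whole matrix
        assert abs(arr.var() / arr.mean() - 1) < 0.1
        # defining sets exist structurally but carry no enrichment
        for guild, fams in defining.items():
            cols = labels.index[labels == guild]
            other = labels.index[labels != guild]
            diff = (m.counts.loc[sorted(fams), cols].mean(axis=1)
                    - m.counts.loc[sorted(fams), other].mean(axis=1))
            assert np.abs(diff).max() < 3.0

    def test_degenerate_params_rejected(self):
        with pytest.raises(GuildscanError):
            syn.GuildSimParams(n_genomes_per_guild=(5, 0, 5))


class TestGenomeTables:
    def test_planted_loci_and_decoys_are_disjoint_and_flagged(self):
        ann, truth = syn.simulate_genome_tables(syn.PulSimParams(seed=2))
        planted_genes = {g for p in truth["planted"]
                         for g in (p["susC"], p["susD"])}
        decoy_genes = {g for d in truth["decoys"] for g in d["genes"]}
        assert not planted_genes & decoy_genes
        kinds = {d["kind"] for d in truth["decoys"]}
        assert kinds <= set(syn.DECOY_KINDS)
        # only the cazyme_beyond_window decoy may still pair
        for d in truth["decoys"]:
            assert d["pair_expected"] == (d["kind"] == "cazyme_beyond_window")

    def test_gene_coordinates_non_overlapping(self):
        ann, _ = syn.simulate_genome_tables(syn.PulSimParams(seed=4))
        for contig in ann.contig_lengths:
            genes = ann.genes_on_contig(contig)
            for a, b in zip(genes, genes[1:]):
                assert b.start > a.end

    def test_seed_determinism(self):
        a1, t1 = syn.simulate_genome_tables(syn.PulSimParams(seed=9))
        a2, t2 = syn.simulate_genome_tables(syn.PulSimParams(seed=9))
        assert a1.genes == a2.genes
        assert t1 == t2


class TestSequencePairs:
    def test_zero_divergence_identical(self):
        a, b, ident = syn.simulate_sequence_pair(syn.DivergenceSimParams(
            length_bp=12_000, substitution_prob=0.0, indel_prob=0.0,
            seed=1))
        assert a == b and ident == 1.0

    def test_realized_identity_near_nominal(self):
        """1 - substitutions/length lands within the binomial CI of the
        nominal substitution probability."""
        p = 0.05
        n = 100_000
        _, _, ident = syn.simulate_sequence_pair(syn.DivergenceSimParams(
            length_bp=n, substitution_prob=p, indel_prob=0.0, seed=7))
        se = np.sqrt(p * (1 - p) / n)
        assert abs((1 - ident) - p) < 3 * se

    def test_seed_determinism(self):
        x = syn.simulate_sequence_pair(syn.DivergenceSimParams(seed=3,
                                       length_bp=12_000))
        y = syn.simulate_sequence_pair(syn.DivergenceSimParams(seed=3,
                                       length_bp=12_000))
        assert x == y

    def test_indels_change_length(self):
        a, b, _ = syn.simulate_sequence_pair(syn.DivergenceSimParams(
            length_bp=50_000, substitution_prob=0.01, indel_prob=0.002,
            seed=5))
        assert len(b) != len(a)


class TestCoverage:
    def test_presence_recovery_is_exact_by_construction(self):
        genomes = ["a", "b", "c"]
        cov, truth = syn.simulate_coverage(
            4, genomes, [{"a"}, {"b", "c"}, set(), {"a", "b", "c"}],
            seed=1)
        frac = cov.mapped_reads.div(cov.total_reads, axis=0)
        assert ((frac >= 0.005) == truth).all().all()

    def test_all_absent_sample(self):
        cov, truth = syn.simulate_coverage(1, ["a", "b"], [set()], seed=2)
        assert not truth.to_numpy().any()

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(GuildscanError):
            syn.simulate_coverage(1, list("abcdefghijklmnopqrstuvwxyz"),
                                  [set("abcdefghijklmnopqrstuvwxyz")],
                                  cutoff=0.005)


class TestTreeSim:
    def test_two_tips_single_cherry(self):
        tree = syn.simulate_tree(2, seed=0)
        assert len(list(tree.tips())) == 2
        assert len(tree.children) == 2

    def test_branch_lengths_nonnegative_and_deterministic(self):
        t1 = syn.simulate_tree(15, seed=4)
        t2 = syn.simulate_tree(15, seed=4)
        assert str(t1) == str(t2)
        assert all((n.length or 0) >= 0
                   for n in t1.traverse(include_self=True))
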