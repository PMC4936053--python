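"""susCD pairing, PUL calls, guild summaries, gene-set census."""

import pytest

from guildscan import synthetic as syn
from guildscan.features import (FeatureSetDef, PulRules, call_puls,
                                census_table, feature_census,
                                find_suscd_pairs, load_feature_sets,
                                pul_summary)
import pandas as pd

from conftest import make_annotation

RULES = PulRules()
SUSC = ("TIGR04056", "TIGRFAM")
SUSD = ("PF07980", "PFAM")


def pair_annotation(strand_c="+", strand_d="+", gap=100, order="CD"):
    """susC/susD pair with configurable geometry on a 100-kb contig."""
    g1 = ("a", 1000, 1900, strand_c if order == "CD" else strand_d)
    g2 = ("a2", 1900 + gap + 1, 1900 + gap + 900,
          strand_d if order == "CD" else strand_c)
    hits = [(("a", *SUSC) if order == "CD" else ("a", *SUSD)),
            (("a2", *SUSD) if order == "CD" else ("a2", *SUSC))]
    return make_annotation(genes=[g1, g2], hits=hits)


class TestSusCDPairs:
    def test_adjacent_same_strand_pair_found(self):
        pairs = find_suscd_pairs(pair_annotation(gap=100), RULES)
        assert len(pairs) == 1
        c, d = pairs[0]
        assert (c.gene_id, d.gene_id) == ("a", "a2")

    def test_opposite_strands_rejected(self):
        pairs = find_suscd_pairs(pair_annotation(strand_d="-"), RULES)
        assert pairs == []

    def test_gap_beyond_limit_rejected(self):
        pairs = find_suscd_pairs(pair_annotation(gap=2000), RULES)
        assert pairs == []

    def test_wrong_order_rejected_then_allowed_by_config(self):
        a = pair_annotation(order="DC")
        assert find_suscd_pairs(a, RULES) == []
        relaxed = PulRules(require_order_C_then_D=False)
        assert len(find_suscd_pairs(a, relaxed)) == 1

    def test_minus_strand_order_is_transcriptional(self):
        # on '-', upstream = higher coordinate: D left of C in genome order
        a = make_annotation(
            genes=[("d", 1000, 1900, "-"), ("c", 2000, 2900, "-")],
            hits=[("d", *SUSD), ("c", *SUSC)])
        pairs = find_suscd_pairs(a, RULES)
        assert len(pairs) == 1
        assert pairs[0][0].gene_id == "c"

    def test_each_gene_in_at_most_one_pair(self):
        # C D D adjacent: greedy takes (C, first D) only
        a = make_annotation(
            genes=[("c", 1000, 1900, "+"), ("d1", 2000, 2900, "+"),
                   ("d2", 3000, 3900, "+")],
            hits=[("c", *SUSC), ("d1", *SUSD), ("d2", *SUSD)])
        pairs = find_suscd_pairs(a, RULES)
        assert [(c.gene_id, d.gene_id) for c, d in pairs] == [("c", "d1")]


class TestCallPuls:
    def test_planted_loci_recovered_with_truth(self):
        """Recall and precision 1.0 on planted loci; decoys never called;
        CAZyme sets and regulator flags match generator truth."""
        for seed in range(10):
            ann, truth = syn.simulate_genome_tables(
                syn.PulSimParams(seed=seed))
            calls = call_puls(ann, RULES)
            expected_pairs = {(p["susC"], p["susD"])
                              for p in truth["planted"]}
            decoy_pairs = {tuple(d["genes"]) for d in truth["decoys"]
                           if d["pair_expected"]}
            got = {(c.susC_gene_id, c.susD_gene_id) for c in calls}
            assert got == expected_pairs | decoy_pairs, seed
            for c in calls:
                key = (c.susC_gene_id, c.susD_gene_id)
                if key in expected_pairs:
                    p = next(p for p in truth["planted"]
                             if (p["susC"], p["susD"]) == key)
                    assert {g for g, _ in c.associated_cazymes} \
                        == p["cazymes"]
                    assert c.regulator_nearby \
                        == (p["regulator"] is not None)
                else:  # cazyme_beyond_window decoy: bare pair
                    assert c.associated_cazymes == []

    def test_cazyme_outside_window_gives_empty_set(self):
        a = make_annotation(
            genes=[("caz", 1000, 1900, "+"), ("c", 14_000, 14_900, "+"),
                   ("d", 15_000, 15_900, "+")],
            hits=[("caz", "GH13", "CAZY"), ("c", *SUSC), ("d", *SUSD)])
        calls = call_puls(a, RULES)
        assert len(calls) == 1
        assert calls[0].associated_cazymes == []

    def test_regulator_within_window_flagged(self):
        a = make_annotation(
            genes=[("c", 1000, 1900, "+"), ("d", 2000, 2900, "+"),
                   ("r", 5_500, 6_400, "+")],
            hits=[("c", *SUSC), ("d", *SUSD), ("r", "PF07730", "PFAM")])
        calls = call_puls(a, RULES)
        assert calls[0].regulator_nearby
        assert calls[0].regulator_gene_id == "r"

    def test_window_shrinkage_is_monotone(self):
        """Shrinking windows never adds calls or associations."""
        ann, _ = syn.simulate_genome_tables(syn.PulSimParams(seed=3))
        wide = call_puls(ann, PulRules())
        narrow = call_puls(ann, PulRules(max_intergenic_bp=50,
                                         cazyme_window_genes=1,
                                         cazyme_window_bp=1500,
                                         regulator_window_bp=500))
        assert len(narrow) <= len(wide)
        assert sum(len(c.associated_cazymes) for c in narrow) \
            <= sum(len(c.associated_cazymes) for c in wide)

    def test_input_order_invariance(self):
        import numpy as np
        from guildscan.core_io import GenomeAnnotation
        ann, _ = syn.simulate_genome_tables(syn.PulSimParams(seed=5))
        rng = np.random.default_rng(0)
        genes = list(ann.genes)
        rng.shuffle(genes)
        ann2 = GenomeAnnotation(genome_id=ann.genome_id,
                                contig_lengths=ann.contig_lengths,
                                genes=genes, hits=ann.hits)
        c1 = [(c.susC_gene_id, c.susD_gene_id) for c in call_puls(ann)]
        c2 = [(c.susC_gene_id, c.susD_gene_id) for c in call_puls(ann2)]
        assert c1 == c2


class TestPulSummary:
    def test_single_genome_guild_means_equal_counts(self):
        ann, _ = syn.simulate_genome_tables(syn.PulSimParams(seed=1))
        calls = call_puls(ann)
        labels = pd.Series({"sim": "plant", "other": "host"})
        table = pul_summary({"sim": calls, "other": []}, labels)
        assert table.loc["plant", "mean_suscd_pairs"] == len(calls)
        assert table.loc["host", "mean_suscd_pairs"] == 0.0

    def test_guild_with_more_planted_puls_ranks_first(self):
        rich, _ = syn.simulate_genome_tables(
            syn.PulSimParams(seed=2, n_planted_puls=6, n_decoys=0))
        poor, _ = syn.simulate_genome_tables(
            syn.PulSimParams(seed=3, n_planted_puls=1, n_decoys=0))
        labels = pd.Series({"rich": "plant", "poor": "alpha"})
        calls = {"rich": call_puls(rich), "poor": call_puls(poor)}
        table = pul_summary(calls, labels)
        assert table.loc["plant", "mean_cazyme_associated"] \
            > table.loc["alpha", "mean_cazyme_associated"]


class TestCensus:
    COMPLEX_I = [f"Nuo{x}" for x in "ABCDHIJKLMN"]

    def _genome(self, symbols, near_edge=None, contig_len=100_000):
        genes, hits = [], []
        pos = 10_000
        for i, sym in enumerate(symbols):
            gid = f"x{i}"
            if sym == near_edge:
                genes.append((gid, contig_len - 2_500, contig_len - 1_600,
                              "+"))
            else:
                genes.append((gid, pos, pos + 900, "+"))
                pos += 1_500
            hits.append((gid, sym, "GENE_SYMBOL"))
        return make_annotation(genes=genes, hits=hits,
                               contig_len=contig_len)

    def test_all_subunits_complete(self):
        defs = [FeatureSetDef("complex_I",
                              frozenset(self.COMPLEX_I), "all")]
        res = feature_census(self._genome(self.COMPLEX_I), defs)
        assert res[0].status == "complete"
        assert not res[0].boundary_flag

    def test_partial_with_boundary_flag(self):
        defs = [FeatureSetDef("complex_I",
                              frozenset(self.COMPLEX_I), "all")]
        nine = self.COMPLEX_I[:9]
        res = feature_census(self._genome(nine, near_edge="NuoA"), defs)
        assert res[0].status == "partial"
        assert res[0].boundary_flag
        assert res[0].missing == set(self.COMPLEX_I[9:])

    def test_absent(self):
        defs = [FeatureSetDef("complex_I",
                              frozenset(self.COMPLEX_I), "all")]
        res = feature_census(self._genome(["CydA"]), defs)
        assert res[0].status == "absent"

    def test_integer_threshold_rule(self):
        defs = [FeatureSetDef("half", frozenset(["A", "B", "C", "D"]), 2)]
        res = feature_census(self._genome(["A", "B"]), defs)
        assert res[0].status == "complete"

    def test_bundled_definitions_load(self):
        defs = load_feature_sets()
        names = {d.name for d in defs}
        assert {"complex_I", "T9SS", "cydAB", "urease_cluster",
                "oxalate_pair"} <= names
        t9ss = next(d for d in defs if d.name == "T9SS")
        assert len(t9ss.required) == 10

    def test_census_table_shape(self):
        defs = load_feature_sets()
        res = feature_census(self._genome(["CydA", "CydB"]), defs)
        table = census_table(res)
        assert set(table["status"]) <= {"complete", "partial", "absent"}
        assert table.loc[table.set_name == "cydAB", "status"].item() \
            == "complete"
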