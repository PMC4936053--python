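"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed, and returns
the planted truth alongside the data so downstream recovery tests consume
the truth rather than re-deriving it.

The defaults encode the study conditions the pipeline is exercised under:
three trophic guilds of 13, 12 and 5 genomes, negative-binomial CAZy-family
counts with 3x enrichment of five defining families per guild at dispersion
0.3 over a baseline mean of 6, and a presence cutoff of 0.5 % of sample
reads for coverage tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import (CountMatrix, CoverageTable, DomainHit, GeneRecord,
                      GenomeAnnotation, GuildscanError, logger)

DNA = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

GUILD_NAMES = ("alpha_glucan", "plant_glycan", "host_glycan")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuildSimParams:
    """Guild-structured CAZy count simulation.

    Counts follow NB(mean mu, dispersion alpha) with variance
    ``mu + alpha * mu**2`` (the convention of count-based differential
    abundance models); a guild's defining families have their mean
    multiplied by ``enrichment_factor`` in that guild's genomes only.
    """

    n_genomes_per_guild: tuple[int, ...] = (13, 12, 5)
    n_families: int = 60
    baseline_mean: float = 6.0
    enrichment_factor: float = 3.0
    n_defining_per_guild: int = 5
    nb_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_genomes_per_guild):
            raise GuildscanError("every guild needs >= 1 genome")
        if self.n_families < 1 or self.n_defining_per_guild < 0:
            raise GuildscanError("family counts must be >= 1")
        if self.n_defining_per_guild * len(self.n_genomes_per_guild) \
                > self.n_families:
            raise GuildscanError("defining sets exceed the family pool")
        if self.enrichment_factor < 1.0:
            raise GuildscanError("enrichment_factor must be >= 1")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0:
            raise GuildscanError("dispersion >= 0 and baseline_mean > 0")


@dataclass(frozen=True)
class PulSimParams:
    """Planted susCD-pair loci and single-clause-violating decoys.

    Decoy kinds cycle through: ``lone_susC`` (no partner), ``separated_pair``
    (an intervening gene breaks adjacency), ``opposite_strand``,
    ``wrong_order`` (D upstream of C in transcription direction), and
    ``cazyme_beyond_window`` (valid pair, no CAZyme within the association
    window). Cassettes are separated by runs of plain genes long enough to
    keep every association window disjoint.
    """

    n_contigs: int = 2
    n_planted_puls: int = 3
    n_decoys: int = 5
    gene_len_bp: int = 900
    intergenic_gap_bp: int = 100
    spacer_genes: int = 13
    susC_accession: str = "TIGR04056"
    susD_accession: str = "PF07980"
    htcs_accession: str = "PF07730"
    cazy_family: str = "GH13"
    core_symbols: tuple[str, ...] = ("CydA", "CydB", "SodA")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intergenic_gap_bp < 0 or self.gene_len_bp < 1:
            raise GuildscanError("bad gene geometry")
        if self.n_contigs < 1:
            raise GuildscanError("need >= 1 contig")


@dataclass(frozen=True)
class DivergenceSimParams:
    """A nucleotide (or protein) pair at controlled divergence."""

    length_bp: int = 100_000
    substitution_prob: float = 0.05
    indel_prob: float = 0.001
    mean_indel_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_prob < 1):
            raise GuildscanError("substitution_prob in [0,1)")
        if not (0 <= self.indel_prob < 1):
            raise GuildscanError("indel_prob in [0,1)")
        if self.length_bp < 10_200:
            raise GuildscanError(
                "length_bp must be >= 10200 (>= 10 fragments of 1020 bp) "
                "for fragment statistics to be meaningful")


# ---------------------------------------------------------------------------
# CAZy count matrices
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + dispersion*mu^2; dispersion 0
    degenerates to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cazy_counts(params: GuildSimParams
                         ) -> tuple[CountMatrix, pd.Series, dict[str, set[str]]]:
    """Simulate a guild-structured CAZy family count matrix.

    Returns (matrix, true labels genome->guild, true defining sets
    guild->families).
    """
    rng = np.random.default_rng(params.seed)
    logger.info("simulate_cazy_counts seed=%d", params.seed)
    k = len(params.n_genomes_per_guild)
    guilds = list(GUILD_NAMES[:k]) if k <= 3 else [
        f"guild_{i + 1}" for i in range(k)]
    families = [f"GH{i + 1}" for i in range(params.n_families)]
    genome_ids, labels = [], []
    for gi, n in enumerate(params.n_genomes_per_guild):
        for j in range(n):
            genome_ids.append(f"g{len(genome_ids) + 1:02d}")
            labels.append(guilds[gi])
    # disjoint defining sets drawn from the family pool
    order = rng.permutation(params.n_families)
    defining: dict[str, set[str]] = {}
    pos = 0
    for g in guilds:
        idx = order[pos:pos + params.n_defining_per_guild]
        defining[g] = {families[i] for i in idx}
        pos += params.n_defining_per_guild
    mean = np.full((params.n_families, len(genome_ids)), params.baseline_mean)
    for g in guilds:
        cols = [i for i, lab in enumerate(labels) if lab == g]
        rows = [families.index(f) for f in sorted(defining[g])]
        mean[np.ix_(rows, cols)] *= params.enrichment_factor
    counts = _nb_draw(rng, mean, params.nb_dispersion)
    m = CountMatrix(counts=pd.DataFrame(
        counts, index=families, columns=genome_ids))
    return m, pd.Series(labels, index=genome_ids, name="guild"), defining


# ---------------------------------------------------------------------------
# Gene tables with planted PULs
# ---------------------------------------------------------------------------

DECOY_KINDS = ("lone_susC", "separated_pair", "opposite_strand",
               "wrong_order", "cazyme_beyond_window")


def simulate_genome_tables(params: PulSimParams
                           ) -> tuple[GenomeAnnotation, dict]:
    """Build one genome annotation with planted PULs and decoys.

    Truth dict:
      ``planted``: list of {susC, susD, cazymes, regulator} gene ids;
      ``decoys``: list of {kind, genes, pair_expected} where
      ``pair_expected`` marks decoys that should still yield a bare susCD
      pair (only ``cazyme_beyond_window``).
    """
    rng = np.random.default_rng(params.seed)
    logger.info("simulate_genome_tables seed=%d", params.seed)
    gid = "sim"
    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    planted, decoys = [], []

    cassettes: list[tuple[str, Optional[dict]]] = []
    for i in range(params.n_planted_puls):
        cassettes.append(("planted", {"regulator": i % 2 == 0}))
    for i in range(params.n_decoys):
        cassettes.append((DECOY_KINDS[i % len(DECOY_KINDS)], None))
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]

    contig_of = [i % params.n_contigs for i in range(len(cassettes))]
    per_contig: dict[str, list] = {
        f"c{c + 1:02d}": [] for c in range(params.n_contigs)}
    for cass, c in zip(cassettes, contig_of):
        per_contig[f"c{c + 1:02d}"].append(cass)

    counter = 0
    contig_lengths: dict[str, int] = {}

    def new_gene(contig: str, pos: int, strand: str,
                 accs: Sequence[tuple[str, str]] = (),
                 product: Optional[str] = None) -> tuple[GeneRecord, int]:
        nonlocal counter
        counter += 1
        g = GeneRecord(genome_id=gid, contig_id=contig,
                       gene_id=f"gene{counter:04d}", start=pos,
                       end=pos + params.gene_len_bp - 1, strand=strand,
                       product=product)
        genes.append(g)
        for acc, ns in accs:
            hits.append(DomainHit(gene_id=g.gene_id, accession=acc,
                                  namespace=ns))
        return g, g.end + 1 + params.intergenic_gap_bp

    susC = [(params.susC_accession, "TIGRFAM")]
    susD = [(params.susD_accession, "PFAM")]
    cazy = [(params.cazy_family, "CAZY")]
    htcs = [(params.htcs_accession, "PFAM")]

    for contig, cass_list in per_contig.items():
        pos = 1 + params.intergenic_gap_bp

        def spacer(pos: int, n: Optional[int] = None) -> int:
            for _ in range(n if n is not None else params.spacer_genes):
                _, pos = new_gene(contig, pos, "+" if rng.random() < 0.5
                                  else "-", product="hypothetical protein")
            return pos

        pos = spacer(pos, 1)
        for kind, opts in cass_list:
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "planted":
                caz_g, pos = new_gene(contig, pos, strand, cazy)
                if strand == "+":
                    c_g, pos = new_gene(contig, pos, strand, susC)
                    d_g, pos = new_gene(contig, pos, strand, susD)
                else:  # transcription right-to-left: C upstream means C right
                    d_g, pos = new_gene(contig, pos, strand, susD)
                    c_g, pos = new_gene(contig, pos, strand, susC)
                entry = {"susC": c_g.gene_id, "susD": d_g.gene_id,
                         "cazymes": {caz_g.gene_id}, "regulator": None}
                if opts and opts["regulator"]:
                    r_g, pos = new_gene(contig, pos, strand, htcs)
                    entry["regulator"] = r_g.gene_id
                planted.append(entry)
            elif kind == "lone_susC":
                c_g, pos = new_gene(contig, pos, strand, susC)
                decoys.append({"kind": kind, "genes": [c_g.gene_id],
                               "pair_expected": False})
            elif kind == "separated_pair":
                if strand == "+":
                    c_g, pos = new_gene(contig, pos, strand, susC)
                    mid, pos = new_gene(contig, pos, strand)
                    d_g, pos = new_gene(contig, pos, strand, susD)
                else:
                    d_g, pos = new_gene(contig, pos, strand, susD)
                    mid, pos = new_gene(contig, pos, strand)
                    c_g, pos = new_gene(contig, pos, strand, susC)
                decoys.append({"kind": kind,
                               "genes": [c_g.gene_id, d_g.gene_id],
                               "pair_expected": False})
            elif kind == "opposite_strand":
                other = "-" if strand == "+" else "+"
                c_g, pos = new_gene(contig, pos, strand, susC)
                d_g, pos = new_gene(contig, pos, other, susD)
                decoys.append({"kind": kind,
                               "genes": [c_g.gene_id, d_g.gene_id],
                               "pair_expected": False})
            elif kind == "wrong_order":
                if strand == "+":  # D first in genomic order = D upstream
                    d_g, pos = new_gene(contig, pos, strand, susD)
                    c_g, pos = new_gene(contig, pos, strand, susC)
                else:
                    c_g, pos = new_gene(contig, pos, strand, susC)
                    d_g, pos = new_gene(contig, pos, strand, susD)
                decoys.append({"kind": kind,
                               "genes": [c_g.gene_id, d_g.gene_id],
                               "pair_expected": False})
            elif kind == "cazyme_beyond_window":
                if strand == "+":
                    c_g, pos = new_gene(contig, pos, strand, susC)
                    d_g, pos = new_gene(contig, pos, strand, susD)
                else:
                    d_g, pos = new_gene(contig, pos, strand, susD)
                    c_g, pos = new_gene(contig, pos, strand, susC)
                decoys.append({"kind": kind,
                               "genes": [c_g.gene_id, d_g.gene_id],
                               "pair_expected": True})
            pos = spacer(pos)
        contig_lengths[contig] = pos + params.intergenic_gap_bp

    # attach core-metabolism gene symbols to the first plain genes so the
    # census stage has material to find
    annotated = {h.gene_id for h in hits}
    plain = [g for g in genes if g.gene_id not in annotated]
    for symbol, g in zip(params.core_symbols, plain):
        hits.append(DomainHit(gene_id=g.gene_id, accession=symbol,
                              namespace="GENE_SYMBOL"))

    ann = GenomeAnnotation(genome_id=gid, contig_lengths=contig_lengths,
                           genes=genes, hits=hits)
    truth = {"planted": planted, "decoys": decoys, "seed": params.seed,
             "core_symbols": list(params.core_symbols)}
    return ann, truth


# ---------------------------------------------------------------------------
# Sequence pairs at controlled divergence
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, alphabet: np.ndarray, p_sub: float,
            rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """i.i.d. substitutions, uniform over the alternative symbols."""
    n = len(seq)
    mask = rng.random(n) < p_sub
    idx = np.flatnonzero(mask)
    if len(idx):
        k = len(alphabet)
        cur = np.searchsorted(alphabet, seq[idx])
        shift = rng.integers(1, k, size=len(idx))
        seq = seq.copy()
        seq[idx] = alphabet[(cur + shift) % k]
    return seq, int(len(idx))


def simulate_sequence_pair(params: DivergenceSimParams
                           ) -> tuple[str, str, float]:
    """A random genome and a diverged copy.

    Substitutions are i.i.d. with probability ``substitution_prob``
    (uniform over the 3 alternative bases); indels start with probability
    ``indel_prob`` per site with geometric lengths (mean
    ``mean_indel_len``), insertion or deletion equally likely.
    ``realized_identity`` = 1 - substitutions/length, recorded as truth.
    """
    rng = np.random.default_rng(params.seed)
    logger.info("simulate_sequence_pair seed=%d", params.seed)
    a = rng.choice(DNA, size=params.length_bp)
    b, n_sub = _mutate(a, DNA, params.substitution_prob, rng)
    realized_identity = 1.0 - n_sub / params.length_bp
    if params.indel_prob > 0:
        p_geo = 1.0 / max(params.mean_indel_len, 1.0)
        starts = np.flatnonzero(rng.random(params.length_bp)
                                < params.indel_prob)
        pieces, prev = [], 0
        for s in starts:
            if s < prev:
                continue
            length = int(rng.geometric(p_geo))
            pieces.append(b[prev:s])
            if rng.random() < 0.5:  # insertion
                pieces.append(rng.choice(DNA, size=length))
                prev = s
            else:  # deletion
                prev = min(s + length, params.length_bp)
        pieces.append(b[prev:])
        b = np.concatenate(pieces)
    return "".join(a), "".join(b), realized_identity


def simulate_proteome_pair(n_proteins: int = 40, length_aa: int = 250,
                           divergence: float = 0.1, seed: int = 0
                           ) -> tuple[dict[str, str], dict[str, str], float]:
    """Paired proteomes at i.i.d. amino-acid divergence (AAI truth input)."""
    if not (0 <= divergence < 1):
        raise GuildscanError("divergence in [0,1)")
    if n_proteins < 1 or length_aa < 10:
        raise GuildscanError("need >= 1 protein of >= 10 aa")
    rng = np.random.default_rng(seed)
    prot_a, prot_b = {}, {}
    total_sub = 0
    for i in range(n_proteins):
        a = rng.choice(AA, size=length_aa)
        b, n_sub = _mutate(a, AA, divergence, rng)
        total_sub += n_sub
        prot_a[f"p{i + 1:03d}"] = "".join(a)
        prot_b[f"q{i + 1:03d}"] = "".join(b)
    realized = 1.0 - total_sub / (n_proteins * length_aa)
    return prot_a, prot_b, realized


# ---------------------------------------------------------------------------
# Coverage tables with known presence
# ---------------------------------------------------------------------------

def simulate_coverage(n_samples: int, genomes: Sequence[str],
                      present_sets: Sequence[set[str]], seed: int = 0,
                      cutoff: float = 0.005, total_reads: int = 1_000_000,
                      genome_lengths: Optional[Sequence[int]] = None
                      ) -> tuple[CoverageTable, pd.DataFrame]:
    """Coverage counts where present genomes sit strictly above the
    detection cutoff and absent ones strictly below; truth returned."""
    if len(present_sets) != n_samples:
        raise GuildscanError("one present set per sample required")
    rng = np.random.default_rng(seed)
    logger.info("simulate_coverage seed=%d", seed)
    genomes = list(genomes)
    for s in present_sets:
        if not set(s) <= set(genomes):
            raise GuildscanError(f"present set {s} outside genome panel")
        if len(s) * 10 * cutoff > 1.0:
            raise GuildscanError("requested present fractions exceed 1")
    if genome_lengths is None:
        lengths = rng.integers(2_000_000, 4_000_000, size=len(genomes))
    else:
        lengths = np.asarray(genome_lengths)
    mapped = np.zeros((n_samples, len(genomes)), dtype=np.int64)
    truth = np.zeros((n_samples, len(genomes)), dtype=bool)
    for si in range(n_samples):
        for gi, g in enumerate(genomes):
            if g in present_sets[si]:
                frac = cutoff * rng.uniform(2.0, 10.0)
                reads = int(np.ceil(frac * total_reads))
                truth[si, gi] = True
            else:
                frac = cutoff * rng.uniform(0.0, 0.5)
                reads = int(np.floor(frac * total_reads))
            mapped[si, gi] = reads
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    cov = CoverageTable(
        mapped_reads=pd.DataFrame(mapped, index=samples, columns=genomes),
        total_reads=pd.Series(total_reads, index=samples, dtype=np.int64),
        genome_lengths=pd.Series(lengths, index=genomes, dtype=np.int64))
    return cov, pd.DataFrame(truth, index=samples, columns=genomes)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int = 0,
                  mean_branch_length: float = 0.1) -> TreeNode:
    """A Yule (random-splitting) topology with exponential branch lengths."""
    if n_tips < 2:
        raise GuildscanError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    logger.info("simulate_tree seed=%d n_tips=%d", seed, n_tips)
    root = TreeNode()
    leaves = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        leaves.append(child)
    while len(leaves) < n_tips:
        pick = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = TreeNode()
            pick.append(child)
            leaves.append(child)
    for i, leaf in enumerate(leaves):
        leaf.name = f"t{i + 1:02d}"
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(mean_branch_length))
    root.length = 0.0
    return root
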