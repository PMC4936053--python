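"""Gene-neighbourhood analyses: susCD-anchored PUL detection and gene-set
presence/absence census.

A PUL anchor is an adjacent (zero intervening genes, intergenic gap <=
``max_intergenic_bp``) same-strand susC->susD pair read 5'->3' on the
pair's strand. Associated CAZymes must fall within both a gene-count and
a bp window of the pair; a hybrid two-component system (HTCS) regulator
within ``regulator_window_bp`` sets the regulator flag. All criteria are
explicit configuration because upstream annotators differ.

The census marks each defined gene set complete / partial / absent per
genome and flags partial sets whose found members sit near contig ends
(possible assembly truncation rather than true absence).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .core_io import GeneRecord, GenomeAnnotation, GuildscanError, logger
from .guilds import GuildLabels, validate_labels


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulRules:
    susC_accessions: frozenset[str] = frozenset({"TIGR04056"})
    susD_accessions: frozenset[str] = frozenset(
        {"PF07980", "PF12741", "PF12771", "PF14322"})
    max_intergenic_bp: int = 500
    require_same_strand: bool = True
    require_order_C_then_D: bool = True
    cazyme_window_genes: int = 10
    cazyme_window_bp: int = 10_000
    regulator_accessions: frozenset[str] = frozenset({"PF07730", "PF08447"})
    regulator_window_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.max_intergenic_bp < 0:
            raise GuildscanError("max_intergenic_bp must be >= 0")
        if min(self.cazyme_window_genes, self.cazyme_window_bp,
               self.regulator_window_bp) <= 0:
            raise GuildscanError("windows must be positive")
        if not self.susC_accessions or not self.susD_accessions:
            raise GuildscanError("accession sets must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PulRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("susC_accessions", "susD_accessions",
                    "regulator_accessions"):
            if key in raw:
                raw[key] = frozenset(raw[key])
        return cls(**raw)


@dataclass
class PulCall:
    genome_id: str
    contig_id: str
    susC_gene_id: str
    susD_gene_id: str
    strand: str
    span_bp: int
    associated_cazymes: list[tuple[str, str]]  # (gene_id, family)
    regulator_nearby: bool
    regulator_gene_id: Optional[str] = None


# ---------------------------------------------------------------------------
# susCD pairs
# ---------------------------------------------------------------------------

def _gene_roles(a: GenomeAnnotation, rules: PulRules
                ) -> tuple[set[str], set[str]]:
    sus_c, sus_d = set(), set()
    for gene_id, hits in a.hits_by_gene().items():
        accs = {h.accession for h in hits}
        if accs & rules.susC_accessions:
            sus_c.add(gene_id)
        if accs & rules.susD_accessions:
            sus_d.add(gene_id)
    return sus_c, sus_d


def find_suscd_pairs(a: GenomeAnnotation, rules: PulRules = PulRules()
                     ) -> list[tuple[GeneRecord, GeneRecord]]:
    """Adjacent susC/susD gene pairs under the configured rules.

    Greedy left-to-right along each contig; each gene joins at most one
    pair. Returned as (susC gene, susD gene).
    """
    sus_c, sus_d = _gene_roles(a, rules)
    pairs: list[tuple[GeneRecord, GeneRecord]] = []
    for contig in sorted(a.contig_lengths):
        genes = a.genes_on_contig(contig)
        i = 0
        while i < len(genes) - 1:
            left, right = genes[i], genes[i + 1]
            gap = right.start - left.end - 1
            if gap > rules.max_intergenic_bp:
                i += 1
                continue
            if rules.require_same_strand and left.strand != right.strand:
                i += 1
                continue
            lc, ld = left.gene_id in sus_c, left.gene_id in sus_d
            rc, rd = right.gene_id in sus_c, right.gene_id in sus_d
            pair: Optional[tuple[GeneRecord, GeneRecord]] = None
            if rules.require_order_C_then_D:
                # C upstream of D in transcription direction
                strand = left.strand if rules.require_same_strand \
                    else (left.strand if lc else right.strand)
                if strand == "+" and lc and rd:
                    pair = (left, right)
                elif strand == "-" and ld and rc:
                    pair = (right, left)
            else:
                if lc and rd:
                    pair = (left, right)
                elif ld and rc:
                    pair = (right, left)
            if pair is not None:
                pairs.append(pair)
                i += 2  # both genes consumed
            else:
                i += 1
    return pairs


# ---------------------------------------------------------------------------
# PUL calls
# ---------------------------------------------------------------------------

def _span_distance(g: GeneRecord, span: tuple[int, int]) -> int:
    lo, hi = span
    if g.end < lo:
        return lo - g.end
    if g.start > hi:
        return g.start - hi
    return 0


def call_puls(a: GenomeAnnotation, rules: PulRules = PulRules()
              ) -> list[PulCall]:
    """Each susCD pair becomes a PulCall with its associated CAZymes
    (within both the gene-count and bp windows) and regulator flag."""
    calls: list[PulCall] = []
    contig_genes = {c: a.genes_on_contig(c) for c in a.contig_lengths}
    index_of = {c: {g.gene_id: i for i, g in enumerate(genes)}
                for c, genes in contig_genes.items()}
    for c_gene, d_gene in find_suscd_pairs(a, rules):
        contig = c_gene.contig_id
        genes = contig_genes[contig]
        idx = index_of[contig]
        lo_idx = min(idx[c_gene.gene_id], idx[d_gene.gene_id])
        hi_idx = max(idx[c_gene.gene_id], idx[d_gene.gene_id])
        span = (min(c_gene.start, d_gene.start),
                max(c_gene.end, d_gene.end))
        cazymes: list[tuple[str, str]] = []
        regulator: Optional[str] = None
        for j, g in enumerate(genes):
            if lo_idx <= j <= hi_idx:
                continue
            dist = _span_distance(g, span)
            gene_dist = lo_idx - j if j < lo_idx else j - hi_idx
            if gene_dist <= rules.cazyme_window_genes \
                    and dist <= rules.cazyme_window_bp:
                for fam in sorted(a.accessions(g.gene_id, namespace="CAZY")):
                    cazymes.append((g.gene_id, fam))
            if regulator is None and dist <= rules.regulator_window_bp:
                if a.accessions(g.gene_id) & rules.regulator_accessions:
                    regulator = g.gene_id
        calls.append(PulCall(
            genome_id=a.genome_id, contig_id=contig,
            susC_gene_id=c_gene.gene_id, susD_gene_id=d_gene.gene_id,
            strand=c_gene.strand, span_bp=span[1] - span[0] + 1,
            associated_cazymes=cazymes,
            regulator_nearby=regulator is not None,
            regulator_gene_id=regulator))
    return calls


def pul_summary(calls_per_genome: Mapping[str, Sequence[PulCall]],
                labels: GuildLabels) -> pd.DataFrame:
    """Per guild: mean susCD pairs/genome, mean CAZyme-associated pairs/
    genome, fraction of PULs with a nearby regulator."""
    validate_labels(labels)
    rows = []
    for guild in sorted(labels.unique()):
        genomes = list(labels.index[labels == guild])
        n_pairs = [len(calls_per_genome.get(g, [])) for g in genomes]
        n_assoc = [sum(1 for c in calls_per_genome.get(g, [])
                       if c.associated_cazymes) for g in genomes]
        all_calls = [c for g in genomes for c in calls_per_genome.get(g, [])]
        frac_reg = (sum(c.regulator_nearby for c in all_calls)
                    / len(all_calls)) if all_calls else 0.0
        rows.append({"guild": guild, "n_genomes": len(genomes),
                     "mean_suscd_pairs": float(pd.Series(n_pairs).mean()),
                     "mean_cazyme_associated":
                         float(pd.Series(n_assoc).mean()),
                     "frac_regulator_nearby": frac_reg})
    return pd.DataFrame(rows).set_index("guild")


# ---------------------------------------------------------------------------
# Gene-set census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSetDef:
    name: str
    required: frozenset[str]
    complete_rule: str | int = "all"  # "all" or an integer threshold

    def __post_init__(self) -> None:
        if not self.required:
            raise GuildscanError(f"feature set {self.name}: empty")
        if isinstance(self.complete_rule, int):
            if not (1 <= self.complete_rule <= len(self.required)):
                raise GuildscanError(
                    f"feature set {self.name}: threshold out of range")
        elif self.complete_rule != "all":
            raise GuildscanError(
                f"feature set {self.name}: rule {self.complete_rule!r}")

    @property
    def threshold(self) -> int:
        return len(self.required) if self.complete_rule == "all" \
            else int(self.complete_rule)


def load_feature_sets(path: Optional[str | Path] = None
                      ) -> list[FeatureSetDef]:
    """Load feature-set definitions from YAML (bundled defaults when no
    path given: respiratory complexes, T9SS, cydAB, urease, oxalate pair,
    oxidative-stress singletons)."""
    if path is None:
        source = resources.files("guildscan.data") / "featuresets.yaml"
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = []
    for entry in raw["feature_sets"]:
        defs.append(FeatureSetDef(
            name=entry["name"],
            required=frozenset(entry["required"]),
            complete_rule=entry.get("complete_rule", "all")))
    return defs


def _infer_namespace(accession: str) -> str:
    """Best-effort namespace of a census accession, for warnings only."""
    if accession.startswith("PF"):
        return "PFAM"
    if accession.startswith("TIGR"):
        return "TIGRFAM"
    if accession.startswith("COG"):
        return "COG"
    if accession.startswith("K") and accession[1:].isdigit():
        return "KO"
    return "GENE_SYMBOL"


@dataclass
class CensusResult:
    genome_id: str
    set_name: str
    status: str  # complete | partial | absent
    found: set[str]
    missing: set[str]
    boundary_flag: bool


def feature_census(a: GenomeAnnotation, defs: Sequence[FeatureSetDef],
                   boundary_bp: int = 5_000) -> list[CensusResult]:
    """Presence/absence census of defined gene sets in one genome.

    boundary_flag is raised only for *partial* sets with a found member
    within ``boundary_bp`` of a contig end — the standard caveat that a
    truncated contig, not gene loss, may explain the missing members.
    """
    present_accs: dict[str, set[str]] = {}
    namespaces_seen = {h.namespace for h in a.hits}
    for h in a.hits:
        present_accs.setdefault(h.accession, set()).add(h.gene_id)
    results = []
    for d in defs:
        absent_ns = {_infer_namespace(acc) for acc in d.required} \
            - namespaces_seen
        if absent_ns:
            logger.warning(
                "%s: feature set %s references namespace(s) %s absent "
                "from the annotation; members treated as missing",
                a.genome_id, d.name, sorted(absent_ns))
        found = {acc for acc in d.required if acc in present_accs}
        missing = set(d.required) - found
        if len(found) >= d.threshold:
            status = "complete"
        elif found:
            status = "partial"
        else:
            status = "absent"
        boundary = False
        if status == "partial":
            gene_lookup = {g.gene_id: g for g in a.genes}
            for acc in found:
                for gene_id in present_accs[acc]:
                    g = gene_lookup[gene_id]
                    clen = a.contig_lengths[g.contig_id]
                    if g.start - 1 < boundary_bp or clen - g.end < boundary_bp:
                        boundary = True
        results.append(CensusResult(
            genome_id=a.genome_id, set_name=d.name, status=status,
            found=found, missing=missing, boundary_flag=boundary))
    return results


def census_table(results: Sequence[CensusResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genome_id": r.genome_id, "set_name": r.set_name,
        "status": r.status, "n_found": len(r.found),
        "n_missing": len(r.missing),
        "found": ",".join(sorted(r.found)),
        "missing": ",".join(sorted(r.missing)),
        "boundary_flag": r.boundary_flag} for r in results])
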