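"""Validated in-memory model and readers/writers for all exchange formats.

Conventions
-----------
* Gene coordinates are 1-based and inclusive on both ends (GFF3); all
  neighbourhood arithmetic downstream uses this convention.
* Strand is strictly ``+`` or ``-``; strandless features are rejected
  because the PUL rules are strand-aware.
* Domain hits live in a single namespaced vocabulary
  (CAZY / PFAM / TIGRFAM / COG / KO / GENE_SYMBOL) so that census and PUL
  rules can mix annotation sources freely.
* Every validation failure raises a typed exception carrying the offending
  record's identifiers.

Formats: genes as GFF3 (``##sequence-region`` pragmas give contig lengths)
or a documented TSV dialect; domain hits, count matrices and coverage
tables as TSV; trees as newick (parsed with scikit-bio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("guildscan")

NAMESPACES = frozenset({"CAZY", "PFAM", "TIGRFAM", "COG", "KO", "GENE_SYMBOL"})


# ---------------------------------------------------------------------------
# Typed errors
# ---------------------------------------------------------------------------

class GuildscanError(Exception):
    """Base class for every guildscan validation or format error."""


class FormatError(GuildscanError):
    """A file does not conform to its documented dialect."""


class UnknownGeneError(GuildscanError):
    """A domain hit references a gene_id absent from the gene table."""


class UnknownContigError(GuildscanError):
    """A gene references a contig with no declared length."""


class CoordinateOverflowError(GuildscanError):
    """A gene's end coordinate exceeds its contig length."""


class UnknownNamespaceError(GuildscanError):
    """A domain hit carries a namespace outside the allowed vocabulary."""


class DuplicateGeneError(GuildscanError):
    """(genome_id, gene_id) is not unique."""


class DuplicateGenomeError(GuildscanError):
    """Two annotations carry the same genome_id."""


class CoverageError(GuildscanError):
    """A coverage table breaks an invariant (e.g. mapped > total)."""


class TreeParseError(GuildscanError):
    """Newick input could not be parsed."""


class DuplicateTipLabelError(GuildscanError):
    """A tree contains two tips with the same label."""


class NoStructureError(GuildscanError):
    """Clustering requested on data with no dissimilarity structure."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene: 1-based inclusive coordinates on a contig of one genome."""

    genome_id: str
    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {{+,-}}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A domain/orthology annotation attached to a gene.

    ``score_kind`` names what ``score`` is ("bitscore" or "evalue") when a
    score is carried at all; upstream annotators differ and the pipeline
    never interprets the score, only reports it.
    """

    gene_id: str
    accession: str
    namespace: str
    score: Optional[float] = None
    score_kind: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise FormatError(f"hit on gene {self.gene_id}: empty accession")
        if self.namespace not in NAMESPACES:
            raise UnknownNamespaceError(
                f"hit {self.accession} on gene {self.gene_id}: "
                f"namespace {self.namespace!r} not in {sorted(NAMESPACES)}")
        if self.score_kind not in (None, "bitscore", "evalue"):
            raise FormatError(
                f"hit {self.accession}: score_kind {self.score_kind!r}")


@dataclass
class GenomeAnnotation:
    """One genome's contigs, genes and domain hits.

    Genes are kept sorted by (contig_id, start); lookup helpers are built
    lazily and cached.
    """

    genome_id: str
    contig_lengths: dict[str, int]
    genes: list[GeneRecord]
    hits: list[DomainHit]
    _hits_by_gene: Optional[dict[str, list[DomainHit]]] = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for cid, length in self.contig_lengths.items():
            if length < 1:
                raise FormatError(
                    f"{self.genome_id}: contig {cid} length {length} < 1")
        self.genes = sorted(
            self.genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.genome_id != self.genome_id:
                raise FormatError(
                    f"gene {g.gene_id} labelled genome {g.genome_id}, "
                    f"annotation is {self.genome_id}")
            if g.gene_id in seen:
                raise DuplicateGeneError(
                    f"{self.genome_id}: duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contig_lengths:
                raise UnknownContigError(
                    f"{self.genome_id}: gene {g.gene_id} on undeclared "
                    f"contig {g.contig_id}")
            if g.end > self.contig_lengths[g.contig_id]:
                raise CoordinateOverflowError(
                    f"{self.genome_id}: gene {g.gene_id} end {g.end} exceeds "
                    f"contig {g.contig_id} length "
                    f"{self.contig_lengths[g.contig_id]}")
        for h in self.hits:
            if h.gene_id not in seen:
                raise UnknownGeneError(
                    f"{self.genome_id}: hit {h.accession} references unknown "
                    f"gene {h.gene_id}")

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths.values())

    def hits_by_gene(self) -> dict[str, list[DomainHit]]:
        if self._hits_by_gene is None:
            d: dict[str, list[DomainHit]] = {}
            for h in self.hits:
                d.setdefault(h.gene_id, []).append(h)
            self._hits_by_gene = d
        return self._hits_by_gene

    def accessions(self, gene_id: str,
                   namespace: Optional[str] = None) -> set[str]:
        hits = self.hits_by_gene().get(gene_id, [])
        return {h.accession for h in hits
                if namespace is None or h.namespace == namespace}

    def genes_on_contig(self, contig_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig_id == contig_id]


@dataclass
class CountMatrix:
    """Feature-family x genome non-negative integer counts."""

    counts: pd.DataFrame  # index = feature ids, columns = genome ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise FormatError("count matrix has duplicate row/column labels")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("count matrix entries must be integers")
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("count matrix entries must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df)


@dataclass
class CoverageTable:
    """Sample x genome mapped-read counts plus totals and genome lengths.

    Column sums over genomes may fall short of the sample total (unmapped
    reads are allowed) but no single cell may exceed it.
    """

    mapped_reads: pd.DataFrame   # index = samples, columns = genomes
    total_reads: pd.Series       # per sample
    genome_lengths: pd.Series    # per genome, bp

    def __post_init__(self) -> None:
        m = self.mapped_reads
        if len(m.columns) == 0:
            raise CoverageError("no genomes in coverage table")
        if len(m.index) == 0:
            raise CoverageError("no samples in coverage table")
        arr = m.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CoverageError("mapped_reads must be integer counts")
            self.mapped_reads = m.astype(np.int64)
            arr = self.mapped_reads.to_numpy()
        if (arr < 0).any():
            raise CoverageError("mapped_reads must be non-negative")
        self.total_reads = self.total_reads.reindex(m.index)
        self.genome_lengths = self.genome_lengths.reindex(m.columns)
        if self.total_reads.isna().any():
            raise CoverageError("total_reads missing for some samples")
        if self.genome_lengths.isna().any():
            raise CoverageError("genome_lengths missing for some genomes")
        if (self.total_reads <= 0).any():
            raise CoverageError("total_reads must be positive")
        if (self.genome_lengths <= 0).any():
            raise CoverageError("genome_lengths must be positive")
        # canonical axis names so write->read round-trips compare equal
        self.mapped_reads.index.name = None
        self.mapped_reads.columns.name = None
        self.total_reads.name = "total_reads"
        self.genome_lengths.name = "genome_length"
        over = self.mapped_reads.gt(self.total_reads, axis=0)
        if over.to_numpy().any():
            s, g = np.argwhere(over.to_numpy())[0]
            raise CoverageError(
                f"mapped_reads[{m.index[s]}, {m.columns[g]}] exceeds "
                f"total_reads[{m.index[s]}]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mapped_reads.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.mapped_reads.columns)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def _parse_gff3(path: Path, genome_id: str
                ) -> tuple[dict[str, int], list[GeneRecord]]:
    contig_lengths: dict[str, int] = {}
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: malformed ##sequence-region")
                contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 GFF3 columns, "
                    f"got {len(cols)}")
            contig, _src, _type, start, end, _score, strand, _phase, attrs \
                = cols
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: feature without ID=")
            genes.append(GeneRecord(
                genome_id=genome_id, contig_id=contig, gene_id=gene_id,
                start=int(start), end=int(end), strand=strand,
                product=attr_map.get("product")))
    return contig_lengths, genes


def _parse_gene_tsv(path: Path, genome_id: str
                    ) -> tuple[dict[str, int], list[GeneRecord]]:
    """TSV dialect: ``#contig <id> <length>`` header lines, then a header
    row ``contig_id gene_id start end strand [product]``."""
    contig_lengths: dict[str, int] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#contig\t"):
                _tag, cid, length = line.rstrip("\n").split("\t")
                contig_lengths[cid] = int(length)
            elif line.startswith("#"):
                continue
            else:
                body.append(line)
    if not body:
        raise FormatError(f"{path}: no gene rows")
    df = pd.read_csv(StringIO("".join(body)), sep="\t", dtype=str)
    required = {"contig_id", "gene_id", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: gene TSV missing columns {sorted(required - set(df.columns))}")
    genes = [GeneRecord(
        genome_id=genome_id, contig_id=r.contig_id, gene_id=r.gene_id,
        start=int(r.start), end=int(r.end), strand=r.strand,
        product=getattr(r, "product", None))
        for r in df.itertuples()]
    return contig_lengths, genes


def read_annotation(gene_table_path: str | Path,
                    domain_table_path: str | Path,
                    genome_id: Optional[str] = None) -> GenomeAnnotation:
    """Read a gene table (GFF3 or TSV dialect) plus a domain-hit TSV.

    The gene table format is chosen by extension (``.gff``/``.gff3`` vs
    anything else). ``genome_id`` defaults to the gene table's file stem.
    """
    gene_path = Path(gene_table_path)
    hit_path = Path(domain_table_path)
    if not gene_path.exists():
        raise FileNotFoundError(gene_path)
    if not hit_path.exists():
        raise FileNotFoundError(hit_path)
    gid = genome_id or gene_path.stem
    if gene_path.suffix.lower() in (".gff", ".gff3"):
        contig_lengths, genes = _parse_gff3(gene_path, gid)
    else:
        contig_lengths, genes = _parse_gene_tsv(gene_path, gid)
    hits_df = pd.read_csv(hit_path, sep="\t", dtype={"gene_id": str,
                                                     "accession": str,
                                                     "namespace": str})
    required = {"gene_id", "accession", "namespace"}
    if not required.issubset(hits_df.columns):
        raise FormatError(
            f"{hit_path}: domain TSV missing columns "
            f"{sorted(required - set(hits_df.columns))}")
    hits = []
    for r in hits_df.itertuples():
        score = getattr(r, "score", None)
        kind = getattr(r, "score_kind", None)
        if score is not None and (isinstance(score, float) and np.isnan(score)):
            score, kind = None, None
        if isinstance(kind, float) and np.isnan(kind):
            kind = None
        hits.append(DomainHit(gene_id=r.gene_id, accession=r.accession,
                              namespace=r.namespace, score=score,
                              score_kind=kind))
    return GenomeAnnotation(genome_id=gid, contig_lengths=contig_lengths,
                            genes=genes, hits=hits)


def write_annotation(a: GenomeAnnotation, gene_table_path: str | Path,
                     domain_table_path: str | Path) -> None:
    """Write GFF3 + domain TSV that round-trip through read_annotation."""
    gene_path = Path(gene_table_path)
    with open(gene_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in sorted(a.contig_lengths):
            fh.write(f"##sequence-region {cid} 1 {a.contig_lengths[cid]}\n")
        for g in a.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([g.contig_id, "guildscan", "gene",
                                str(g.start), str(g.end), ".", g.strand,
                                ".", attrs]) + "\n")
    rows = [{"gene_id": h.gene_id, "accession": h.accession,
             "namespace": h.namespace,
             "score": "" if h.score is None else h.score,
             "score_kind": "" if h.score_kind is None else h.score_kind}
            for h in a.hits]
    pd.DataFrame(rows, columns=["gene_id", "accession", "namespace",
                                "score", "score_kind"]).to_csv(
        domain_table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coverage I/O
# ---------------------------------------------------------------------------

def read_coverage(path: str | Path) -> CoverageTable:
    """Read a coverage TSV.

    Dialect: ``#genome_length <genome> <bp>`` header lines, then a header
    row ``sample_id  total_reads  <genome> ...`` followed by one row per
    sample of integer read counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lengths: dict[str, int] = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#genome_length\t"):
                _tag, gid, length = line.rstrip("\n").split("\t")
                lengths[gid] = int(length)
            elif line.startswith("#"):
                continue
            else:
                body.append(line)
    if not body:
        raise CoverageError(f"{path}: empty coverage table")
    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    if "sample_id" not in df.columns or "total_reads" not in df.columns:
        raise FormatError(f"{path}: need sample_id and total_reads columns")
    df = df.set_index("sample_id")
    total = df.pop("total_reads")
    if len(df.columns) == 0:
        raise CoverageError(f"{path}: no genomes")
    missing = [g for g in df.columns if g not in lengths]
    if missing:
        raise CoverageError(f"{path}: no #genome_length for {missing}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any() or not np.allclose(bad, np.round(bad)):
            raise CoverageError(f"{path}: non-integer counts in {col}")
    return CoverageTable(
        mapped_reads=df.astype(np.int64),
        total_reads=total.astype(np.int64),
        genome_lengths=pd.Series(lengths, dtype=np.int64)[list(df.columns)])


def write_coverage(cov: CoverageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in cov.genome_ids:
            fh.write(f"#genome_length\t{gid}\t{int(cov.genome_lengths[gid])}\n")
        out = cov.mapped_reads.copy()
        out.insert(0, "total_reads", cov.total_reads)
        out.to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> TreeNode:
    """Parse a rooted newick tree; validates tip uniqueness and lengths.

    Missing branch lengths default to 0 with a logged warning; negative
    lengths are rejected.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise TreeParseError(f"{path}: {exc}") from exc
    return validate_tree(tree, source=str(path))


def validate_tree(tree: TreeNode, source: str = "<tree>") -> TreeNode:
    tips = [t.name for t in tree.tips()]
    seen: set[str] = set()
    for name in tips:
        if name in seen:
            raise DuplicateTipLabelError(f"{source}: duplicate tip {name!r}")
        seen.add(name)
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
            if not node.is_root():
                n_missing += 1
        elif node.length < 0:
            raise TreeParseError(
                f"{source}: negative branch length at {node.name!r}")
    if n_missing:
        logger.warning("%s: %d branch lengths missing, set to 0",
                       source, n_missing)
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# FASTA convenience (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
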