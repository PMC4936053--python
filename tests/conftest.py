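import numpy as np
import pandas as pd
import pytest

from guildscan.core_io import DomainHit, GeneRecord, GenomeAnnotation


def make_annotation(genome_id="g", contig_len=100_000, genes=(), hits=()):
    """Compact annotation builder: genes as (gene_id, start, end, strand),
    hits as (gene_id, accession, namespace)."""
    return GenomeAnnotation(
        genome_id=genome_id,
        contig_lengths={"c1": contig_len},
        genes=[GeneRecord(genome_id=genome_id, contig_id="c1", gene_id=g,
                          start=s, end=e, strand=st)
               for g, s, e, st in genes],
        hits=[DomainHit(gene_id=g, accession=a, namespace=ns)
              for g, a, ns in hits])


@pytest.fixture
def two_gene_annotation():
    return make_annotation(
        genes=[("g1", 100, 1000, "+"), ("g2", 1200, 2000, "+")],
        hits=[("g1", "GH13", "CAZY")])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
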