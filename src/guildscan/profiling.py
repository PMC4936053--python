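"""CAZy family count/percent matrices and count-model normalisations.

The counting unit is gene x family: a gene annotated with k distinct CAZy
families contributes 1 to each family's count (domain-level annotations,
family counts read as category abundances). Percentages are taken against
the total number of CAZy-annotated gene-family assignments per genome.

``size_factors`` implements the median-of-ratios construction used by
count-based differential abundance models; ``stabilize`` is a shifted-log
transform of size-factor-normalised counts used only for clustering,
heatmaps and ordination — the inferential path works on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (CountMatrix, DuplicateGenomeError, GenomeAnnotation,
                      GuildscanError, logger)


@dataclass
class ProfileMatrix:
    """Per-genome percentage profile; non-degenerate columns sum to 100."""

    percent: pd.DataFrame  # index = families, columns = genomes

    @property
    def feature_ids(self) -> list[str]:
        return list(self.percent.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.percent.columns)

    def write_tsv(self, path) -> None:
        self.percent.to_csv(path, sep="\t", index_label="feature_id")


def build_cazy_matrix(annotations: Sequence[GenomeAnnotation]) -> CountMatrix:
    """Count CAZy families per genome (gene x distinct family unit)."""
    seen: set[str] = set()
    for a in annotations:
        if a.genome_id in seen:
            raise DuplicateGenomeError(f"duplicate genome_id {a.genome_id}")
        seen.add(a.genome_id)
    per_genome: dict[str, dict[str, int]] = {}
    families: set[str] = set()
    for a in annotations:
        counts: dict[str, int] = {}
        for g in a.genes:
            for fam in a.accessions(g.gene_id, namespace="CAZY"):
                counts[fam] = counts.get(fam, 0) + 1
        if not counts:
            logger.warning("genome %s has no CAZy-annotated genes",
                           a.genome_id)
        per_genome[a.genome_id] = counts
        families.update(counts)
    index = sorted(families)
    df = pd.DataFrame(
        {gid: [per_genome[gid].get(f, 0) for f in index]
         for gid in per_genome},
        index=index, dtype=np.int64)
    return CountMatrix(counts=df)


def percent_of_cazy(m: CountMatrix) -> ProfileMatrix:
    """100 x count / per-genome CAZy total; all-zero genomes stay zero."""
    totals = m.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("genomes with zero CAZy counts kept as zero "
                       "columns: %s", list(totals.index[zero]))
    safe = totals.replace(0, 1)
    return ProfileMatrix(percent=100.0 * m.counts / safe)


def size_factors(m: CountMatrix, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference for each feature is its geometric mean across genomes;
    features containing a zero are excluded (their geometric mean is 0).
    If no feature is nonzero in every genome, an error advises the
    ``pseudo_reference`` fallback, which takes geometric means over
    positive counts only.
    """
    counts = m.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_positive = (counts > 0).all(axis=1)
    if pseudo_reference:
        logger.info("size_factors: pseudo-reference mode (positive-count "
                    "geometric means)")
        pos = counts > 0
        usable = pos.any(axis=1)
        ref = np.full(counts.shape[0], np.nan)
        for j in np.flatnonzero(usable):
            ref[j] = np.exp(logc[j, pos[j]].mean())
        use = usable
    else:
        if not all_positive.any():
            raise GuildscanError(
                "no feature has nonzero counts in every genome; rerun "
                "with pseudo_reference=True (positive-count geometric "
                "means)")
        ref = np.exp(np.where(all_positive, logc.mean(axis=1), np.nan))
        use = all_positive
    ratios = counts[use] / ref[use, None]
    s = np.array([np.median(col[col > 0]) if (col > 0).any() else np.nan
                  for col in ratios.T])
    if np.isnan(s).any():
        raise GuildscanError("size factor undefined for some genome "
                             "(all reference features zero)")
    s = s / np.exp(np.log(s).mean())  # geometric-mean normalisation
    return pd.Series(s, index=m.counts.columns, name="size_factor")


def stabilize(m: CountMatrix, s: pd.Series) -> pd.DataFrame:
    """log2(count / s_g + 1) — visualization/clustering transform only."""
    if (s <= 0).any():
        raise GuildscanError("size factors must be positive")
    return np.log2(m.counts / s.reindex(m.counts.columns) + 1.0)


def most_abundant(m: CountMatrix, n: int = 30,
                  prefix: str = "GH") -> list[str]:
    """The n most abundant families (by total count across genomes) with
    the given accession prefix; ties broken lexicographically."""
    sub = m.counts[m.counts.index.str.startswith(prefix)] \
        if prefix else m.counts
    totals = sub.sum(axis=1)
    order = sorted(totals.index, key=lambda f: (-totals[f], f))
    return order[:n]
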