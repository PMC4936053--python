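"""Presence/absence and relative abundance from read-mapping counts.

A genome is *present* in a sample when its mapped reads amount to at
least ``cutoff_fraction`` (default 0.5 %) of the sample's total reads.
The boundary is decided with exact rational arithmetic — mapped/total is
never formed as a float — so a sample sitting exactly on the cutoff is
inclusively present.

Relative abundance of present genomes is the percentage of total reads
attributed to the genome, rescaled by mean-panel-length / genome-length
so that equal sequencing depth yields equal abundance regardless of
genome size ("normalized for genome size"). A ``raw_fraction`` mode
reports the unnormalised read percentage; the mode used is recorded in
the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import pandas as pd

from .core_io import CoverageTable, GuildscanError


@dataclass
class PresenceMatrix:
    presence: pd.DataFrame  # bool, samples x genomes
    cutoff_fraction: Fraction


@dataclass
class AbundanceMatrix:
    abundance: pd.DataFrame  # percent, samples x genomes; 0 where absent
    normalization: dict = field(default_factory=dict)


def _as_fraction(cutoff: float | str | Fraction) -> Fraction:
    if isinstance(cutoff, Fraction):
        f = cutoff
    else:
        f = Fraction(str(cutoff))
    if not (0 <= f <= 1):
        raise GuildscanError(f"cutoff {cutoff} outside [0, 1]")
    return f


def detect_presence(cov: CoverageTable,
                    cutoff: float | str | Fraction = 0.005
                    ) -> PresenceMatrix:
    """presence[s, g] <=> mapped[s, g] / total[s] >= cutoff (inclusive),
    compared as mapped * cutoff_den >= cutoff_num * total in integers."""
    frac = _as_fraction(cutoff)
    num, den = frac.numerator, frac.denominator
    mapped = cov.mapped_reads.to_numpy(dtype=object)
    total = cov.total_reads.to_numpy(dtype=object)
    present = (mapped * den) >= (total[:, None] * num)
    return PresenceMatrix(
        presence=pd.DataFrame(present.astype(bool),
                              index=cov.sample_ids,
                              columns=cov.genome_ids),
        cutoff_fraction=frac)


def relative_abundance(cov: CoverageTable, presence: PresenceMatrix,
                       mode: str = "size_normalized") -> AbundanceMatrix:
    """Percent abundance of present genomes; absent genomes are 0.

    ``size_normalized`` (default): 100 * mapped/total * (mean panel
    length / genome length). ``raw_fraction``: 100 * mapped/total.
    """
    if mode not in ("size_normalized", "raw_fraction"):
        raise GuildscanError(f"unknown normalization mode {mode!r}")
    frac = cov.mapped_reads.div(cov.total_reads, axis=0)
    pct = 100.0 * frac
    meta = {"mode": mode}
    if mode == "size_normalized":
        mean_len = float(cov.genome_lengths.mean())
        scale = mean_len / cov.genome_lengths.astype(float)
        pct = pct.mul(scale, axis=1)
        meta.update(mean_genome_length=mean_len,
                    formula="100 * mapped/total * mean_len/genome_len")
    else:
        meta.update(formula="100 * mapped/total")
    pct = pct.where(presence.presence, 0.0)
    return AbundanceMatrix(abundance=pct, normalization=meta)


def summarize(presence: PresenceMatrix, abundance: AbundanceMatrix,
              groups: Optional[pd.Series] = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genome prevalence and mean abundance among positive samples,
    plus overall family-level prevalence (any genome present).

    Returns (per_genome table, overall table); with ``groups`` (a sample
    -> group Series) both are additionally stratified.
    """
    pres = presence.presence
    ab = abundance.abundance

    def _summary(p: pd.DataFrame, a: pd.DataFrame, label: str
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
        prev = p.mean(axis=0)
        mean_ab = a.where(p).mean(axis=0).fillna(0.0)
        per_genome = pd.DataFrame({
            "group": label, "prevalence": prev,
            "mean_abundance_when_present": mean_ab,
            "n_samples": len(p)})
        family_prev = float(p.any(axis=1).mean())
        overall = pd.DataFrame([{
            "group": label, "family_prevalence": family_prev,
            "n_samples": len(p)}])
        return per_genome, overall

    per, over = _summary(pres, ab, "all")
    tables_g, tables_o = [per], [over]
    if groups is not None:
        groups = groups.reindex(pres.index)
        if groups.isna().any():
            raise GuildscanError("group labels missing for some samples")
        for label in sorted(groups.unique()):
            idx = groups.index[groups == label]
            pg, og = _summary(pres.loc[idx], ab.loc[idx], str(label))
            tables_g.append(pg)
            tables_o.append(og)
    per_genome = pd.concat(tables_g).rename_axis("genome_id").reset_index()
    overall = pd.concat(tables_o, ignore_index=True)
    return per_genome, overall
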