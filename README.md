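# guildscan

Comparative genomics of gut *Bacteroidales* population genomes:
trophic-guild inference from carbohydrate-active enzyme (CAZyme)
profiles, polysaccharide utilization locus (PUL) detection, species and
genus delineation by fragment ANI and reciprocal-best-hit AAI, Faith's
phylogenetic diversity on gene trees, a core-metabolism gene-set census,
and read-mapping prevalence across metagenome samples.

The package is written for microbial ecologists working with draft
(metagenome-assembled) genomes whose upstream annotation — gene calls,
Pfam/TIGRFAM/CAZy/COG/KO assignments, read-mapping counts, gene trees —
already exists as tables. guildscan consumes those tables, never runs the
annotators, and ships a synthetic-data module that generates every input
with planted ground truth, so the entire pipeline is testable without
downloading any external dataset.

## The statistics at the core

**Trophic guilds.** Genomes are clustered by average-linkage hierarchical
clustering of Bray–Curtis dissimilarities between percent CAZy profiles
(on the 30 most abundant families). A family *defines* a guild only when
two independent tests agree:

1. *Indicator value* (Dufrêne–Legendre): IndVal_jk = 100 · A_jk · B_jk
   with specificity A_jk = μ_jk / Σ_k' μ_jk' and fidelity B_jk =
   occupancy, tested against random relabellings preserving group sizes
   with Benjamini–Hochberg correction across families; and
2. a *negative-binomial Wald test* (Var = μ + αμ²; median-of-ratios size
   factors; moment dispersion shrunk toward the across-family median)
   showing enrichment toward the guild against **every** other guild at
   q ≤ α.

**PULs.** A locus is anchored by an adjacent same-strand susC→susD gene
pair (TonB-dependent transporter + surface glycan-binding lipoprotein,
gap ≤ 500 bp, C upstream of D in transcription direction), with
associated CAZymes within 10 genes and 10 kb and an optional hybrid
two-component sensor within 5 kb.

**Relatedness.** ANI cuts the query into 1020-bp fragments, aligns each
against the subject (exact affine local alignment, edlib-seeded), keeps
fragments at ≥ 30 % identity over ≥ 70 % length, and averages both
directions; species are single-linkage components of the >95 % graph.
AAI averages identities over reciprocal best hits (BLOSUM62, ≥ 30 %
identity, ≥ 70 % coverage).

**Diversity and prevalence.** Faith's PD is the branch-length sum of the
minimal spanning subtree per guild tip set. A genome is present in a
sample when mapped/total ≥ 0.5 % of reads, decided in exact rational
arithmetic; abundance is the read percentage normalised by genome size.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
cohort (seed 1):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_cazy_guilds.py
python analysis/03_pul_census.py
python analysis/04_relatedness.py
python analysis/05_diversity_prevalence.py
```

which prints, among other things:

```
clustering ARI vs planted guilds: 1.000
  alpha_glucan: 4 defining families (planted 5, jaccard 0.80): GH26, GH32, GH45, GH59
  host_glycan: 3 defining families (planted 5, jaccard 0.60): GH24, GH36, GH54
  plant_glycan: 4 defining families (planted 5, jaccard 0.80): GH17, GH28, GH29, GH7
4 susCD pairs called (3 with associated CAZymes, 2 near an HTCS regulator)
planted PULs recovered: 3/3; decoy pairs wrongly called: 0
p_sub 0.05: ANI 95.074 (truth 95.048, error +0.026)
species partition: 27 clusters from 30 genomes with 3 pairs above 95% ANI
presence agrees with planted truth in 100.0% of cells; family-level prevalence 85.0% of samples
```

Reading: the clustering recovers the three planted guilds exactly
(adjusted Rand index 1.0); the dual criterion recovers 11 of 15 planted
defining families with no false positives (recall against the small
5-genome guild is power-limited — see `docs/methods.md`); all planted
PULs are found and no decoy is called; the ANI estimator tracks the
simulated 5 % divergence to 0.03 points; and the single-linkage worked
example with three >95 % pairs among 30 genomes yields 27 species.

The same stages are available as a CLI (`guildscan simulate|profile|
guilds|puls|census|ani|aai|cluster|pd|prevalence|run`) and as one
config-driven pipeline:

```bash
guildscan run --config config.yaml   # mode: synthetic | user-data
```

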