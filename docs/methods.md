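# Methods

guildscan re-implements, as a tested library plus analysis drivers, the
comparative-genomics workflow used to characterise an uncultured gut
bacterial family from draft population genomes: CAZyme-profile trophic
guilds, polysaccharide utilization locus (PUL) detection, fragment-based
ANI / reciprocal-best-hit AAI species and genus delineation, Faith's
phylogenetic diversity on gene trees, a gene-set census, and read-mapping
prevalence. Because the original deposited genomes and metagenomes are not
required, every stage runs on synthetic inputs with planted ground truth;
this note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Synthetic cohort

The generator module defines the study conditions the pipeline is
exercised under; its defaults are fixed and are not tuning knobs.

**CAZy counts.** Family-by-genome counts are negative binomial with mean
mu and dispersion alpha, Var = mu + alpha*mu^2 (the parameterisation of
count-based differential-abundance models). Defaults: three guilds of
13, 12 and 5 genomes (the alpha-glucan / plant-glycan / host-glycan guild
sizes of the motivating study), 60 families, baseline mean 6, dispersion
0.3, and five defining families per guild whose mean is multiplied by 3
in that guild's genomes only. Dispersion 0 degenerates to Poisson;
enrichment 1 gives a pure null. The generator returns the planted labels
and defining sets, and downstream recovery tests consume that truth
rather than re-deriving it.

What this emulates — and does not: real CAZy profiles have family-specific
baselines, phylogenetic correlation between genomes, and annotation noise;
the generator has exchangeable genomes and a single baseline. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery at the stated effect sizes, not performance on real annotations.

**Gene tables.** One genome is laid out as equal-length (900 bp) genes
separated by a constant 100-bp intergenic gap. Planted PULs are adjacent
same-strand susC→susD pairs (susC = TIGR04056, susD = PF07980 by default)
with a CAZy-annotated gene adjacent and, in alternate loci, a hybrid
two-component system (HTCS) gene within 5 kb. Decoys each violate exactly
one clause of the detection rule: lone susC, separated pair (an
intervening gene), opposite strands, D-before-C in transcription
direction, and a valid pair whose nearest CAZyme lies beyond the
association window. Cassettes are separated by 13 plain genes (~13 kb) so
association windows never overlap.

**Sequence pairs.** A random genome and a copy with i.i.d. substitutions
(uniform over the three alternative bases — identity, not evolutionary
realism, is what the ANI oracle needs) and optional geometric-length
indels. The realized identity 1 − substitutions/length is recorded as
truth. Proteome pairs are built the same way over the 20 amino acids.

**Coverage tables.** Present genomes draw read fractions in
[2x, 10x] of the presence cutoff (rounded up), absent genomes in
[0, 0.5x] (rounded down), so presence truth is exact by construction.
**Trees** are Yule topologies with exponential branch lengths (mean 0.1).

All generators are pure functions of parameters + seed.

## CAZy profiling

The counting unit is gene x family: a gene with k distinct CAZy
accessions increments k rows (domain-level annotations read as category
abundances). Percent profiles divide by the per-genome CAZy total
(columns of non-degenerate genomes sum to 100). Size factors are
median-of-ratios against per-feature geometric means, rescaled to
geometric mean 1; when no feature is positive in every genome the
function refuses and offers a pseudo-reference fallback (geometric means
over positive counts only, logged). The variance-stabilising transform is
log2(count/s + 1) on normalised counts; it feeds clustering, heatmaps and
PCA only — the inferential path always works on raw counts.

## Guild inference

**Candidate labels** come from average-linkage hierarchical clustering of
Bray–Curtis dissimilarities between percent profiles, cut to K groups.
Clustering is computed on the 30 most abundant families (total percent,
ties lexicographic) — the heatmap scope the guilds were originally
delineated from; the full profile is available via `top_n=None`. The
restriction matters: on default simulations label recovery averages
ARI 0.90 on the top-30 scope versus 0.80 on the full 60-family profile,
because the low-count families contribute mostly multinomial noise to the
dissimilarity. All-zero dissimilarity is rejected as structureless rather
than split arbitrarily. User-supplied labels may replace the clustering
(reproduction mode).

**Indicator families (IndVal).** For family j and guild k, specificity
A_jk = mean_jk / sum_k' mean_jk' and fidelity B_jk = occupancy; the
statistic is max_k 100*A*B with ties to the first guild in sorted order.
Significance comes from random relabellings preserving group sizes, with
the (1+b)/(1+n) estimator so p is never 0, and BH correction across
families. All-zero families are flagged with statistic 0 and p 1. Because
the statistic depends on counts only through group sums and positivity,
its permutation null is a coarse lattice for integer counts: p-values are
super-uniform (valid but conservative), not exactly uniform — the unit
tests assert exactly that.

**Pairwise enrichment.** A self-contained negative-binomial Wald test per
family and guild pair: size-factor-normalised group means; per-family
method-of-moments dispersion (pooled within-group variance) shrunk 50/50
toward the across-family median and floored at 1e-8; log2 fold change
with a 0.5 pseudo-mean; standard error from the NB variance
mu/s + alpha*mu^2 through the delta method (equivalently, the Fisher
information of the NB mean); two-sided normal p; BH within each
comparison. At the null conditions used in testing (200 families,
dispersion 0.3, 10 vs 10) the empirical size at 0.05 is ~0.04.

**Dual criterion.** A family defines guild k iff it is the family's best
indicator guild with BH-adjusted IndVal p <= alpha AND it is enriched
toward k against *every* other guild at q <= alpha. The criterion is
monotone in alpha and empirically has precision ~1 on simulations (what
it retains was planted). Its recall is bounded by the weakest pairwise
comparison: against the 5-genome guild the Wald statistic for a 3x effect
at dispersion 0.3 has expectation ~3.1, i.e. per-family power ~0.75 after
BH — an intrinsic property of the study conditions (an independent
DESeq2 run on the same simulated counts recovers a comparable fraction),
so full recovery of planted defining sets should not be expected at these
sample sizes.

**Ordination** is column-centred SVD of the stabilised matrix with the
sign convention that each component's largest-magnitude loading is
positive.

## PUL detection and census

A susCD pair requires: same contig, adjacent genes (zero intervening),
intergenic gap <= 500 bp, same strand, and C upstream of D in
transcription direction (on the minus strand susD precedes susC in genome
coordinates). Pairing is greedy left-to-right; each gene joins at most
one pair. Every clause is explicit configuration because upstream
annotators and operon architectures differ. Associated CAZymes must lie
within 10 genes AND 10 kb of the pair span; an HTCS regulator within 5 kb
sets the regulator flag. Shrinking any window can only remove calls or
associations.

The census marks each defined gene set (respiratory complex I in its
11-subunit form lacking the NuoEFG dehydrogenase module, ATP synthase,
three-subunit complex II, Nqr, cydAB, the ten-component T9SS plus PorXY,
the urease cluster, the oxalate pair with its permease, and
oxidative-stress singletons) complete / partial / absent. Partial sets
with a found member within 5 kb of a contig end are boundary-flagged:
truncated assembly, not gene loss, may explain the absence. The flag is
deliberately restricted to partial sets.

## Genome relatedness

**ANI** follows the fragment recipe: the query is cut into consecutive
non-overlapping 1020-bp fragments (trailing remainder discarded), each
fragment is aligned against the whole subject on both strands, and
fragments are retained only at >= 30 % identity over >= 70 % of their
length; ANI is 100x the mean retained identity, computed in both
directions with the reciprocal mean as headline. Identity denominators
include gap columns. The alignment kernel seeds each fragment with an
edlib infix (semi-global) search on both strands to locate the best
subject region, then computes the exact affine local alignment
(match +1, mismatch −2, gap open −5, gap extend −2, 150-bp window margin)
with Biopython's PairwiseAligner. The seeded-exact design keeps per-pair
cost at seconds for 100-kb genomes while the retention contract is
unchanged; the kernel is pluggable behind the same interface. On
simulated pairs without indels the estimator tracks 100x(1−p_sub) to
within 0.07 points up to 10 % divergence; unrelated sequences retain no
fragments and yield a below-detection sentinel, never 0.

**AAI** is the mean identity over reciprocal best hits of all-vs-all
exact local alignments under BLOSUM62 (open −11, extend −1), with hits
required to reach 30 % identity and 70 % coverage of the shorter
sequence; ties break deterministically by index, and each protein joins
at most one pair. Zero RBHs yields the sentinel.

**Species/genus partitioning** is single-linkage: connected components of
the graph with edges strictly above the threshold (matching an
"ANI > 95 %" species rule; inclusive mode available). Partitions refine
monotonically as the threshold rises. No default genus-level AAI
threshold is pretended: it is required configuration.

## Phylogenetic diversity

Faith's PD of a tip set is the branch-length sum of the minimal spanning
subtree. With include_root=true (the default of the reference R
implementation, and ours) an edge counts iff its subtree contains a
selected tip; without the root an edge counts iff selected tips lie on
both of its sides, so a singleton scores 0. Branch lengths missing from
input default to 0 with a warning. Per-guild scores average across the
supplied gene trees (susC and susD handled as separate trees); whether
the original study pooled or averaged per tree is unstated, so both the
per-tree values and the mean are reported.

## Prevalence

A genome is present in a sample when mapped/total >= cutoff (default
0.5 %). The comparison is exact rational arithmetic (mapped * den >=
num * total), so the boundary is inclusive with no floating-point
tolerance. "Normalised for genome size" is ambiguous in the source
procedure; the adopted form is 100 * mapped/total * (mean panel length /
genome length), which preserves the percent-of-reads anchor, is invariant
to common rescaling of all lengths, and is recorded in the output
metadata; `raw_fraction` mode reports the plain read percentage.
Prevalence is the fraction of samples present (per genome, and any-genome
for the family), with abundance averaged over positive samples only, and
optional stratification by sample metadata.

## Problem sizes and determinism

Default analysis and acceptance runs use 30 genomes x 60 families,
999 permutations, 20 simulation seeds for recovery metrics, 100-kb genome
pairs at four divergence levels, 25x200-aa proteomes, 20-30-tip trees and
15-20 coverage samples — sizes chosen so a complete run finishes in
about a minute on one core while every statistic retains enough
replication to be meaningful. Every stochastic step takes an explicit
seed and logs it; reruns with the same config are identical.

## Known limitations

* The NB Wald test uses normal asymptotics with moment dispersions; at
  group sizes below ~5 its size is not guaranteed, and the dual criterion
  is conservative by construction.
* The seeded ANI kernel could in principle miss the optimal local
  alignment when a fragment matches two distant subject regions almost
  equally well; for genome pairs related at >= 70 % identity this has no
  practical effect.
* Synthetic genomes have uniform gene length and spacing; PUL rule
  behaviour on irregular real gene tables is exercised only through the
  configurable windows, not through realistic geometry.
* AAI all-vs-all alignment is quadratic in proteome size and intended for
  the reduced proteomes used here, not full 2000-protein genomes.
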