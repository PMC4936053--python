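"""Trophic-guild assignment and guild-defining enzyme families.

Guild candidates come from average-linkage hierarchical clustering of
Bray-Curtis dissimilarities between per-genome percent profiles (or from
user-supplied labels in reproduction mode). A family *defines* a guild
only when two independent lines of evidence agree:

1. it is the guild's best indicator (Dufrene-Legendre IndVal, permutation
   null, BH-adjusted), and
2. it is significantly enriched in that guild against *every* other guild
   in pairwise negative-binomial Wald tests.

The NB Wald test is self-contained: per-family method-of-moments
dispersion shrunk 50/50 toward the across-family median, Fisher-information
standard errors, BH correction within each comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, GuildscanError, NoStructureError, logger
from .profiling import ProfileMatrix, size_factors

GuildLabels = pd.Series  # genome_id -> guild label


def validate_labels(labels: GuildLabels) -> None:
    if labels.index.has_duplicates:
        raise GuildscanError("a genome is labelled more than once")
    if labels.isna().any():
        raise GuildscanError("unlabelled genomes present")
    if labels.nunique() < 2:
        raise GuildscanError("need >= 2 guilds")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_guilds(profile: ProfileMatrix, k: int,
                   top_n: Optional[int] = 30) -> GuildLabels:
    """Average-linkage / Bray-Curtis hierarchical clustering cut to k.

    Clustering is computed on the ``top_n`` most abundant families (by
    total percent across genomes, ties lexicographic) — the heatmap scope
    guilds are delineated from; pass ``top_n=None`` to use the full
    profile. Deterministic for a given input order (scipy merges the
    earliest pair among equal dissimilarities). All-zero dissimilarity is
    rejected as structureless rather than split arbitrarily.
    """
    genomes = profile.genome_ids
    if k > len(genomes):
        raise GuildscanError(f"k={k} exceeds {len(genomes)} genomes")
    if k < 2:
        raise GuildscanError("k must be >= 2")
    percent = profile.percent
    if top_n is not None and top_n < len(percent):
        totals = percent.sum(axis=1)
        keep = sorted(percent.index,
                      key=lambda f: (-totals[f], f))[:top_n]
        percent = percent.loc[keep]
    x = percent.to_numpy().T  # genomes as observations
    d = pdist(x, metric="braycurtis")
    if not np.isfinite(d).all():
        raise GuildscanError("undefined dissimilarity (all-zero profile?)")
    if np.allclose(d, 0):
        raise NoStructureError("all pairwise dissimilarities are zero")
    z = linkage(d, method="average")
    assign = fcluster(z, t=k, criterion="maxclust")
    return pd.Series([f"guild_{c}" for c in assign], index=genomes,
                     name="guild")


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------

@dataclass
class IndValResult:
    """Per-family indicator statistics.

    ``table`` columns: A_<guild>, B_<guild>, indval_<guild> for each guild,
    plus ``stat`` (max indval), ``best_guild`` (ties -> first guild in
    ``guild_order``), ``p`` (permutation, (1+b)/(1+n) estimator), ``q``
    (BH across families) and ``all_zero`` flag.
    """

    table: pd.DataFrame
    guild_order: list[str]
    n_perm: int
    seed: int


def _group_stats(counts: np.ndarray, member: np.ndarray,
                 sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group means and occupancy fractions. counts (F,G), member (G,K)."""
    sums = counts @ member
    means = sums / sizes
    occ = (counts > 0).astype(float) @ member / sizes
    return means, occ


def _indval_parts(counts: np.ndarray, member: np.ndarray,
                  sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means, occ = _group_stats(counts, member, sizes)
    denom = means.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    iv = 100.0 * a * occ
    return a, occ, iv


def indval(m: CountMatrix, labels: GuildLabels, n_perm: int = 999,
           seed: int = 0) -> IndValResult:
    """Dufrene-Legendre indicator values with a permutation null.

    A_jk = mean_jk / sum_k' mean_jk' (specificity), B_jk = occupancy
    (fidelity), indval = 100*A*B; the family statistic is max_k indval and
    its p-value comes from random relabellings preserving group sizes.
    All-zero families are flagged with indval 0 and p 1.
    """
    if n_perm < 99:
        raise GuildscanError("n_perm must be >= 99")
    validate_labels(labels)
    labels = labels.reindex(m.counts.columns)
    if labels.isna().any():
        raise GuildscanError("labels missing for some genomes")
    rng = np.random.default_rng(seed)
    logger.info("indval: n_perm=%d seed=%d", n_perm, seed)
    guilds = sorted(labels.unique())
    counts = m.counts.to_numpy(dtype=float)
    member = np.stack([(labels == g).to_numpy(float) for g in guilds],
                      axis=1)
    sizes = member.sum(axis=0)
    a, b, iv = _indval_parts(counts, member, sizes)
    stat = iv.max(axis=1)
    best = iv.argmax(axis=1)  # ties -> lowest guild index
    all_zero = counts.sum(axis=1) == 0

    exceed = np.zeros(counts.shape[0])
    lab_idx = np.array([guilds.index(l) for l in labels])
    for _ in range(n_perm):
        perm = rng.permutation(lab_idx)
        pm = np.zeros_like(member)
        pm[np.arange(len(perm)), perm] = 1.0
        _, _, iv_p = _indval_parts(counts, pm, sizes)
        exceed += iv_p.max(axis=1) >= stat - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    p = np.where(all_zero, 1.0, p)
    stat = np.where(all_zero, 0.0, stat)
    q = multipletests(p, method="fdr_bh")[1]

    data = {}
    for ki, g in enumerate(guilds):
        data[f"A_{g}"] = a[:, ki]
        data[f"B_{g}"] = b[:, ki]
        data[f"indval_{g}"] = iv[:, ki]
    data["stat"] = stat
    data["best_guild"] = [guilds[i] for i in best]
    data["p"] = p
    data["q"] = q
    data["all_zero"] = all_zero
    return IndValResult(table=pd.DataFrame(data, index=m.counts.index),
                        guild_order=guilds, n_perm=n_perm, seed=seed)


def indval_exhaustive(m: CountMatrix, labels: GuildLabels
                      ) -> tuple[pd.Series, pd.Series]:
    """Exact permutation p for the max-indval statistic by enumerating all
    distinct relabellings with fixed group sizes. Oracle-grade; only
    feasible for small n. Returns (stat, exact_p)."""
    validate_labels(labels)
    labels = labels.reindex(m.counts.columns)
    guilds = sorted(labels.unique())
    counts = m.counts.to_numpy(dtype=float)
    member = np.stack([(labels == g).to_numpy(float) for g in guilds],
                      axis=1)
    sizes = member.sum(axis=0)
    _, _, iv = _indval_parts(counts, member, sizes)
    stat = iv.max(axis=1)

    lab_idx = tuple(guilds.index(l) for l in labels)
    seen = set()
    exceed = np.zeros(counts.shape[0])
    total = 0
    for perm in set(permutations(lab_idx)):
        if perm in seen:
            continue
        seen.add(perm)
        pm = np.zeros_like(member)
        pm[np.arange(len(perm)), list(perm)] = 1.0
        _, _, iv_p = _indval_parts(counts, pm, sizes)
        exceed += iv_p.max(axis=1) >= stat - 1e-12
        total += 1
    p = exceed / total
    idx = m.counts.index
    return pd.Series(stat, index=idx), pd.Series(p, index=idx)


# ---------------------------------------------------------------------------
# Negative-binomial pairwise differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DAResult:
    """Wald test results per family for one ordered guild pair.

    ``lfc`` is log2(mu_2/mu_1) (positive = enriched in ``pair[1]``), with
    0.5 pseudo-mean stabilisation; ``excluded`` lists families zero in
    both groups.
    """

    pair: tuple[str, str]
    table: pd.DataFrame  # lfc, se, z, p, q, direction
    excluded: list[str]


def nb_pairwise_da(m: CountMatrix, labels: GuildLabels,
                   pair: tuple[str, str],
                   s: Optional[pd.Series] = None) -> DAResult:
    """Negative-binomial Wald test between two guilds, per family.

    Normalised counts z = y/s; per-family MoM dispersion (pooled
    within-group variance) shrunk 50/50 toward the across-family median
    and floored at 1e-8; SE from the NB Fisher information with the same
    0.5 pseudo-mean used in the fold change.
    """
    validate_labels(labels)
    k1, k2 = pair
    g1 = labels.index[labels == k1]
    g2 = labels.index[labels == k2]
    if len(g1) < 2 or len(g2) < 2:
        raise GuildscanError(f"both guilds need >= 2 genomes "
                             f"({k1}: {len(g1)}, {k2}: {len(g2)})")
    if s is None:
        s = size_factors(m)
    z = (m.counts / s.reindex(m.counts.columns)).astype(float)
    z1, z2 = z[g1].to_numpy(), z[g2].to_numpy()
    s1, s2 = s[g1].to_numpy(), s[g2].to_numpy()
    n1, n2 = z1.shape[1], z2.shape[1]

    both_zero = (z1.sum(axis=1) == 0) & (z2.sum(axis=1) == 0)
    if both_zero.any():
        logger.info("nb_pairwise_da %s vs %s: excluding %d all-zero "
                    "families", k1, k2, int(both_zero.sum()))

    mu1 = z1.mean(axis=1)
    mu2 = z2.mean(axis=1)
    # pooled within-group MoM dispersion
    resid = np.concatenate([z1 - mu1[:, None], z2 - mu2[:, None]], axis=1)
    s2_hat = (resid ** 2).sum(axis=1) / (n1 + n2 - 2)
    mbar = np.concatenate([z1, z2], axis=1).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_raw = np.where(mbar > 0, (s2_hat - mbar) / mbar ** 2, 0.0)
    alpha_raw = np.clip(alpha_raw, 0.0, None)
    usable = ~both_zero
    med = np.median(alpha_raw[usable]) if usable.any() else 0.0
    alpha = np.maximum(0.5 * alpha_raw + 0.5 * med, 1e-8)

    m1 = mu1 + 0.5
    m2 = mu2 + 0.5
    lfc = np.log2(m2 / m1)
    ln2sq = np.log(2.0) ** 2
    var1 = (m1[:, None] / s1[None, :] + alpha[:, None] * m1[:, None] ** 2
            ).sum(axis=1) / n1 ** 2
    var2 = (m2[:, None] / s2[None, :] + alpha[:, None] * m2[:, None] ** 2
            ).sum(axis=1) / n2 ** 2
    se = np.sqrt(var1 / (m1 ** 2 * ln2sq) + var2 / (m2 ** 2 * ln2sq))
    zstat = lfc / se
    p = 2.0 * norm.sf(np.abs(zstat))

    keep = ~both_zero
    idx = m.counts.index
    q = np.full(len(idx), np.nan)
    if keep.any():
        q[keep] = multipletests(p[keep], method="fdr_bh")[1]
    table = pd.DataFrame({
        "lfc": lfc, "se": se, "z": zstat, "p": p, "q": q,
        "direction": np.where(lfc > 0, k2, k1),
        "dispersion": alpha}, index=idx)[keep]
    return DAResult(pair=(k1, k2), table=table,
                    excluded=list(idx[both_zero]))


def all_pairwise_da(m: CountMatrix, labels: GuildLabels
                    ) -> dict[tuple[str, str], DAResult]:
    """nb_pairwise_da over every unordered guild pair (sorted order)."""
    s = size_factors(m)
    guilds = sorted(labels.unique())
    return {(a, b): nb_pairwise_da(m, labels, (a, b), s=s)
            for a, b in combinations(guilds, 2)}


# ---------------------------------------------------------------------------
# Dual criterion
# ---------------------------------------------------------------------------

@dataclass
class GuildDefinition:
    labels: GuildLabels
    defining: dict[str, set[str]]
    alpha: float
    evidence: pd.DataFrame  # per retained (family, guild): iv stat, q's


def define_guild_enzymes(iv: IndValResult,
                         da_all_pairs: Mapping[tuple[str, str], DAResult],
                         labels: GuildLabels,
                         alpha: float = 0.05) -> GuildDefinition:
    """Families defining each guild: indicator AND enriched vs every
    alternative guild (positive fold change toward the guild, BH q <=
    alpha in each pairwise comparison)."""
    validate_labels(labels)
    guilds = sorted(labels.unique())
    needed = set(frozenset(p) for p in combinations(guilds, 2))
    have = set(frozenset(p) for p in da_all_pairs)
    if not needed <= have:
        raise GuildscanError("da_all_pairs must cover every guild pair")

    defining: dict[str, set[str]] = {g: set() for g in guilds}
    rows = []
    t = iv.table
    for fam in t.index:
        if t.loc[fam, "all_zero"] or t.loc[fam, "q"] > alpha:
            continue
        k = t.loc[fam, "best_guild"]
        ok = True
        qs = {}
        for other in guilds:
            if other == k:
                continue
            key = (k, other) if (k, other) in da_all_pairs else (other, k)
            res = da_all_pairs[key]
            if fam not in res.table.index:
                ok = False
                break
            row = res.table.loc[fam]
            enriched_toward_k = (row["lfc"] > 0) == (key[1] == k)
            if not (enriched_toward_k and row["q"] <= alpha):
                ok = False
                break
            qs[other] = row["q"]
        if ok:
            defining[k].add(fam)
            rows.append({"family": fam, "guild": k,
                         "indval": t.loc[fam, "stat"],
                         "q_indval": t.loc[fam, "q"],
                         **{f"q_vs_{o}": qv for o, qv in qs.items()}})
    evidence = pd.DataFrame(rows)
    return GuildDefinition(labels=labels, defining=defining, alpha=alpha,
                           evidence=evidence)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def ordinate(x: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA by column-centred SVD; rows are observations (genomes).

    Returns first-two-component coordinates and explained variance
    fractions. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if x.shape[0] < 3:
        raise GuildscanError("need >= 3 genomes to ordinate")
    arr = x.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=0)
    if np.allclose(centred, 0):
        raise GuildscanError("constant matrix cannot be ordinated")
    u, sv, vt = np.linalg.svd(centred, full_matrices=False)
    for i in range(min(2, len(sv))):
        j = np.abs(vt[i]).argmax()
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var = sv ** 2 / (sv ** 2).sum()
    coords = pd.DataFrame(
        u[:, :2] * sv[:2], index=x.index, columns=["PC1", "PC2"])
    return coords, var[:2]
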