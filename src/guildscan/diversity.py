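"""Faith's phylogenetic diversity (PD) of tip subsets on gene trees.

PD(S) is the sum of branch lengths of the minimal subtree spanning the
tips in S. With ``include_root=True`` (the default of the reference R
implementation) the path from the subtree to the root is included: an
edge contributes iff its subtree contains at least one selected tip.
Without the root, an edge contributes iff selected tips lie on both of
its sides, so a single-tip subset scores 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from skbio import TreeNode

from .core_io import GuildscanError, logger


def faith_pd(tree: TreeNode, tips: Iterable[str],
             include_root: bool = True) -> float:
    """PD of a tip subset; raises on unknown tip labels."""
    tip_set = set(tips)
    if not tip_set:
        raise GuildscanError("tip set must be non-empty")
    tree_tips = {t.name for t in tree.tips()}
    unknown = tip_set - tree_tips
    if unknown:
        raise GuildscanError(f"unknown tip label(s): {sorted(unknown)}")
    total = len(tip_set)
    counts: dict[int, int] = {}
    pd_sum = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            counts[id(node)] = 1 if node.name in tip_set else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
        if node.is_root():
            continue
        n_sel = counts[id(node)]
        length = node.length or 0.0
        if include_root:
            if n_sel >= 1:
                pd_sum += length
        else:
            if 1 <= n_sel <= total - 1:
                pd_sum += length
    return pd_sum


def guild_pd(trees: TreeNode | Sequence[TreeNode],
             tip_guild_map: Mapping[str, str],
             include_root: bool = True) -> pd.DataFrame:
    """Per-guild PD on one or several gene trees.

    Each guild's tip set is scored on every tree that contains it; the
    table reports per-tree PD and the across-tree mean. Guilds with no
    tips on a tree are omitted from that tree with a warning.
    """
    if isinstance(trees, TreeNode):
        trees = [trees]
    guilds = sorted(set(tip_guild_map.values()))
    rows = []
    for ti, tree in enumerate(trees):
        tree_tips = {t.name for t in tree.tips()}
        unknown = set(tip_guild_map) - tree_tips
        if unknown:
            raise GuildscanError(
                f"tree {ti}: mapped tips absent: {sorted(unknown)}")
        for g in guilds:
            tips = {t for t, lab in tip_guild_map.items() if lab == g}
            if not tips:
                logger.warning("guild %s has no tips on tree %d; omitted",
                               g, ti)
                continue
            rows.append({"tree": ti, "guild": g, "n_tips": len(tips),
                         "pd": faith_pd(tree, tips,
                                        include_root=include_root)})
    table = pd.DataFrame(rows)
    mean = table.groupby("guild")["pd"].mean().rename("mean_pd")
    return table.merge(mean, on="guild")
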