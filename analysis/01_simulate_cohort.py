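#!/usr/bin/env python
"""Generate the synthetic study cohort every downstream analysis consumes.

Writes, under results/data/: a guild-structured CAZy count matrix with its
planted labels and defining families, a genome annotation with planted
PULs and decoys, genome/proteome pairs at controlled divergence, a gene
tree, and a coverage table with known presence — each with its truth file.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from guildscan import synthetic as syn
from guildscan.core_io import write_annotation, write_coverage, write_tree


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    m, labels, defining = syn.simulate_cazy_counts(
        syn.GuildSimParams(seed=args.seed))
    m.write_tsv(out / "cazy_counts.tsv")
    labels.to_csv(out / "guild_labels_truth.tsv", sep="\t", header=True)
    json.dump({g: sorted(s) for g, s in defining.items()},
              open(out / "defining_truth.json", "w"), indent=2)

    ann, pul_truth = syn.simulate_genome_tables(
        syn.PulSimParams(seed=args.seed))
    write_annotation(ann, out / "sim_genes.gff3", out / "sim_hits.tsv")
    json.dump(pul_truth, open(out / "pul_truth.json", "w"), indent=2,
              default=list)

    # genome pairs at controlled divergence are pure functions of the
    # seed and large; 04_relatedness.py regenerates them in memory
    ani_truth = {}
    for p_sub in (0.01, 0.02, 0.05, 0.10):
        _, _, ident = syn.simulate_sequence_pair(syn.DivergenceSimParams(
            length_bp=100_000, substitution_prob=p_sub, indel_prob=0.0,
            seed=args.seed))
        ani_truth[f"{p_sub}"] = ident
    json.dump(ani_truth, open(out / "ani_truth.json", "w"), indent=2)

    tree = syn.simulate_tree(n_tips=30, seed=args.seed)
    write_tree(tree, out / "gene_tree.nwk")

    rng = np.random.default_rng(args.seed)
    genomes = list(m.genome_ids)
    present = [set(rng.choice(genomes, size=int(rng.integers(0, 6)),
                              replace=False)) for _ in range(20)]
    cov, truth = syn.simulate_coverage(20, genomes, present,
                                       seed=args.seed)
    write_coverage(cov, out / "coverage.tsv")
    truth.to_csv(out / "presence_truth.tsv", sep="\t")

    print(f"cohort written to {out}: {m.counts.shape[1]} genomes, "
          f"{m.counts.shape[0]} CAZy families, "
          f"{len(pul_truth['planted'])} planted PULs + "
          f"{len(pul_truth['decoys'])} decoys, 4 genome pairs, "
          f"1 gene tree, 20 coverage samples")


if __name__ == "__main__":
    main()
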