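#!/usr/bin/env python
"""Nei genetic distances and the neighbor-joining tree.

Writes the 80 x 80 individual-level Nei (1972) distance matrix (labeled TSV
and PHYLIP square) and the NJ tree in Newick form, then summarizes the
within/between-subspecies distance contrast and how many cultivar pairs
(diploid + its tetraploid derivative) end up as sister leaves.
"""
import argparse
from pathlib import Path

import numpy as np

from ssrhet.distance_tree import read_newick
from ssrhet.panel_io import read_genotype_table
from ssrhet.pipeline import RunConfig, run_tree


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = RunConfig(outdir=args.outdir, seed=args.seed)
    paths = run_tree(cfg)
    panel = read_genotype_table(args.outdir / "genotypes.tsv")
    import pandas as pd

    dm = pd.read_csv(paths["distances"], sep="\t", index_col=0)
    sub = {i.id: i.subgroup for i in panel.individuals}
    ids = list(dm.index)
    within, between = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            (within if sub[a] == sub[b] else between).append(dm.loc[a, b])
    print(f"mean Nei D within subspecies  = {np.mean(within):.3f}")
    print(f"mean Nei D between subspecies = {np.mean(between):.3f}")

    tree = read_newick(paths["tree"].read_text())
    sisters = 0
    for two, four in panel.pair_map().values():
        t2 = tree.find(two)
        if any(t.name == four for t in t2.parent.children):
            sisters += 1
    print(f"{sisters} of {len(panel.pair_map())} 2x/4x cultivar pairs are "
          f"sister leaves in the NJ tree ({paths['tree']})")


if __name__ == "__main__":
    main()
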