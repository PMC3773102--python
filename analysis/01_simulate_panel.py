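#!/usr/bin/env python
"""Generate the synthetic study inputs.

Draws the paired diploid/autotetraploid panel (40 cultivar pairs x 99 SSR
loci, two subspecies), the 4 japonica x 7 indica incomplete diallel at both
ploidies, and the replicate-level trait table, then writes them under
results/ as the inputs for every later stage.
"""
import argparse
from pathlib import Path

from ssrhet.pipeline import RunConfig, run_simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = RunConfig(outdir=args.outdir, seed=args.seed, simulate=True)
    paths = run_simulate(cfg)
    print("wrote study inputs:")
    for name, path in sorted(paths.items()):
        print(f"  {name}: {path}")
    print(
        "\npanel: 80 individuals (40 diploid cultivars + their tetraploid "
        "derivatives) x 99 loci; diallel: 28 crosses per ploidy, 3 replicates."
    )


if __name__ == "__main__":
    main()
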