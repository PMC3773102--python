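#!/usr/bin/env python
"""Does parental genetic distance predict heterosis?

Correlates the parents' Nei distance with per-cross heterobeltiosis for
every trait, separately for the diploid and tetraploid diallels, fits the
distance-vs-yield-heterobeltiosis regression per group, and (optionally)
draws the scatter.  Under the default generator the tetraploid yield column
is distance-coupled and the diploid one is null, so the printed table shows
the predictive-in-4x / null-in-2x contrast.
"""
import argparse
from pathlib import Path

import pandas as pd

from ssrhet.pipeline import RunConfig, run_association


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true",
                    help="write a GD-vs-yield-HB scatter per ploidy")
    args = ap.parse_args()

    paths = run_association(RunConfig(outdir=args.outdir, seed=args.seed))
    gd = pd.read_csv(paths["gd_correlations"], sep="\t").fillna({"stars": ""})
    print("genetic distance vs heterobeltiosis (Pearson r):")
    wide = gd.pivot(index="trait", columns="ploidy", values=["r", "stars"])
    for trait in wide.index:
        r2, r4 = wide.loc[trait, ("r", 2)], wide.loc[trait, ("r", 4)]
        s2, s4 = wide.loc[trait, ("stars", 2)], wide.loc[trait, ("stars", 4)]
        print(f"  {trait:5s}  2x {r2:+.3f}{s2:<2s}   4x {r4:+.3f}{s4:<2s}")
    reg = pd.read_csv(paths["regression"], sep="\t")
    for _, row in reg.iterrows():
        print(f"GD -> yield HB regression ({int(row.ploidy)}x): slope "
              f"{row.slope:.1f} %/D, R^2 = {row.r_squared:.4f}")

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from ssrhet.association import parental_distances
        from ssrhet.panel_io import read_crossplan

        plan = read_crossplan(args.outdir / "crossplan.tsv")
        records = pd.read_csv(paths.get("records", args.outdir / "heterosis_records.tsv"),
                              sep="\t") if (args.outdir / "heterosis_records.tsv").exists() else None
        dmat = pd.read_csv(args.outdir / "nei_distances.tsv", sep="\t", index_col=0)
        from skbio import DistanceMatrix

        dm = DistanceMatrix(dmat.to_numpy(), ids=list(dmat.index))
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, ploidy in zip(axes, (2, 4)):
            gdist = parental_distances(dm, plan, ploidy)
            hb = records[(records.ploidy == ploidy) & (records.trait == "GY")]
            hb = hb.set_index("hybrid_id")["hb"].reindex(gdist.index)
            ax.scatter(gdist, hb, s=18)
            ax.set_title(f"{ploidy}x")
            ax.set_xlabel("parental Nei D")
        axes[0].set_ylabel("yield heterobeltiosis (%)")
        fig.tight_layout()
        out = args.outdir / "gd_vs_yield_hb.png"
        fig.savefig(out, dpi=120)
        print(f"scatter written to {out}")


if __name__ == "__main__":
    main()
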