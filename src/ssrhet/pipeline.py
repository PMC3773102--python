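"""Stage orchestration: simulate -> diversity -> tree -> heterosis -> association.

Each ``run_*`` function is a thin, reproducible wrapper over the library
modules: it resolves its inputs (files on disk or a simulation config),
executes the stage, writes delimited reports plus a machine-readable
provenance record (seed, config hash, input digests) into the output
directory, and returns the written paths.  Stages are composable: running
association on precomputed stage outputs equals running end to end.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from skbio import DistanceMatrix

from . import __version__
from .association import (
    gd_heterosis_table,
    gd_yield_regression,
    yield_trait_correlation_table,
)
from .distance_tree import nei_distance_matrix, neighbor_joining, to_newick
from .diversity import diversity_table, report_round
from .heterosis import compute_heterosis, heterosis_summary_table, trait_variation_table
from .panel_io import (
    CrossPlan,
    GenotypePanel,
    TraitTable,
    read_crossplan,
    read_genotype_table,
    read_trait_table,
    split_by_ploidy,
    write_crossplan,
    write_genotype_table,
    write_trait_table,
)
from .synthetic import (
    PanelSimConfig,
    TraitSimConfig,
    make_crossplan,
    simulate_diallel_traits,
    simulate_panel,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_DEGENERATE = 3


@dataclass
class RunConfig:
    """Inputs, mode flags and output location for one pipeline run."""

    outdir: Path = Path("results")
    seed: int = 0
    # file inputs (exclusive with simulation for each data source)
    genotypes: Path | None = None
    traits: Path | None = None
    crossplan: Path | None = None
    simulate: bool = False
    # mode flags
    freq_mode: str = "copy"
    nei_variant: str = "1972"
    distance_unit: str = "individual"
    yield_trait: str = "GY"
    precision: int = 3
    n_pairs: int = 40
    n_loci: int = 99
    n_female: int = 4
    n_male: int = 7

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate and (self.genotypes or self.traits or self.crossplan):
            raise ValueError("give either input files or --simulate, not both")


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(cfg).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_provenance(cfg: RunConfig, stage: str, inputs: dict[str, Path]) -> Path:
    record = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "inputs": {k: _file_digest(p) for k, p in inputs.items() if p and Path(p).exists()},
    }
    path = cfg.outdir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path


def _resolve_panel(cfg: RunConfig) -> GenotypePanel:
    if cfg.genotypes:
        return read_genotype_table(cfg.genotypes)
    if cfg.simulate:
        return simulate_panel(PanelSimConfig(n_pairs=cfg.n_pairs, n_loci=cfg.n_loci,
                                             seed=cfg.seed))
    # fall back to a previous simulate stage in outdir
    candidate = cfg.outdir / "genotypes.tsv"
    if candidate.exists():
        return read_genotype_table(candidate)
    raise FileNotFoundError("no genotype input: give a file, --simulate, or run simulate first")


def _resolve_traits(cfg: RunConfig) -> TraitTable:
    if cfg.traits:
        return read_trait_table(cfg.traits)
    candidate = cfg.outdir / "traits.tsv"
    if candidate.exists():
        return read_trait_table(candidate)
    raise FileNotFoundError("no trait input: give a file or run simulate first")


def _resolve_crossplan(cfg: RunConfig) -> CrossPlan:
    if cfg.crossplan:
        return read_crossplan(cfg.crossplan)
    candidate = cfg.outdir / "crossplan.tsv"
    if candidate.exists():
        return read_crossplan(candidate)
    raise FileNotFoundError("no cross plan: give a file or run simulate first")


def _resolve_distance_matrix(cfg: RunConfig) -> DistanceMatrix:
    candidate = cfg.outdir / "nei_distances.tsv"
    if candidate.exists():
        df = pd.read_csv(candidate, sep="\t", index_col=0)
        return DistanceMatrix(df.to_numpy(), ids=list(df.index))
    panel = _resolve_panel(cfg)
    return nei_distance_matrix(
        panel, unit=cfg.distance_unit, mode=cfg.freq_mode, variant=cfg.nei_variant
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(
    cfg: RunConfig,
    panel_cfg: PanelSimConfig | None = None,
    trait_cfg: TraitSimConfig | None = None,
) -> dict[str, Path]:
    """Generate a panel, a diallel cross plan and a trait table onto disk."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    panel_cfg = panel_cfg or PanelSimConfig(
        n_pairs=cfg.n_pairs, n_loci=cfg.n_loci, seed=cfg.seed
    )
    trait_cfg = trait_cfg or TraitSimConfig(seed=cfg.seed)
    panel = simulate_panel(panel_cfg)
    plan = make_crossplan(
        panel, n_female=cfg.n_female, n_male=cfg.n_male,
        female_subgroup=panel_cfg.subgroups[1], male_subgroup=panel_cfg.subgroups[0],
    )
    dm = nei_distance_matrix(panel, variant=cfg.nei_variant)
    traits = simulate_diallel_traits(panel, plan, trait_cfg, dm=dm)
    paths = {
        "genotypes": cfg.outdir / "genotypes.tsv",
        "crossplan": cfg.outdir / "crossplan.tsv",
        "traits": cfg.outdir / "traits.tsv",
    }
    write_genotype_table(panel, paths["genotypes"])
    write_crossplan(plan, paths["crossplan"])
    write_trait_table(traits, paths["traits"])
    paths["provenance"] = _write_provenance(cfg, "simulate", paths)
    logger.info("simulated %d individuals x %d loci, %d crosses",
                len(panel.individuals), len(panel.markers), len(plan.crosses))
    return paths


def run_diversity(cfg: RunConfig) -> dict[str, Path]:
    """Per-ploidy per-locus diversity reports with Mean/St.Dev footers."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    panel = _resolve_panel(cfg)
    panel_2x, panel_4x = split_by_ploidy(panel)
    paths: dict[str, Path] = {}
    for label, sub in (("2x", panel_2x), ("4x", panel_4x)):
        if not sub.individuals:
            logger.warning("no %s individuals; report skipped", label)
            continue
        summary = diversity_table(sub, mode=cfg.freq_mode)
        out = cfg.outdir / f"diversity_{label}.tsv"
        summary.report_frame(cfg.precision).to_csv(out, sep="\t", index=False)
        paths[f"diversity_{label}"] = out
        for locus, why in summary.flagged.items():
            logger.warning("%s locus %s: %s", label, locus, why)
    if not paths:
        raise ValueError("no individuals in panel")
    paths["provenance"] = _write_provenance(
        cfg, "diversity", {"genotypes": cfg.genotypes or cfg.outdir / "genotypes.tsv"}
    )
    return paths


def run_tree(cfg: RunConfig) -> dict[str, Path]:
    """Nei distance matrix (labeled TSV + PHYLIP square) and NJ Newick tree."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    panel = _resolve_panel(cfg)
    dm = nei_distance_matrix(
        panel, unit=cfg.distance_unit, mode=cfg.freq_mode, variant=cfg.nei_variant
    )
    tree = neighbor_joining(dm)
    paths = {
        "distances": cfg.outdir / "nei_distances.tsv",
        "distances_phylip": cfg.outdir / "nei_distances.phy",
        "tree": cfg.outdir / "nj_tree.nwk",
    }
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        paths["distances"], sep="\t"
    )
    with paths["distances_phylip"].open("w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
    paths["tree"].write_text(to_newick(tree, precision=6) + "\n")
    paths["provenance"] = _write_provenance(
        cfg, "tree", {"genotypes": cfg.genotypes or cfg.outdir / "genotypes.tsv"}
    )
    return paths


def run_heterosis(cfg: RunConfig) -> dict[str, Path]:
    """Per-cross heterosis records, summary table and trait-variation table."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    traits = _resolve_traits(cfg)
    plan = _resolve_crossplan(cfg)
    records = compute_heterosis(traits, plan)
    if records.empty:
        raise ValueError("no computable heterosis record")
    summary = heterosis_summary_table(records)
    paths = {
        "records": cfg.outdir / "heterosis_records.tsv",
        "summary": cfg.outdir / "heterosis_summary.tsv",
    }
    rec_out = records.copy()
    for col in ("hb", "mp", "ch"):
        rec_out[col] = rec_out[col].map(lambda v: report_round(v, 2))
    rec_out.to_csv(paths["records"], sep="\t", index=False)
    sum_out = summary.copy()
    for col in ("minimum", "maximum", "mean"):
        sum_out[col] = sum_out[col].map(lambda v: report_round(v, 2))
    sum_out.to_csv(paths["summary"], sep="\t", index=False)

    # paired 2x/4x trait variation, when the panel provides the pairing
    try:
        panel = _resolve_panel(cfg)
    except FileNotFoundError:
        panel = None
    if panel is not None:
        pair_map = panel.pair_map()
        pairing = {two: four for two, four in pair_map.values()}
        if len(pairing) >= 2:
            variation = trait_variation_table(traits, pairing)
            paths["trait_variation"] = cfg.outdir / "trait_variation.tsv"
            variation.to_csv(paths["trait_variation"], sep="\t", index=False)
    paths["provenance"] = _write_provenance(
        cfg, "heterosis",
        {"traits": cfg.traits or cfg.outdir / "traits.tsv",
         "crossplan": cfg.crossplan or cfg.outdir / "crossplan.tsv"},
    )
    return paths


def run_association(cfg: RunConfig) -> dict[str, Path]:
    """Distance-heterosis correlations, yield-trait correlations, regression."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    traits = _resolve_traits(cfg)
    plan = _resolve_crossplan(cfg)
    dm = _resolve_distance_matrix(cfg)
    records = compute_heterosis(traits, plan, with_significance=False)
    gd_table = gd_heterosis_table(dm, records, plan)
    yt_table = yield_trait_correlation_table(records, yield_trait=cfg.yield_trait)
    paths = {
        "gd_correlations": cfg.outdir / "gd_heterosis_correlations.tsv",
        "yield_correlations": cfg.outdir / "yield_trait_correlations.tsv",
        "regression": cfg.outdir / "gd_yield_regression.tsv",
    }
    gd_table.to_csv(paths["gd_correlations"], sep="\t", index=False)
    yt_table.to_csv(paths["yield_correlations"], sep="\t", index=False)
    reg = gd_yield_regression(dm, records, plan, yield_trait=cfg.yield_trait)
    pd.DataFrame(
        [
            {"ploidy": ploidy, "slope": r.slope, "intercept": r.intercept,
             "r_squared": r.r_squared}
            for ploidy, r in sorted(reg.items())
        ]
    ).to_csv(paths["regression"], sep="\t", index=False)
    paths["provenance"] = _write_provenance(
        cfg, "association",
        {"traits": cfg.traits or cfg.outdir / "traits.tsv",
         "crossplan": cfg.crossplan or cfg.outdir / "crossplan.tsv"},
    )
    return paths


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """simulate (when requested) then diversity, tree, heterosis, association."""
    paths: dict[str, Path] = {}
    if cfg.simulate:
        paths.update(run_simulate(cfg))
        # downstream stages read the simulated files from outdir
        cfg = dataclasses.replace(cfg, simulate=False)
    paths.update(run_diversity(cfg))
    paths.update(run_tree(cfg))
    paths.update(run_heterosis(cfg))
    paths.update(run_association(cfg))
    return paths
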