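"""Synthetic paired diploid/autotetraploid SSR panels and diallel trait tables.

The generator emulates the structure of a two-subspecies (indica/japonica)
rice panel in which every diploid cultivar has a colchicine-derived
autotetraploid counterpart:

* per locus, an allele count k in 2..5 is drawn from a configurable
  distribution (default matching the empirical 99-marker spectrum:
  P(2)=.42, P(3)=.36, P(4)=.14, P(5)=.08) and ancestral frequencies from a
  flat Dirichlet;
* the two subgroups diverge by a Balding-Nichols draw with fixation index
  F (subgroup frequencies ~ Dirichlet(p * (1 - F) / F));
* cultivars are fully inbred fixed lines by default (one allele per locus,
  sampled from their subgroup's frequencies; a residual-heterozygosity rate
  is configurable), and each tetraploid line copies its diploid parent's
  genotype and then mutates per locus with probability ``mu_t`` (gaining or
  swapping an allele), emulating the observed 2x/4x divergence;
* loci are rejection-sampled so every drawn allele is actually observed in
  the panel, mirroring the pre-screening of markers for polymorphism.

Trait tables follow an additive + dominance + distance-coupled model: the
F1 mean for a cross is

    F1 = MPV * (1 + (dominance_ploidy + beta_ploidy * D(parents) + eps) / 100)

with MPV the mid-parent value, D the parental Nei distance, eps a per-cross
Gaussian residual, and replicates drawn around entity means with a fixed
CV.  Setting beta per ploidy generates both a distance-coupled group and a
null group.  All draws are deterministic given the config seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
import pandas as pd

from .distance_tree import nei_distance_matrix
from .panel_io import (
    Cross,
    CrossPlan,
    GenotypePanel,
    IndividualMeta,
    MarkerDef,
    MISSING,
    TraitTable,
)

_ALLELE_LABELS = ("A", "B", "C", "D", "E")


@dataclass
class PanelSimConfig:
    """Study-design parameters of the simulated genotype panel."""

    n_pairs: int = 40
    n_loci: int = 99
    allele_count_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.42, 3: 0.36, 4: 0.14, 5: 0.08}
    )
    subgroups: tuple[str, str] = ("indica", "japonica")
    #: fraction of pairs in the first subgroup (the panel is roughly balanced)
    first_subgroup_fraction: float = 0.5
    #: between-subgroup fixation index (Balding-Nichols divergence)
    divergence_f: float = 0.35
    #: per-locus probability that a 4x line gains/swaps an allele vs its parent
    tetraploid_mutation_rate: float = 0.08
    residual_heterozygosity: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1 or self.n_loci < 1:
            raise ValueError("n_pairs and n_loci must be positive")
        counts = sorted(self.allele_count_probs)
        if not counts or counts[0] < 1 or counts[-1] > len(_ALLELE_LABELS):
            raise ValueError("allele counts must lie in 1..5")
        if abs(sum(self.allele_count_probs.values()) - 1.0) > 1e-9:
            raise ValueError("allele-count probabilities must sum to 1")
        for name in ("divergence_f", "tetraploid_mutation_rate",
                     "residual_heterozygosity", "missing_rate",
                     "first_subgroup_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "divergence_f" and v >= 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait generator parameters, per ploidy group.

    ``mean/cv/lo/hi`` describe the parent-mean distribution (normal with the
    given CV%, clipped to the range); ``dominance`` maps ploidy to the
    baseline mid-parent heterosis percentage common to all crosses of that
    ploidy (the ploidy effect); ``beta`` maps ploidy to the genetic-distance
    coupling in heterosis % per unit Nei D; ``cross_noise_sd`` overrides the
    table-wide per-cross residual for this trait.
    """

    name: str
    mean_2x: float
    lo_2x: float
    hi_2x: float
    cv_2x: float
    mean_4x: float
    lo_4x: float
    hi_4x: float
    cv_4x: float
    dominance: dict[int, float] = field(default_factory=lambda: {2: 5.0, 4: 5.0})
    beta: dict[int, float] = field(default_factory=lambda: {2: 0.0, 4: 0.0})
    cross_noise_sd: float | None = None

    def parent_params(self, ploidy: int) -> tuple[float, float, float, float]:
        if ploidy == 2:
            return self.mean_2x, self.cv_2x, self.lo_2x, self.hi_2x
        return self.mean_4x, self.cv_4x, self.lo_4x, self.hi_4x


def _dom(v2: float, v4: float | None = None) -> dict[int, float]:
    return {2: v2, 4: v2 if v4 is None else v4}


def default_trait_specs() -> list[TraitSpec]:
    """The 14-trait rice panel with group means/ranges/CVs from field data.

    Distance coupling (beta) is nonzero only in the tetraploid group and
    only for grain yield, grain length and grain shape -- the configuration
    under which marker distance predicts yield heterosis in 4x but not 2x.
    Tetraploid yield heterosis is generated almost entirely by the distance
    term (strong beta over a negative baseline), reflecting hybrids whose
    vigor rises steeply with parental divergence while undiverged crosses
    yield poorly.
    """
    t = TraitSpec
    return [
        t("PH", 99.51, 66.67, 152.00, 20.60, 90.63, 70.83, 137.67, 15.61, dominance=_dom(10.0)),
        t("PL", 22.22, 14.59, 35.87, 17.89, 25.12, 18.58, 31.34, 10.49, dominance=_dom(10.0)),
        t("EPN", 7.10, 4.33, 11.00, 23.35, 5.09, 2.33, 8.33, 31.58, dominance=_dom(8.0)),
        t("TGP", 514.21, 281.00, 946.33, 29.93, 420.17, 206.67, 704.00, 31.17, dominance=_dom(15.0)),
        t("GPP", 128.07, 82.67, 229.00, 27.10, 90.08, 54.00, 142.56, 28.84, dominance=_dom(20.0)),
        t("FLL", 33.93, 18.63, 46.90, 20.00, 37.06, 26.33, 48.23, 14.56),
        t("FLW", 1.68, 1.17, 2.23, 14.19, 1.75, 1.30, 2.27, 14.52),
        t("GL", 7.88, 6.15, 11.97, 16.13, 9.69, 8.00, 12.92, 11.79,
          dominance=_dom(-5.0, -15.0), beta={2: 0.0, 4: 33.0}, cross_noise_sd=5.0),
        t("GW", 2.84, 2.00, 3.53, 16.40, 3.17, 2.20, 4.10, 13.60, dominance=_dom(2.0)),
        t("L/W", 2.89, 1.74, 5.07, 28.98, 3.13, 2.14, 4.83, 20.81,
          dominance=_dom(-15.0, -35.0), beta={2: 0.0, 4: 30.0}, cross_noise_sd=6.0),
        t("GD", 58.20, 37.40, 92.90, 24.70, 35.80, 24.40, 53.80, 25.60,
          dominance=_dom(0.0, -25.0)),
        t("GY", 2.98, 0.63, 5.74, 35.89, 1.50, 0.11, 4.97, 72.21,
          dominance=_dom(-30.0, -100.0), beta={2: 0.0, 4: 400.0}),
        t("GWT", 24.49, 19.60, 43.03, 18.26, 33.88, 28.30, 52.80, 14.72, dominance=_dom(8.0)),
        t("SS", 79.29, 25.68, 96.76, 19.36, 33.05, 2.54, 67.57, 52.43,
          dominance=_dom(-60.0, -20.0)),
    ]


@dataclass
class TraitSimConfig:
    """Parameters of the simulated diallel trait table."""

    traits: list[TraitSpec] = field(default_factory=default_trait_specs)
    n_replicates: int = 3
    #: per-cross Gaussian residual on the heterosis percentage
    cross_noise_sd: float = 10.0
    #: replicate CV around entity means, in percent
    replicate_cv: float = 5.0
    #: CV shrinkage for individuals used as diallel parents: selected elite
    #: cultivars are agronomically far more uniform than the whole panel
    parent_cv_scale: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.cross_noise_sd < 0 or self.replicate_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0.0 < self.parent_cv_scale <= 1.0:
            raise ValueError("parent_cv_scale must be in (0, 1]")


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------

def simulate_panel(cfg: PanelSimConfig) -> GenotypePanel:
    """Draw a paired 2x/4x panel; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_first = round(cfg.n_pairs * cfg.first_subgroup_fraction)
    pair_subgroups = [
        cfg.subgroups[0] if i < n_first else cfg.subgroups[1]
        for i in range(cfg.n_pairs)
    ]
    individuals: list[IndividualMeta] = []
    for i, sub in enumerate(pair_subgroups):
        base = f"{sub[:3].upper()}{i + 1:02d}"
        for ploidy in (2, 4):
            individuals.append(
                IndividualMeta(
                    id=f"{base}-{ploidy}x", ploidy=ploidy, subgroup=sub, pair_id=base
                )
            )

    counts = sorted(cfg.allele_count_probs)
    probs = np.array([cfg.allele_count_probs[c] for c in counts])
    markers = []
    columns = []  # per locus: list of calls aligned with `individuals`
    for j in range(cfg.n_loci):
        # a panel of fixed lines cannot carry more observed alleles than pairs
        k = min(int(rng.choice(counts, p=probs)), max(2, cfg.n_pairs))
        markers.append(MarkerDef(name=f"SIM{j + 1:03d}", chromosome=j % 12 + 1))
        columns.append(_simulate_locus(rng, cfg, k, pair_subgroups))

    calls = [[columns[j][i] for j in range(cfg.n_loci)]
             for i in range(len(individuals))]
    if cfg.missing_rate > 0:
        mask = rng.random((len(individuals), cfg.n_loci)) < cfg.missing_rate
        for i in range(len(individuals)):
            for j in range(cfg.n_loci):
                if mask[i, j]:
                    calls[i][j] = MISSING
    return GenotypePanel(markers=markers, individuals=individuals, calls=calls)


def _simulate_locus(rng, cfg: PanelSimConfig, k: int, pair_subgroups) -> list:
    """Calls for one locus, rejection-sampled until all k alleles are seen.

    Emulates polymorphism pre-screening: a locus whose rare alleles were
    never sampled in this panel would not have been scored with k alleles.
    """
    labels = _ALLELE_LABELS[:k]
    f = cfg.divergence_f
    for _ in range(500):
        p_anc = rng.dirichlet(np.ones(k))
        sub_freqs = {}
        for sub in cfg.subgroups:
            if f == 0.0:
                sub_freqs[sub] = p_anc
            else:
                sub_freqs[sub] = rng.dirichlet(p_anc * (1.0 - f) / f + 1e-9)
        column: list = []
        seen: set[str] = set()
        for sub in pair_subgroups:
            p = sub_freqs[sub]
            alleles = {labels[rng.choice(k, p=p)]}
            if cfg.residual_heterozygosity > 0 and rng.random() < cfg.residual_heterozygosity:
                alleles.add(labels[rng.choice(k, p=p)])
            call_2x = frozenset(alleles)
            call_4x = _mutate_tetraploid(rng, call_2x, labels, cfg.tetraploid_mutation_rate)
            column.append(call_2x)
            column.append(call_4x)
            seen |= call_2x | call_4x
        if len(seen) == k:
            return column
    raise RuntimeError(f"could not realize a {k}-allele locus in 500 attempts")


def _mutate_tetraploid(rng, call: frozenset, labels, mu_t: float) -> frozenset:
    if mu_t <= 0 or rng.random() >= mu_t or len(labels) < 2:
        return call
    others = [a for a in labels if a not in call]
    if others and (rng.random() < 0.5 or len(call) >= 4):
        # gain an allele absent from the parent
        return call | {others[rng.choice(len(others))]}
    # swap one allele for another
    current = sorted(call)
    lost = current[rng.choice(len(current))]
    pool = [a for a in labels if a != lost and a not in call]
    if not pool:
        return call
    gained = pool[rng.choice(len(pool))]
    return (call - {lost}) | {gained}


# ---------------------------------------------------------------------------
# cross plan
# ---------------------------------------------------------------------------

def make_crossplan(
    panel: GenotypePanel,
    n_female: int = 4,
    n_male: int = 7,
    female_subgroup: str = "japonica",
    male_subgroup: str = "indica",
) -> CrossPlan:
    """Incomplete diallel at both ploidies: n_female x n_male cultivar pairs.

    Females are drawn from one subgroup, males from the other (an
    inter-subspecific design); each 4x hybrid is linked to the 2x hybrid of
    the same cultivar pair via the counterpart map.
    """
    pair_map = panel.pair_map()
    sub_of = {ind.pair_id: ind.subgroup for ind in panel.individuals if ind.pair_id}
    females = sorted(p for p in pair_map if sub_of.get(p) == female_subgroup)[:n_female]
    males = sorted(p for p in pair_map if sub_of.get(p) == male_subgroup)[:n_male]
    if len(females) < n_female or len(males) < n_male:
        raise ValueError(
            f"panel has only {len(females)} {female_subgroup} / {len(males)} "
            f"{male_subgroup} complete pairs"
        )
    crosses = []
    counterpart = {}
    for f in females:
        for m in males:
            for ploidy in (2, 4):
                idx = 0 if ploidy == 2 else 1
                crosses.append(
                    Cross(
                        female=pair_map[f][idx],
                        male=pair_map[m][idx],
                        hybrid_id=f"{f}x{m}-{ploidy}x",
                        ploidy=ploidy,
                    )
                )
            counterpart[f"{f}x{m}-4x"] = f"{f}x{m}-2x"
    return CrossPlan(crosses=crosses, counterpart=counterpart)


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

def simulate_diallel_traits(
    panel: GenotypePanel,
    plan: CrossPlan,
    cfg: TraitSimConfig,
    dm: DistanceMatrix | None = None,
) -> TraitTable:
    """Replicate-level trait values for all panel individuals and hybrids.

    Every panel individual gets parent-distribution trait means (so paired
    2x/4x variation summaries can use the whole panel); hybrids follow the
    additive + dominance + distance-coupled model described in the module
    docstring.  ``dm`` defaults to the panel's individual Nei matrix.
    """
    cfg.validate()
    if dm is None:
        dm = nei_distance_matrix(panel)
    rng = np.random.default_rng(cfg.seed)
    dm_ids = set(dm.ids)

    rows = []

    def add_replicates(entity: str, trait: str, mean: float) -> None:
        sd = abs(mean) * cfg.replicate_cv / 100.0
        for rep in range(1, cfg.n_replicates + 1):
            value = rng.normal(mean, sd) if sd > 0 else mean
            rows.append(
                {"entity": entity, "trait": trait, "replicate": rep, "value": value}
            )

    diallel_parents = {c.female for c in plan.crosses} | {c.male for c in plan.crosses}
    for spec in cfg.traits:
        # parent means for every panel individual
        parent_mean: dict[str, float] = {}
        for ind in panel.individuals:
            mean, cv, lo, hi = spec.parent_params(ind.ploidy)
            if ind.id in diallel_parents:
                cv *= cfg.parent_cv_scale
            value = float(np.clip(rng.normal(mean, mean * cv / 100.0), lo, hi))
            parent_mean[ind.id] = value
            add_replicates(ind.id, spec.name, value)
        # hybrids
        noise_sd = (
            spec.cross_noise_sd if spec.cross_noise_sd is not None else cfg.cross_noise_sd
        )
        for cross in plan.crosses:
            if cross.female not in parent_mean or cross.male not in parent_mean:
                raise ValueError(
                    f"cross {cross.hybrid_id!r}: parent not in panel"
                )
            mpv = (parent_mean[cross.female] + parent_mean[cross.male]) / 2.0
            if cross.female in dm_ids and cross.male in dm_ids:
                gd = float(dm[cross.female, cross.male])
            else:
                gd = 0.0
            dominance = spec.dominance.get(cross.ploidy, 0.0)
            beta = spec.beta.get(cross.ploidy, 0.0)
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            f1_mean = mpv * (1.0 + (dominance + beta * gd + eps) / 100.0)
            add_replicates(cross.hybrid_id, spec.name, max(f1_mean, 0.0))

    table = pd.DataFrame(rows, columns=["entity", "trait", "replicate", "value"])
    return TraitTable(data=table, directions={s.name: True for s in cfg.traits})


# ---------------------------------------------------------------------------
# fast end-to-end fixture
# ---------------------------------------------------------------------------

def end_to_end_fixture(seed: int = 0) -> tuple[GenotypePanel, CrossPlan, TraitTable]:
    """Small panel (12 pairs, 20 loci) with a 2x3 diallel; exercises every
    pipeline stage in a few seconds and is byte-identical per seed."""
    panel_cfg = PanelSimConfig(n_pairs=12, n_loci=20, seed=seed)
    panel = simulate_panel(panel_cfg)
    plan = make_crossplan(panel, n_female=2, n_male=3)
    traits = simulate_diallel_traits(
        panel, plan, TraitSimConfig(seed=seed)
    )
    return panel, plan, traits
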