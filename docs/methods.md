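# Methods

`ssrhet` implements the marker-diversity and heterosis analysis used in
paired diploid/autotetraploid rice panels: per-locus SSR diversity
statistics, Nei genetic distance with neighbor-joining clustering,
heterobeltiosis / competitive-heterosis computation for an inter-subspecific
diallel, and the correlation of parental genetic distance with hybrid
performance.  Because no raw genotypes or field phenotypes are public for
this design, a first-class synthetic-data generator produces inputs with the
study's structure, and all statistical machinery is validated against
closed forms, brute-force oracles and independent implementations.

## Data model

A `GenotypePanel` is an individuals × loci matrix of *allele-label sets*.
Gel-based SSR scoring cannot resolve dosage in a tetraploid, so a call
stores 1..ploidy distinct labels; labels are opaque strings (band labels are
never interpreted numerically).  Individuals carry ploidy (2 or 4), an
optional subspecies label (indica/japonica) and an optional `pair_id`
linking a diploid cultivar with its colchicine-derived tetraploid.  Traits
are stored replicate-level in long format so unbalanced designs are
representable; a cross plan lists the diallel and maps each tetraploid
hybrid to the diploid hybrid of the same cultivar pair.

## Diversity statistics

For allele frequencies `p_i` at a locus:

* observed allele count `Na`, effective allele number `Ae = 1/Σp²`;
* expected heterozygosity (Nei gene diversity) `He = 1 − Σp²`, with an
  optional small-sample correction `C/(C−1)` (C = total allele copies),
  off by default — the uncorrected form reproduces the worked reference
  cells;
* Shannon information index `I = −Σ p ln p` (nats);
* polymorphism information content.  The default is the Botstein form
  `PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²`; the simplified form `1 − Σp²`
  (identical to He) is exposed separately because published reports often
  print the simplified formula while tabulating Botstein values — the
  worked reference cells (He 0.500 with PIC 0.375; He 0.455 with PIC 0.352)
  are only consistent with Botstein.  For an equifrequent k-allele locus
  the Botstein value is `1 − 1/k − (k−1)/k³`.

Tetraploid dosage ambiguity is handled by the frequency *mode*:
`copy` (default) splits an individual's `ploidy` copies equally across its
observed alleles; `presence` counts each observed allele once.  Both
coincide exactly on dosage-resolved diploid data.  Frequencies are
renormalized over scored individuals; all-missing loci are excluded and
flagged, loci scored in fewer than two individuals are flagged but kept.
Report tables round at 3 decimals, half away from zero; the sample standard
deviation uses n−1 and is reported missing for a single locus.

## Genetic distance and clustering

Nei's (1972) standard distance is the default: `D = −ln I` with
`I = J̄xy/√(J̄x·J̄y)`, the `J̄` terms being arithmetic means over shared
loci of `Σ p_xi p_yi`, `Σ p_xi²`, `Σ p_yi²`.  Loci missing in either unit
are excluded pairwise.  The unbiased 1978 variant (sample-corrected within-
unit homozygosity) is an option.  Because the analysis clusters cultivars,
not populations, a single individual's "frequencies" are its own equal-dose
copy proportions — appropriate for near-fixed inbred lines.  `I = 0`
(fully disjoint allele sets) is capped at `D = 10` with a warning rather
than erroring so disjoint pairs remain clusterable.  Dice/Jaccard band-
similarity distances (1 − S) are available as an alternative backend.

Neighbor joining follows Saitou–Nei with the standard Q-criterion
`Q(i,j) = (r−2)d(i,j) − R_i − R_j`.  Ties are broken deterministically by
the lexicographically smallest pair of clade representative labels, and
negative branch-length estimates are clamped to zero (pre-clamp values
logged), so runs are bit-reproducible.  The all-pairs distance matrix is
computed by a vectorized routine verified (to 2e-16) against the per-pair
reference implementation; NJ itself is verified against additive-matrix
inversion (exact recovery of 100 random 5–10-taxon trees) and cross-checked
against scikit-bio's independent NJ on non-additive matrices.

## Heterosis

On entity means (replicate averages): heterobeltiosis
`HB = 100(F1 − BP)/BP` with the better parent taken as the larger mean
unless a per-trait direction flag says otherwise; mid-parent heterosis
`MP = 100(F1 − MPV)/MPV`; competitive heterosis
`CH = 100(F1_4x − F1_2x)/F1_2x` over the counterpart map.  Zero
denominators produce missing values with warnings, never exceptions, so a
degenerate trait cannot abort a batch.  Per-cross significance is a
two-sided Welch t on replicates at α = 0.05 (the conventional choice; the
original analysis does not name its per-cross test).  The paired
diploid/tetraploid trait comparison uses a paired t on pair-matched
cultivar means (df = n_pairs − 1); all-zero differences give t = 0, p = 1,
constant nonzero differences are reported missing.

## Association

Pearson r with two-sided p from `t = r√((n−2)/(1−r²))`, pairwise-complete
deletion, stars at 0.05/0.01, and OLS for the distance-vs-yield regression
(R² = r² by construction).  No multiple-testing correction by default,
matching standard practice in this literature; Benjamini–Hochberg adjusted
p-values are available as an option.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed from the
published design and are not tuning knobs.

Panel (`PanelSimConfig`): 40 cultivar pairs × 99 loci, two subspecies of
20 pairs each.  Per locus an allele count k ∈ {2..5} is drawn with
P = .42/.36/.14/.08 (the empirical spectrum of the 99-marker table;
capped at the pair count, since a panel of fixed lines cannot carry more
observed alleles).  Ancestral frequencies are flat-Dirichlet; subspecies
frequencies follow a Balding–Nichols draw with fixation index F = 0.35 —
chosen to give a clear two-group NJ structure at 99 loci while keeping
within-group variation realistic.  Cultivars are fully inbred fixed lines
(residual heterozygosity configurable, default 0); each tetraploid copies
its diploid parent and then gains or swaps an allele per locus with
probability μ_t = 0.08, emulating the genotypic divergence observed between
derived tetraploids and their parents.  Loci are rejection-sampled until
all k alleles are observed, mirroring polymorphism pre-screening of
markers.  Missing data default to 0 (the reference table is complete).

Traits (`TraitSimConfig`): the 14-trait agronomic panel with group means,
ranges and CVs taken from the published field summaries.  Parent means are
normal draws (clipped to the range); individuals used as diallel parents
are drawn with their CV scaled by 0.3, reflecting that parents are
selected, agronomically comparable cultivars rather than a random sample of
a panel whose printed CVs include extreme lines.  Hybrid means follow

    F1 = MPV · (1 + (dominance_ploidy + β_ploidy · D(parents) + ε)/100)

with MPV the mid-parent value, D the parental Nei distance, ε a per-cross
Gaussian residual (default sd 10 percentage points) and replicates drawn at
CV 5%.  Distance coupling is confined to the tetraploid group: grain yield
β₄ₓ = 400 %/D over a −100 baseline (heterosis driven almost entirely by
parental divergence — low-divergence tetraploid crosses yield poorly, a
pattern under which the distance–heterosis correlation is strong), grain
length and grain shape carry mild coupling (β₄ₓ = 33 and 30), and every
diploid β is 0, generating the predictive-in-4x / null-in-2x contrast.
The β₄ₓ magnitude is set against the noise that heterobeltiosis inherits
from the better-parent/mid-parent gap: that gap scales with (100 + h) just
like the coupling term, so the signal-to-noise ratio — not β alone —
determines the attainable correlation, and the default ratio yields a mean
r ≈ 0.8 at 28 crosses.

What the generator does *not* emulate: linkage and map positions, SSR
mutation processes (alleles are exchangeable labels), segregation within
crosses, genotype-phenotype coupling other than through the distance term,
and environment/block effects.  Passing tests therefore demonstrate the
correctness and power of the *analysis machinery* under the stated model,
not field-data effect sizes.

### Why the divergence property is group-level

Between two fixed lines the within-unit homozygosity is identically 1 and
the expected cross-group allele match `Σ E[p1]E[p2] = Σ p_anc²` does not
depend on F, so the *individual-level* between-group Nei D is flat in F on
average; drift instead raises within-group similarity and the pooled
group-level homozygosity.  The monotonicity test accordingly checks the
pooled-group Nei D (and NJ separation, which is driven by the
within/between contrast).

## Problem sizes

Deterministic checks run at the published scale (40 pairs × 99 loci, 28
crosses per ploidy).  Replicated simulation checks use 100 seeds at full
panel scale for coupling recovery, 100 random 5–10-taxon trees for NJ
inversion, 1,000 random spectra for the PIC oracle and 1,000 null
replicates for p-value uniformity; structural tree checks use reduced
panels (8–12 pairs, 20–40 loci) over 20–50 seeds.

## Known limitations

* Allele labels are per-locus letters A–E; fragment-size binning and
  null alleles are out of scope.
* The POPGENE/NTSYS coding of tetraploid banding patterns used originally
  is unstated; the `copy`/`presence` modes bracket the plausible choices
  but neither is guaranteed to match it.
* Exact reproduction of the original tree topology and trait tables is
  impossible without the undeposited raw data; only structural and
  statistical properties are asserted.
* Heterosis significance testing is a design choice (Welch/paired t);
  the original software's exact tests may differ in degenerate cases.
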