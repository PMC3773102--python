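"""Per-locus allele frequencies and SSR diversity statistics.

For every locus the module estimates an allele-frequency spectrum and derives
the standard POPGENE-style diversity panel:

* ``Na`` — observed allele count,
* ``Ae`` — effective allele number ``1 / sum(p^2)``,
* ``He`` — expected heterozygosity (Nei gene diversity) ``1 - sum(p^2)``,
* ``I``  — Shannon information index ``-sum(p ln p)`` in nats,
* PIC  — polymorphism information content.

Two PIC variants are exposed.  The Botstein et al. (1980) form

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

is the default; the simplified form ``1 - sum(p^2)`` (identical to He) is
kept as :func:`pic_simple` because some published reports print the
simplified formula while tabulating Botstein values.

Tetraploid dosage ambiguity is handled by the frequency-estimation *mode*:

* ``"copy"`` (equal-dose, default) — each scored individual contributes
  ``ploidy`` allele copies split equally across its distinct observed
  alleles (a tetraploid scored {A, B} adds 2 copies of each);
* ``"presence"`` — each distinct allele per individual contributes one
  count, ignoring ploidy.

Both modes coincide exactly on dosage-resolved diploid data.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel_io import MISSING, GenotypePanel

logger = logging.getLogger(__name__)

FREQ_MODES = ("copy", "presence")

_SUM_TOL = 1e-9


class LocusDataError(ValueError):
    """Raised when a locus has no scorable data for the requested statistic."""


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Allele label -> frequency map for one locus.

    ``n_scored`` counts non-missing individuals; ``n_copies`` is the total
    count mass behind the frequencies (allele copies in ``copy`` mode,
    presence counts in ``presence`` mode) and feeds optional small-sample
    corrections.
    """

    locus: str
    freqs: Mapping[str, float]
    n_scored: int
    n_copies: float
    mode: str

    def __post_init__(self) -> None:
        if not self.freqs:
            raise LocusDataError(f"locus {self.locus!r}: empty spectrum")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise LocusDataError(
                f"locus {self.locus!r}: frequencies sum to {total!r}, not 1"
            )
        if any(p <= 0 for p in self.freqs.values()):
            raise LocusDataError(f"locus {self.locus!r}: non-positive frequency")

    @property
    def p(self) -> np.ndarray:
        return np.array([self.freqs[a] for a in sorted(self.freqs)], dtype=float)


def spectrum_from_freqs(
    freqs: Mapping[str, float], locus: str = "locus", n_scored: int = 0,
    n_copies: float = 0.0, mode: str = "copy",
) -> AlleleFrequencySpectrum:
    """Convenience constructor for a spectrum given frequencies directly."""
    return AlleleFrequencySpectrum(
        locus=locus, freqs=dict(freqs), n_scored=n_scored,
        n_copies=n_copies, mode=mode,
    )


def allele_frequencies(
    panel: GenotypePanel, locus: str, mode: str = "copy"
) -> AlleleFrequencySpectrum:
    """Estimate the allele-frequency spectrum of one locus.

    Frequencies are renormalized over scored (non-missing) individuals; a
    locus with no scored call raises :class:`LocusDataError`.
    """
    if mode not in FREQ_MODES:
        raise ValueError(f"mode must be one of {FREQ_MODES}, got {mode!r}")
    counts: dict[str, float] = {}
    n_scored = 0
    j = panel.marker_index(locus)
    for ind, row in zip(panel.individuals, panel.calls):
        call = row[j]
        if call is MISSING:
            continue
        n_scored += 1
        if mode == "copy":
            dose = ind.ploidy / len(call)
            for allele in call:
                counts[allele] = counts.get(allele, 0.0) + dose
        else:
            for allele in call:
                counts[allele] = counts.get(allele, 0.0) + 1.0
    if n_scored == 0:
        raise LocusDataError(f"locus {locus!r}: all calls missing")
    total = sum(counts.values())
    return AlleleFrequencySpectrum(
        locus=locus,
        freqs={a: c / total for a, c in counts.items()},
        n_scored=n_scored,
        n_copies=total,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# per-spectrum statistics
# ---------------------------------------------------------------------------

def observed_allele_count(spec: AlleleFrequencySpectrum) -> int:
    return len(spec.freqs)


def effective_allele_count(spec: AlleleFrequencySpectrum) -> float:
    """Effective allele number 1 / sum(p^2)."""
    return float(1.0 / np.sum(spec.p ** 2))


def expected_heterozygosity(
    spec: AlleleFrequencySpectrum, corrected: bool = False
) -> float:
    """Nei gene diversity 1 - sum(p^2).

    ``corrected=True`` applies the small-sample factor ``C/(C-1)`` where C is
    the total copy count behind the spectrum.
    """
    he = float(1.0 - np.sum(spec.p ** 2))
    if corrected:
        c = spec.n_copies
        if c <= 1:
            raise LocusDataError(
                f"locus {spec.locus!r}: sample correction needs > 1 allele copy"
            )
        he *= c / (c - 1.0)
    return he


def shannon_index(spec: AlleleFrequencySpectrum) -> float:
    """Shannon information index -sum(p ln p) in nats."""
    p = spec.p
    return float(-np.sum(p * np.log(p)))


def pic_botstein(spec: AlleleFrequencySpectrum) -> float:
    """Botstein PIC: 1 - sum(p^2) - sum_{i<j} 2 p_i^2 p_j^2.

    Uses the closed form of the pairwise double sum:
    sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4.
    """
    p2 = spec.p ** 2
    s2 = float(np.sum(p2))
    s4 = float(np.sum(p2 ** 2))
    return 1.0 - s2 - (s2 * s2 - s4)


def pic_simple(spec: AlleleFrequencySpectrum) -> float:
    """Simplified PIC, 1 - sum(p^2); numerically identical to He."""
    return expected_heterozygosity(spec)


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    chromosome: int
    n_alleles: int
    eff_alleles: float
    he: float
    shannon: float
    pic_botstein: float
    pic_simple: float
    n_scored: int


def locus_diversity(
    panel: GenotypePanel, locus: str, mode: str = "copy"
) -> LocusDiversity:
    """All diversity statistics of one locus, derived from a single spectrum."""
    spec = allele_frequencies(panel, locus, mode=mode)
    chrom = panel.markers[panel.marker_index(locus)].chromosome
    return LocusDiversity(
        locus=locus,
        chromosome=chrom,
        n_alleles=observed_allele_count(spec),
        eff_alleles=effective_allele_count(spec),
        he=expected_heterozygosity(spec),
        shannon=shannon_index(spec),
        pic_botstein=pic_botstein(spec),
        pic_simple=pic_simple(spec),
        n_scored=spec.n_scored,
    )


_STAT_COLS = ["n_alleles", "eff_alleles", "he", "shannon", "pic_botstein", "pic_simple"]


@dataclass
class DiversitySummary:
    """Per-locus diversity rows plus column summaries for one ploidy group."""

    per_locus: pd.DataFrame
    summary: pd.DataFrame  # rows: mean, st_dev, min, max
    total_alleles: int
    flagged: dict[str, str] = field(default_factory=dict)

    def report_frame(self, precision: int = 3) -> pd.DataFrame:
        """Per-locus rows with Mean/St.Dev/Min/Max footer, display-rounded."""
        body = self.per_locus.copy()
        for col in _STAT_COLS[1:]:
            body[col] = body[col].map(lambda v: report_round(v, precision))
        footer = self.summary.reset_index(names="locus")
        footer.insert(1, "chromosome", "")
        footer["n_scored"] = ""
        for col in _STAT_COLS:
            footer[col] = footer[col].map(
                lambda v: "" if pd.isna(v) else report_round(float(v), precision)
            )
        return pd.concat([body, footer], ignore_index=True)


def diversity_table(panel: GenotypePanel, mode: str = "copy") -> DiversitySummary:
    """Per-locus diversity table with Mean/St.Dev/Min/Max column summaries.

    Loci with every call missing are excluded from the rows (and therefore
    from the column summaries) and flagged; loci scored in fewer than two
    individuals stay in the table but are flagged.  Standard deviations use
    the n-1 denominator and are reported as missing when only one locus
    contributes.
    """
    if not panel.markers:
        raise LocusDataError("panel has no markers")
    rows = []
    flagged: dict[str, str] = {}
    for marker in panel.markers:
        try:
            ld = locus_diversity(panel, marker.name, mode=mode)
        except LocusDataError:
            flagged[marker.name] = "all calls missing; excluded"
            logger.warning("locus %s: all calls missing; excluded from table", marker.name)
            continue
        if ld.n_scored < 2:
            flagged[marker.name] = f"only {ld.n_scored} scored individual(s)"
            logger.warning("locus %s: only %d scored individual(s)", marker.name, ld.n_scored)
        rows.append(ld.__dict__)
    if not rows:
        raise LocusDataError("no locus with scorable data")
    per_locus = pd.DataFrame(rows)[
        ["locus", "chromosome"] + _STAT_COLS + ["n_scored"]
    ]
    stats = per_locus[_STAT_COLS]
    summary = pd.DataFrame(
        {
            "mean": stats.mean(),
            "st_dev": stats.std(ddof=1) if len(stats) > 1 else np.nan,
            "min": stats.min(),
            "max": stats.max(),
        }
    ).T
    return DiversitySummary(
        per_locus=per_locus,
        summary=summary,
        total_alleles=int(per_locus["n_alleles"].sum()),
        flagged=flagged,
    )


def report_round(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, the convention used in the printed reports."""
    if x != x or math.isinf(x):  # nan / inf pass through
        return x
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
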