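"""Allele frequencies and the per-locus diversity statistics.

Worked numeric cases mirror analytically forced cells of the published
99-marker table: a biallelic equifrequent locus, the 0.975/0.025 rare-allele
locus and the 0.65/0.35 locus.
"""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrhet.diversity import (
    LocusDataError,
    allele_frequencies,
    diversity_table,
    effective_allele_count,
    expected_heterozygosity,
    locus_diversity,
    observed_allele_count,
    pic_botstein,
    pic_simple,
    report_round,
    shannon_index,
    spectrum_from_freqs,
)
from ssrhet.panel_io import GenotypePanel, IndividualMeta, MarkerDef, MISSING


def _spec(*ps):
    labels = "ABCDEFG"
    return spectrum_from_freqs({labels[i]: p for i, p in enumerate(ps)})


def pic_botstein_bruteforce(ps):
    """Independent oracle: explicit double loop over ordered pairs."""
    s = 1.0 - sum(p * p for p in ps)
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            s -= 2.0 * ps[i] ** 2 * ps[j] ** 2
    return s


class TestFrequencyModes:
    def test_rare_allele_copy_mode(self, rare_allele_panel):
        spec = allele_frequencies(rare_allele_panel, "RM175", mode="copy")
        assert spec.freqs == {"A": pytest.approx(0.975), "B": pytest.approx(0.025)}
        assert spec.n_scored == 40 and spec.n_copies == 80

    def test_tetraploid_equal_dose_split(self):
        panel = GenotypePanel(
            markers=[MarkerDef("L")],
            individuals=[IndividualMeta("x", 4), IndividualMeta("y", 4)],
            calls=[[frozenset({"A", "B"})], [frozenset({"C"})]],
        )
        spec = allele_frequencies(panel, "L", mode="copy")
        # x contributes 2 copies of A and 2 of B; y contributes 4 of C
        assert spec.freqs == {
            "A": pytest.approx(0.25), "B": pytest.approx(0.25),
            "C": pytest.approx(0.5),
        }

    def test_presence_mode_counts_bands(self):
        panel = GenotypePanel(
            markers=[MarkerDef("L")],
            individuals=[IndividualMeta("x", 4), IndividualMeta("y", 4)],
            calls=[[frozenset({"A", "B"})], [frozenset({"A"})]],
        )
        spec = allele_frequencies(panel, "L", mode="presence")
        assert spec.freqs == {"A": pytest.approx(2 / 3), "B": pytest.approx(1 / 3)}

    def test_modes_coincide_on_resolved_diploids(self, rng):
        # fully homozygous diploids: copy and presence frequencies identical
        calls = [[frozenset({rng.choice(list("ABC"))})] for _ in range(30)]
        panel = GenotypePanel(
            markers=[MarkerDef("L")],
            individuals=[IndividualMeta(f"i{k}", 2) for k in range(30)],
            calls=calls,
        )
        c = allele_frequencies(panel, "L", mode="copy")
        p = allele_frequencies(panel, "L", mode="presence")
        assert c.freqs == p.freqs

    def test_all_missing_locus_errors(self):
        panel = GenotypePanel(
            markers=[MarkerDef("L")],
            individuals=[IndividualMeta("x", 2)],
            calls=[[MISSING]],
        )
        with pytest.raises(LocusDataError, match="'L'"):
            allele_frequencies(panel, "L")

    def test_renormalization_over_scored_individuals(self):
        panel = GenotypePanel(
            markers=[MarkerDef("L")],
            individuals=[IndividualMeta("x", 2), IndividualMeta("y", 2)],
            calls=[[frozenset({"A"})], [MISSING]],
        )
        spec = allele_frequencies(panel, "L")
        assert spec.freqs == {"A": 1.0} and spec.n_scored == 1


class TestWorkedStatistics:
    """Numeric cells forced by their printed companions, at 3 decimals."""

    def test_biallelic_equifrequent_locus(self, equifrequent_panel):
        ld = locus_diversity(equifrequent_panel, "PSM416")
        assert ld.n_alleles == 2
        assert ld.eff_alleles == pytest.approx(2.0)
        assert report_round(ld.he) == 0.500
        assert report_round(ld.shannon) == 0.693
        assert report_round(ld.pic_botstein) == 0.375
        assert ld.pic_simple == pytest.approx(ld.he)

    def test_rare_allele_locus(self, rare_allele_panel):
        ld = locus_diversity(rare_allele_panel, "RM175")
        assert ld.n_alleles == 2
        assert ld.eff_alleles == pytest.approx(1.0 / (0.975**2 + 0.025**2))
        assert report_round(ld.eff_alleles) == 1.051
        assert report_round(ld.he) == 0.049
        assert report_round(ld.shannon) == 0.117
        assert report_round(ld.pic_botstein) == 0.048

    def test_p65_p35_locus(self, p65_panel):
        ld = locus_diversity(p65_panel, "PSM429")
        assert report_round(ld.he) == 0.455
        assert ld.pic_botstein == pytest.approx(pic_botstein_bruteforce([0.65, 0.35]))
        # printed value 0.352 reflects half-up rounding of ~0.35149
        assert abs(ld.pic_botstein - 0.352) <= 5.5e-4

    def test_monomorphic_locus_is_all_zero(self):
        s = _spec(1.0)
        assert observed_allele_count(s) == 1
        assert effective_allele_count(s) == pytest.approx(1.0)
        assert expected_heterozygosity(s) == 0.0
        assert shannon_index(s) == 0.0
        assert pic_botstein(s) == pytest.approx(0.0)
        assert pic_simple(s) == 0.0

    def test_sample_corrected_he(self):
        s = spectrum_from_freqs({"A": 0.975, "B": 0.025}, n_copies=80)
        he = expected_heterozygosity(s)
        assert expected_heterozygosity(s, corrected=True) == pytest.approx(
            he * 80 / 79
        )


# -- property tests ---------------------------------------------------------

freq_lists = st.lists(
    st.floats(0.01, 1.0, allow_nan=False), min_size=1, max_size=6
).map(lambda xs: [x / sum(xs) for x in xs])


@given(freq_lists)
def test_diversity_invariants(ps):
    s = _spec(*ps)
    k = len(ps)
    na = observed_allele_count(s)
    ae = effective_allele_count(s)
    he = expected_heterozygosity(s)
    i = shannon_index(s)
    pb = pic_botstein(s)
    assert na == k
    assert 1.0 - 1e-12 <= ae <= na + 1e-12
    assert -1e-12 <= he <= 1.0 - 1.0 / na + 1e-12
    assert -1e-12 <= i <= math.log(na) + 1e-12
    assert pb <= he + 1e-12
    assert pic_simple(s) == pytest.approx(he)
    if k > 1 and max(ps) < 1.0 - 1e-9:
        assert pb < he  # equality only when monomorphic


@given(freq_lists)
def test_pic_botstein_matches_bruteforce(ps):
    assert pic_botstein(_spec(*ps)) == pytest.approx(
        pic_botstein_bruteforce(ps), abs=1e-12
    )


def test_pic_bruteforce_on_many_random_spectra(rng):
    for _ in range(1000):
        k = rng.integers(1, 7)
        ps = rng.dirichlet(np.ones(k))
        assert abs(pic_botstein(_spec(*ps)) - pic_botstein_bruteforce(ps)) < 1e-12


@pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
def test_equifrequent_closed_forms(k):
    s = _spec(*([1.0 / k] * k))
    assert effective_allele_count(s) == pytest.approx(k)
    assert expected_heterozygosity(s) == pytest.approx(1.0 - 1.0 / k)
    assert shannon_index(s) == pytest.approx(math.log(k))
    # 1 - 1/k for the homozygosity term, k(k-1)/2 pairs each contributing 2/k^4
    assert pic_botstein(s) == pytest.approx(1.0 - 1.0 / k - (k - 1.0) / k**3)
    assert pic_botstein(s) == pytest.approx(pic_botstein_bruteforce([1.0 / k] * k))


def test_individual_order_is_irrelevant(rare_allele_panel):
    reversed_panel = rare_allele_panel.subset(rare_allele_panel.individual_ids[::-1])
    a = locus_diversity(rare_allele_panel, "RM175")
    b = locus_diversity(reversed_panel, "RM175")
    assert a == b


# -- table assembly ---------------------------------------------------------

class TestDiversityTable:
    def _panel(self):
        markers = [MarkerDef("L1", 1), MarkerDef("L2", 2), MarkerDef("L3", 3)]
        inds = [IndividualMeta(f"i{k}", 2) for k in range(4)]
        calls = [
            [frozenset("A"), frozenset("A"), MISSING],
            [frozenset("A"), frozenset("B"), MISSING],
            [frozenset("B"), frozenset("B"), MISSING],
            [frozenset("B"), frozenset("A"), MISSING],
        ]
        return GenotypePanel(markers=markers, individuals=inds, calls=calls)

    def test_all_missing_locus_flagged_and_excluded(self):
        summary = diversity_table(self._panel())
        assert list(summary.per_locus["locus"]) == ["L1", "L2"]
        assert "L3" in summary.flagged
        assert summary.total_alleles == 4

    def test_summary_rows_are_column_statistics(self):
        summary = diversity_table(self._panel())
        he = summary.per_locus["he"]
        assert summary.summary.loc["mean", "he"] == pytest.approx(he.mean())
        assert summary.summary.loc["st_dev", "he"] == pytest.approx(he.std(ddof=1))
        assert summary.summary.loc["min", "n_alleles"] == 2
        assert summary.summary.loc["max", "n_alleles"] == 2

    def test_single_locus_st_dev_missing(self):
        panel = GenotypePanel(
            markers=[MarkerDef("only")],
            individuals=[IndividualMeta("a", 2), IndividualMeta("b", 2)],
            calls=[[frozenset("A")], [frozenset("B")]],
        )
        summary = diversity_table(panel)
        assert np.isnan(summary.summary.loc["st_dev", "he"])

    def test_report_frame_has_footer(self):
        frame = diversity_table(self._panel()).report_frame()
        assert list(frame["locus"])[-4:] == ["mean", "st_dev", "min", "max"]


@pytest.mark.parametrize(
    "x,expected",
    [(0.3515, 0.352), (0.0485, 0.049), (-0.3515, -0.352), (0.5, 0.5)],
)
def test_report_round_half_away_from_zero(x, expected):
    assert report_round(x, 3) == expected
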