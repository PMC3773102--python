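"""Data-model validation and round-trip I/O for panels, traits and cross plans."""
import dataclasses

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrhet.panel_io import (
    Cross,
    CrossPlan,
    GenotypePanel,
    IndividualMeta,
    MarkerDef,
    MISSING,
    PanelFormatError,
    TraitTable,
    empty_panel,
    infer_pairs_from_names,
    read_crossplan,
    read_genotype_table,
    read_trait_table,
    split_by_ploidy,
    strip_ploidy_suffix,
    write_crossplan,
    write_genotype_table,
    write_trait_table,
)


def _panel(rows, ploidies=None, markers=("M1",)):
    ploidies = ploidies or [2] * len(rows)
    return GenotypePanel(
        markers=[MarkerDef(m) for m in markers],
        individuals=[IndividualMeta(f"i{k}", p) for k, p in enumerate(ploidies)],
        calls=[[frozenset(c) if c else MISSING for c in row] for row in rows],
    )


class TestGenotypeTableParsing:
    def test_minimal_two_individual_parse(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tploidy\tsubgroup\tpair_id\tM1:3\n"
            "a\t2\t\t\tA/B\n"
            "b\t2\t\t\tA/A\n"
        )
        panel = read_genotype_table(path)
        assert panel.markers == [MarkerDef("M1", 3)]
        assert panel.alleles_at("M1") == ["A", "B"]
        assert panel.calls[0][0] == frozenset({"A", "B"})
        assert panel.calls[1][0] == frozenset({"A"})

    def test_dosage_ambiguous_tetraploid_call(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("id\tploidy\tsubgroup\tpair_id\tM1\nx\t4\t\t\tA/B/C\n")
        panel = read_genotype_table(path)
        assert panel.calls[0][0] == frozenset({"A", "B", "C"})

    def test_diploid_triallelic_cell_names_coordinates(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("id\tploidy\tsubgroup\tpair_id\tM1\nx\t2\t\t\tA/B/C\n")
        with pytest.raises(PanelFormatError, match="'x'.*'M1'"):
            read_genotype_table(path)

    @pytest.mark.parametrize(
        "body", ["x\t3\t\t\tA\n", "x\ttwo\t\t\tA\n"], ids=["ploidy3", "nonint"]
    )
    def test_unknown_ploidy_rejected(self, tmp_path, body):
        path = tmp_path / "g.tsv"
        path.write_text("id\tploidy\tsubgroup\tpair_id\tM1\n" + body)
        with pytest.raises(PanelFormatError):
            read_genotype_table(path)

    def test_duplicate_individual_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "id\tploidy\tsubgroup\tpair_id\tM1\nx\t2\t\t\tA\nx\t2\t\t\tB\n"
        )
        with pytest.raises(PanelFormatError, match="duplicate"):
            read_genotype_table(path)

    def test_comma_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,ploidy,subgroup,pair_id,M1\nx,2,,,A/B\n")
        assert read_genotype_table(path).calls[0][0] == frozenset({"A", "B"})


class TestPanelValidation:
    def test_call_exceeding_ploidy_rejected(self):
        with pytest.raises(PanelFormatError, match="exceed"):
            _panel([[{"A", "B", "C"}]])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(PanelFormatError):
            GenotypePanel(
                markers=[MarkerDef("M1"), MarkerDef("M2")],
                individuals=[IndividualMeta("a", 2)],
                calls=[[frozenset("A")]],
            )

    def test_duplicate_marker_rejected(self):
        with pytest.raises(PanelFormatError, match="duplicate marker"):
            _panel([[{"A"}, {"A"}]], markers=("M1", "M1"))

    def test_two_diploids_sharing_pair_id_rejected(self):
        with pytest.raises(PanelFormatError, match="pair_id"):
            GenotypePanel(
                markers=[MarkerDef("M1")],
                individuals=[
                    IndividualMeta("a", 2, pair_id="P"),
                    IndividualMeta("b", 2, pair_id="P"),
                ],
                calls=[[frozenset("A")], [frozenset("A")]],
            )

    def test_chromosome_must_be_positive(self):
        with pytest.raises(PanelFormatError):
            MarkerDef("M1", 0)


# hypothesis strategies for random valid panels -----------------------------

_labels = st.text(alphabet="ACGT0123456789", min_size=1, max_size=3)


@st.composite
def panels(draw):
    n_ind = draw(st.integers(1, 5))
    n_mark = draw(st.integers(1, 4))
    ploidies = draw(st.lists(st.sampled_from([2, 4]), min_size=n_ind, max_size=n_ind))
    markers = [MarkerDef(f"M{j}", j + 1) for j in range(n_mark)]
    individuals = [
        IndividualMeta(
            f"ind{i}",
            ploidies[i],
            subgroup=draw(st.sampled_from([None, "indica", "japonica"])),
        )
        for i in range(n_ind)
    ]
    calls = []
    for i in range(n_ind):
        row = []
        for _ in range(n_mark):
            k = draw(st.integers(1, ploidies[i]))
            row.append(frozenset(draw(
                st.lists(_labels, min_size=k, max_size=k, unique=True)
            )))
        # occasional missing cell
        if draw(st.booleans()) and n_mark > 1:
            row[draw(st.integers(0, n_mark - 1))] = MISSING
        calls.append(row)
    return GenotypePanel(markers=markers, individuals=individuals, calls=calls)


@given(panels())
def test_genotype_roundtrip_is_identity(tmp_path_factory, panel):
    path = tmp_path_factory.mktemp("rt") / "panel.tsv"
    write_genotype_table(panel, path)
    assert read_genotype_table(path) == panel


@given(panels())
def test_split_by_ploidy_partitions_individuals(panel):
    p2, p4 = split_by_ploidy(panel)
    assert len(p2.individuals) + len(p4.individuals) == len(panel.individuals)
    assert all(i.ploidy == 2 for i in p2.individuals)
    assert all(i.ploidy == 4 for i in p4.individuals)
    assert p2.markers == panel.markers and p4.markers == panel.markers


def test_split_all_diploid_and_empty():
    panel = _panel([[{"A"}], [{"B"}]])
    p2, p4 = split_by_ploidy(panel)
    assert p2 == panel and not p4.individuals
    e2, e4 = split_by_ploidy(empty_panel([MarkerDef("M1")]))
    assert not e2.individuals and not e4.individuals


def test_write_empty_marker_list_rejected(tmp_path):
    with pytest.raises(PanelFormatError, match="no markers"):
        write_genotype_table(empty_panel(), tmp_path / "x.tsv")


def test_missing_token_roundtrip(tmp_path):
    panel = _panel([[{"A"}, None], [None, {"B"}]], markers=("M1", "M2"))
    path = tmp_path / "m.tsv"
    write_genotype_table(panel, path)
    assert "." in path.read_text()
    assert read_genotype_table(path) == panel


class TestTraitTable:
    def test_long_format_read(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "entity\ttrait\treplicate\tvalue\n"
            "h1\tGY\t1\t2.5\nh1\tGY\t2\t2.7\nh1\tGY\t3\t2.6\n"
        )
        table = read_trait_table(path)
        assert list(table.replicates("h1", "GY")) == [2.5, 2.7, 2.6]
        assert table.entity_mean("h1", "GY") == pytest.approx(2.6)

    def test_directions_default_to_larger_is_better(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("entity\ttrait\treplicate\tvalue\nh1\tGY\t1\t2.5\n")
        assert read_trait_table(path).directions == {"GY": True}

    def test_na_replicate_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "t.tsv"
        path.write_text(
            "entity\ttrait\treplicate\tvalue\nh1\tGY\t1\tNA\nh1\tGY\t2\t2.0\n"
        )
        with caplog.at_level("WARNING"):
            table = read_trait_table(path)
        assert len(table.data) == 1
        assert "dropping" in caplog.text

    def test_nonnumeric_value_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("entity\ttrait\treplicate\tvalue\nh1\tGY\t1\ttall\n")
        with pytest.raises(PanelFormatError, match="non-numeric"):
            read_trait_table(path)

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "entity\ttrait\treplicate\tvalue\nh1\tGY\t1\t2.0\nh1\tGY\t1\t2.1\n"
        )
        with pytest.raises(PanelFormatError, match="duplicated"):
            read_trait_table(path)

    def test_roundtrip_with_direction_sidecar(self, tmp_path):
        table = TraitTable(
            data=pd.DataFrame(
                {"entity": ["a", "a"], "trait": ["GY", "GY"],
                 "replicate": [1, 2], "value": [1.0, 2.0]}
            ),
            directions={"GY": False},
        )
        main, side = tmp_path / "t.tsv", tmp_path / "d.tsv"
        write_trait_table(table, main, side)
        back = read_trait_table(main, side)
        assert back.directions == {"GY": False}
        pd.testing.assert_frame_equal(
            back.data.astype({"replicate": int}), table.data
        )


class TestCrossPlan:
    def _plan(self):
        crosses = [
            Cross("F-2x", "M-2x", "FxM-2x", 2),
            Cross("F-4x", "M-4x", "FxM-4x", 4),
        ]
        return CrossPlan(crosses=crosses, counterpart={"FxM-4x": "FxM-2x"})

    def test_roundtrip(self, tmp_path):
        plan = self._plan()
        path = tmp_path / "c.tsv"
        write_crossplan(plan, path)
        back = read_crossplan(path)
        assert back.crosses == plan.crosses
        assert back.counterpart == plan.counterpart

    def test_counterpart_must_link_same_cultivars(self):
        crosses = [
            Cross("F-2x", "Other-2x", "a", 2),
            Cross("F-4x", "M-4x", "b", 4),
        ]
        with pytest.raises(PanelFormatError, match="different cultivars"):
            CrossPlan(crosses=crosses, counterpart={"b": "a"})

    def test_counterpart_injective(self):
        crosses = [
            Cross("F-2x", "M-2x", "a", 2),
            Cross("F-4x", "M-4x", "b", 4),
            Cross("F-4x", "M-4x", "c", 4),
        ]
        with pytest.raises(PanelFormatError, match="injective"):
            CrossPlan(crosses=crosses, counterpart={"b": "a", "c": "a"})

    def test_counterpart_ploidy_direction(self):
        crosses = [
            Cross("F-2x", "M-2x", "a", 2),
            Cross("F-4x", "M-4x", "b", 4),
        ]
        with pytest.raises(PanelFormatError, match="4x hybrid to a 2x"):
            CrossPlan(crosses=crosses, counterpart={"a": "b"})


@pytest.mark.parametrize(
    "name,base",
    [("Taichung 65-4x", "Taichung 65"), ("IND01-2x", "IND01"), ("plain", "plain")],
)
def test_strip_ploidy_suffix(name, base):
    assert strip_ploidy_suffix(name) == base


def test_infer_pairs_from_names():
    inds = [
        IndividualMeta("A-2x", 2),
        IndividualMeta("A-4x", 4),
        IndividualMeta("B-2x", 2),  # no 4x partner
        IndividualMeta("C-4x", 4, pair_id="keep"),
    ]
    out = infer_pairs_from_names(inds)
    assert out[0].pair_id == "A" and out[1].pair_id == "A"
    assert out[2].pair_id is None
    assert out[3].pair_id == "keep"
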