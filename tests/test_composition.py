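"""Standardisation of long-format composition data into relative covers."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from borealis import composition
from borealis.composition import (
    CompositionSchema,
    SchemaError,
    ValidationError,
    aggregate_infraspecifics,
    build_plot_series,
    filter_morphospecies,
    read_composition,
    to_relative_cover,
)


def write_csv(tmp_path, text, name="comp.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadComposition:
    def test_parses_records_through_schema_mapping(self, tmp_path):
        path = write_csv(
            tmp_path,
            "site,sub,plot,yr,species,hits\n"
            "A,A1,A1p1,2000,Carex,5\n"
            "A,A1,A1p1,2000,Salix,15\n"
            "A,A1,A1p2,2005,Poa,3\n",
        )
        schema = {"study_area": "site", "subsite": "sub", "plot": "plot",
                  "year": "yr", "taxon": "species", "abundance": "hits"}
        records = read_composition(path, schema)
        assert len(records) == 3
        assert list(records.columns) == composition.RECORD_COLUMNS
        assert records["category"].eq("vascular").all()
        assert records["treatment"].eq("control").all()

    def test_negative_abundance_names_the_row(self, tmp_path):
        path = write_csv(
            tmp_path,
            "study_area,subsite,plot,year,taxon,abundance\n"
            "A,A1,p1,2000,Carex,5\nA,A1,p1,2000,Salix,-1\n",
        )
        with pytest.raises(ValidationError, match="negative abundance.*1"):
            read_composition(path)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        path = write_csv(tmp_path, "study_area,subsite,plot,year,taxon\nA,A1,p1,2000,Carex\n")
        with pytest.raises(SchemaError, match="abundance"):
            read_composition(path)

    def test_extra_columns_ignored(self, tmp_path, caplog):
        path = write_csv(
            tmp_path,
            "study_area,subsite,plot,year,taxon,abundance,observer\n"
            "A,A1,p1,2000,Carex,5,mgc\n",
        )
        with caplog.at_level("INFO"):
            records = read_composition(path)
        assert len(records) == 1
        assert "observer" not in records.columns
        assert any("observer" in m for m in caplog.messages)

    def test_category_lookup_used_when_no_category_column(self, tmp_path):
        path = write_csv(
            tmp_path,
            "study_area,subsite,plot,year,taxon,abundance\n"
            "A,A1,p1,2000,rock,5\nA,A1,p1,2000,Carex,5\n",
        )
        records = read_composition(path, category_lookup={"rock": "abiotic"})
        assert set(records["category"]) == {"abiotic", "vascular"}

    def test_year_bounds_enforced(self, tmp_path):
        path = write_csv(
            tmp_path,
            "study_area,subsite,plot,year,taxon,abundance\nA,A1,p1,1950,Carex,5\n",
        )
        with pytest.raises(ValidationError, match="year"):
            read_composition(path)
        read_composition(path, year_bounds=(1900, 2023))  # configurable


def records_frame(rows):
    return pd.DataFrame(
        rows,
        columns=composition.RECORD_COLUMNS,
    )


class TestToRelativeCover:
    @pytest.mark.parametrize(
        "abundances, expected",
        [
            ({"A": (5, "vascular"), "B": (15, "vascular"), "rock": (30, "abiotic")},
             {"A": 25.0, "B": 75.0}),
            ({"X": (7, "vascular")}, {"X": 100.0}),
            ({"A": (1, "vascular"), "B": (1, "vascular"), "C": (2, "vascular")},
             {"A": 25.0, "B": 25.0, "C": 50.0}),
        ],
    )
    def test_proportions_after_abiotic_removal(self, abundances, expected):
        rows = [
            ("a", "s", "p", 2000, taxon, ab, cat, "control")
            for taxon, (ab, cat) in abundances.items()
        ]
        covers = to_relative_cover(records_frame(rows))
        got = dict(zip(covers["taxon"], covers["cover"]))
        assert got == pytest.approx(expected)

    def test_zero_vascular_group_rejected(self, caplog):
        rows = [
            ("a", "s", "p1", 2000, "rock", 30, "abiotic", "control"),
            ("a", "s", "p2", 2000, "Carex", 5, "vascular", "control"),
        ]
        with caplog.at_level("WARNING"):
            covers = to_relative_cover(records_frame(rows))
        assert set(covers["plot"]) == {"p2"}
        assert any("zero vascular" in m for m in caplog.messages)

    def test_non_vascular_excluded_from_denominator(self):
        rows = [
            ("a", "s", "p", 2000, "Carex", 5, "vascular", "control"),
            ("a", "s", "p", 2000, "Sphagnum", 95, "non_vascular", "control"),
        ]
        covers = to_relative_cover(records_frame(rows))
        assert covers["cover"].tolist() == [100.0]


class TestMorphospeciesFilter:
    def cover_frame(self, morpho_pct):
        rows = [
            ("a", "s", "p", 2000, "Carex", 100.0 - morpho_pct, "vascular"),
            ("a", "s", "p", 2000, "Unknown1", morpho_pct, "morphospecies"),
        ]
        return pd.DataFrame(rows, columns=composition.COVER_COLUMNS)

    def test_over_threshold_removed(self):
        assert filter_morphospecies(self.cover_frame(12.0)).empty

    def test_exactly_threshold_retained_strict(self):
        out = filter_morphospecies(self.cover_frame(10.0))
        assert set(out["plot"]) == {"p"}

    def test_zero_morphospecies_unchanged(self):
        out = filter_morphospecies(self.cover_frame(0.0))
        assert out["cover"].sum() == pytest.approx(100.0)

    def test_survivors_renormalised_without_morphospecies(self):
        out = filter_morphospecies(self.cover_frame(8.0))
        assert set(out["category"]) == {"vascular"}
        assert out["cover"].sum() == pytest.approx(100.0)

    def test_raising_threshold_never_removes_more(self):
        frames = pd.concat([
            self.cover_frame(5.0).assign(plot="p5"),
            self.cover_frame(12.0).assign(plot="p12"),
            self.cover_frame(25.0).assign(plot="p25"),
        ])
        kept = [
            set(filter_morphospecies(frames, thr)["plot"])
            for thr in (4.0, 10.0, 20.0, 30.0)
        ]
        for smaller, larger in zip(kept, kept[1:]):
            assert smaller <= larger


class TestAggregateInfraspecifics:
    def test_infraspecifics_summed(self):
        covers = pd.DataFrame(
            [("a", "s", "p", 2000, "X subsp. a", 10.0, "vascular"),
             ("a", "s", "p", 2000, "X subsp. b", 20.0, "vascular"),
             ("a", "s", "p", 2000, "Y", 70.0, "vascular")],
            columns=composition.COVER_COLUMNS,
        )
        out = aggregate_infraspecifics(covers, {"X subsp. a": "X", "X subsp. b": "X"})
        got = dict(zip(out["taxon"], out["cover"]))
        assert got == pytest.approx({"X": 30.0, "Y": 70.0})
        assert out["cover"].sum() == pytest.approx(100.0)

    def test_empty_table_is_identity(self):
        covers = pd.DataFrame(
            [("a", "s", "p", 2000, "Y var. v", 100.0, "vascular")],
            columns=composition.COVER_COLUMNS,
        )
        out = aggregate_infraspecifics(covers, {})
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), covers.reset_index(drop=True)
        )

    def test_rename_to_accepted_species(self):
        covers = pd.DataFrame(
            [("a", "s", "p", 2000, "Y var. v", 100.0, "vascular")],
            columns=composition.COVER_COLUMNS,
        )
        out = aggregate_infraspecifics(covers, {"Y var. v": "Z"})
        assert out["taxon"].tolist() == ["Z"]
        assert out["cover"].tolist() == [100.0]


class TestBuildPlotSeries:
    def cover_rows(self, plot, years):
        return [
            ("a", "s", plot, y, "Carex", 100.0, "vascular") for y in years
        ]

    def test_eligibility_rules(self):
        rows = (
            self.cover_rows("short", [2000, 2003])       # 3 yr span: excluded
            + self.cover_rows("ok", [2000, 2004, 2010])  # endpoints span 10 yr
            + self.cover_rows("single", [2000])          # one survey: excluded
        )
        covers = pd.DataFrame(rows, columns=composition.COVER_COLUMNS)
        series = build_plot_series(covers, min_duration=5)
        assert [s.plot for s in series] == ["ok"]
        assert series[0].duration_years == 10
        assert series[0].years == [2000, 2004, 2010]


plot_year_strategy = st.dictionaries(
    st.sampled_from([f"sp{i}" for i in range(8)]),
    st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
    min_size=1,
    max_size=6,
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(plot_year_strategy)
def test_relative_cover_conserves_and_is_idempotent(abundances):
    rows = [("a", "s", "p", 2000, t, v, "vascular", "control")
            for t, v in abundances.items()]
    covers = to_relative_cover(records_frame(rows))
    assert covers["cover"].sum() == pytest.approx(100.0, abs=1e-6)
    again = to_relative_cover(
        covers.rename(columns={"cover": "abundance"}).assign(treatment="control")
    )
    merged = covers.merge(again, on="taxon", suffixes=("_1", "_2"))
    assert np.allclose(merged["cover_1"], merged["cover_2"], atol=1e-9)


def test_cover_roundtrip_exact(tmp_path, small_pipeline):
    covers = small_pipeline["covers"]
    path = tmp_path / "covers.csv"
    composition.write_cover_csv(covers, path)
    back = composition.read_cover_csv(path)
    merged = covers.merge(
        back, on=["study_area", "subsite", "plot", "year", "taxon"],
        suffixes=("_w", "_r"),
    )
    assert len(merged) == len(covers)
    assert np.allclose(merged["cover_w"], merged["cover_r"], atol=1e-9)
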