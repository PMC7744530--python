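"""Concentration-table parsing, summary statistics, and guideline screening."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmrisk.datamodel import (
    ConcentrationRecord,
    ConcentrationTable,
    ExposureParameters,
    ValidationError,
    canonical_metal,
    compare_to_guidelines,
    summarize,
)
from hmrisk.io import SchemaError, read_concentration_table, write_concentration_table
from tests.conftest import summary_from_stats


def _write(tmp_path, text, name="conc.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadConcentrationTable:
    def test_plain_rows_parse_as_detected(self, tmp_path):
        p = _write(tmp_path, "sample_id,metal,value\ns1,Cd,10.0\ns1,Pb,28.0\n")
        t = read_concentration_table(p, "soil", "site")
        assert len(t.records) == 2
        assert all(r.detected for r in t.records)
        assert t.detected_values("Cd").tolist() == [10.0]

    def test_nd_token_becomes_nondetect_and_is_excluded_downstream(self, tmp_path):
        p = _write(tmp_path, "sample_id,metal,value\nw1,Ag,ND\nw2,Ag,na\nw3,Ag,\nw1,Zn,2.5\n")
        t = read_concentration_table(p, "water", "site")
        assert t.nondetect_count("Ag") == 3
        assert t.detected_values("Ag").size == 0
        summ = summarize(t)
        assert summ["Ag"].not_detectable
        assert summ["Ag"].mean is None
        assert summ["Zn"].mean == 2.5

    def test_negative_value_names_offending_row(self, tmp_path):
        p = _write(tmp_path, "sample_id,metal,value\ns1,Cd,1.0\ns2,Cd,-3\n")
        with pytest.raises(ValidationError, match="line 3"):
            read_concentration_table(p, "soil", "site")

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "sample,metal,value\ns1,Cd,1.0\n")
        with pytest.raises(SchemaError, match="sample_id"):
            read_concentration_table(p, "soil", "site")

    def test_unknown_metal_rejected_and_names_canonicalized(self, tmp_path):
        p = _write(tmp_path, "sample_id,metal,value\ns1,lead,1.0\ns2,CD,2.0\n")
        t = read_concentration_table(p, "soil", "site")
        assert set(t.metals) == {"Pb", "Cd"}
        bad = _write(tmp_path, "sample_id,metal,value\ns1,Hg,1.0\n", "bad.csv")
        with pytest.raises(ValidationError, match="Hg"):
            read_concentration_table(bad, "soil", "site")

    def test_duplicate_sample_metal_pair_rejected(self):
        recs = [ConcentrationRecord("s1", "Cd", 1.0), ConcentrationRecord("s1", "Cd", 2.0)]
        with pytest.raises(ValidationError, match="duplicate"):
            ConcentrationTable("soil", "site", recs)


class TestSummarize:
    def test_single_value_has_undefined_sd(self):
        t = ConcentrationTable("soil", "site", [ConcentrationRecord("s1", "Cd", 5.0)])
        ms = summarize(t)["Cd"]
        assert ms.minimum == ms.maximum == ms.mean == 5.0
        assert ms.sd is None and ms.cv_percent is None

    def test_sample_sd_uses_n_minus_1(self):
        recs = [ConcentrationRecord(f"s{i}", "Cd", v) for i, v in enumerate([1.0, 2.0, 3.0])]
        ms = summarize(ConcentrationTable("soil", "site", recs))["Cd"]
        assert ms.mean == pytest.approx(2.0)
        assert ms.sd == pytest.approx(1.0)  # sqrt(((1)^2+0+(1)^2)/2)
        assert ms.cv_percent == pytest.approx(50.0)

    def test_min_max_match_zn_site_range(self):
        recs = [ConcentrationRecord("s1", "Zn", 105.0), ConcentrationRecord("s2", "Zn", 210.0)]
        ms = summarize(ConcentrationTable("soil", "site", recs))["Zn"]
        assert (ms.minimum, ms.maximum) == (105.0, 210.0)

    @given(st.lists(st.floats(0.001, 1e6), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_ordered(self, values):
        recs = [ConcentrationRecord(f"s{i}", "Cd", v) for i, v in enumerate(values)]
        fwd = summarize(ConcentrationTable("soil", "site", recs))["Cd"]
        rev = summarize(ConcentrationTable("soil", "site", list(reversed(recs))))["Cd"]
        assert (fwd.n, fwd.minimum, fwd.maximum) == (rev.n, rev.minimum, rev.maximum)
        assert fwd.mean == pytest.approx(rev.mean, rel=1e-12)
        assert fwd.sd == pytest.approx(rev.sd, rel=1e-9, abs=1e-15)
        assert fwd.minimum <= fwd.mean <= fwd.maximum


@given(
    st.lists(
        st.decimals(min_value="0.000001", max_value="999999", places=6).map(float),
        min_size=1,
        max_size=20,
    )
)
@settings(max_examples=50, deadline=None)
def test_csv_round_trip_is_bit_identical(tmp_path_factory, values):
    table = ConcentrationTable(
        "water", "site", [ConcentrationRecord(f"s{i}", "Cd", v) for i, v in enumerate(values)]
    )
    path = tmp_path_factory.mktemp("rt") / "t.csv"
    write_concentration_table(table, path)
    back = read_concentration_table(path, "water", "site")
    assert [r.value for r in back.records] == [r.value for r in table.records]


class TestGuidelines:
    def test_cd_mean_exceeds_who_limit(self, toxicity):
        summ = summary_from_stats({"Cd": (0.18, 0.25, 0.22, 0.03)}, "water", "site", 5)
        (status,) = compare_to_guidelines(summ, toxicity, authorities=["WHO"])
        assert status.status == "exceeds"
        assert status.ratio == pytest.approx(0.22 / 0.03, rel=1e-12)
        assert status.ratio == pytest.approx(7.3, abs=0.05)

    def test_zn_mean_below_who_limit(self, toxicity):
        summ = summary_from_stats({"Zn": (1.5, 3.0, 2.15, 0.63)}, "water", "site", 5)
        (status,) = compare_to_guidelines(summ, toxicity, authorities=["WHO"])
        assert status.status == "below"

    def test_absent_limit_reports_no_guideline(self, toxicity):
        summ = summary_from_stats({"Mg": (0.7, 1.5, 1.09, 0.35)}, "water", "site", 5)
        (status,) = compare_to_guidelines(summ, toxicity, authorities=["WHO"])
        assert status.status == "no-guideline"
        assert status.ratio is None


class TestExposureParameters:
    def test_at_defaults_to_ed_times_365(self):
        p = ExposureParameters(ed=55.0, at=None)
        assert p.at == 55.0 * 365.0

    @pytest.mark.parametrize("bad", [{"bw": 0.0}, {"ef": -1.0}, {"pef": math.nan}])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValidationError):
            ExposureParameters(**bad)


def test_canonical_metal_accepts_names_and_symbols():
    assert canonical_metal("lead") == "Pb"
    assert canonical_metal("FE") == "Fe"
    assert canonical_metal(" as ") == "As"
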