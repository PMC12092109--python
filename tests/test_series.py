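"""Measurement I/O, imputation and length summation."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caudawhip.errors import ImputationError, SchemaError, ValidationError
from caudawhip.series import (
    VertebraRecord,
    VertebralSeries,
    impute_missing,
    profile,
    read_measurements,
    total_length,
    write_measurements,
)
from caudawhip.synthetic import SyntheticSeriesSpec, generate_series

from conftest import make_series


def _write(tmp_path, text, name="meas.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadMeasurements:
    def test_direct_parse(self, tmp_path):
        p = _write(
            tmp_path,
            "position,length_cm,height_cm\n1,10,25\n2,9,20\n3,8,15\n",
        )
        s = read_measurements(p)
        assert len(s) == 3
        assert all(r.preserved and not r.imputed for r in s)
        assert s.records[0].centrum_length_cm == 10.0
        assert s.missing_positions == ()

    def test_blank_measurement_becomes_missing(self, tmp_path):
        p = _write(
            tmp_path,
            "position,length_cm,height_cm\n1,10,25\n2,9,20\n3,8,15\n4,,\n5,7,12\n",
        )
        s = read_measurements(p)
        assert s.missing_positions == (4,)
        assert [r.position for r in s] == [1, 2, 3, 5]

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = _write(tmp_path, "position\tlength_cm\theight_cm\n1\t10\t25\n2\t9\t20\n")
        assert len(read_measurements(p)) == 2

    def test_schema_mapping(self, tmp_path):
        p = _write(tmp_path, "ca,len,ht\n1,10,25\n")
        s = read_measurements(p, schema={"position": "ca", "length": "len", "height": "ht"})
        assert s.records[0].total_height_cm == 25.0

    def test_missing_column_names_the_column(self, tmp_path):
        p = _write(tmp_path, "position,length_cm\n1,10\n")
        with pytest.raises(SchemaError, match="height_cm"):
            read_measurements(p)

    def test_nonpositive_measurement_reports_row(self, tmp_path):
        p = _write(tmp_path, "position,length_cm,height_cm\n1,10,25\n2,-3,20\n")
        with pytest.raises(ValidationError, match="row 3"):
            read_measurements(p)

    def test_duplicate_position_rejected(self, tmp_path):
        p = _write(tmp_path, "position,length_cm,height_cm\n1,10,25\n1,9,20\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_measurements(p)

    def test_roundtrip_preserves_fields(self, tmp_path):
        spec = SyntheticSeriesSpec(
            n_vertebrae=20, tp_true=10, missing_positions=(5, 12), seed=3
        )
        s1 = generate_series(spec)
        path = write_measurements(s1, tmp_path / "rt.csv")
        s2 = read_measurements(path, specimen_id=s1.specimen_id, taxon=s1.taxon)
        s2 = dataclasses.replace(s2, expected_count=s1.expected_count)
        assert s1 == s2


class TestRecordInvariants:
    def test_position_must_be_positive(self):
        with pytest.raises(ValidationError):
            VertebraRecord(position=0, centrum_length_cm=1, total_height_cm=1)

    def test_imputed_implies_not_preserved(self):
        with pytest.raises(ValidationError):
            VertebraRecord(
                position=1, centrum_length_cm=1, total_height_cm=1,
                preserved=True, imputed=True,
            )

    def test_preserved_clashing_with_missing_rejected(self):
        with pytest.raises(ValidationError):
            make_series([(1, 10, 25), (2, 9, 20)], missing=(2,))


class TestImputeMissing:
    def test_single_gap_is_adjacent_mean(self):
        s = make_series([(1, 5.0, 11.0), (3, 7.0, 9.0)], missing=(2,))
        out = impute_missing(s)
        rec = out.require(2)
        assert rec.imputed and not rec.preserved
        assert rec.centrum_length_cm == pytest.approx(6.0)
        assert rec.total_height_cm == pytest.approx(10.0)
        assert out.missing_positions == ()

    def test_no_missing_is_identity(self, simple_series):
        assert impute_missing(simple_series) == simple_series

    def test_original_series_unchanged(self):
        s = make_series([(1, 5.0, 11.0), (3, 7.0, 9.0)], missing=(2,))
        impute_missing(s)
        assert s.missing_positions == (2,)
        assert len(s) == 2

    def test_run_of_gaps_interpolated_linearly(self):
        s = make_series([(1, 6.0, 12.0), (4, 3.0, 6.0)], missing=(2, 3))
        out = impute_missing(s)
        assert out.require(2).centrum_length_cm == pytest.approx(5.0)
        assert out.require(3).centrum_length_cm == pytest.approx(4.0)
        assert out.require(2).total_height_cm == pytest.approx(10.0)

    def test_terminal_gap_raises(self):
        s = make_series([(2, 9.0, 20.0), (3, 8.0, 15.0)], missing=(1,))
        with pytest.raises(ImputationError, match="Ca1"):
            impute_missing(s)
        s = make_series([(1, 9.0, 20.0), (2, 8.0, 15.0)], missing=(3,))
        with pytest.raises(ImputationError, match="Ca3"):
            impute_missing(s)

    def test_every_position_filled_after_imputation(self):
        spec = SyntheticSeriesSpec(
            n_vertebrae=30, tp_true=15, missing_positions=(4, 9, 27), seed=0
        )
        out = impute_missing(generate_series(spec))
        assert [r.position for r in out] == list(range(1, 31))

    @given(
        left=st.floats(0.1, 100),
        right=st.floats(0.1, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_imputed_value_between_neighbours(self, left, right):
        s = make_series([(1, left, 50.0), (3, right, 40.0)], missing=(2,))
        rec = impute_missing(s).require(2)
        lo, hi = min(left, right), max(left, right)
        assert lo <= rec.centrum_length_cm <= hi
        assert rec.centrum_length_cm == pytest.approx((left + right) / 2)


class TestTotalLength:
    def test_simple_sum(self, simple_series):
        assert total_length(simple_series) == pytest.approx(27.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            total_length(VertebralSeries(specimen_id="x"))

    def test_imputed_total_at_least_preserved_total(self):
        spec = SyntheticSeriesSpec(
            n_vertebrae=25, tp_true=12, missing_positions=(4, 9), seed=1
        )
        s = impute_missing(generate_series(spec))
        with_imp = total_length(s, include_imputed=True)
        bones_only = total_length(s, include_imputed=False)
        assert with_imp > bones_only

    def test_equality_when_nothing_missing(self, simple_series):
        assert total_length(simple_series, True) == total_length(simple_series, False)


class TestProfile:
    def test_ratio_column(self, simple_series):
        rows = profile(simple_series)
        assert rows[0] == (1, 10.0, 25.0, pytest.approx(0.4))

    def test_generator_heights_monotone_decreasing(self, vienna_like_spec):
        rows = profile(generate_series(vienna_like_spec))
        heights = [h for _, _, h, _ in rows]
        assert all(a > b for a, b in zip(heights, heights[1:]))
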