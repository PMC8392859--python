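import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverwq.core_data import (
    PARAMETERS,
    MonitoringRecord,
    PeriodBoundaries,
    ThresholdRuleSet,
    classify_tcb,
    classify_trophic_and_limitation,
    period_of,
    pivot_to_matrix,
    read_long_csv,
    season_of,
    write_long_csv,
)


def _rec(site, iso, param, value):
    return MonitoringRecord(site, dt.date.fromisoformat(iso), param, value)


class TestRecordValidation:
    def test_rejects_unknown_parameter(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            _rec("S1", "2010-01-01", "XYZ", 1.0)

    def test_rejects_negative_value_and_out_of_range_ph(self):
        with pytest.raises(ValueError):
            _rec("S1", "2010-01-01", "TP", -1.0)
        with pytest.raises(ValueError):
            _rec("S1", "2010-01-01", "pH", 15.0)


class TestReadLongCsv:
    def test_round_trip_and_rejects(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "site_id,date,parameter,value\n"
            "S1,2010-01-01,TP,120.5\n"
            "S1,2010-01-01,XYZ,1.0\n"
            "S1,bad-date,TN,2.0\n"
            "S2,2010-02-01,BOD,3.0\n"
        )
        records, report = read_long_csv(path)
        assert len(records) == 2
        assert report.n_rows == 4
        assert [rowno for rowno, _ in report.rejects] == [3, 4]

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("site_id,date,parameter,value\n")
        records, report = read_long_csv(path)
        assert records == [] and report.n_rows == 0

    def test_missing_header_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="header"):
            read_long_csv(path)

    def test_write_then_read_is_identity(self, tmp_path):
        records = [_rec("S1", "2010-01-01", "TP", 120.5),
                   _rec("S2", "2010-02-01", "DO", 8.25)]
        path = tmp_path / "rt.csv"
        write_long_csv(records, path)
        back, report = read_long_csv(path)
        assert back == records and not report.rejects


class TestPivot:
    def test_duplicates_averaged(self):
        recs = [_rec("S1", "2010-01-01", "TP", 4.0),
                _rec("S1", "2010-01-01", "TP", 6.0)]
        m = pivot_to_matrix(recs)
        assert m.values.loc[0, "TP"] == pytest.approx(5.0)

    def test_single_record_masks_other_cells(self):
        m = pivot_to_matrix([_rec("S1", "2010-01-01", "TP", 4.0)])
        assert m.values.shape == (1, 11)
        assert int(m.mask.sum().sum()) == 10

    def test_dense_construction(self):
        recs = [
            _rec(site, date, p, i + 1.0)
            for i, (site, date, p) in enumerate(
                (s, d, p)
                for s in ("S1", "S2")
                for d in ("2010-01-01", "2010-02-01")
                for p in PARAMETERS if p != "pH")
        ]
        recs += [_rec(s, d, "pH", 7.5) for s in ("S1", "S2")
                 for d in ("2010-01-01", "2010-02-01")]
        m = pivot_to_matrix(recs)
        assert m.values.shape == (4, 11)
        assert not m.mask.any().any()

    def test_round_trip_to_long(self, tiny):
        matrix, _ = tiny
        back = matrix.to_long()
        again = pivot_to_matrix(back)
        assert np.allclose(again.values.to_numpy(), matrix.values.to_numpy(),
                           equal_nan=True)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pivot_to_matrix([])


class TestSeasonPeriod:
    @pytest.mark.parametrize("month,season", [
        (1, "premonsoon"), (6, "premonsoon"), (7, "monsoon"),
        (8, "monsoon"), (9, "postmonsoon"), (12, "postmonsoon"),
    ])
    def test_season_boundaries(self, month, season):
        assert season_of(month) == season

    def test_season_partition_is_6_2_4(self):
        counts = {"premonsoon": 0, "monsoon": 0, "postmonsoon": 0}
        for m in range(1, 13):
            counts[season_of(m)] += 1
        assert counts == {"premonsoon": 6, "monsoon": 2, "postmonsoon": 4}

    def test_season_rejects_bad_month(self):
        for bad in (0, 13, 2.5):
            with pytest.raises(ValueError):
                season_of(bad)

    @pytest.mark.parametrize("iso,period", [
        ("2008-05-01", "pre-weir"), ("2012-06-01", "transition"),
        ("2015-03-01", "post-weir"),
    ])
    def test_default_period_boundaries(self, iso, period):
        assert period_of(dt.date.fromisoformat(iso)) == period

    def test_inverted_boundaries_error(self):
        with pytest.raises(ValueError):
            PeriodBoundaries(dt.date(2014, 1, 1), dt.date(2013, 1, 1))


class TestClassifications:
    @pytest.mark.parametrize("tcb,band", [
        (400, "little pollution"),
        (75274.6, "critical pollution"),
        (2_000_000, "excessive pollution"),
        (500, "little pollution"),       # inclusive upper edge
        (10_000, "moderate pollution"),
    ])
    def test_tcb_bands(self, tcb, band):
        assert classify_tcb(tcb) == band

    def test_tcb_negative_errors(self):
        with pytest.raises(ValueError):
            classify_tcb(-1)

    def test_tcb_monotone_step(self):
        values = np.linspace(0, 2e6, 200)
        order = {label: i for i, label in enumerate(ThresholdRuleSet().tcb_labels)}
        ranks = [order[classify_tcb(v)] for v in values]
        assert ranks == sorted(ranks)

    def test_heavily_polluted_site_is_fully_eutrophic(self):
        a = classify_trophic_and_limitation(tp=430.40, tn=7.95, chl=49.26)
        assert a.tp_eutrophic and a.tn_eutrophic and a.chl_eutrophic

    def test_clean_sample_has_no_flags(self):
        a = classify_trophic_and_limitation(tp=50, tn=1.0, chl=10)
        assert not (a.tp_eutrophic or a.tn_eutrophic or a.chl_eutrophic)

    def test_ratio_40_is_p_limited(self):
        # TN 4 mg/L vs TP 100 ug/L -> mass ratio 40 on the common ug/L basis
        a = classify_trophic_and_limitation(tp=100.0, tn=4.0, chl=20.0)
        assert a.tn_tp_ratio == pytest.approx(40.0)
        assert a.limitation == "P-limited"

    def test_zero_tp_flags_undefined_ratio(self):
        a = classify_trophic_and_limitation(tp=0.0, tn=1.0, chl=5.0)
        assert a.tn_tp_ratio is None and a.limitation == "undefined"


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0, max_value=5e6, allow_nan=False))
def test_tcb_band_always_defined(tcb):
    assert classify_tcb(tcb) in ThresholdRuleSet().tcb_labels
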