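"""Baseline-characteristic summaries, annual counts and time-to-onset."""

import datetime as dt
import math

import pytest

from pvsignal.descriptives import (DEFAULT_TTO_EDGES, age_bucket,
                                   annual_counts, percentage,
                                   summarize_categorical,
                                   summarize_indications, time_to_onset)
from pvsignal.faers_ingest import CaseReport, DrugRecord


def _case(cid, sex="female", age=50.0, country="US", reporter="physician",
          outcomes=(), route="ORAL", receipt=dt.date(2020, 6, 1),
          start=None, onset=None, indication=None):
    drug = DrugRecord("X", "X", "PS", route=route,
                      therapy_start_date=start, indication_pt=indication)
    return CaseReport(case_id=cid, report_id=cid * 100 + 1,
                      receipt_date=receipt, sex=sex, age_years=age,
                      weight_kg=None, country=country, reporter=reporter,
                      outcomes=tuple(outcomes), drugs=(drug,),
                      events=("PT1",), event_onset_date=onset)


class TestPercentage:
    @pytest.mark.parametrize("count, denom, expected", [
        # published tallies recomputed exactly to two decimals
        (7297, 13602, 53.65),    # sex: male over known sex
        (6305, 13602, 46.35),    # sex: female
        (8591, 13605, 63.15),    # route: oral over known routes
        (4841, 13529, 35.78),    # outcome: hospitalization over all codes
        (2053, 9349, 21.96),     # onset within 30 days over non-missing
        (1119, 9349, 11.97),     # onset 31-60 days
    ])
    def test_published_tallies(self, count, denom, expected):
        assert percentage(count, denom) == expected

    def test_half_up_rounding(self):
        # 0.125% must round up to 0.13, not banker's-round to 0.12
        assert percentage(1, 800) == 0.13

    def test_single_category_is_exactly_100(self):
        assert percentage(7, 7) == 100.0

    def test_zero_denominator_is_nan(self):
        assert math.isnan(percentage(3, 0))


class TestAgeBucket:
    @pytest.mark.parametrize("age, bucket", [
        (0.5, "<20"), (19.99, "<20"), (20.0, "20-40"), (39.9, "20-40"),
        (40.0, "40-60"), (60.0, ">=60"), (95.0, ">=60"), (None, "unknown"),
    ])
    def test_boundaries(self, age, bucket):
        assert age_bucket(age) == bucket


class TestSummarizeCategorical:
    def test_known_only_denominator_excludes_unknown(self):
        cases = [_case(1, sex="male"), _case(2, sex="male"),
                 _case(3, sex="female"), _case(4, sex="unknown")]
        s = summarize_categorical(cases, "sex")
        assert s.denominator == 3
        by_cat = {cat: (k, p) for cat, k, p in s.rows}
        assert by_cat["male"] == (2, 66.67)
        assert by_cat["female"] == (1, 33.33)
        assert by_cat["unknown"][0] == 1
        assert math.isnan(by_cat["unknown"][1])

    def test_known_percentages_sum_to_about_100(self):
        cases = [_case(i, sex=x) for i, x in
                 enumerate(["male"] * 7 + ["female"] * 5 + ["unknown"] * 2)]
        s = summarize_categorical(cases, "sex")
        known = [p for cat, _, p in s.rows if cat != "unknown"]
        assert sum(known) == pytest.approx(100.0, abs=0.02)

    def test_rows_sorted_by_descending_count(self):
        cases = [_case(i, country=c) for i, c in
                 enumerate(["US"] * 3 + ["JP"] * 5 + ["CA"])]
        s = summarize_categorical(cases, "country")
        assert [cat for cat, _, _ in s.rows] == ["JP", "US", "CA"]

    def test_outcome_uses_all_codes_denominator(self):
        cases = [_case(1, outcomes=("HO", "DE")), _case(2, outcomes=("HO",)),
                 _case(3, outcomes=())]
        s = summarize_categorical(cases, "outcome", "all-rows")
        assert s.denominator == 3  # three outcome codes, not three cases
        by_cat = {cat: (k, p) for cat, k, p in s.rows}
        assert by_cat["HO"] == (2, 66.67)
        assert by_cat["DE"] == (1, 33.33)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            summarize_categorical([], "weight")


def test_annual_counts_by_receipt_year():
    cases = [_case(1, receipt=dt.date(2019, 2, 1)),
             _case(2, receipt=dt.date(2021, 7, 1)),
             _case(3, receipt=dt.date(2021, 12, 31)),
             _case(4, receipt=None)]
    assert annual_counts(cases) == [(2019, 1), (2021, 2)]


class TestTimeToOnset:
    def test_identical_lags_give_degenerate_quartiles(self):
        cases = [_case(i, start=dt.date(2020, 1, 1),
                       onset=dt.date(2020, 1, 1) + dt.timedelta(days=45))
                 for i in range(4)]
        tto = time_to_onset(cases)
        assert tto.lags_days == (45, 45, 45, 45)
        assert (tto.q1, tto.median, tto.q3) == (45.0, 45.0, 45.0)

    def test_negative_lag_excluded_and_counted(self):
        cases = [_case(1, start=dt.date(2020, 2, 1),
                       onset=dt.date(2020, 1, 1)),
                 _case(2, start=dt.date(2020, 1, 1),
                       onset=dt.date(2020, 1, 11))]
        tto = time_to_onset(cases)
        assert tto.lags_days == (10,)
        assert tto.n_negative_excluded == 1

    def test_missing_dates_counted(self):
        cases = [_case(1), _case(2, start=dt.date(2020, 1, 1))]
        tto = time_to_onset(cases)
        assert tto.n_missing == 2 and tto.lags_days == ()
        assert math.isnan(tto.median)

    def test_binning_edges_inclusive_on_right(self):
        # lags 0, 30, 31, 730, 731 under default edges
        lags = [0, 30, 31, 730, 731]
        cases = [_case(i, start=dt.date(2020, 1, 1),
                       onset=dt.date(2020, 1, 1) + dt.timedelta(days=lag))
                 for i, lag in enumerate(lags)]
        tto = time_to_onset(cases, DEFAULT_TTO_EDGES)
        counts = {b: k for b, k, _ in tto.bins}
        assert counts["0-30d"] == 2      # 0 and 30 both inside
        assert counts["31-60d"] == 1
        assert counts["366-730d"] == 1   # 730 inside the closed right edge
        assert counts[">730d"] == 1
        assert sum(counts.values()) == len(lags)
        assert sum(p for _, _, p in tto.bins) == pytest.approx(100.0, abs=0.02)

    def test_target_filter_uses_earliest_target_start(self):
        drug_a = DrugRecord("TEMODAR", "TEMODAR", "PS", route="ORAL",
                            therapy_start_date=dt.date(2020, 1, 11))
        drug_b = DrugRecord("OTHER", "OTHER", "C", route="ORAL",
                            therapy_start_date=dt.date(2020, 1, 1))
        case = CaseReport(case_id=1, report_id=101,
                          receipt_date=dt.date(2020, 6, 1), sex="male",
                          age_years=None, weight_kg=None, country=None,
                          reporter="unknown", outcomes=(),
                          drugs=(drug_a, drug_b), events=("PT1",),
                          event_onset_date=dt.date(2020, 1, 21))
        syn = {"TEMODAR": "TEMOZOLOMIDE"}
        unfiltered = time_to_onset([case])
        filtered = time_to_onset([case], target="TEMOZOLOMIDE", synonyms=syn)
        assert unfiltered.lags_days == (20,)   # earliest start of any drug
        assert filtered.lags_days == (10,)     # earliest target start only


class TestIndications:
    def test_merge_map_groups_variants(self):
        cases = [_case(1, indication="GLIOBLASTOMA"),
                 _case(2, indication="GLIOMA"),
                 _case(3, indication="MELANOMA"),
                 _case(4, indication=None)]
        merged = summarize_indications(
            cases, {"GLIOBLASTOMA": "GLIOMA", "GLIOMA": "GLIOMA"})
        assert merged == [("GLIOMA", 2), ("MELANOMA", 1)]

    def test_unmapped_labels_pass_through(self):
        cases = [_case(1, indication="MELANOMA")]
        assert summarize_indications(cases) == [("MELANOMA", 1)]
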