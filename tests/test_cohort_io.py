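"""Cohort data model, CSV round-trips and stratified summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from screenbias.cohort import (BMI_CATEGORIES, HISTOLOGIES, STAGES,
                               CohortSchemaError, CohortSummary,
                               CohortValidationError, PatientRecord,
                               bmi_category_from_bmi, from_records,
                               published_summary, read_cohort,
                               summarize_cohort, to_records, validate_cohort,
                               write_cohort)
from tests.conftest import make_cohort_frame


class TestReadWrite:
    def test_round_trip_identity(self, tiny_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(tiny_cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, tiny_cohort)

    def test_missing_event_column_names_it(self, tiny_cohort, tmp_path):
        path = tmp_path / "broken.csv"
        tiny_cohort.drop(columns=["event"]).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="event"):
            read_cohort(path)

    def test_invalid_stage_reports_row(self, tiny_cohort, tmp_path):
        bad = tiny_cohort.copy()
        bad.loc[3, "stage"] = "V"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortValidationError, match="row 3"):
            read_cohort(path)

    def test_non_positive_time_rejected(self, tiny_cohort):
        bad = tiny_cohort.copy()
        bad.loc[0, "time_days"] = 0.0
        with pytest.raises(CohortValidationError, match="time_days"):
            validate_cohort(bad)

    @pytest.mark.parametrize("token,expected", [
        ("1", True), ("true", True), ("YES", True),
        ("0", False), ("False", False), ("no", False)])
    def test_boolean_tokens(self, tiny_cohort, tmp_path, token, expected):
        df = tiny_cohort.astype({"screened": object}).copy()
        df.loc[0, "screened"] = token
        out = validate_cohort(df)
        assert out.loc[0, "screened"] == expected

    def test_unknown_columns_dropped_with_warning(self, tiny_cohort, caplog):
        df = tiny_cohort.copy()
        df["hospital"] = "YCH"
        with caplog.at_level("WARNING"):
            out = validate_cohort(df)
        assert "hospital" in caplog.text
        assert "hospital" not in out.columns

    def test_raw_bmi_discretized_only_when_category_absent(self, tiny_cohort):
        df = tiny_cohort.drop(columns=["bmi_category"]).copy()
        df["bmi"] = [17.0, 18.5, 22.9, 23.0, 24.9, 25.0, 30.0, 20.0, 21.0, 26.0]
        out = validate_cohort(df)
        assert list(out["bmi_category"][:6]) == [
            "underweight", "normal", "normal", "overweight", "overweight", "obese"]
        # explicit categorical column takes precedence over raw values
        df2 = tiny_cohort.copy()
        df2["bmi"] = 17.0
        out2 = validate_cohort(df2)
        assert list(out2["bmi_category"]) == list(tiny_cohort["bmi_category"])

    def test_record_conversion_round_trip(self, tiny_cohort):
        records = to_records(tiny_cohort)
        assert all(isinstance(r, PatientRecord) for r in records)
        pd.testing.assert_frame_equal(from_records(records), tiny_cohort)

    def test_invalid_record_rejected(self):
        with pytest.raises(CohortValidationError):
            PatientRecord(id="x", region="Mars", screened=False, age_years=60,
                          sex="male", ethnicity="Han", stage="I",
                          histology="other", bmi_category="normal",
                          cci_gt3=False, kps_gt70=True, smoker=False,
                          surgery=False, chemo=False, radio=False,
                          targeted=False, time_days=10.0, event=False)


valid_rows = st.fixed_dictionaries({
    "region": st.sampled_from(["XF", "nonXF"]),
    "screened": st.booleans(),
    "sex": st.sampled_from(["male", "female"]),
    "stage": st.sampled_from(STAGES),
    "histology": st.sampled_from(HISTOLOGIES),
    "bmi_category": st.sampled_from(BMI_CATEGORIES),
    "event": st.booleans(),
    "time_days": st.floats(0.5, 5000.0, allow_nan=False),
    "age_years": st.floats(20.0, 95.0, allow_nan=False),
})


class TestSummaries:
    @settings(max_examples=25, deadline=None)
    @given(rows=st.lists(valid_rows, min_size=1, max_size=30))
    def test_round_trip_and_count_consistency(self, rows):
        cohort = make_cohort_frame(rows)
        summary = summarize_cohort(cohort)
        # counts in every variable's cells sum to the stratum size
        for var, by_stratum in summary.counts.items():
            for stratum, cells in by_stratum.items():
                assert sum(cells.values()) == summary.stratum_n[stratum]
        for var, by_stratum in summary.proportions.items():
            for cells in by_stratum.values():
                assert all(0 <= p <= 1 for p in cells.values()
                           if not np.isnan(p))

    @settings(max_examples=15, deadline=None)
    @given(rows_a=st.lists(valid_rows, min_size=1, max_size=15),
           rows_b=st.lists(valid_rows, min_size=1, max_size=15))
    def test_union_additivity(self, rows_a, rows_b):
        """Summarising a union equals cell-wise sums of the parts."""
        a, b = make_cohort_frame(rows_a), make_cohort_frame(rows_b)
        b = b.assign(id="b_" + b["id"])
        union = validate_cohort(pd.concat([a, b], ignore_index=True))
        sa, sb, su = summarize_cohort(a), summarize_cohort(b), summarize_cohort(union)
        for var in su.counts:
            for stratum, cells in su.counts[var].items():
                for level, count in cells.items():
                    assert count == (sa.counts[var][stratum][level]
                                     + sb.counts[var][stratum][level])

    def test_empty_cohort_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            summarize_cohort(tiny_cohort.iloc[0:0])

    def test_sex_ratio_undefined_without_females(self):
        cohort = make_cohort_frame([{"sex": "male"}, {"sex": "male"}])
        summary = summarize_cohort(cohort)
        key = ("nonXF", False)
        assert not summary.sex_ratio_defined[key]
        assert np.isnan(summary.sex_ratio[key])

    def test_json_export(self, tiny_cohort, tmp_path):
        summary = summarize_cohort(tiny_cohort)
        text = summary.to_json(tmp_path / "s.json")
        assert "screened_fraction_by_region" in text


class TestPublishedComposition:
    """Derived quantities recomputed from the published stratified counts."""

    @pytest.fixture
    def summary(self) -> CohortSummary:
        return published_summary()

    def test_sex_ratios(self, summary):
        assert round(summary.sex_ratio[("nonXF", False)], 2) == 2.62
        assert round(summary.sex_ratio[("XF", True)], 2) == 1.37

    def test_screened_fractions(self, summary):
        assert round(100 * summary.screened_fraction_by_region["XF"], 1) == 17.6
        assert round(100 * summary.screened_fraction_by_region["nonXF"], 1) == 5.3
        assert round(100 * summary.screened_fraction_overall, 1) == 7.8

    def test_stage1_screened_share(self, summary):
        # screening found 27.5% of stage I cases; 46.6% of those live in XF
        assert round(100 * summary.screened_fraction_by_stage["I"], 1) == 27.5
        assert round(100 * summary.stage1_screened_region_share["XF"], 1) == 46.6
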