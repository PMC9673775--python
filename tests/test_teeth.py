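import io
import math

import pytest

from toothratio import (
    ANTERIOR_FDI_CODES,
    AnteriorWidths,
    Cohort,
    ToothRef,
    WidthError,
    bilateral_mean,
    cohort_summary,
    load_widths,
    validate,
    write_widths,
)


class TestToothRef:
    @pytest.mark.parametrize(
        "code, arch, tooth_type, side",
        [
            (11, "upper", "central", "right"),
            (22, "upper", "lateral", "left"),
            (13, "upper", "canine", "right"),
            (31, "lower", "central", "left"),
            (42, "lower", "lateral", "right"),
            (33, "lower", "canine", "left"),
        ],
    )
    def test_fdi_code_determines_anatomy(self, code, arch, tooth_type, side):
        ref = ToothRef(code)
        assert (ref.arch, ref.tooth_type, ref.side) == (arch, tooth_type, side)

    @pytest.mark.parametrize("code", [14, 24, 34, 44, 18, 51, 0, 99, 10])
    def test_non_anterior_codes_rejected(self, code):
        with pytest.raises(WidthError):
            ToothRef(code)


class TestAnteriorWidths:
    def test_completeness_predicates(self, reference_record):
        assert reference_record.is_bolton_complete
        assert reference_record.is_satr_complete
        laterals_only = AnteriorWidths(
            "s", {12: 7.0, 22: 7.1, 32: 6.0, 42: 6.1}
        )
        assert laterals_only.is_satr_complete
        assert not laterals_only.is_bolton_complete

    def test_nonpositive_width_rejected(self):
        with pytest.raises(WidthError):
            AnteriorWidths("s", {11: 0.0})

    def test_duplicate_subject_ids_rejected(self):
        rec = AnteriorWidths("same", {11: 8.0})
        with pytest.raises(WidthError, match="same"):
            Cohort(records=[rec, AnteriorWidths("same", {21: 8.0})])


class TestValidate:
    def test_complete_plausible_record_is_clean(self, reference_record):
        assert validate(reference_record, "bolton").ok

    def test_missing_tooth_named(self, reference_record):
        del reference_record.widths[ToothRef(42)]
        report = validate(reference_record, "satr")
        assert report.missing_codes == [42]
        assert not report.ok

    def test_implausible_width_flagged(self, reference_record):
        reference_record.widths[ToothRef(11)] = 2.0
        report = validate(reference_record, "bolton")
        assert (11, 2.0) in report.implausible


class TestBilateralMean:
    def test_equal_sides_return_the_common_width(self, reference_record):
        assert bilateral_mean(reference_record, "upper", "lateral") == pytest.approx(7.216)

    def test_mean_of_unequal_sides(self):
        rec = AnteriorWidths("s", {12: 6.0, 22: 8.0})
        assert bilateral_mean(rec, "upper", "lateral") == pytest.approx(7.0)

    def test_symmetric_in_sides(self):
        a = AnteriorWidths("a", {12: 6.0, 22: 8.0})
        b = AnteriorWidths("b", {12: 8.0, 22: 6.0})
        assert bilateral_mean(a, "upper", "lateral") == bilateral_mean(b, "upper", "lateral")

    def test_missing_side_errors_with_code(self):
        rec = AnteriorWidths("s", {12: 6.0})
        with pytest.raises(WidthError, match="22"):
            bilateral_mean(rec, "upper", "lateral")


class TestCohortSummary:
    def test_identical_subjects_have_zero_sd(self, reference_record):
        twin = AnteriorWidths("twin", dict(reference_record.widths))
        cohort = Cohort(records=[reference_record, twin])
        table = cohort_summary(cohort)
        assert (table["sd_mm"] == 0).all()
        assert table.loc[("all", "upper", "lateral"), "mean_mm"] == pytest.approx(7.216)

    def test_two_subject_mean_and_sample_sd(self):
        a = AnteriorWidths("a", {c: 6.0 for c in ANTERIOR_FDI_CODES})
        b = AnteriorWidths("b", {c: 8.0 for c in ANTERIOR_FDI_CODES})
        cell = cohort_summary(Cohort(records=[a, b])).loc[("all", "upper", "lateral")]
        assert cell["mean_mm"] == pytest.approx(7.0)
        assert cell["sd_mm"] == pytest.approx(math.sqrt(2.0), abs=1e-4)  # n-1

    def test_singleton_group_sd_undefined(self, reference_record):
        cohort = Cohort(records=[reference_record])
        table = cohort_summary(cohort)
        assert table["sd_mm"].isna().all()

    def test_single_group_equals_ungrouped(self, reference_record):
        twin = AnteriorWidths("twin", {c: w + 0.3 for c, w in reference_record.widths.items()})
        cohort = Cohort(records=[reference_record, twin])
        grouped = cohort_summary(cohort, {"ref": "g", "twin": "g"})
        ungrouped = cohort_summary(cohort)
        assert (grouped.to_numpy() == ungrouped.to_numpy()).all()


class TestCsvIO:
    def test_wide_single_subject_bolton_complete(self, wide_csv, reference_record):
        stream = wide_csv({"s1": {c.fdi_code: w for c, w in reference_record.widths.items()}})
        cohort = load_widths(stream, layout="wide")
        assert len(cohort) == 1
        assert cohort.records[0].is_bolton_complete

    def test_long_rejects_posterior_code(self):
        stream = io.StringIO("subject_id,tooth_fdi,width_mm\ns1,14,7.0\n")
        with pytest.raises(WidthError, match="14"):
            load_widths(stream, layout="long")

    def test_wide_laterals_only_is_satr_complete(self, wide_csv):
        stream = wide_csv({"s1": {12: 7.0, 22: 7.1, 32: 6.0, 42: 6.1}},
                          codes=(12, 22, 32, 42))
        rec = load_widths(stream).records[0]
        assert rec.is_satr_complete and not rec.is_bolton_complete

    def test_non_numeric_width_names_subject_and_tooth(self):
        stream = io.StringIO("subject_id,tooth_fdi,width_mm\ns9,12,abc\n")
        with pytest.raises(WidthError, match="s9"):
            load_widths(stream, layout="long")

    def test_duplicate_entry_is_hard_error(self):
        stream = io.StringIO(
            "subject_id,tooth_fdi,width_mm\ns1,12,7.0\ns1,12,7.1\n"
        )
        with pytest.raises(WidthError, match="s1"):
            load_widths(stream, layout="long")

    def test_empty_file_is_hard_error(self):
        with pytest.raises(WidthError, match="empty"):
            load_widths(io.StringIO(""), layout="wide")

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip_full_precision(self, reference_record, layout):
        other = AnteriorWidths(
            "s2", {c: w + 1 / 3 for c, w in reference_record.widths.items()}
        )
        cohort = Cohort(records=[reference_record, other])
        text = write_widths(cohort, layout=layout)
        back = load_widths(io.StringIO(text), layout=layout)
        for orig, rec in zip(cohort.records, back.records):
            assert rec.subject_id == orig.subject_id
            assert rec.widths == orig.widths  # exact float equality

    def test_group_column_round_trips(self, reference_record):
        cohort = Cohort(records=[reference_record], groups={"ref": "normal"})
        back = load_widths(io.StringIO(write_widths(cohort)), layout="wide")
        assert back.groups == {"ref": "normal"}
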