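import itertools

import numpy as np
import pandas as pd
import pytest

from calaudit.cohort_assembly import (AssemblyError, reduce_admissions,
                                      smd_binary, smd_continuous,
                                      smd_multicategory, split_train_holdout,
                                      summarize_baseline)


def frame(rows, cols):
    return pd.DataFrame(rows, columns=cols)


class TestReduceAdmissions:
    def test_max_eligible_prediction_with_following_assessment(self):
        """The d5 prediction has no later assessment, so the max among
        predictions followed by one (d3, 0.7) wins; outcome from d4."""
        preds = frame([("p1", "2021-01-01", 0.3), ("p1", "2021-01-03", 0.7),
                       ("p1", "2021-01-05", 0.5)],
                      ["patient_id", "date", "p_hat"])
        assess = frame([("p1", "2021-01-04", 0)],
                       ["patient_id", "date", "diagnosis"])
        records, summary = reduce_admissions(preds, assess)
        assert len(records) == 1
        assert records.loc[0, "p_hat"] == 0.7
        assert records.loc[0, "outcome"] == 0
        assert summary.retained == 1

    def test_patient_without_assessment_excluded(self):
        preds = frame([("p1", "2021-01-01", 0.4)],
                      ["patient_id", "date", "p_hat"])
        assess = frame([], ["patient_id", "date", "diagnosis"])
        records, summary = reduce_admissions(preds, assess)
        assert records.empty
        assert summary.excluded_no_assessment == 1

    def test_same_day_assessment_counts_as_after(self):
        preds = frame([("p1", "2021-01-02", 0.6)],
                      ["patient_id", "date", "p_hat"])
        assess = frame([("p1", "2021-01-02", 1)],
                       ["patient_id", "date", "diagnosis"])
        records, _ = reduce_admissions(preds, assess)
        assert len(records) == 1
        assert records.loc[0, "outcome"] == 1

    def test_no_prediction_before_any_assessment_excluded(self):
        preds = frame([("p1", "2021-01-09", 0.6)],
                      ["patient_id", "date", "p_hat"])
        assess = frame([("p1", "2021-01-02", 1)],
                       ["patient_id", "date", "diagnosis"])
        records, summary = reduce_admissions(preds, assess)
        assert records.empty
        assert summary.excluded_no_pairing == 1

    def test_duplicate_same_day_predictions_keep_larger(self):
        preds = frame([("p1", "2021-01-01", 0.2), ("p1", "2021-01-01", 0.5)],
                      ["patient_id", "date", "p_hat"])
        assess = frame([("p1", "2021-01-02", 0)],
                       ["patient_id", "date", "diagnosis"])
        records, _ = reduce_admissions(preds, assess)
        assert records.loc[0, "p_hat"] == 0.5

    def test_retained_plus_excluded_partitions_patients(self):
        preds = frame([("a", "2021-01-01", 0.3), ("b", "2021-01-05", 0.4),
                       ("c", "2021-01-01", 0.9)],
                      ["patient_id", "date", "p_hat"])
        assess = frame([("a", "2021-01-02", 1), ("b", "2021-01-01", 0)],
                       ["patient_id", "date", "diagnosis"])
        records, s = reduce_admissions(preds, assess)
        assert (s.retained + s.excluded_no_assessment
                + s.excluded_no_pairing) == 3
        assert records["patient_id"].is_unique


class TestSplitTrainHoldout:
    def test_boundary_is_inclusive_on_train_side(self):
        recs = frame([("a", "2022-12-31"), ("b", "2023-01-01")],
                     ["patient_id", "admit_date"])
        out = split_train_holdout(recs, "2022-12-31")
        assert list(out["sample"]) == ["train", "holdout"]

    def test_missing_dates_error_lists_ids(self):
        recs = frame([("a", None)], ["patient_id", "admit_date"])
        with pytest.raises(AssemblyError, match="a"):
            split_train_holdout(recs, "2022-12-31")

    def test_one_sided_split_warns_not_raises(self, caplog):
        recs = frame([("a", "2021-05-01"), ("b", "2021-06-01")],
                     ["patient_id", "admit_date"])
        with caplog.at_level("WARNING"):
            out = split_train_holdout(recs, "2022-12-31")
        assert (out["sample"] == "train").all()
        assert any("empty" in r.message for r in caplog.records)


class TestSMD:
    def test_binary_hand_computation(self):
        # p1 = 3/4, p2 = 1/4 -> 0.5 / sqrt(0.1875) = 1.1547
        assert smd_binary(3, 4, 1, 4) == pytest.approx(0.5 / np.sqrt(0.1875),
                                                       abs=1e-10)

    def test_binary_equal_proportions_zero(self):
        assert smd_binary(10, 40, 5, 20) == 0.0

    def test_binary_degenerate_unequal_errors(self):
        with pytest.raises(AssemblyError):
            smd_binary(4, 4, 0, 4)

    def test_multicategory_identical_distributions_zero(self):
        c = [30, 50, 20]
        assert smd_multicategory(c, [x * 3 for x in c]) == pytest.approx(0.0,
                                                                         abs=1e-12)

    def test_two_category_reduces_to_binary(self):
        assert smd_multicategory([30, 70], [45, 55]) == pytest.approx(
            smd_binary(30, 100, 45, 100), abs=1e-12)

    def test_invariant_to_category_permutation(self):
        c1 = np.array([25, 40, 15, 20])
        c2 = np.array([30, 28, 22, 20])
        base = smd_multicategory(c1, c2)
        for perm in itertools.permutations(range(4)):
            assert smd_multicategory(c1[list(perm)], c2[list(perm)]) == \
                pytest.approx(base, abs=1e-10)

    def test_empty_shared_category_errors(self):
        with pytest.raises(AssemblyError):
            smd_multicategory([10, 0, 5], [8, 0, 9])

    def test_continuous_formula(self):
        assert smd_continuous(1.0, 2.0, 0.0, 2.0) == pytest.approx(0.5)
        assert smd_continuous(3.0, 1.0, 3.0, 5.0) == 0.0


class TestSummarizeBaseline:
    def test_identical_groups_all_zero_smd(self):
        half = pd.DataFrame({
            "gender": ["F", "M"] * 10, "age": list(range(20))})
        df = pd.concat([half.assign(outcome=0), half.assign(outcome=1)])
        table = summarize_baseline(df, {"gender": "categorical",
                                        "age": "continuous"})
        assert (table["smd"].dropna() == 0).all()

    def test_continuous_smd_hand_checked_fixture(self):
        df = pd.DataFrame({
            "outcome": [0, 0, 0, 1, 1, 1],
            "bmi": [20.0, 25.0, 30.0, 18.0, 21.0, 24.0]})
        table = summarize_baseline(df, {"bmi": "continuous"})
        # means 25 vs 21, both sds 5 and 3 -> 4 / sqrt((25+9)/2)
        expected = 4.0 / np.sqrt((25.0 + 9.0) / 2.0)
        assert table.loc[0, "smd"] == pytest.approx(expected, abs=1e-4)

    def test_missing_values_reported_not_imputed(self):
        df = pd.DataFrame({"outcome": [0, 0, 1, 1],
                           "bmi": [20.0, np.nan, 22.0, np.nan]})
        table = summarize_baseline(df, {"bmi": "continuous"})
        assert "Missing" in set(table["level"])

    def test_unknown_variable_errors(self):
        df = pd.DataFrame({"outcome": [0, 1]})
        with pytest.raises(AssemblyError):
            summarize_baseline(df, {"ghost": "categorical"})

    def test_default_cohort_gender_composition(self):
        from calaudit.synthetic_cohort import default_config, generate_cohort
        df = generate_cohort(default_config(n=20_000, seed=17))
        assert abs((df["gender"] == "Female").mean() - 0.499) < 0.01
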