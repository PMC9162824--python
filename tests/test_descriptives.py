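"""Onset binning, SOC / demographic / outcome tabulations, indication shares."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal import datasets
from pvsignal.dates import parse_partial_date
from pvsignal.descriptives import (
    ONSET_BIN_LABELS,
    bin_onset,
    compute_onset_days,
    demographic_tabulate,
    indication_shares,
    onset_summary,
    outcome_tabulate,
    soc_tabulate,
)
from pvsignal.records import OutcomeEntry, ReactionEntry, TherapyEntry

from conftest import cohort_of, make_aspirin_case, make_report, merge


class TestOnsetDays:
    def test_date_arithmetic(self):
        case = make_report(1, event="20150411")
        ther = [TherapyEntry(1, 1, parse_partial_date("20150101"))]
        assert compute_onset_days(case, ther, [1]) == 100.0

    def test_year_only_start_without_duration_is_unknown(self):
        case = make_report(1, event="20150411")
        ther = [TherapyEntry(1, 1, parse_partial_date("2015"))]
        assert compute_onset_days(case, ther, [1]) is None

    def test_duration_fallback_in_months(self):
        case = make_report(1, event="")
        ther = [TherapyEntry(1, 1, duration_value=3, duration_unit="MON")]
        assert compute_onset_days(case, ther, [1]) == pytest.approx(91.3, abs=0.02)

    def test_negative_onset_is_unknown(self):
        case = make_report(1, event="20140101")
        ther = [TherapyEntry(1, 1, parse_partial_date("20150101"))]
        assert compute_onset_days(case, ther, [1]) is None

    def test_earliest_start_of_target_drug_wins(self):
        case = make_report(1, event="20150411")
        ther = [
            TherapyEntry(1, 1, parse_partial_date("20150301")),
            TherapyEntry(1, 1, parse_partial_date("20150101")),
            TherapyEntry(1, 2, parse_partial_date("20100101")),  # other drug
        ]
        assert compute_onset_days(case, ther, [1]) == 100.0


class TestBinning:
    @pytest.mark.parametrize(
        "days, label",
        [
            (0, "0~1 month"),
            (30, "0~1 month"),
            (31, "1~3 months"),
            (100, "3~6 months"),  # 100 / 30.4375 = 3.29 months
            (2000, "60~ months"),  # 65.7 months
        ],
    )
    def test_bin_examples(self, days, label):
        assert bin_onset(days) == label

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            bin_onset(-1)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0, max_value=1e5, allow_nan=False))
    def test_bins_partition_nonnegative_days(self, days):
        assert bin_onset(days) in ONSET_BIN_LABELS

    def test_bin_counts_match_brute_force_on_10k_onsets(self):
        rng = np.random.default_rng(5)
        onsets = rng.lognormal(5.5, 1.0, size=10_000)
        binning = onset_summary({"x": onsets})
        brute = dict.fromkeys(ONSET_BIN_LABELS, 0)
        for d in onsets:
            brute[bin_onset(d)] += 1
        for label in ONSET_BIN_LABELS:
            assert binning.bin_counts.loc["x", label] == brute[label]
        assert binning.bin_counts.loc["x", "Total"] == 10_000


class TestOnsetSummary:
    def test_single_indication_mean(self):
        binning = onset_summary({"x": [10, 20, 30]})
        assert binning.summaries.loc["x", "mean_days"] == pytest.approx(20.0)
        assert binning.overall_mean_days == pytest.approx(20.0)

    def test_case_weighted_overall_mean_from_published_rows(self):
        """Constant per-indication onsets at the published means reproduce the
        published case-weighted overall average of 871.1 days."""
        onsets = {
            ind: [datasets.ONSET_MEAN_DAYS[ind]] * sum(bins)
            for ind, bins in datasets.ONSET_BIN_COUNTS.items()
        }
        binning = onset_summary(onsets)
        assert round(binning.overall_mean_days, 1) == 871.1


class TestSocTable:
    def test_gi_share_on_published_scale_fixture(self):
        """542 of 858 cases with a GI reaction -> 63.2%."""
        parts = [
            make_aspirin_case(i, reactions=("Melaena",)) for i in range(1, 543)
        ] + [
            make_aspirin_case(i, reactions=("Rash",)) for i in range(543, 859)
        ]
        cohort, _ = cohort_of(merge(*parts))
        table = soc_tabulate(cohort)
        gi = table[table["soc"] == "Gastrointestinal disorders"].iloc[0]
        assert gi["cases"] == 542 and gi["percent"] == 63.2

    def test_multi_soc_case_counts_in_each(self):
        db = make_aspirin_case(1, reactions=("Melaena", "Rash"))
        cohort, _ = cohort_of(db)
        table = soc_tabulate(cohort)
        assert set(table["soc"]) == {
            "Gastrointestinal disorders",
            "Skin and subcutaneous tissue disorders",
        }
        assert (table["cases"] == 1).all()
        assert table["cases"].sum() == 2  # exceeds the single-case total

    def test_empty_cohort_gives_empty_table(self):
        cohort, _ = cohort_of(make_aspirin_case(1, role="C"))
        assert len(soc_tabulate(cohort)) == 0


class TestDemographics:
    def test_sex_share_fixture(self):
        parts = (
            [make_aspirin_case(i, sex="F") for i in range(1, 395)]
            + [make_aspirin_case(i, sex="M") for i in range(395, 796)]
            + [make_aspirin_case(i, sex="UNK") for i in range(796, 859)]
        )
        cohort, _ = cohort_of(merge(*parts))
        table = demographic_tabulate(cohort)
        sex = table[table["characteristic"] == "sex"].set_index("level")
        assert sex.loc["Female", "count"] == 394
        assert sex.loc["Female", "percent"] == 45.9
        assert sex.loc["Male", "percent"] == 46.7

    def test_region_share_two_decimals(self):
        parts = [make_aspirin_case(i, country="DE") for i in range(1, 553)] + [
            make_aspirin_case(i, country="") for i in range(553, 859)
        ]
        cohort, _ = cohort_of(merge(*parts))
        table = demographic_tabulate(cohort)
        region = table[table["characteristic"] == "region"].set_index("level")
        assert region.loc["Europe", "count"] == 552
        assert region.loc["Europe", "percent"] == 64.34

    def test_all_unknown_sex_single_row(self):
        cohort, _ = cohort_of(make_aspirin_case(1, sex="UNK"))
        table = demographic_tabulate(cohort)
        sex = table[table["characteristic"] == "sex"]
        assert list(sex["level"]) == ["Unknown"] and list(sex["percent"]) == [100.0]

    def test_age_bands_are_closed_open(self):
        parts = [
            make_aspirin_case(1, age=17.9, age_unit="YR"),
            make_aspirin_case(2, age=18, age_unit="YR"),
            make_aspirin_case(3, age=75, age_unit="YR"),
            make_aspirin_case(4),  # missing age
        ]
        cohort, _ = cohort_of(merge(*parts))
        table = demographic_tabulate(cohort)
        ages = table[table["characteristic"] == "age_band"].set_index("level")["count"]
        assert ages["0 to 18"] == 1 and ages["18 to 45"] == 1
        assert ages["75 to"] == 1 and ages["Unknown"] == 1


class TestOutcomes:
    def test_hospitalization_column_total_from_published_rows(self):
        parts = []
        pid = 0
        for indication, counts in datasets.OUTCOME_COUNTS.items():
            for code, count in zip(datasets.OUTCOME_COLUMNS, counts):
                for _ in range(count):
                    pid += 1
                    parts.append(
                        make_aspirin_case(pid, indication=indication, outcomes=(code,))
                    )
        cohort, _ = cohort_of(merge(*parts))
        table = outcome_tabulate(cohort)
        assert table.loc["Total", "HO"] == 655
        assert tuple(table.loc["Total"]) == datasets.OUTCOME_COLUMN_TOTALS

    def test_multi_outcome_case_counts_once_per_code(self):
        db = make_aspirin_case(1, outcomes=("DE", "HO"))
        db.outcomes.append(OutcomeEntry(1, "HO"))  # repeated code counts once
        cohort, _ = cohort_of(db)
        table = outcome_tabulate(cohort)
        assert table.loc["Prophylaxis (NEC)", "DE"] == 1
        assert table.loc["Prophylaxis (NEC)", "HO"] == 1

    def test_total_row_equals_column_sums(self, small_cohort):
        table = outcome_tabulate(small_cohort)
        body = table.drop(index="Total")
        assert (table.loc["Total"] == body.sum(axis=0)).all()


class TestIndicationShares:
    def test_share_arithmetic(self):
        counts = {
            "Prophylaxis (NEC)": 480,
            "Thrombosis prophylaxis": 380,
            "Cardiovascular event prophylaxis": 50,
            "Ischemic heart disease prophylaxis": 40,
            "Cerebrovascular accident prophylaxis": 40,
            "Blood disorder prophylaxis": 10,
        }
        parts, pid = [], 0
        for indication, count in counts.items():
            for _ in range(count):
                pid += 1
                parts.append(make_aspirin_case(pid, indication=indication))
        cohort, _ = cohort_of(merge(*parts))
        shares = indication_shares(cohort)
        assert shares["Prophylaxis (NEC)"] == 48
        assert shares["Thrombosis prophylaxis"] == 38
        assert shares["Blood disorder prophylaxis"] == 1

    def test_single_indication_is_100(self):
        cohort, _ = cohort_of(make_aspirin_case(1))
        assert indication_shares(cohort) == {"Prophylaxis (NEC)": 100}

    def test_shares_sum_to_100_within_rounding(self, small_cohort):
        total = sum(indication_shares(small_cohort).values())
        assert 97 <= total <= 103  # whole-percent rounding over 9 categories
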