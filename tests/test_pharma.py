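"""Expenditure filters, yearly summaries, class ranking and trend models."""

import numpy as np
import pandas as pd
import pytest

from masld_cua.cohort import CohortSpec, generate_expenditures
from masld_cua.pharma import (
    class_year_matrix,
    filter_consecutive_years,
    filter_min_packages,
    patient_year_totals,
    summarize_years,
    top_k_classes,
    trend_mixed_model,
    trend_rm_anova,
)


def records(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "year", "atc_class", "cost", "packages"]
    )


class TestMinPackagesFilter:
    def test_boundary_fewer_than_three_excluded(self):
        recs = records(
            [
                ("a", 2018, "C09BB", 10.0, 2),  # 2 packages -> out
                ("b", 2018, "C09BB", 10.0, 3),  # exactly 3 -> kept
            ]
        )
        out = filter_min_packages(recs)
        assert list(out["patient_id"]) == ["b"]

    def test_counts_pooled_within_patient_class(self):
        recs = records(
            [("a", 2018, "C09BB", 5.0, 1), ("a", 2019, "C09BB", 5.0, 2)]
        )
        assert len(filter_min_packages(recs)) == 2

    def test_missing_packages_skips_with_warning(self):
        recs = records([("a", 2018, "C09BB", 5.0, None)])
        recs["packages"] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            out = filter_min_packages(recs)
        assert len(out) == 1

    def test_empty_input(self):
        with pytest.warns(UserWarning):
            assert filter_min_packages(records([])).empty


class TestConsecutiveYearsFilter:
    @pytest.mark.parametrize(
        "years,kept",
        [((2018, 2019), True), ((2019,), False), ((2018, 2020), False)],
    )
    def test_consecutive_run_rule(self, years, kept):
        recs = records([("a", y, "C10AX", 50.0, 3) for y in years])
        out = filter_consecutive_years(recs)
        assert (len(out) > 0) == kept

    def test_zero_cost_years_do_not_count_as_presence(self):
        recs = records(
            [("a", 2018, "C10AX", 50.0, 3), ("a", 2019, "C10AX", 0.0, 0)]
        )
        assert filter_consecutive_years(recs).empty

    def test_cohort_wide_pooling(self):
        # presence in adjacent years via different patients still counts
        recs = records(
            [("a", 2018, "C10AX", 50.0, 3), ("b", 2019, "C10AX", 20.0, 3)]
        )
        assert len(filter_consecutive_years(recs)) == 2

    def test_filters_commute_on_independent_inputs(self):
        spec = CohortSpec(seed=21)
        recs = generate_expenditures(spec)
        ab = filter_consecutive_years(filter_min_packages(recs))
        ba = filter_min_packages(filter_consecutive_years(recs))
        pd.testing.assert_frame_equal(
            ab.sort_values(list(ab.columns)).reset_index(drop=True),
            ba.sort_values(list(ba.columns)).reset_index(drop=True),
        )


class TestSummaries:
    def test_two_patient_hand_example(self):
        recs = records([("a", 2018, "C09BB", 100.0, 3), ("b", 2018, "C09BB", 0.0, 0)])
        (summary,) = summarize_years(recs, roster=recs[["patient_id", "year"]])
        assert (summary.total, summary.mean, summary.median) == (100.0, 50.0, 50.0)
        assert summary.n_patients == 2

    def test_all_zero_year(self):
        recs = records([("a", 2018, "C09BB", 0.0, 0), ("b", 2018, "C09BB", 0.0, 0)])
        (summary,) = summarize_years(recs, roster=recs[["patient_id", "year"]])
        assert summary.total == 0.0 and summary.iqr == 0.0

    def test_roster_zero_fills_missing_patient_years(self):
        recs = records([("a", 2018, "C09BB", 100.0, 3)])
        roster = pd.DataFrame(
            {"patient_id": ["a", "b"], "year": [2018, 2018]}
        )
        (summary,) = summarize_years(recs, roster)
        assert summary.n_patients == 2 and summary.mean == 50.0

    def test_missing_roster_warns(self):
        recs = records([("a", 2018, "C09BB", 100.0, 3)])
        with pytest.warns(UserWarning, match="roster"):
            summarize_years(recs)

    def test_totals_invariant_to_record_splitting(self):
        whole = records([("a", 2018, "C09BB", 100.0, 4)])
        split = records(
            [("a", 2018, "C09BB", 60.0, 2), ("a", 2018, "C09BB", 40.0, 2)]
        )
        roster = whole[["patient_id", "year"]]
        assert summarize_years(whole, roster) == summarize_years(split, roster)

    def test_generator_year_means_recovered(self):
        spec = CohortSpec(n_patients=1000, seed=22)
        recs = generate_expenditures(spec)
        roster = recs[["patient_id", "year"]].drop_duplicates()
        for summary in summarize_years(recs, roster):
            configured = spec.expenditure_year_means[summary.year]
            costs = recs.loc[recs["year"] == summary.year, "cost"]
            se = costs.std(ddof=1) / np.sqrt(len(costs))
            assert abs(summary.mean - configured) < 3 * se


class TestTopK:
    def test_dominant_class_first(self):
        recs = records(
            [("a", 2018, "C09BB", 500.0, 9), ("a", 2018, "C10AX", 10.0, 3)]
        )
        assert top_k_classes(recs, 1) == ["C09BB"]

    def test_tie_broken_lexicographically(self):
        recs = records(
            [("a", 2018, "ZZZ", 100.0, 3), ("a", 2018, "AAA", 100.0, 3)]
        )
        assert top_k_classes(recs, 1) == ["AAA"]

    def test_fewer_classes_than_k_all_returned(self):
        recs = records([("a", 2018, "C09BB", 10.0, 3)])
        assert top_k_classes(recs, 5) == ["C09BB"]

    def test_generator_seeded_classes_recovered(self):
        recs = generate_expenditures(CohortSpec(n_patients=200, seed=23))
        assert set(top_k_classes(recs, 5)) == {
            "C09BB", "C10AX", "C02CA", "N06AX", "R03AK"
        }


class TestTrend:
    @staticmethod
    def noise_free_totals(slope=-19.2, n=10):
        rows = [
            {"patient_id": f"p{i}", "year": y, "cost": 200.0 + 10 * i + slope * (y - 2018)}
            for i in range(n)
            for y in (2018, 2019, 2020, 2021)
        ]
        return pd.DataFrame(rows)

    def test_noise_free_decline_recovered_exactly(self):
        res = trend_mixed_model(self.noise_free_totals())
        assert res.slope == pytest.approx(-19.2, abs=1e-6)
        assert res.p_value < 1e-6

    def test_year_permutation_nulls_the_slope(self):
        rng = np.random.default_rng(24)
        totals = self.noise_free_totals(slope=0.0, n=60)
        totals["cost"] += rng.normal(0, 30, size=len(totals))
        res = trend_mixed_model(totals)
        assert abs(res.slope) < 3 * res.slope_se + 1e-9

    def test_single_year_rejected(self):
        with pytest.raises(ValueError, match="two years"):
            trend_mixed_model(
                pd.DataFrame(
                    {"patient_id": ["a", "b"], "year": [2018, 2018], "cost": [1.0, 2.0]}
                )
            )

    def test_rm_anova_requires_balanced_panel(self):
        totals = self.noise_free_totals().iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            trend_rm_anova(totals)

    def test_rm_anova_detects_strong_trend(self):
        rng = np.random.default_rng(25)
        totals = self.noise_free_totals(slope=-40.0, n=20)
        totals["cost"] += rng.normal(0, 5, size=len(totals))
        res = trend_rm_anova(totals)
        assert res.model == "rm_anova" and res.p_value < 0.01

    def test_ci_coverage_of_true_slope(self):
        """Reduced-replicate recovery check; the acceptance suite runs the
        full 300-replicate version."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(3_000 + rep)
            rows = []
            for i in range(27):
                b = rng.normal(0, 30)
                for y in (2018, 2019, 2020, 2021):
                    rows.append(
                        {
                            "patient_id": f"p{i}",
                            "year": y,
                            "cost": 120 + b - 19.2 * (y - 2018) + rng.normal(0, 40),
                        }
                    )
            res = trend_mixed_model(pd.DataFrame(rows))
            hits += res.ci_low <= -19.2 <= res.ci_high
        assert hits / n_rep > 0.85


class TestClassYearMatrix:
    def test_matrix_totals_match_groupby(self):
        recs = generate_expenditures(CohortSpec(seed=26))
        matrix = class_year_matrix(recs)
        assert matrix.to_numpy().sum() == pytest.approx(recs["cost"].sum())
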