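"""ATC-class pharmaceutical-expenditure aggregation and trend analysis.

Works on per-patient, per-year, per-ATC-class outpatient dispensing
records (EUR cost, optional package counts).  The analysis chain:

1. filter out (patient, class) groups with fewer than a minimum number
   of dispensed packages (occasional or short-term prescriptions) -
   used for baseline comorbidity profiling;
2. restrict longitudinal analyses to classes with non-zero cohort-level
   expenditure in a minimum number of consecutive years, excluding
   isolated prescriptions;
3. summarize per-patient yearly totals (zero-filled from an explicit
   patient-year roster, so zero-cost years keep the denominators
   honest) as total / mean / median / IQR per year;
4. rank classes by cumulative cost and keep the top k;
5. fit the year trend with a random-intercept mixed model (EUR/year
   fixed slope), with repeated-measures ANOVA as a sensitivity check.

Expenditures are analyzed as euros rather than defined daily doses,
which are unsuitable for intermittent, variable-dose regimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPENDITURE_COLUMNS = ("patient_id", "year", "atc_class", "cost")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXPENDITURE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"expenditure table missing columns: {sorted(missing)}")
    if (records["cost"] < 0).any():
        raise ValueError("negative costs in expenditure records")
    return records


def filter_min_packages(
    records: pd.DataFrame, min_packages: int = 3
) -> pd.DataFrame:
    """Drop (patient, class) groups with fewer than ``min_packages`` packages.

    "Fewer than three dispensed packages" are excluded by default, so a
    group totalling exactly three is retained.  If the table carries no
    usable ``packages`` column the filter is skipped with a warning.
    """
    _validate(records)
    if "packages" not in records.columns or records["packages"].isna().all():
        warnings.warn(
            "no package counts available; min-packages filter skipped",
            stacklevel=2,
        )
        return records.copy()
    totals = records.groupby(["patient_id", "atc_class"])["packages"].transform("sum")
    return records[totals >= min_packages].copy()


def filter_consecutive_years(
    records: pd.DataFrame, min_run: int = 2
) -> pd.DataFrame:
    """Keep classes with non-zero cohort cost in >= ``min_run`` consecutive years.

    A class dispensed in a single isolated year (or in non-adjacent years
    only) is excluded from longitudinal analyses.
    """
    _validate(records)
    if records.empty:
        return records.copy()
    yearly = (
        records.groupby(["atc_class", "year"])["cost"].sum().reset_index()
    )
    keep = set()
    for atc, grp in yearly.groupby("atc_class"):
        years = sorted(grp.loc[grp["cost"] > 0, "year"].unique())
        run = best = 0
        prev = None
        for y in years:
            run = run + 1 if prev is not None and y == prev + 1 else 1
            best = max(best, run)
            prev = y
        if best >= min_run:
            keep.add(atc)
    return records[records["atc_class"].isin(keep)].copy()


def patient_year_totals(
    records: pd.DataFrame, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-patient yearly cost totals, zero-filled from the roster.

    ``roster`` is a (patient_id, year) frame naming who contributes to
    each year's denominator; patient-years in the roster without records
    enter with cost 0.  Without a roster the patients observed in each
    year (including explicit zero-cost rows) define the denominator, with
    a warning, since per-year denominators may genuinely vary.
    """
    _validate(records)
    sums = (
        records.groupby(["patient_id", "year"])["cost"].sum().reset_index()
    )
    if roster is None:
        warnings.warn(
            "no patient-year roster supplied; denominators default to the "
            "patients observed in each year",
            stacklevel=2,
        )
        return sums
    roster = roster[["patient_id", "year"]].drop_duplicates()
    out = roster.merge(sums, on=["patient_id", "year"], how="left")
    out["cost"] = out["cost"].fillna(0.0)
    return out.sort_values(["year", "patient_id"]).reset_index(drop=True)


@dataclass(frozen=True)
class YearSummary:
    """One calendar year's expenditure summary over the contributing patients."""

    year: int
    total: float
    mean: float
    median: float
    iqr: float
    n_patients: int


def summarize_years(
    records: pd.DataFrame, roster: pd.DataFrame | None = None
) -> list[YearSummary]:
    """Total, mean, median and IQR of per-patient yearly sums, per year."""
    totals = patient_year_totals(records, roster)
    out = []
    for year, grp in totals.groupby("year", sort=True):
        costs = grp["cost"].to_numpy(dtype=float)
        q1, q3 = np.percentile(costs, [25, 75])
        out.append(
            YearSummary(
                year=int(year),
                total=float(costs.sum()),
                mean=float(costs.mean()),
                median=float(np.median(costs)),
                iqr=float(q3 - q1),
                n_patients=int(costs.size),
            )
        )
    return out


def year_summary_frame(summaries: Sequence[YearSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def top_k_classes(records: pd.DataFrame, k: int = 5) -> list[str]:
    """The k ATC classes with the highest cumulative cost across all years.

    Ties at the cut are broken lexicographically by ATC code.  If fewer
    than k classes exist, all are returned.
    """
    _validate(records)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    totals = records.groupby("atc_class")["cost"].sum()
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [atc for atc, _ in ranked[:k]]


def class_year_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """ATC-class x year cost matrix (heatmap source)."""
    _validate(records)
    return (
        records.pivot_table(
            index="atc_class", columns="year", values="cost", aggfunc="sum", fill_value=0.0
        )
        .sort_index()
    )


@dataclass(frozen=True)
class TrendResult:
    """Linear year-trend of per-patient expenditure totals."""

    slope: float  # EUR per year
    slope_se: float
    p_value: float
    ci_low: float
    ci_high: float
    n_obs: int
    model: str  # "mixed" or "rm_anova"


def trend_mixed_model(
    totals: pd.DataFrame, level: float = 0.95
) -> TrendResult:
    """Random-intercept mixed model of cost on year (REML).

    ``totals`` holds per-patient yearly sums (patient_id, year, cost),
    typically from :func:`patient_year_totals` so zero years are
    represented.  Year enters as an integer offset from the first year;
    the slope is therefore in EUR per year.
    """
    from masld_cua.qaly import _fit_slope

    for col in ("patient_id", "year", "cost"):
        if col not in totals.columns:
            raise ValueError(f"totals frame missing column {col!r}")
    if totals["year"].nunique() < 2:
        raise ValueError("trend model needs at least two years")
    if totals["patient_id"].nunique() < 2:
        raise ValueError("trend model needs at least two patients")

    long = totals.copy()
    long["year_offset"] = long["year"] - long["year"].min()
    slope, se, _ = _fit_slope(long, response="cost", time="year_offset")
    if se > 0:
        zstat = slope / se
        p = 2 * stats.norm.sf(abs(zstat))
    else:
        p = 0.0 if slope != 0 else 1.0
    z = stats.norm.ppf((1 + level) / 2)
    return TrendResult(
        slope=float(slope),
        slope_se=float(se),
        p_value=float(p),
        ci_low=float(slope - z * se),
        ci_high=float(slope + z * se),
        n_obs=int(len(long)),
        model="mixed",
    )


def trend_rm_anova(totals: pd.DataFrame) -> TrendResult:
    """Repeated-measures ANOVA on year as a sensitivity analysis.

    Requires a balanced panel (every patient observed - possibly with a
    zero - in every year), which a roster-based zero fill provides.
    ``p_value`` is the ANOVA year-effect p; the F test carries no slope,
    so the slope fields report the pooled OLS fit for orientation.
    """
    from statsmodels.stats.anova import AnovaRM
    import statsmodels.api as sm

    counts = totals.groupby("patient_id")["year"].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != totals["year"].nunique():
        raise ValueError(
            "repeated-measures ANOVA needs a balanced patient x year panel; "
            "zero-fill via patient_year_totals with a roster"
        )
    res = AnovaRM(
        data=totals, depvar="cost", subject="patient_id", within=["year"]
    ).fit()
    p = float(res.anova_table["Pr > F"].iloc[0])

    x = sm.add_constant((totals["year"] - totals["year"].min()).to_numpy(dtype=float))
    ols = sm.OLS(totals["cost"].to_numpy(dtype=float), x).fit()
    return TrendResult(
        slope=float(ols.params[1]),
        slope_se=float(ols.bse[1]),
        p_value=p,
        ci_low=float(ols.conf_int()[1][0]),
        ci_high=float(ols.conf_int()[1][1]),
        n_obs=int(len(totals)),
        model="rm_anova",
    )
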