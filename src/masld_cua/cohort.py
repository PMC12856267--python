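"""Seeded synthetic cohort generator.

The study's raw patient data are not public, so every downstream stage is
exercised on synthetic tables with the same statistical structure:

- an SF-36 visit panel whose latent per-visit EQ-5D utility follows a
  random-intercept linear growth model (baseline mean + patient
  intercept + slope x month + residual), with domain scores constructed
  as an exact inverse of the SF-36 -> EQ-5D mapping so that mapping the
  generated scores recovers the latent utility to machine precision;
- pre/post clinical markers (blood pressure, aminotransferases) drawn as
  correlated bivariate normals per patient;
- pre/post ordinal steatosis grades (0-6 scale) drawn from configured
  probability vectors coupled through a Gaussian copula;
- binary maintained-activity flags;
- per-patient, per-year, per-ATC-class outpatient expenditure records
  with zero-inflation (zero-cost patient-years retained as rows).

Defaults reproduce the published study's conditions: 27 patients,
visits every 2 months to month 8, a utility trend yielding a mean gain
of 0.081 over 8 months, the reported pre/post marker means and SDs, a
steatosis distribution shifting toward lower grades, a 15/27 maintained
activity rate, and per-patient yearly expenditure means of EUR 74/71/46/50
over 2018-2021.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from masld_cua.mapping import (
    SF36_DOMAINS,
    MappingCoefficients,
    SF36Visit,
    visits_to_frame,
)

#: Pre-intervention marker (mean, sd) in native units: systolic and
#: diastolic blood pressure in mmHg, AST and ALT in U/L.
DEFAULT_MARKERS_PRE = {
    "sbp": (129.26, 12.91),
    "dbp": (82.59, 8.70),
    "ast": (25.33, 9.39),
    "alt": (29.71, 14.42),
}
DEFAULT_MARKERS_POST = {
    "sbp": (123.70, 9.67),
    "dbp": (78.89, 6.98),
    "ast": (21.56, 5.08),
    "alt": (23.80, 9.24),
}

#: Steatosis grade (0-6) probability vectors.  The pre vector centers the
#: cohort near grade 2 (median 2, upper quartile reaching grade 4); the
#: post vector concentrates mass on grades 1-2, reproducing the observed
#: distributional shift toward lower grades with an unchanged median.
DEFAULT_STEATOSIS_PRE = (0.05, 0.18, 0.30, 0.12, 0.15, 0.12, 0.08)
DEFAULT_STEATOSIS_POST = (0.10, 0.28, 0.38, 0.12, 0.07, 0.03, 0.02)

#: The five ATC classes with the highest cumulative costs in the study,
#: with generator sampling weights putting most spending on the
#: antihypertensive combination class.
DEFAULT_ATC_CLASSES = ("C09BB", "C10AX", "C02CA", "N06AX", "R03AK")
DEFAULT_ATC_WEIGHTS = (0.50, 0.16, 0.14, 0.12, 0.08)


@dataclass(frozen=True)
class CohortSpec:
    """Generative conditions of the synthetic cohort.

    The utility trajectory is ``baseline_mean + b_i + slope * month +
    eps`` with ``b_i ~ N(0, random_intercept_sd^2)`` and ``eps ~ N(0,
    residual_sd^2)``.  The default slope 0.010125/month accumulates to a
    0.081 utility gain over the 8-month follow-up.
    """

    n_patients: int = 27
    visit_months: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    utility_baseline_mean: float = 0.70
    utility_slope_per_month: float = 0.010125
    random_intercept_sd: float = 0.05
    residual_sd: float = 0.03
    dropout_prob: float = 0.0
    marker_means_pre: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS_PRE)
    )
    marker_means_post: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS_POST)
    )
    marker_correlation: float = 0.6
    steatosis_probs_pre: tuple[float, ...] = DEFAULT_STEATOSIS_PRE
    steatosis_probs_post: tuple[float, ...] = DEFAULT_STEATOSIS_POST
    steatosis_correlation: float = 0.6
    activity_maintain_prob: float = 15 / 27
    expenditure_year_means: Mapping[int, float] = field(
        default_factory=lambda: {2018: 74.0, 2019: 71.0, 2020: 46.0, 2021: 50.0}
    )
    expenditure_zero_prob: float = 0.30
    expenditure_cv: float = 0.80
    atc_classes: tuple[str, ...] = DEFAULT_ATC_CLASSES
    atc_weights: tuple[float, ...] = DEFAULT_ATC_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        months = self.visit_months
        if not months or months[0] != 0:
            raise ValueError("visit_months must start at 0")
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("visit_months must be strictly increasing")
        for name in ("random_intercept_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for label, probs in (
            ("steatosis_probs_pre", self.steatosis_probs_pre),
            ("steatosis_probs_post", self.steatosis_probs_post),
        ):
            probs = tuple(probs)
            if len(probs) != 7 or any(p < 0 for p in probs):
                raise ValueError(f"{label} must be 7 non-negative grade probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{label} must sum to 1, got {sum(probs)}")
        for prob_name in ("activity_maintain_prob", "expenditure_zero_prob", "dropout_prob"):
            p = getattr(self, prob_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{prob_name} must be a probability, got {p}")
        if not -1 < self.marker_correlation < 1 or not -1 < self.steatosis_correlation < 1:
            raise ValueError("within-patient correlations must lie in (-1, 1)")
        for marker, arms in (("pre", self.marker_means_pre), ("post", self.marker_means_post)):
            for name, (_, sd) in arms.items():
                if sd < 0:
                    raise ValueError(f"{marker} sd for {name!r} must be non-negative")
        if set(self.marker_means_pre) != set(self.marker_means_post):
            raise ValueError("pre and post marker sets must match")
        if any(m < 0 for m in self.expenditure_year_means.values()):
            raise ValueError("expenditure year means must be non-negative")
        if len(self.atc_weights) != len(self.atc_classes):
            raise ValueError("one weight per ATC class required")

    def patient_ids(self) -> list[str]:
        width = len(str(self.n_patients))
        return [f"P{str(i + 1).zfill(width)}" for i in range(self.n_patients)]


@dataclass(frozen=True)
class SyntheticCohort:
    """The generated tables, ready for the analysis pipeline."""

    sf36_visits: pd.DataFrame
    clinical_prepost: pd.DataFrame  # long: patient_id, marker, pre, post
    steatosis_prepost: pd.DataFrame  # patient_id, pre, post
    activity_flags: pd.DataFrame  # patient_id, maintained (0/1)
    expenditures: pd.DataFrame  # patient_id, year, atc_class, cost, packages
    spec: CohortSpec


def _invert_mapping(
    utility: float, coeffs: MappingCoefficients
) -> dict[str, float]:
    """Domain scores whose mapped utility equals ``utility`` exactly.

    Moves from the domain-cube center (all scores 50) along the fixed
    direction ``sign(slope_d)``, i.e. toward the cube corner that raises
    the utility fastest; the step length is chosen so the affine mapping
    lands on the target.  A single direction keeps the generator an exact
    right inverse of the mapping, and the corner direction maximizes the
    representable utility band inside [0, 100]^8 (center +/- 50 times the
    sum of absolute slopes).
    """
    slopes = np.array([coeffs.slopes[d] for d in SF36_DOMAINS])
    direction = np.sign(slopes)
    gradient = float(np.abs(slopes).sum())
    if gradient == 0.0:
        raise ValueError("mapping has all-zero slopes; cannot invert")
    mid_utility = coeffs.intercept + 50.0 * float(slopes.sum())
    t = (utility - mid_utility) / gradient
    scores = 50.0 + t * direction
    if scores.min() < -1e-9 or scores.max() > 100.0 + 1e-9:
        reach = 50.0 * gradient
        raise ValueError(
            f"latent utility {utility:.4f} outside the representable band "
            f"[{mid_utility - reach:.4f}, {mid_utility + reach:.4f}]; adjust the "
            "cohort spec's utility parameters"
        )
    scores = np.clip(scores, 0.0, 100.0)
    return dict(zip(SF36_DOMAINS, scores.tolist()))


def generate_sf36_panel(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    coeffs: MappingCoefficients | None = None,
) -> list[SF36Visit]:
    """SF-36 visits realizing the latent random-intercept utility model."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    coeffs = coeffs or MappingCoefficients.default()
    visits = []
    for pid in spec.patient_ids():
        b_i = rng.normal(0.0, spec.random_intercept_sd)
        for month in spec.visit_months:
            if month > 0 and spec.dropout_prob > 0 and rng.random() < spec.dropout_prob:
                continue
            eps = rng.normal(0.0, spec.residual_sd)
            latent = (
                spec.utility_baseline_mean
                + b_i
                + spec.utility_slope_per_month * month
                + eps
            )
            visits.append(
                SF36Visit(
                    patient_id=pid,
                    month=float(month),
                    **_invert_mapping(latent, coeffs),
                )
            )
    return visits


def _correlated_pair(
    rng: np.random.Generator, n: int, correlation: float
) -> np.ndarray:
    cov = [[1.0, correlation], [correlation, 1.0]]
    return rng.multivariate_normal([0.0, 0.0], cov, size=n)


def generate_clinical_prepost(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Continuous markers and ordinal steatosis grades, pre and post.

    Continuous markers: per patient, (pre, post) is bivariate normal
    with the configured marginal means/SDs and within-patient
    correlation.  Steatosis: a latent bivariate normal with the
    configured correlation is pushed through each arm's categorical
    quantile function; the coupling raises the chance that an
    individual's post grade sits low when the pre grade did, but does not
    forbid individual increases.
    """
    from scipy import stats

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    pids = spec.patient_ids()
    n = spec.n_patients

    rows = []
    for marker in sorted(spec.marker_means_pre):
        mean_pre, sd_pre = spec.marker_means_pre[marker]
        mean_post, sd_post = spec.marker_means_post[marker]
        z = _correlated_pair(rng, n, spec.marker_correlation)
        pre = mean_pre + sd_pre * z[:, 0]
        post = mean_post + sd_post * z[:, 1]
        rows.extend(
            {"patient_id": pid, "marker": marker, "pre": float(a), "post": float(b)}
            for pid, a, b in zip(pids, pre, post)
        )
    clinical = pd.DataFrame(rows, columns=["patient_id", "marker", "pre", "post"])

    z = _correlated_pair(rng, n, spec.steatosis_correlation)
    u = stats.norm.cdf(z)
    cut_pre = np.cumsum(spec.steatosis_probs_pre)
    cut_post = np.cumsum(spec.steatosis_probs_post)
    grades_pre = np.searchsorted(cut_pre, u[:, 0], side="left")
    grades_post = np.searchsorted(cut_post, u[:, 1], side="left")
    steatosis = pd.DataFrame(
        {
            "patient_id": pids,
            "pre": np.minimum(grades_pre, 6).astype(int),
            "post": np.minimum(grades_post, 6).astype(int),
        }
    )
    return clinical, steatosis


def generate_activity_flags(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    flags = (rng.random(spec.n_patients) < spec.activity_maintain_prob).astype(int)
    return pd.DataFrame({"patient_id": spec.patient_ids(), "maintained": flags})


def generate_expenditures(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Zero-inflated gamma expenditure records per patient-year.

    With probability ``expenditure_zero_prob`` a patient-year has no
    dispensing; the row is still emitted (cost 0, packages 0) so yearly
    denominators stay consistent.  Otherwise the year's cost is gamma
    with conditional mean ``year_mean / (1 - zero_prob)`` - making the
    unconditional patient-year mean equal the configured mean - assigned
    to an ATC class drawn by the configured weights, with a package
    count scaling with cost.
    """
    if not spec.expenditure_year_means:
        raise ValueError("expenditure_year_means is empty")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    zero_p = spec.expenditure_zero_prob
    weights = np.asarray(spec.atc_weights, dtype=float)
    weights = weights / weights.sum()

    rows = []
    for pid in spec.patient_ids():
        for year in sorted(spec.expenditure_year_means):
            mean = spec.expenditure_year_means[year]
            atc = spec.atc_classes[rng.choice(len(weights), p=weights)]
            if mean == 0.0 or zero_p >= 1.0 or rng.random() < zero_p:
                rows.append(
                    {"patient_id": pid, "year": year, "atc_class": atc,
                     "cost": 0.0, "packages": 0}
                )
                continue
            cond_mean = mean / (1.0 - zero_p)
            cv = spec.expenditure_cv
            if cv == 0.0:
                cost = cond_mean
            else:
                shape = 1.0 / cv**2
                cost = rng.gamma(shape, cond_mean / shape)
            packages = 1 + rng.poisson(cost / 25.0)
            rows.append(
                {"patient_id": pid, "year": year, "atc_class": atc,
                 "cost": float(cost), "packages": int(packages)}
            )
    return pd.DataFrame(
        rows, columns=["patient_id", "year", "atc_class", "cost", "packages"]
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """All synthetic tables from one seeded generator stream."""
    rng = np.random.default_rng(spec.seed)
    sf36 = visits_to_frame(generate_sf36_panel(spec, rng))
    clinical, steatosis = generate_clinical_prepost(spec, rng)
    activity = generate_activity_flags(spec, rng)
    expenditures = generate_expenditures(spec, rng)
    return SyntheticCohort(
        sf36_visits=sf36,
        clinical_prepost=clinical,
        steatosis_prepost=steatosis,
        activity_flags=activity,
        expenditures=expenditures,
        spec=spec,
    )


def write_cohort_csvs(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write sf36_visits.csv, clinical_prepost.csv, steatosis_prepost.csv,
    activity_flags.csv and expenditures.csv to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("sf36_visits", cohort.sf36_visits),
        ("clinical_prepost", cohort.clinical_prepost),
        ("steatosis_prepost", cohort.steatosis_prepost),
        ("activity_flags", cohort.activity_flags),
        ("expenditures", cohort.expenditures),
    ):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
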