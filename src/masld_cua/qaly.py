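"""QALY-gain estimation from longitudinal EQ-5D utilities.

Two estimators are provided, mirroring the usual practice in small
single-arm lifestyle studies:

``locf``
    the simple first-versus-last contrast per patient ("last observation
    carried forward"), with a t-based confidence interval on the mean
    delta;

``lmm``
    a linear mixed-effects model — fixed intercept and linear time
    effect, per-patient random intercept, Gaussian residual, fitted by
    REML — whose fixed slope, scaled by the follow-up horizon, gives the
    utility gain.  The mixed model uses every visit, tolerates unbalanced
    schedules, and accounts for intra-patient correlation.

A utility delta sustained over the one-year program horizon is treated as
a QALY gain of the same magnitude (0.081 utility points maintained for one
year = 0.081 QALY); no discounting is applied at a one-year horizon.  An
area-under-curve alternative is available via ``auc=True`` on the LOCF
estimator but is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from masld_cua.mapping import UtilitySeries


@dataclass(frozen=True)
class QalyEstimate:
    """A QALY-gain point estimate with its 95% confidence interval."""

    method: str  # "locf" or "lmm"
    gain: float
    ci_low: float
    ci_high: float
    n_patients: int
    follow_up_months: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.gain <= self.ci_high):
            raise ValueError(
                f"inconsistent estimate: ci_low={self.ci_low} gain={self.gain} "
                f"ci_high={self.ci_high}"
            )


def estimate_gain_locf(
    series: Sequence[UtilitySeries], level: float = 0.95, auc: bool = False
) -> QalyEstimate:
    """First-versus-last utility contrast, averaged over patients.

    Patients with fewer than two visits carry no contrast and are dropped
    with a warning.  With ``auc=True`` the per-patient quantity is instead
    the trapezoidal mean utility over follow-up minus the baseline
    utility (area-under-curve operationalization).
    """
    deltas = []
    dropped = []
    horizons = []
    for s in series:
        if len(s) < 2:
            dropped.append(s.patient_id)
            continue
        if auc:
            mean_u = np.trapezoid(s.utilities, s.months) / (s.months[-1] - s.months[0])
            deltas.append(mean_u - s.utilities[0])
        else:
            deltas.append(s.utilities[-1] - s.utilities[0])
        horizons.append(s.months[-1] - s.months[0])
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} patient(s) with <2 visits: {dropped}",
            stacklevel=2,
        )
    if not deltas:
        raise ValueError("no patient has two or more visits; LOCF undefined")

    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    gain = float(deltas.mean())
    sd = float(deltas.std(ddof=1)) if n > 1 else 0.0
    if n == 1 or sd == 0.0:
        lo = hi = gain
    else:
        half = stats.t.ppf((1 + level) / 2, df=n - 1) * sd / np.sqrt(n)
        lo, hi = gain - half, gain + half
    return QalyEstimate(
        method="locf",
        gain=gain,
        ci_low=float(lo),
        ci_high=float(hi),
        n_patients=n,
        follow_up_months=float(max(horizons)),
    )


def _series_to_long(series: Sequence[UtilitySeries]) -> pd.DataFrame:
    rows = [
        {"patient_id": s.patient_id, "month": m, "utility": u}
        for s in sorted(series, key=lambda s: s.patient_id)
        for m, u in zip(s.months, s.utilities)
    ]
    return pd.DataFrame(rows)


def estimate_gain_lmm(
    series: Sequence[UtilitySeries],
    horizon_months: float | None = None,
    level: float = 0.95,
) -> QalyEstimate:
    """Random-intercept mixed-model slope, scaled by the follow-up horizon.

    Fits ``utility ~ 1 + month`` with a per-patient random intercept by
    REML; the gain is the fixed month slope times ``horizon_months``
    (default: the latest observed month), with a Wald confidence interval
    scaled the same way.

    If the mixed model is unidentifiable (no residual or between-patient
    variance, e.g. noise-free data) or fails to converge, the estimator
    falls back to pooled ordinary least squares with a warning.
    """
    long = _series_to_long(series)
    if long["patient_id"].nunique() < 2:
        raise ValueError("mixed model needs at least two patients")
    if long["month"].nunique() < 2:
        raise ValueError("mixed model needs at least two distinct months")
    if horizon_months is None:
        horizon_months = float(long["month"].max())

    slope, se, n = _fit_slope(long, response="utility", time="month")
    gain = slope * horizon_months
    z = stats.norm.ppf((1 + level) / 2)
    half = z * se * horizon_months
    return QalyEstimate(
        method="lmm",
        gain=float(gain),
        ci_low=float(gain - half),
        ci_high=float(gain + half),
        n_patients=n,
        follow_up_months=float(horizon_months),
    )


def _fit_slope(long: pd.DataFrame, response: str, time: str) -> tuple[float, float, int]:
    """Fixed linear-time slope and its SE from a random-intercept LMM.

    Shared by the utility and expenditure trend models.  Degenerate data
    (an exact linear fit, zero variance) and convergence failures fall
    back to pooled OLS.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n_patients = long["patient_id"].nunique()

    # Perfectly linear pooled data has no estimable variance components;
    # the OLS fit is then exact and its zero SE is the honest answer.
    x = sm.add_constant(long[time].to_numpy(dtype=float))
    y = long[response].to_numpy(dtype=float)
    ols = sm.OLS(y, x).fit()
    if float(ols.mse_resid) < 1e-16:
        return float(ols.params[1]), 0.0, n_patients

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                f"{response} ~ {time}", data=long, groups=long["patient_id"]
            )
            fit = model.fit(reml=True)
        slope = float(fit.fe_params[time])
        se = float(fit.bse_fe[time])
        if not np.isfinite(slope) or not np.isfinite(se):
            raise ValueError("non-finite mixed-model estimates")
        return slope, se, n_patients
    except Exception as exc:  # singular fit, convergence failure
        warnings.warn(
            f"mixed model failed ({exc}); falling back to pooled OLS",
            stacklevel=3,
        )
        return float(ols.params[1]), float(ols.bse[1]), n_patients
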