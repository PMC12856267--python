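"""Pre/post clinical-marker statistics.

Covers the within-patient analyses of a single-arm lifestyle study:

- normality-gated paired tests on continuous markers (blood pressure,
  aminotransferases): Shapiro-Wilk on the paired deltas decides between
  the paired t-test and the Wilcoxon signed-rank test;
- ordinal analysis of the ultrasound steatosis grade (0-6 scale) by the
  Wilcoxon signed-rank test with median (IQR) descriptives;
- Wilson score intervals for binary outcomes (maintained physical
  activity);
- simulation-based post-hoc power for the Wilcoxon signed-rank test by
  nonparametric bootstrap of the observed deltas, with a power-vs-n
  curve.

Conventions: zero paired differences are dropped before signed-ranking
(classic Wilcoxon; Pratt's method is available via ``zero_method``), the
exact null distribution is used for up to 25 non-zero pairs and the
normal approximation with continuity correction above that, and all tests
are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

#: Largest number of non-zero pairs for which the exact Wilcoxon null
#: distribution is enumerated; beyond this the normal approximation with
#: continuity correction is used.
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedSample:
    """One patient's pre/post marker values in native units."""

    patient_id: str
    pre: float
    post: float

    @property
    def delta(self) -> float:
        return self.post - self.pre


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of a normality-gated paired comparison."""

    test_used: str  # "paired_t" or "wilcoxon"
    mean_delta: float
    median_delta: float
    statistic: float
    p_value: float
    n: int
    normality_p: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _as_arrays(pre, post) -> tuple[np.ndarray, np.ndarray]:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    ok = ~(np.isnan(pre) | np.isnan(post))
    return pre[ok], post[ok]


def signed_rank_exact_p(deltas: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p-value, valid under tied magnitudes.

    Conditions on the observed absolute deltas: zeros are dropped,
    magnitudes receive midranks, and the null distribution of the
    positive-rank sum W+ over all 2^n equiprobable sign patterns is built
    by subset-sum dynamic programming (midranks doubled to integers), so
    the result equals full sign-pattern enumeration.  Returns (W+, p).
    """
    d = deltas[deltas != 0]
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(np.int64)  # midranks are multiples of 1/2
    w2_obs = int(r2[d > 0].sum())
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:-r]
    counts /= counts.sum()
    cdf = counts[: w2_obs + 1].sum()
    sf = counts[w2_obs:].sum()
    return w2_obs / 2.0, float(min(1.0, 2 * min(cdf, sf)))


def _wilcoxon(deltas: np.ndarray, zero_method: str = "wilcox"):
    """Two-sided signed-rank test: exact for small n, corrected normal above.

    The exact branch uses :func:`signed_rank_exact_p`, which stays exact
    in the presence of tied magnitudes (relevant for ordinal grades); the
    large-sample branch is the tie-corrected normal approximation with
    continuity correction.  ``zero_method="wilcox"`` drops zero
    differences before ranking; ``"pratt"`` ranks them (large-sample
    branch only).
    """
    from types import SimpleNamespace

    nonzero = np.count_nonzero(deltas)
    if nonzero <= WILCOXON_EXACT_MAX_N and zero_method == "wilcox":
        statistic, p = signed_rank_exact_p(deltas)
        return SimpleNamespace(statistic=statistic, pvalue=p)
    return stats.wilcoxon(
        deltas,
        zero_method=zero_method,
        alternative="two-sided",
        correction=True,
        method="approx",
    )


def paired_test(
    pre,
    post,
    alpha_normality: float = 0.05,
    zero_method: str = "wilcox",
) -> PairedTestResult:
    """Paired t-test or Wilcoxon signed-rank, gated by Shapiro-Wilk.

    The Shapiro-Wilk test is run on the paired deltas; when its p-value
    is at least ``alpha_normality`` the paired t-test is used, otherwise
    the Wilcoxon signed-rank test.  All-zero deltas (post identical to
    pre) make both tests degenerate; the result is then reported on the
    Wilcoxon path with p = 1 and ``degenerate=True``.
    """
    pre, post = _as_arrays(pre, post)
    n = pre.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    deltas = post - pre

    if np.ptp(deltas) == 0.0 and deltas[0] == 0.0:
        return PairedTestResult(
            test_used="wilcoxon",
            mean_delta=0.0,
            median_delta=0.0,
            statistic=0.0,
            p_value=1.0,
            n=n,
            normality_p=1.0,
            degenerate=True,
        )

    if np.ptp(deltas) == 0.0:
        # constant non-zero shift: Shapiro is undefined, the t-test has
        # zero variance; the signed-rank test handles it exactly
        normality_p = 0.0
    else:
        normality_p = float(stats.shapiro(deltas).pvalue)

    if normality_p >= alpha_normality:
        res = stats.ttest_rel(post, pre)
        test_used = "paired_t"
    else:
        res = _wilcoxon(deltas, zero_method=zero_method)
        test_used = "wilcoxon"

    return PairedTestResult(
        test_used=test_used,
        mean_delta=float(deltas.mean()),
        median_delta=float(np.median(deltas)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        normality_p=normality_p,
    )


@dataclass(frozen=True)
class OrdinalTestResult:
    """Wilcoxon signed-rank on ordinal grades plus arm descriptives."""

    statistic: float
    p_value: float
    n: int
    median_delta: float
    pre_median: float
    pre_iqr: tuple[float, float]
    post_median: float
    post_iqr: tuple[float, float]
    all_ties: bool = False


def ordinal_wilcoxon(
    pre, post, zero_method: str = "wilcox"
) -> OrdinalTestResult:
    """Wilcoxon signed-rank on paired ordinal steatosis grades (0-6).

    Zero differences are dropped before ranking (``zero_method="wilcox"``;
    pass ``"pratt"`` to rank them).  Medians and interquartile ranges of
    both arms are reported alongside the test, matching how ordinal
    ultrasound grades are conventionally summarized.
    """
    pre, post = _as_arrays(pre, post)
    if pre.size == 0:
        raise ValueError("no complete pairs")
    for arr, name in ((pre, "pre"), (post, "post")):
        if not np.all((arr == np.round(arr)) & (arr >= 0) & (arr <= 6)):
            raise ValueError(f"{name} grades must be integers in 0..6")

    deltas = post - pre
    descr = dict(
        pre_median=float(np.median(pre)),
        pre_iqr=(float(np.percentile(pre, 25)), float(np.percentile(pre, 75))),
        post_median=float(np.median(post)),
        post_iqr=(float(np.percentile(post, 25)), float(np.percentile(post, 75))),
    )
    if np.all(deltas == 0):
        return OrdinalTestResult(
            statistic=0.0,
            p_value=1.0,
            n=int(pre.size),
            median_delta=0.0,
            all_ties=True,
            **descr,
        )
    res = _wilcoxon(deltas, zero_method=zero_method)
    return OrdinalTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(pre.size),
        median_delta=float(np.median(deltas)),
        **descr,
    )


@dataclass(frozen=True)
class ProportionCI:
    """Wilson score interval for a binomial proportion."""

    k: int
    n: int
    point: float
    low: float
    high: float
    level: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.point <= self.high <= 1.0:
            raise ValueError(
                f"interval ordering violated: {self.low}, {self.point}, {self.high}"
            )


def wilson_interval(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Wilson score confidence interval for k successes in n trials."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    low, high = proportion_confint(k, n, alpha=1 - level, method="wilson")
    point = k / n
    # guard floating-point spill at the k=0 / k=n boundaries
    low = min(max(float(low), 0.0), point)
    high = max(min(float(high), 1.0), point)
    return ProportionCI(k=k, n=n, point=point, low=low, high=high, level=level)


@dataclass(frozen=True)
class PowerResult:
    """Simulation-based power of the Wilcoxon signed-rank test."""

    power: float
    alpha: float
    n: int
    n_sims: int
    scheme: str
    curve: tuple[tuple[int, float], ...] = ()


def posthoc_power_wilcoxon(
    deltas,
    alpha: float = 0.05,
    n_sims: int = 2_000,
    seed: int | None = None,
    n_grid: Sequence[int] | None = None,
) -> PowerResult:
    """Post-hoc power by nonparametric bootstrap of observed deltas.

    Each simulation resamples ``n`` deltas with replacement from the
    observed delta distribution and runs a two-sided Wilcoxon signed-rank
    test at ``alpha``; power is the rejection fraction.  When ``n_grid``
    is given, a power-vs-sample-size curve over those n values is also
    computed from the same resampling scheme.

    Post-hoc power computed from the observed effect is a descriptive
    companion to a non-significant result, not an inferential quantity;
    interpret accordingly.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 1 or deltas.size < 2:
        raise ValueError("deltas must be a 1-D array with at least 2 values")
    if np.all(deltas == 0):
        raise ValueError("all observed deltas are zero; power undefined")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    rng = np.random.default_rng(seed)

    def rejection_rate(n: int) -> float:
        hits = 0
        for _ in range(n_sims):
            sample = rng.choice(deltas, size=n, replace=True)
            if np.all(sample == 0):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = _wilcoxon(sample).pvalue
            if p < alpha:
                hits += 1
        return hits / n_sims

    n = deltas.size
    power = rejection_rate(n)
    curve = tuple(
        (int(m), rejection_rate(int(m))) for m in (n_grid or ())
    )
    return PowerResult(
        power=power,
        alpha=alpha,
        n=n,
        n_sims=n_sims,
        scheme="nonparametric bootstrap of observed deltas",
        curve=curve,
    )


def summarize_markers(
    prepost: "pd.DataFrame", alpha_normality: float = 0.05
) -> "pd.DataFrame":
    """Per-marker paired-test table from a long pre/post frame.

    Expects columns ``patient_id``, ``marker``, ``pre``, ``post``;
    returns one row per marker with means, SDs, delta, the test that
    fired and its p-value - the layout of a clinical pre/post results
    table.
    """
    import pandas as pd

    rows = []
    for marker, grp in prepost.groupby("marker", sort=True):
        res = paired_test(grp["pre"], grp["post"], alpha_normality=alpha_normality)
        rows.append(
            {
                "marker": marker,
                "n": res.n,
                "pre_mean": float(grp["pre"].mean()),
                "pre_sd": float(grp["pre"].std(ddof=1)),
                "post_mean": float(grp["post"].mean()),
                "post_sd": float(grp["post"].std(ddof=1)),
                "mean_delta": res.mean_delta,
                "test": res.test_used,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
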