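"""OWSA tornado entries, moment matching, copula PSA, CEAC and CE plane."""

import math

import numpy as np
import pytest
from scipy import stats

from masld_cua.economics import EconomicInputs, ThresholdSet
from masld_cua.sensitivity import (
    OwsaRange,
    PSAConfig,
    ce_plane_points,
    moment_match_gamma,
    moment_match_lognormal,
    run_owsa,
    sample_psa,
    summarize_psa,
)

BASE = EconomicInputs(c1=1440.0, e1=0.081)
RANGES = [OwsaRange("qaly_gain", 0.01, 0.161), OwsaRange("cost", 1152.0, 1728.0)]


class TestOwsa:
    def test_published_swings_and_nmb_deltas(self):
        """The qaly and cost ranges reproduce the four printed tornado
        figures: ICER swings ~135,056 and ~7,111 EUR/QALY, and NMB deltas
        at 30k of -2,130/+2,400 (qaly) and -/+288 (cost)."""
        entries = run_owsa(BASE, RANGES)
        qaly, cost = entries[0], entries[1]  # sorted by descending swing
        assert qaly.parameter == "qaly_gain"
        assert qaly.icer_swing == pytest.approx(135_055.9, abs=0.5)
        assert cost.icer_swing == pytest.approx(7_111.11, abs=0.01)
        assert qaly.delta_nmb_low[30_000.0] == pytest.approx(-2_130.0)
        assert qaly.delta_nmb_high[30_000.0] == pytest.approx(2_400.0)
        assert cost.delta_nmb_low[30_000.0] == pytest.approx(288.0)
        assert cost.delta_nmb_high[30_000.0] == pytest.approx(-288.0)

    def test_swing_vanishes_for_degenerate_range(self):
        entries = run_owsa(BASE, [OwsaRange("cost", 1440.0 - 1e-9, 1440.0 + 1e-9)])
        assert entries[0].icer_swing == pytest.approx(0.0, abs=1e-6)

    def test_range_crossing_zero_effect_flagged_undefined(self):
        entries = run_owsa(BASE, [OwsaRange("qaly_gain", -0.05, 0.161)])
        assert "low" in entries[0].undefined_at
        assert math.isnan(entries[0].icer_at_low)

    def test_requires_positive_base_effect(self):
        with pytest.raises(ValueError, match="positive"):
            run_owsa(EconomicInputs(c1=100.0, e1=0.0), RANGES)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            OwsaRange("cost", 10.0, 10.0)


class TestMomentMatching:
    def test_lognormal_closed_form(self):
        mu, sigma = moment_match_lognormal(0.081, 0.040816)
        assert mu == pytest.approx(-2.6264, abs=5e-4)
        assert sigma == pytest.approx(0.4756, abs=5e-4)

    def test_lognormal_degenerate_sd(self):
        mu, sigma = moment_match_lognormal(0.5, 0.0)
        assert (mu, sigma) == (math.log(0.5), 0.0)

    def test_gamma_closed_form(self):
        shape, scale = moment_match_gamma(1440.0, 288.0)
        assert (shape, scale) == (pytest.approx(25.0), pytest.approx(57.6))
        assert shape * scale == pytest.approx(1440.0)

    @pytest.mark.parametrize("mean,sd", [(0.081, 0.0408), (3.0, 1.5)])
    def test_lognormal_moments_recovered_in_sampling(self, mean, sd):
        mu, sigma = moment_match_lognormal(mean, sd)
        x = np.random.default_rng(0).lognormal(mu, sigma, size=1_000_000)
        se = sd / 1000
        assert abs(x.mean() - mean) < 4 * se

    def test_gamma_sd_recovered_in_sampling(self):
        shape, scale = moment_match_gamma(1440.0, 288.0)
        x = np.random.default_rng(1).gamma(shape, scale, size=1_000_000)
        assert abs(x.std(ddof=1) - 288.0) < 4 * 288.0 / 1000

    @pytest.mark.parametrize("fn", [moment_match_lognormal, moment_match_gamma])
    def test_nonpositive_mean_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(-1.0, 1.0)


class TestSamplePsa:
    def test_seeded_determinism(self):
        a = sample_psa(PSAConfig(n_sims=500, seed=3))
        b = sample_psa(PSAConfig(n_sims=500, seed=3))
        assert np.array_equal(a.qaly, b.qaly) and np.array_equal(a.cost, b.cost)

    def test_zero_rho_margins_uncorrelated(self):
        draws = sample_psa(PSAConfig(n_sims=1_000_000, rho=0.0, seed=4))
        r = np.corrcoef(draws.qaly, draws.cost)[0, 1]
        assert abs(r) < 0.01

    def test_copula_preserves_marginals(self):
        """KS distance between each sampled margin and its moment-matched
        target stays below 0.01 at n = 1e5 despite the correlation."""
        config = PSAConfig(n_sims=100_000, seed=5, qaly_exclusion_floor=0.0)
        draws = sample_psa(config)
        mu = math.log(config.qaly_mean) - math.log1p((config.qaly_sd / config.qaly_mean) ** 2) / 2
        sigma = math.sqrt(math.log1p((config.qaly_sd / config.qaly_mean) ** 2))
        ks_q = stats.kstest(draws.qaly, "lognorm", args=(sigma, 0, math.exp(mu))).statistic
        shape = (config.cost_mean / config.cost_sd) ** 2
        scale = config.cost_sd**2 / config.cost_mean
        ks_c = stats.kstest(draws.cost, "gamma", args=(shape, 0, scale)).statistic
        assert ks_q < 0.01 and ks_c < 0.01

    def test_floor_exclusion_counted(self):
        config = PSAConfig(n_sims=20_000, qaly_exclusion_floor=0.05, seed=6)
        draws = sample_psa(config)
        assert draws.qaly.min() >= 0.05
        assert len(draws) + draws.n_excluded == 20_000
        assert draws.n_excluded > 0

    def test_floor_above_all_draws_raises(self):
        with pytest.raises(ValueError, match="below the QALY floor"):
            sample_psa(PSAConfig(n_sims=100, qaly_exclusion_floor=10.0, seed=7))

    def test_floor_removes_negligible_mass_at_defaults(self):
        draws = sample_psa(PSAConfig(n_sims=200_000, seed=8))
        assert abs(draws.qaly.mean() - 0.081) / 0.081 < 0.005


class TestSummaries:
    def test_degenerate_draws_all_percentiles_equal(self):
        config = PSAConfig(n_sims=100, qaly_sd=0.0, cost_cv=0.0, seed=9)
        draws = sample_psa(config)
        summary = summarize_psa(draws)
        expected = 1440.0 / 0.081
        for key in ("min", "p25", "median", "p75", "max"):
            assert summary.icer[key] == pytest.approx(expected)
        probs = [p for _, p in summary.ceac]
        # step CEAC: zero below the common ICER, one above
        assert set(probs) <= {0.0, 1.0}

    def test_ceac_monotone_nondecreasing(self):
        draws = sample_psa(PSAConfig(n_sims=10_000, seed=10))
        probs = [p for _, p in summarize_psa(draws).ceac]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_prob_positive_equals_one_minus_icer_cdf(self):
        """For positive-quadrant draws, Pr(NMB>0 at wtp) is the share of
        draws whose per-draw ICER is below wtp."""
        draws = sample_psa(PSAConfig(n_sims=10_000, seed=11))
        summary = summarize_psa(draws)
        icer = draws.cost / draws.qaly
        for w, entry in summary.nmb.items():
            assert entry["prob_positive"] == pytest.approx((icer < w).mean())

    def test_ce_plane_counts_sum_and_match_ceac(self):
        draws = sample_psa(PSAConfig(n_sims=10_000, seed=12))
        plane = ce_plane_points(draws)
        assert sum(plane.quadrants.values()) == len(draws)
        assert plane.quadrants["NE"] == len(draws)  # both margins positive
        summary = summarize_psa(draws)
        for w, count in plane.below_or_on_ray.items():
            # continuous draws: ties on the ray have probability zero
            assert count / len(draws) == pytest.approx(summary.nmb[w]["prob_positive"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PSAConfig(rho=1.0)
        with pytest.raises(ValueError):
            PSAConfig(n_sims=0)
        with pytest.raises(ValueError):
            PSAConfig(qaly_mean=-0.1)
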