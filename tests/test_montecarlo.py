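"""Monte Carlo layer: distribution fitting, sampling, propagation,
percentile summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from eggrisk import (
    ConfigError,
    DistributionSpec,
    MCConfig,
    MCResult,
    SurveySummary,
    ValidationError,
    build_distribution,
    compute_ilcr,
    compute_thq,
    draw_samples,
    run_mcs,
    summarize_mcs,
)
from eggrisk.defaults import DEFAULT_EXPOSURE, TOX_PROFILES

AS, HG = TOX_PROFILES["As"], TOX_PROFILES["Hg"]


def _result(draws, percentiles=(50.0, 95.0)):
    draws = np.asarray(draws, dtype=float)
    cfg = MCConfig(n_iterations=len(draws), seed=0, percentiles=percentiles)
    return MCResult(
        metric="THQ",
        metal="As",
        draws=draws,
        mean=float(draws.mean()),
        percentile_table={},
        config=cfg,
        conc_spec=DistributionSpec("point", {"value": 1.0}),
    )


class TestBuildDistribution:
    def test_lognormal_moment_matching_closed_form(self):
        spec = build_distribution(1.0, sd=0.5, family="lognormal")
        assert spec.params["sigma"] ** 2 == pytest.approx(math.log(1.25), rel=1e-12)
        assert spec.params["mu"] == pytest.approx(-math.log(1.25) / 2, rel=1e-12)

    def test_zero_spread_downgrades_to_point(self):
        spec = build_distribution(0.10, sd=0.0, family="lognormal")
        assert spec.family == "point"
        assert spec.params["value"] == 0.10

    def test_survey_summary_mean_is_recovered(self):
        """Winter-arsenic-like summary (mean 0.52, se 0.050, n 42): the
        moment-matched lognormal's analytic mean returns 0.52 exactly."""
        summ = SurveySummary("As", "winter", 42, 0.1, 1.5, 0.52, 0.050)
        spec = build_distribution(summ, family="lognormal")
        assert spec.family == "lognormal"
        assert spec.analytic_mean == pytest.approx(0.52, rel=1e-12)

    def test_nonpositive_mean_rejected_for_lognormal(self):
        with pytest.raises(ValidationError):
            build_distribution(0.0, sd=0.1, family="lognormal")

    @pytest.mark.parametrize("family", ["normal", "uniform", "triangular"])
    def test_other_families_match_first_two_moments(self, family):
        spec = build_distribution(2.0, sd=0.3, family=family)
        assert spec.analytic_mean == pytest.approx(2.0, rel=1e-12)
        draws = draw_samples(
            DistributionSpec(spec.family, dict(spec.params), lower=None),
            MCConfig(n_iterations=40_000, seed=1),
        )
        assert draws.std(ddof=1) == pytest.approx(0.3, rel=0.05)


class TestDrawSamples:
    def test_point_mass_is_exact(self):
        spec = DistributionSpec("point", {"value": 0.79})
        draws = draw_samples(spec, MCConfig(n_iterations=10_000, seed=3))
        assert draws.shape == (10_000,)
        assert np.all(draws == 0.79)

    def test_same_seed_bit_identical(self):
        spec = build_distribution(0.79, sd=0.5)
        a = draw_samples(spec, MCConfig(seed=42))
        b = draw_samples(spec, MCConfig(seed=42))
        assert np.array_equal(a, b)
        c = draw_samples(spec, MCConfig(seed=43))
        assert not np.array_equal(a, c)

    def test_lognormal_mean_within_three_standard_errors(self):
        spec = build_distribution(0.79, sd=0.5)
        draws = draw_samples(spec, MCConfig(n_iterations=10_000, seed=0))
        se = 0.5 / math.sqrt(10_000)
        assert abs(draws.mean() - 0.79) < 3 * se

    def test_truncation_enforced(self):
        spec = DistributionSpec("normal", {"mean": 0.1, "sd": 1.0}, lower=0.0)
        draws = draw_samples(spec, MCConfig(n_iterations=5_000, seed=1))
        assert draws.min() >= 0.0

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("normal", {"mean": 0, "sd": 1}, lower=1.0, upper=0.0)

    def test_vanishing_acceptance_region_errors(self):
        spec = DistributionSpec(
            "normal", {"mean": 0.0, "sd": 1e-6}, lower=5.0, upper=6.0
        )
        with pytest.raises(ConfigError):
            draw_samples(spec, MCConfig(n_iterations=100, seed=0))


class TestRunMCS:
    def test_point_mass_degenerates_to_deterministic_thq(self):
        spec = DistributionSpec("point", {"value": 0.26})
        res = run_mcs(spec, DEFAULT_EXPOSURE, HG, MCConfig(n_iterations=10_000, seed=0))
        det = compute_thq(0.26, DEFAULT_EXPOSURE, HG)
        assert np.all(res.draws == det)
        assert res.mean == det
        assert all(v == det for v in res.percentile_table.values())

    def test_point_mass_ilcr_matches_deterministic_engine(self):
        spec = DistributionSpec("point", {"value": 0.79})
        res = run_mcs(
            spec, DEFAULT_EXPOSURE, AS, MCConfig(n_iterations=10_000, seed=0),
            metric="ILCR",
        )
        det = compute_ilcr(25.4 * 0.79 / 70, AS)
        assert np.all(res.draws == det)
        assert det == pytest.approx(4.30e-4, abs=0.005e-4)

    def test_ilcr_without_csf_is_config_error(self):
        spec = DistributionSpec("point", {"value": 0.1})
        with pytest.raises(ConfigError, match="CSF"):
            run_mcs(spec, DEFAULT_EXPOSURE, HG, MCConfig(seed=0), metric="ILCR")

    def test_seeded_runs_bit_reproducible(self):
        spec = build_distribution(0.79, sd=0.5)
        cfg = MCConfig(n_iterations=10_000, seed=17)
        a = run_mcs(spec, DEFAULT_EXPOSURE, AS, cfg)
        b = run_mcs(spec, DEFAULT_EXPOSURE, AS, cfg)
        assert np.array_equal(a.draws, b.draws)
        assert a.percentile_table == b.percentile_table

    def test_p95_matches_closed_form_lognormal_quantile(self):
        """THQ is linear in the concentration, so its 95th percentile must
        match k times the closed-form lognormal quantile, within three
        Monte Carlo standard errors of the order statistic."""
        n = 10_000
        spec = build_distribution(0.79, sd=0.5)
        res = run_mcs(spec, DEFAULT_EXPOSURE, AS, MCConfig(n_iterations=n, seed=2))
        k = compute_thq(1.0, DEFAULT_EXPOSURE, AS)  # THQ per unit µg/kg
        mu, sigma = spec.params["mu"], spec.params["sigma"]
        dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        q95 = dist.ppf(0.95)
        se_q = math.sqrt(0.95 * 0.05 / n) / dist.pdf(q95)
        assert abs(res.percentile_table[95.0] - k * q95) < 3 * k * se_q

    def test_stochastically_larger_input_raises_percentiles(self):
        lo = DistributionSpec("uniform", {"low": 0.2, "high": 0.8})
        hi = DistributionSpec("uniform", {"low": 0.3, "high": 0.9})  # +0.1 shift
        cfg = MCConfig(n_iterations=5_000, seed=6)
        r_lo = run_mcs(lo, DEFAULT_EXPOSURE, AS, cfg)
        r_hi = run_mcs(hi, DEFAULT_EXPOSURE, AS, cfg)
        for p in cfg.percentiles:
            assert r_hi.percentile_table[p] > r_lo.percentile_table[p]

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError):
            run_mcs(
                DistributionSpec("point", {"value": 1.0}),
                DEFAULT_EXPOSURE, AS, MCConfig(seed=0), metric="HQ",
            )


class TestSummarizeMCS:
    def test_interpolated_rank_oracle(self):
        """Rank 1 + 99 x 0.95 = 95.05 under linear order-statistic
        interpolation of the draws 1..100."""
        row = summarize_mcs(_result(np.arange(1, 101), percentiles=(95.0,)))
        assert row["p95"] == pytest.approx(95.05)

    def test_median_interpolation(self):
        row = summarize_mcs(_result([1, 2, 3, 4], percentiles=(50.0,)))
        assert row["p50"] == pytest.approx(2.5)

    def test_constant_draws(self):
        row = summarize_mcs(_result([0.3] * 50, percentiles=(5.0, 95.0)))
        assert row["p5"] == row["p95"] == pytest.approx(0.3)

    def test_percentiles_nondecreasing_and_curve_valid(self):
        spec = build_distribution(0.5, sd=0.2)
        res = run_mcs(
            spec, DEFAULT_EXPOSURE, AS,
            MCConfig(n_iterations=2_000, seed=8, percentiles=(5, 25, 50, 75, 95)),
        )
        levels = sorted(res.percentile_table)
        vals = [res.percentile_table[p] for p in levels]
        assert vals == sorted(vals)
        curve = res.cumulative_curve
        assert np.all(np.diff(curve[:, 1]) >= 0)
        assert curve[0, 1] > 0 and curve[-1, 1] == pytest.approx(1.0)


def test_plot_cumulative_curve_writes_file(tmp_path):
    spec = build_distribution(0.5, sd=0.2)
    res = run_mcs(spec, DEFAULT_EXPOSURE, AS, MCConfig(n_iterations=500, seed=0))
    out = tmp_path / "curve.png"
    from eggrisk import plot_cumulative_curve

    plot_cumulative_curve(res, out)
    assert out.stat().st_size > 0
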