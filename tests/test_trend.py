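"""Errors-in-variables trend models: responses, splines, TP transform, fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from isocod.splines import build_spline_basis
from isocod.synthetic import SynthConfig, generate_assemblage
from isocod.trend import (
    OFFSET_PROXIES,
    TrendConfig,
    compute_response,
    compute_responses,
    fit_linear_eiv,
    fit_trend_gam,
    predict_trend,
    refine_dating,
    sensitivity_over_time_imputations,
    tp_transform,
)


class TestComputeResponse:
    def test_difference_with_quadrature_sd(self):
        record = {
            "d15N_Glx": 15.0, "d15N_Glx_sd": 0.3,
            "d15N_Phe": 5.0, "d15N_Phe_sd": 0.4,
        }
        value, sd = compute_response(record, "D15N_Glx_Phe")
        assert value == pytest.approx(10.0)
        assert sd == pytest.approx(0.5)

    def test_equal_constituents_give_zero(self):
        record = {"d15N_Glx": 7.7, "d15N_Phe": 7.7}
        value, _ = compute_response(record, "D15N_Glx_Phe")
        assert value == 0.0

    def test_single_aa_passthrough(self):
        record = {"d15N_Phe": 6.1, "d15N_Phe_sd": 0.2}
        value, sd = compute_response(record, "d15N_Phe")
        assert (value, sd) == (6.1, 0.2)

    def test_missing_constituent_skipped_with_reason(self):
        df = pd.DataFrame(
            {"d15N_Glx": [15.0, 14.0], "d15N_Phe": [5.0, np.nan]}
        )
        out = compute_responses(df, "D15N_Glx_Phe")
        assert list(out.index) == [0]

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError, match="response"):
            TrendConfig(response="d15N_Martian")


class TestSplineBasis:
    def test_partition_of_unity(self):
        t = np.linspace(500, 2000, 40)
        B, _, _ = build_spline_basis(t, k=10)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_second_order_penalty_annihilates_lines(self):
        t = np.linspace(0, 1, 20)
        _, S, _ = build_spline_basis(t, k=8, penalty_order=2)
        line = 2.0 + 3.0 * np.arange(8)
        assert line @ S @ line == pytest.approx(0.0, abs=1e-10)
        eigs = np.linalg.eigvalsh(S)
        assert (eigs > -1e-10).all()
        assert (np.abs(eigs) < 1e-10).sum() == 2  # null space dim = order

    def test_penalty_quadratic_form_matches_difference_oracle(self, rng):
        _, S, _ = build_spline_basis(np.linspace(0, 10, 30), k=12, penalty_order=2)
        for _ in range(10):
            b = rng.normal(size=12)
            assert b @ S @ b == pytest.approx(
                float(np.sum(np.diff(b, 2) ** 2)), abs=1e-10
            )

    def test_degenerate_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            build_spline_basis(np.full(10, 1500.0), k=8)

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            build_spline_basis(np.linspace(0, 1, 10), k=3)


class TestTPTransform:
    def test_offset_identity(self):
        for tef in (3.0, 6.6, 12.0):
            tp = tp_transform(np.array([2.9]), tef_draws=[tef])
            assert tp[0] == pytest.approx(1.0)

    def test_one_level_enrichment(self):
        tp = tp_transform(np.array([9.5]), tef_draws=[6.6])
        assert tp[0] == pytest.approx(2.0)

    def test_monte_carlo_mean_matches_numerical_integration(self):
        """E[(Y-2.9)/TEF] + 1 under the truncated-normal TEF prior.

        E[1/TEF] has a mild logarithmic divergence at zero enrichment, so
        the expectation is compared conditionally on TEF >= 0.1 per mil —
        a region containing all but ~1e-5 of the prior mass, which the
        Monte-Carlo draws satisfy with near certainty.
        """
        y, n, floor = 12.0, 100_000, 0.1
        draws = tp_transform(np.full(n, y), rng=np.random.default_rng(8))
        a = -6.6 / 1.7
        trunc = stats.truncnorm(a, np.inf, loc=6.6, scale=1.7)
        mass = 1.0 - trunc.cdf(floor)
        expected = integrate.quad(
            lambda tef: (y - 2.9) / tef * trunc.pdf(tef), floor, np.inf, limit=200
        )[0] / mass + 1.0
        mcse = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * mcse

    def test_monotone_in_y_and_tef(self):
        y = np.array([5.0, 6.0, 7.0])
        tp = tp_transform(y, tef_draws=[6.6, 6.6, 6.6])
        assert (np.diff(tp) > 0).all()
        hi = tp_transform(np.array([12.0]), tef_draws=[5.0])
        lo = tp_transform(np.array([12.0]), tef_draws=[8.0])
        assert hi[0] > lo[0]

    def test_pure_source_response_refused(self):
        with pytest.raises(ValueError, match="offset proxy"):
            tp_transform(np.array([5.0]), response="d15N_Phe")

    def test_offset_proxies_accepted(self):
        for name in OFFSET_PROXIES:
            tp_transform(np.array([5.0]), response=name, tef_draws=[6.6])

    def test_nonpositive_tef_draws_rejected(self):
        with pytest.raises(ValueError):
            tp_transform(np.array([5.0]), tef_draws=[-1.0])


@pytest.fixture(scope="module")
def linear_fit():
    """One shared linear EIV fit on a linear-trend assemblage."""
    config = SynthConfig(
        n_specimens=120, trend=("linear", {"slope": 0.01, "level": 19.4}), seed=23
    )
    records, truth = generate_assemblage(config)
    tcfg = TrendConfig(
        seed=23, chains=2, walkers=16, warmup=300, steps=300, n_draws=800,
        rhat_threshold=1.05, ess_threshold=100.0,
    )
    return records, truth, fit_linear_eiv(records, tcfg)


class TestLinearEIV:
    def test_latent_times_respect_windows(self, linear_fit):
        records, _, fit = linear_fit
        t = fit.posterior["t"]
        t0 = fit.data.t0[None, :]
        t1 = fit.data.t1[None, :]
        assert (t >= t0 - 1e-6).all() and (t <= t1 + 1e-6).all()

    def test_sigma_draws_positive(self, linear_fit):
        _, _, fit = linear_fit
        assert (fit.posterior["sigma"] > 0).all()

    def test_slope_recovers_truth(self, linear_fit):
        _, _, fit = linear_fit
        b0 = fit.posterior["beta0"]
        lo, hi = np.quantile(b0, [0.025, 0.975])
        assert lo < 0.01 < hi

    def test_same_seed_identical_draws(self, linear_fit):
        records, _, fit = linear_fit
        tcfg = TrendConfig(
            seed=23, chains=2, walkers=16, warmup=300, steps=300, n_draws=800,
            rhat_threshold=1.05, ess_threshold=100.0,
        )
        refit = fit_linear_eiv(records, tcfg)
        pd.testing.assert_frame_equal(fit.draws_dataframe(), refit.draws_dataframe())

    def test_degenerate_windows_match_fixed_t_oracle(self):
        """With zero-width windows the latent t is a point mass and the slope
        posterior agrees with a known-time regression."""
        config = SynthConfig(
            n_specimens=120, window_half_width=0.0,
            trend=("linear", {"slope": 0.01, "level": 19.4}),
            sigma_size=0.0, seed=29,
        )
        records, truth = generate_assemblage(config)
        tcfg = TrendConfig(
            seed=29, chains=2, walkers=16, warmup=300, steps=300, n_draws=800,
            rhat_threshold=1.05, ess_threshold=100.0,
        )
        fit = fit_linear_eiv(records, tcfg)
        t = fit.posterior["t"]
        assert np.max(np.abs(t - fit.data.t0[None, :])) < 1e-9
        # fixed-t oracle: OLS of y on (t, size prior mean)
        resp = compute_responses(records, "D15N_Glx_Phe")
        X = np.column_stack(
            [np.ones(len(records)), records.t0, records.etl_mean]
        )
        beta = np.linalg.lstsq(X, resp["y"].to_numpy(), rcond=None)[0]
        b0 = fit.posterior["beta0"]
        assert abs(b0.mean() - beta[1]) < 3 * b0.std()

    def test_dating_refinement_intervals_inside_prior_window(self, linear_fit):
        _, _, fit = linear_fit
        refined = refine_dating(fit)
        assert (refined.t_q2_5 >= refined.t0 - 1e-6).all()
        assert (refined.t_q97_5 <= refined.t1 + 1e-6).all()

    def test_refine_dating_requires_latent_times(self, linear_fit, fast_mcmc):
        records, _, _ = linear_fit
        gam = fit_trend_gam(records, TrendConfig(seed=23, **fast_mcmc))
        with pytest.raises(ValueError, match="latent time"):
            refine_dating(gam)


class TestGAM:
    def test_flat_trend_band_covers_constant(self, fast_mcmc):
        config = SynthConfig(
            n_specimens=120, tp_size_slope=0.0,
            trend=("constant", {"level": 19.4}), seed=41,
        )
        records, _ = generate_assemblage(config)
        fit = fit_trend_gam(records, TrendConfig(seed=41, **fast_mcmc))
        grid = np.linspace(*fit.time_span, 25)
        pred = predict_trend(fit, grid)
        inside = (pred.lower <= 19.4) & (19.4 <= pred.upper)
        assert inside.mean() >= 0.9

    def test_prediction_interval_ordering(self, fast_mcmc, assemblage):
        _, records, _ = assemblage
        fit = fit_trend_gam(records, TrendConfig(seed=11, **fast_mcmc))
        pred = predict_trend(fit, np.linspace(*fit.time_span, 30))
        assert (pred.lower <= pred.mean + 1e-9).all()
        assert (pred.mean <= pred.upper + 1e-9).all()

    def test_fixed_size_shifts_trend_by_size_slope(self, fast_mcmc, assemblage):
        _, records, _ = assemblage
        fit = fit_trend_gam(records, TrendConfig(seed=11, **fast_mcmc))
        grid = np.linspace(*fit.time_span, 5)
        at_mean = predict_trend(fit, grid)
        at_big = predict_trend(fit, grid, fixed_size=fit.data.size_center + 100)
        shift = at_big.mean - at_mean.mean
        expected = 100 * fit.posterior["beta1"].mean()
        np.testing.assert_allclose(shift, expected, atol=0.05)

    def test_empty_grid_rejected(self, fast_mcmc, assemblage):
        _, records, _ = assemblage
        fit = fit_trend_gam(records, TrendConfig(seed=11, **fast_mcmc))
        with pytest.raises(ValueError, match="empty"):
            predict_trend(fit, np.array([]))

    def test_extrapolated_grid_points_flagged(self, fast_mcmc, assemblage):
        _, records, _ = assemblage
        fit = fit_trend_gam(records, TrendConfig(seed=11, **fast_mcmc))
        lo, hi = fit.time_span
        pred = predict_trend(fit, np.array([lo - 100, (lo + hi) / 2, hi + 100]))
        assert list(pred.extrapolated) == [True, False, True]

    def test_tp_summaries_attached_for_offset_proxy(self, fast_mcmc, assemblage):
        _, records, _ = assemblage
        fit = fit_trend_gam(records, TrendConfig(seed=11, **fast_mcmc))
        pred = predict_trend(fit, np.linspace(*fit.time_span, 5))
        assert pred.tp_mean is not None
        assert (pred.tp_lower <= pred.tp_mean).all()

    def test_too_few_records_rejected(self, fast_mcmc):
        records, _ = generate_assemblage(SynthConfig(n_specimens=5, seed=1))
        with pytest.raises(ValueError, match="at least 10"):
            fit_trend_gam(records, TrendConfig(seed=1, **fast_mcmc))


class TestSensitivity:
    def _small(self, **kw):
        base = dict(n_specimens=60, seed=53)
        base.update(kw)
        records, _ = generate_assemblage(SynthConfig(**base))
        return records

    def _config(self):
        return TrendConfig(
            seed=53, chains=2, walkers=16, warmup=200, steps=200, n_draws=400,
            rhat_threshold=1.2, ess_threshold=20.0, k=6,
        )

    def test_zero_width_windows_never_diverge(self):
        records = self._small(window_half_width=0.0)
        result = sensitivity_over_time_imputations(
            records, self._config(), n_random=1
        )
        assert not result.divergent

    def test_one_block_per_strategy(self):
        records = self._small(window_half_width=50.0)
        result = sensitivity_over_time_imputations(
            records, self._config(), n_random=2
        )
        strategies = result.table.strategy.unique()
        assert list(strategies) == ["midpoint", "t0", "t1", "random:0", "random:1"]
        counts = result.table.groupby("strategy").size()
        assert counts.nunique() == 1

    def test_wide_windows_with_steep_trend_diverge(self):
        records = self._small(
            window_half_width=400.0,
            trend=("linear", {"slope": 0.02, "level": 22.0}),
            sigma_machine=0.1, sigma_residual=0.1,
        )
        result = sensitivity_over_time_imputations(
            records, self._config(), n_random=1
        )
        assert result.divergent

    def test_empty_strategy_list_rejected(self):
        records = self._small()
        with pytest.raises(ValueError, match="empty"):
            sensitivity_over_time_imputations(records, self._config(), strategies=[])
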