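"""Flow-cytometry mixture deconvolution and first-order activation fits."""

import numpy as np
import pandas as pd
import pytest

from episwitch.activation_fitting import (
    ActivationCurve,
    GaussianComponent,
    biallelic_fraction_series,
    default_component2_bounds,
    fit_first_order,
    fit_single_component,
    fit_two_component,
    fraction_error,
    histogram2d,
    read_flow_csv,
)
from episwitch.synthetic_data import DEFAULT_COMP1, DEFAULT_COMP2, simulate_flow_timecourse


def cloud_df(comp, n, seed, time_h=5.0):
    """Events from a single component at one time point."""
    return simulate_flow_timecourse(
        lambda_=0.0, comp1=comp, comp2=comp, sample_times=[time_h],
        n_per_time=n, start_fraction2=0.0, seed=seed,
    )


class TestHistogram2D:
    def test_mass_conservation(self):
        events = cloud_df(DEFAULT_COMP1, 5_000, seed=0)
        hist = histogram2d(events)
        assert hist.counts.sum() == 5_000
        assert hist.n_events == 5_000

    def test_too_few_events_named(self):
        events = cloud_df(DEFAULT_COMP1, 50, seed=1)
        with pytest.raises(ValueError, match="bin-A"):
            histogram2d(events, label="bin-A")

    def test_dead_events_excluded(self):
        events = cloud_df(DEFAULT_COMP1, 2_000, seed=2)
        events.loc[: len(events) // 2, "live"] = False
        hist = histogram2d(events)
        assert hist.counts.sum() == events["live"].sum()


class TestSingleComponentFit:
    def test_parameter_recovery(self):
        truth = GaussianComponent(1.0, 3.0, 1.2, 0.3, 0.22, 0.4)
        events = cloud_df(truth, 10_000, seed=3)
        comp = fit_single_component(histogram2d(events))
        assert comp.mu_r == pytest.approx(truth.mu_r, abs=0.03 * truth.mu_r)
        assert comp.mu_y == pytest.approx(truth.mu_y, abs=0.03 * truth.mu_y)
        assert comp.sigma_r == pytest.approx(truth.sigma_r, rel=0.05)
        assert comp.sigma_y == pytest.approx(truth.sigma_y, rel=0.05)
        assert comp.rho == pytest.approx(truth.rho, abs=0.05)

    def test_uncorrelated_cloud_recovers_zero_rho(self):
        truth = GaussianComponent(1.0, 2.5, 2.5, 0.25, 0.25, 0.0)
        events = cloud_df(truth, 10_000, seed=4)
        comp = fit_single_component(histogram2d(events))
        assert abs(comp.rho) < 0.05

    def test_amplitude_integrates_to_event_count(self):
        events = cloud_df(DEFAULT_COMP1, 8_000, seed=5)
        comp = fit_single_component(histogram2d(events))
        assert comp.amplitude == pytest.approx(8_000, rel=0.05)


class TestTwoComponentFit:
    def _mixture_hist(self, frac2, n, seed):
        events = simulate_flow_timecourse(
            lambda_=0.0, comp1=DEFAULT_COMP1, comp2=DEFAULT_COMP2,
            sample_times=[5.0], n_per_time=n, start_fraction2=frac2, seed=seed,
        )
        return histogram2d(events)

    def test_mixture_fraction_recovery(self):
        n = 10_000
        hist = self._mixture_hist(0.30, n, seed=6)
        comp1 = fit_single_component(self._mixture_hist(0.0, n, seed=7))
        fit = fit_two_component(hist, comp1, default_component2_bounds(comp1, hist))
        f2 = fit.N2 / (fit.N1 + fit.N2)
        binom_se = np.sqrt(0.3 * 0.7 / n)
        assert abs(f2 - 0.30) < 5 * binom_se + 0.01

    def test_pure_component1_gives_zero_fraction(self):
        n = 10_000
        hist = self._mixture_hist(0.0, n, seed=8)
        comp1 = fit_single_component(hist)
        fit = fit_two_component(hist, comp1, default_component2_bounds(comp1, hist))
        assert fit.N2 / (fit.N1 + fit.N2) < 0.02

    def test_component1_shape_frozen(self):
        n = 8_000
        hist = self._mixture_hist(0.25, n, seed=9)
        comp1 = fit_single_component(self._mixture_hist(0.0, n, seed=10))
        fit = fit_two_component(hist, comp1, default_component2_bounds(comp1, hist))
        for field in ("mu_r", "mu_y", "sigma_r", "sigma_y", "rho"):
            assert getattr(fit.component1, field) == getattr(comp1, field)


class TestFractionError:
    def test_plugin_example(self):
        # N1=900, N2=100, dN1=30, dN2=10:
        # f2 = 0.100, df2 = 0.1*sqrt((10/100)^2 + (900+100)/1000^2) ~ 0.0105
        f2, df2 = fraction_error(900, 100, 30, 10)
        assert f2 == pytest.approx(0.100)
        assert df2 == pytest.approx(0.1 * np.sqrt(0.01 + 1000 / 1_000_000), rel=1e-9)
        assert df2 == pytest.approx(0.0105, abs=2e-4)

    def test_zero_component2(self):
        f2, df2 = fraction_error(500, 0, 20, 0)
        assert f2 == 0.0
        assert df2 == 0.0


class TestActivationCurveSeries:
    def test_fractions_follow_first_order_kinetics(self):
        lam = 0.02
        events = simulate_flow_timecourse(
            lambda_=lam, sample_times=np.arange(10.0, 110.0, 20.0),
            n_per_time=3_000, seed=11,
        )
        curve = biallelic_fraction_series(events, bin_width_h=20.0)
        expected = 1 - np.exp(-lam * curve.bin_centers)
        assert np.all(np.abs(curve.f2obs - expected) < 0.06)

    def test_affine_rescaling_invariance(self):
        # scaling both channels consistently must not change fractions
        events = simulate_flow_timecourse(lambda_=0.02, n_per_time=2_000, seed=12)
        scaled = events.copy()
        scaled[["r", "y"]] *= 10.0
        c1 = biallelic_fraction_series(events)
        c2 = biallelic_fraction_series(scaled)
        np.testing.assert_allclose(c1.f2obs, c2.f2obs, atol=0.02)

    def test_event_order_invariance(self):
        events = simulate_flow_timecourse(lambda_=0.02, n_per_time=2_000, seed=13)
        shuffled = events.sample(frac=1.0, random_state=0).reset_index(drop=True)
        c1 = biallelic_fraction_series(events)
        c2 = biallelic_fraction_series(shuffled)
        np.testing.assert_allclose(c1.f2obs, c2.f2obs, atol=1e-9)


class TestFirstOrderFit:
    def test_noiseless_rate_recovery(self):
        t = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
        lam = 0.02
        curve = ActivationCurve(
            bin_centers=t, f2obs=1 - np.exp(-lam * t),
            delta_f2obs=np.full(t.size, 1e-3), n_per_bin=np.full(t.size, 1000),
        )
        fit = fit_first_order(curve, plateau="fixed_1")
        assert fit.rate == pytest.approx(lam, rel=1e-6)

    def test_half_activation_time(self):
        # lambda = 0.025/h: half-activation at ln2/0.025 ~ 27.7 h
        lam = 0.025
        t = np.linspace(5, 200, 12)
        curve = ActivationCurve(
            bin_centers=t, f2obs=1 - np.exp(-lam * t),
            delta_f2obs=np.full(t.size, 1e-3), n_per_bin=np.full(t.size, 1000),
        )
        fit = fit_first_order(curve)
        t_half = np.log(2) / fit.rate
        assert t_half == pytest.approx(27.7, abs=0.1)

    def test_plateau_form_recovery(self):
        F, k = 0.8, 0.03
        t = np.linspace(10, 150, 10)
        rng = np.random.default_rng(14)
        y = F * (1 - np.exp(-k * t)) + rng.normal(0, 0.005, t.size)
        curve = ActivationCurve(
            bin_centers=t, f2obs=np.clip(y, 0, 1),
            delta_f2obs=np.full(t.size, 0.005), n_per_bin=np.full(t.size, 1000),
        )
        fit = fit_first_order(curve, plateau="free_F")
        assert fit.rate == pytest.approx(k, rel=0.05)
        assert fit.plateau == pytest.approx(F, rel=0.05)

    def test_plateau_free_agrees_with_fixed_on_saturating_data(self):
        lam = 0.02
        t = np.linspace(10, 250, 12)
        curve = ActivationCurve(
            bin_centers=t, f2obs=1 - np.exp(-lam * t),
            delta_f2obs=np.full(t.size, 1e-3), n_per_bin=np.full(t.size, 1000),
        )
        fixed = fit_first_order(curve, plateau="fixed_1")
        free = fit_first_order(curve, plateau="free_F")
        assert free.rate == pytest.approx(fixed.rate, rel=1e-3)
        assert free.plateau == pytest.approx(1.0, abs=1e-3)

    def test_too_few_bins_raises(self):
        curve = ActivationCurve(
            bin_centers=np.array([10.0, 30.0]), f2obs=np.array([0.1, 0.2]),
            delta_f2obs=np.array([0.01, 0.01]), n_per_bin=np.array([100, 100]),
        )
        with pytest.raises(ValueError):
            fit_first_order(curve)


class TestFlowCSV:
    def test_roundtrip_and_missing_columns(self, tmp_path):
        events = simulate_flow_timecourse(lambda_=0.02, n_per_time=200, seed=15)
        path = tmp_path / "events.csv"
        events.to_csv(path, index=False)
        loaded = read_flow_csv(path)
        assert list(loaded.columns[:4]) == ["time_h", "r", "y", "live"]
        bad = tmp_path / "bad.csv"
        events.drop(columns=["y"]).to_csv(bad, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_flow_csv(bad)
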