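import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from heterowheat import phenology as phen
from heterowheat.data import WeatherSeries
from heterowheat.phenology import (NDVISeries, PhenologyError, build_thermal_axis,
                                   fit_line, fit_plot, fit_senescence,
                                   logistic_antiderivative, logistic_ndvi,
                                   phase_areas, phenology_pipeline,
                                   segment_phases, tfn)

from conftest import constant_weather

LN9, LN99 = math.log(9), math.log(99)


# ---------------------------------------------------------------------------
# Thermal time axis


class TestThermalAxis:
    def test_constant_temperature(self, flat_weather):
        sowing = dt.date(2019, 10, 1)
        heading = sowing + dt.timedelta(days=100)
        axis = build_thermal_axis(flat_weather, sowing, heading)
        assert axis.tt_of(sowing) == pytest.approx(-1000.0)
        assert axis.tt_of(heading) == pytest.approx(0.0)
        assert np.all(np.diff(axis.tt) >= 0)

    def test_subzero_day_contributes_nothing(self):
        ws = constant_weather(days=10, tmin=-6.0, tmax=-4.0)
        axis = build_thermal_axis(ws, dt.date(2019, 10, 1),
                                  dt.date(2019, 10, 5))
        assert np.all(axis.tt == 0.0)  # every daily mean is below the base

    def test_matches_per_day_loop(self, rng):
        start = dt.date(2019, 10, 1)
        n = 120
        tmin = rng.normal(4, 6, n)
        tmax = tmin + np.abs(rng.normal(8, 3, n))
        ws = WeatherSeries("L1", pd.DataFrame({
            "date": [start + dt.timedelta(days=i) for i in range(n)],
            "tmin": tmin, "tmax": tmax, "rainfall": 0.0}))
        heading = start + dt.timedelta(days=80)
        axis = build_thermal_axis(ws, start, heading)
        cum, expected = 0.0, []
        for i in range(n):
            cum += max((tmin[i] + tmax[i]) / 2, 0.0)
            expected.append(cum)
        expected = np.array(expected) - expected[80]
        np.testing.assert_allclose(axis.tt, expected, atol=1e-9)

    def test_heading_outside_coverage(self, flat_weather):
        with pytest.raises(PhenologyError):
            build_thermal_axis(flat_weather, dt.date(2019, 10, 1),
                               dt.date(2021, 1, 1))


# ---------------------------------------------------------------------------
# Line and logistic fits


class TestLineFits:
    def test_exact_line(self):
        tt = np.linspace(-800, -100, 6)
        a, b, r = fit_line(tt, 0.001 * tt + 1.0)
        assert a == pytest.approx(0.001, abs=1e-12)
        assert b == pytest.approx(1.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        a, b, r = fit_line(np.array([0.0, 100.0]), np.array([0.5, 0.7]))
        assert a == pytest.approx(0.002)
        assert r == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        for _ in range(25):
            tt = rng.uniform(-900, 500, 10)
            y = rng.uniform(0, 1, 10)
            a, b, _ = fit_line(tt, y)
            X = np.column_stack([tt, np.ones(10)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert a == pytest.approx(beta[0], rel=1e-9)
            assert b == pytest.approx(beta[1], rel=1e-9)

    def test_identical_tt_rejected(self):
        with pytest.raises(PhenologyError):
            fit_line(np.array([1.0, 1.0, 1.0]), np.array([0.1, 0.2, 0.3]))


class TestSenescenceFit:
    A3, B3 = 0.02, -13.77
    FINAL, AMP = 0.15, 0.7

    def _points(self, n=8, lo=450, hi=1200):
        tt = np.linspace(lo, hi, n)
        return tt, logistic_ndvi(tt, self.A3, self.B3, self.FINAL, self.AMP)

    def test_noiseless_recovery(self):
        tt, y = self._points()
        fit = fit_senescence(tt, y, self.FINAL, self.AMP)
        assert fit.converged
        assert fit.a3 == pytest.approx(self.A3, abs=1e-6)
        assert fit.b3 == pytest.approx(self.B3, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_zero_amplitude_rejected(self):
        tt, y = self._points()
        with pytest.raises(PhenologyError):
            fit_senescence(tt, y, self.FINAL, 0.0)

    def test_noisy_fit_beats_truth_sse(self, rng):
        tt, y = self._points()
        y = y + rng.normal(0, 0.02, len(y))
        fit = fit_senescence(tt, y, self.FINAL, self.AMP)
        sse_truth = float(np.sum(
            (logistic_ndvi(tt, self.A3, self.B3, self.FINAL, self.AMP) - y) ** 2))
        assert fit.sse <= sse_truth + 1e-12

    def test_noisy_recovery_median_error(self, rng):
        """With sigma=0.02 NDVI noise the senescence rate is recovered to
        a few percent (median over 500 replicates at 14 observation times
        spanning the transition, plus-harvest style)."""
        quantiles = np.linspace(0.95, 0.05, 13)
        tt = np.array([tfn(self.A3, self.B3, q) for q in quantiles] + [1250.0])
        errs = []
        for _ in range(500):
            y = logistic_ndvi(tt, self.A3, self.B3, self.FINAL, self.AMP)
            y = np.clip(y + rng.normal(0, 0.02, len(y)), 0, 1)
            fit = fit_senescence(tt, y, self.FINAL, self.AMP)
            if fit.converged:
                errs.append(abs(fit.a3 - self.A3) / self.A3)
        assert len(errs) > 480
        assert np.median(errs) < 0.05


# ---------------------------------------------------------------------------
# Stay-green statistics


class TestTfn:
    def test_reported_parameterisation(self):
        # a3 = 0.02, b3 = -13.77 puts mid-senescence at 688.5 degC days
        assert tfn(0.02, -13.77, 0.50) == pytest.approx(688.5)
        assert tfn(0.02, -13.77, 0.90) == pytest.approx(688.5 - LN9 / 0.02)

    def test_logistic_symmetry(self):
        t90, t50, t10 = (tfn(0.02, -13.77, f) for f in (0.90, 0.50, 0.10))
        assert t10 - t50 == pytest.approx(t50 - t90, abs=1e-9)
        assert t10 - t50 == pytest.approx(LN9 / 0.02, abs=1e-6)

    def test_matches_bisection_inversion(self, rng):
        """Closed-form quantiles equal numeric inversion of the curve."""
        for _ in range(200):
            a3 = rng.uniform(0.005, 0.08)
            b3 = rng.uniform(-40, -2)
            final, amp = rng.uniform(0.05, 0.3), rng.uniform(0.3, 0.8)
            for frac in (0.90, 0.50, 0.10, 0.01):
                target = final + frac * amp
                root = optimize.brentq(
                    lambda t: logistic_ndvi(t, a3, b3, final, amp) - target,
                    -1e6, 1e6, xtol=1e-9)
                assert tfn(a3, b3, frac) == pytest.approx(root, abs=1e-6)

    def test_ordering_invariant(self, rng):
        for _ in range(100):
            a3, b3 = rng.uniform(0.005, 0.08), rng.uniform(-40, -2)
            t90, t50, t10, t1 = (tfn(a3, b3, f) for f in (0.9, 0.5, 0.1, 0.01))
            assert t90 < t50 < t10 < t1
            assert t50 == pytest.approx((t90 + t10) / 2, abs=1e-9)
            assert (t1 - t50) / (t10 - t50) == pytest.approx(LN99 / LN9, abs=1e-9)

    def test_averaging_linearity(self, rng):
        """Mean TFN spans scale exactly by ln99/ln9 across any genotype set."""
        a3 = rng.uniform(0.01, 0.05, 40)
        b3 = rng.uniform(-40, -5, 40)
        t50 = np.array([tfn(a, b, 0.5) for a, b in zip(a3, b3)])
        t10 = np.array([tfn(a, b, 0.1) for a, b in zip(a3, b3)])
        t1 = np.array([tfn(a, b, 0.01) for a, b in zip(a3, b3)])
        assert np.mean(t1 - t50) == pytest.approx(
            (LN99 / LN9) * np.mean(t10 - t50), rel=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(PhenologyError):
            tfn(-0.01, -13.0, 0.5)


class TestPhaseAreas:
    def test_zero_amplitude_constant_integrand(self):
        m = phen.PhenologyModel("p", a3=0.02, b3=-13.77, ndvi_final=0.2,
                                ndvi_amplitude=0.0, tt_flower_end=400.0,
                                a2=0.0, b2=0.2, tt_nmax=400.0,
                                senescence_available=True)
        out = phase_areas(m, ta_mode="modelled")
        tfn1 = tfn(0.02, -13.77, 0.01)
        assert out["SPA"] == pytest.approx(0.2 * (tfn1 - 400.0), rel=1e-9)

    def test_closed_form_matches_quadrature(self, rng):
        for _ in range(50):
            a3 = rng.uniform(0.005, 0.08)
            b3 = rng.uniform(-40, -2)
            final, amp = rng.uniform(0.05, 0.3), rng.uniform(0.3, 0.8)
            t0 = tfn(a3, b3, 0.99)
            t1 = tfn(a3, b3, 0.01)
            closed = (logistic_antiderivative(t1, a3, b3, final, amp)
                      - logistic_antiderivative(t0, a3, b3, final, amp))
            quad, _ = integrate.quad(
                lambda t: logistic_ndvi(t, a3, b3, final, amp), t0, t1,
                limit=200)
            assert closed == pytest.approx(quad, rel=1e-6)

    def test_dpa_is_fpa_plus_spa(self, noiseless_bundle):
        data, truth = noiseless_bundle
        traits_df, _, _ = _run_pipeline_subset(data, n=12)
        ok = traits_df.dropna(subset=["dpa"])
        assert len(ok) > 0
        np.testing.assert_allclose(ok["dpa"], ok["fpa"] + ok["spa"], rtol=1e-12)


# ---------------------------------------------------------------------------
# Segmentation and the per-plot pipeline


def _piecewise_series(plot="p1", n_flower=3, n_sen=6, noise=0.0, rng=None):
    """Hand-built three-phase curve with a known breakpoint."""
    a1, b1 = 8e-4, 0.85
    nmax_tt = 0.0
    tt_grow = np.linspace(-900, nmax_tt, 6)
    y_grow = a1 * tt_grow + b1
    a3, b3, final = 0.02, -13.0, 0.15
    tt_fe = (-LN99 - b3) / a3
    a2 = -0.05 / (tt_fe - nmax_tt)
    b2 = y_grow[-1] - a2 * nmax_tt
    amp = a2 * tt_fe + b2 - final
    tt_fl = np.linspace(60, tt_fe, n_flower)
    y_fl = a2 * tt_fl + b2
    tt_se = np.linspace(tt_fe + 40, (LN9 * 3 - b3) / a3, n_sen)
    y_se = logistic_ndvi(tt_se, a3, b3, final, amp)
    tt = np.concatenate([tt_grow, tt_fl, tt_se])
    y = np.concatenate([y_grow, y_fl, y_se])
    if noise and rng is not None:
        y = np.clip(y + rng.normal(0, noise, len(y)), 0, 1)
    return NDVISeries(plot, tt, y, tt_sowing=-1000.0), {
        "a1": a1, "b1": b1, "a2": a2, "b2": b2, "a3": a3, "b3": b3,
        "final": final, "amp": amp, "tt_fe": tt_fe, "break_index": 6 + n_flower}


class TestSegmentation:
    def test_recovers_known_breakpoint(self):
        series, truth = _piecewise_series()
        seg = segment_phases(series)
        assert seg.available
        # senescence starts at the first generated senescence point (or one off)
        assert abs(int(seg.senescence[0]) - truth["break_index"]) <= 1

    def test_strictly_increasing_series_unavailable(self):
        tt = np.linspace(-900, 200, 10)
        series = NDVISeries("p", tt, np.linspace(0.1, 0.9, 10), -1000.0)
        seg = segment_phases(series)
        assert not seg.available
        assert len(seg.growing) == 10

    def test_short_series_not_fitted(self):
        tt = np.linspace(-500, 500, 7)
        y = np.concatenate([np.linspace(0.2, 0.9, 3), np.linspace(0.8, 0.2, 4)])
        seg = segment_phases(NDVISeries("p", tt, y, -600.0))
        assert not seg.available

    def test_field_shaped_plot_has_three_segments(self, default_bundle):
        data, _ = default_bundle
        series = _series_for(data, data.plots[0].plot_id)
        seg = segment_phases(series)
        assert seg.available
        assert len(seg.growing) and len(seg.flowering) and len(seg.senescence)


def _series_for(data, plot_id):
    plot = next(p for p in data.plots if p.plot_id == plot_id)
    site = data.meta[plot.location]
    hd = data.traits.frame
    hd_val = hd[(hd["unit"] == plot_id) & (hd["trait"] == "HD")]["value"].iloc[0]
    heading = dt.date(site.harvest_date.year, 1, 1) + dt.timedelta(
        days=int(round(hd_val)) - 1)
    axis = build_thermal_axis(data.weather[plot.location], site.sowing_date,
                              heading)
    return phen.series_from_table(
        data.ndvi[data.ndvi["plot_id"] == plot_id], {plot_id: axis}, {})[0]


def _run_pipeline_subset(data, n=12):
    series = [_series_for(data, p.plot_id) for p in data.plots[:n]]
    return phenology_pipeline(series)


class TestPipeline:
    def test_noiseless_fits_are_exact(self, noiseless_bundle):
        data, truth = noiseless_bundle
        traits_df, models_df, report = _run_pipeline_subset(data, n=10)
        assert report["n_fitted"] == 10
        assert report["mean_r_growing"] > 1 - 1e-9
        assert report["mean_r_senescence"] > 1 - 1e-6
        pt = truth.phenology.set_index("plot_id")
        merged = traits_df.set_index("plot_id").join(pt, rsuffix="_true")
        rel_a3 = np.abs(models_df.set_index("plot_id")["a3"]
                        - pt.loc[models_df["plot_id"], "a3"]) / pt.loc[
                            models_df["plot_id"], "a3"]
        assert rel_a3.max() < 1e-2
        assert (merged["tfn50"] - merged["tfn50_true"]).abs().max() < 0.5

    def test_noisy_cohort_growing_quality(self, default_bundle):
        data, _ = default_bundle
        _, _, report = _run_pipeline_subset(data, n=20)
        assert report["mean_r_growing"] >= 0.95

    def test_short_series_flagged_not_dropped(self, noiseless_bundle):
        data, _ = noiseless_bundle
        series = [_series_for(data, p.plot_id) for p in data.plots[:4]]
        stub = NDVISeries("stub", np.linspace(-500, 300, 4),
                          np.array([0.3, 0.6, 0.8, 0.5]), -600.0)
        traits_df, _, report = phenology_pipeline(series + [stub])
        assert report["n_fitted"] == 4
        assert ("stub" in dict(report["unavailable"]))
        assert len(traits_df) == 5  # flagged plot still has a row

    def test_tfn_invariants_on_fitted_cohort(self, default_bundle):
        data, _ = default_bundle
        traits_df, _, _ = _run_pipeline_subset(data, n=15)
        ok = traits_df.dropna(subset=["tfn50"])
        assert len(ok) >= 10
        assert (ok["tfn90"] < ok["tfn50"]).all()
        assert (ok["tfn50"] < ok["tfn10"]).all()
        assert (ok["tfn10"] < ok["tfn1"]).all()
        np.testing.assert_allclose(ok["tfn50"], (ok["tfn90"] + ok["tfn10"]) / 2,
                                   atol=1e-9)
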