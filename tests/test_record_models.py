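"""Stage-1 estimators: penalized-spline AR(1), linear GLS, state-space."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from climpop import (WeatherGAMM, WeatherLinearModel, simulate_abundance,
                     simulate_growth_series)
from climpop.errors import DegenerateInputError, InvalidArgumentError
from climpop.record_models import (StateSpaceWeatherModel, effect_batch,
                                   fit_weather_gamm, fit_weather_linear)


def make_xy(T=30, seed=0):
    rng = np.random.default_rng(seed)
    years = np.arange(1980, 1980 + T)
    W = rng.normal(0, 1, T)
    return years, W


class TestWeatherGAMM:
    def test_noiseless_linear_signal_exact(self):
        years, W = make_xy()
        eff = fit_weather_gamm(1.0 * W, W, years)
        assert eff.omega == pytest.approx(1.0, abs=1e-6)
        assert eff.edf_trend < 0.5

    def test_linear_trend_absorbed(self):
        years, W = make_xy(seed=1)
        r = W + 0.05 * (years - years[0])
        eff = fit_weather_gamm(r, W, years)
        assert eff.omega == pytest.approx(1.0, abs=0.01)

    def test_curved_trend_absorbed(self):
        years, W = make_xy(seed=2)
        r = W + 0.4 * np.sin((years - years[0]) / 8.0)
        eff = fit_weather_gamm(r, W, years)
        assert eff.omega == pytest.approx(1.0, abs=0.02)
        assert eff.edf_trend > 1.0

    def test_constant_driver_rejected(self):
        years, _ = make_xy()
        with pytest.raises(DegenerateInputError):
            fit_weather_gamm(np.ones(30), np.ones(30), years)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_weather_gamm(np.ones(4), np.arange(4.0), np.arange(4))

    def test_edf_bounded_by_basis(self):
        years, W = make_xy(seed=3)
        rng = np.random.default_rng(0)
        r = W + rng.normal(0, 0.5, 30)
        eff = fit_weather_gamm(r, W, years, basis_dim=5)
        assert 0 <= eff.edf_trend <= 4

    def test_monte_carlo_recovery_and_coverage(self):
        """T=30, omega=1, AR(1) noise: unbiased with ~95% CI coverage."""
        hits, oms = 0, []
        for i in range(150):
            yrs, W, r = simulate_growth_series(30, omega=1.0, noise_sd=0.2,
                                               rho=0.3, seed=5000 + i)
            m = WeatherGAMM().fit(np.column_stack([yrs, W]), r)
            oms.append(m.omega_)
            lo, hi = m.ci_omega()
            hits += lo <= 1.0 <= hi
        assert np.mean(oms) == pytest.approx(1.0, abs=0.05)
        assert 0.88 <= hits / 150 <= 0.99

    def test_variance_shrinks_with_record_length(self):
        """Sampling variance of omega-hat decreases from T=10 to T=30."""
        var = {}
        for T in (10, 20, 30):
            est = [WeatherGAMM().fit(
                np.column_stack(s[:1] + s[1:2]), s[2]).omega_
                for s in (simulate_growth_series(T, omega=1.0, noise_sd=0.3,
                                                 rho=0.2, seed=900 * T + i)
                          for i in range(80))]
            var[T] = np.var(est)
        assert var[10] >= var[20] >= var[30]


class TestWeatherLinear:
    def test_matches_spline_on_noiseless_input(self):
        years, W = make_xy(seed=4)
        r = 1.0 * W
        e1 = fit_weather_gamm(r, W, years)
        e2 = fit_weather_linear(r, W, years)
        assert e1.omega == pytest.approx(e2.omega, abs=1e-6)

    def test_orthogonal_driver_equals_simple_slope(self):
        years, W = make_xy(seed=5)
        x = (years - years.mean()).astype(float)
        W = W - W.mean() - (W @ x) / (x @ x) * x  # orthogonal to [1, year]
        rng = np.random.default_rng(1)
        r = 0.7 * W + rng.normal(0, 0.1, W.size)
        eff = fit_weather_linear(r, W, years, rho=0.0)
        simple = (W @ r) / (W @ W)
        assert eff.omega == pytest.approx(simple, abs=1e-9)

    def test_spline_and_linear_estimates_track_each_other(self):
        """Across a synthetic batch, spline and linear omega correlate."""
        spl, lin = [], []
        for i in range(80):
            yrs, W, r = simulate_growth_series(
                18, omega=np.random.default_rng(i).normal(0, 1),
                noise_sd=0.4, rho=0.2, seed=200 + i)
            spl.append(fit_weather_gamm(r, W, yrs).omega)
            lin.append(fit_weather_linear(r, W, yrs).omega)
        assert np.corrcoef(spl, lin)[0, 1] > 0.9

    def test_heavy_smoothing_limit_matches_linear(self):
        """As the smoothing penalty grows the spline fit collapses onto the
        linear-year fit."""
        yrs, W, r = simulate_growth_series(25, omega=0.8, noise_sd=0.3,
                                           rho=0.2, seed=77)
        lam_hi = WeatherGAMM(rho=0.2, lam_range=(18.0, 18.0))
        lam_hi._fit_core(r, W, yrs)
        lin = WeatherLinearModel(rho=0.2)
        lin._fit_core(r, W, yrs)
        assert abs(lam_hi.omega_ - lin.omega_) < 1e-3


class TestAgainstReferenceGAMM:
    def test_matches_mgcv_gamm(self, tmp_path):
        """Cross-check against R mgcv::gamm with corAR1 on one record."""
        yrs, W, r = simulate_growth_series(30, omega=1.0, noise_sd=0.3,
                                           rho=0.3, seed=42)
        ours = fit_weather_gamm(r, W, yrs)
        df = pd.DataFrame({"year": yrs, "W": W, "r": r})
        csv = tmp_path / "rec.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(textwrap.dedent(f"""
            suppressMessages({{library(mgcv); library(nlme)}})
            d <- read.csv("{csv}")
            fit <- gamm(r ~ W + s(year, k=5, bs="tp"), data=d,
                        correlation=corAR1(form=~year))
            co <- summary(fit$gam)$p.table
            cat(co["W","Estimate"], co["W","Std. Error"], sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        omega_r, se_r = map(float, out.stdout.strip().split("\n")[-2:])
        assert ours.omega == pytest.approx(omega_r, abs=0.02)
        assert ours.se_omega == pytest.approx(se_r, abs=0.01)


class TestStateSpace:
    def test_deterministic_input_recovers_omega(self):
        # high baseline abundance so the zero-guarding +1 transform is
        # negligible and the no-noise limit is an exact identity
        T = 25
        W = np.random.default_rng(3).normal(0, 1, T - 1)
        ab, _ = simulate_abundance(T, 1.0, W, process_sd=0.0,
                                   x0=np.log(1e6))
        m = StateSpaceWeatherModel(seed=1).fit(
            np.column_stack([ab, np.append(W, 0.0)]))
        assert m.omega_ == pytest.approx(1.0, abs=0.05)
        assert m.fit_to_sample() > 0.99

    def test_constant_driver_rejected(self):
        with pytest.raises(DegenerateInputError):
            StateSpaceWeatherModel().fit(
                np.column_stack([np.ones(12), np.ones(12)]))

    def test_posterior_sd_reported(self):
        T = 20
        W = np.random.default_rng(5).normal(0, 1, T - 1)
        ab, _ = simulate_abundance(T, 0.5, W, process_sd=0.3, seed=2)
        m = StateSpaceWeatherModel(seed=3, n_steps=800, n_burn=400).fit(
            np.column_stack([ab, np.append(W, 0.0)]))
        assert m.se_omega_ > 0
        assert np.isfinite(m.rhat_)


class TestEffectBatch:
    def batch_inputs(self, n_missing=0, zero_anom=False):
        from climpop.prep import GrowthRateSeries
        rng = np.random.default_rng(0)
        series, weather_rows = [], []
        for i in range(4):
            yrs = np.arange(1990, 2005)
            W = rng.normal(0, 1, 15)
            series.append(GrowthRateSeries(f"rec{i}", yrs[:-1],
                                           1.0 * W[:-1] + rng.normal(0, 0.2, 14),
                                           15))
            wyears = yrs if (i > 0 or n_missing == 0) else yrs[:-n_missing - 2]
            for v in ("temp", "precip"):
                anom = np.zeros(wyears.size) if (zero_anom and i == 0) \
                    else rng.normal(0, 1, wyears.size)
                if v == "temp" and i < len(series):
                    anom = W[:wyears.size]
                weather_rows += [{"record_id": f"rec{i}", "variable": v,
                                  "year": int(y), "anomaly": float(a),
                                  "variance": float(abs(a)) + 0.5}
                                 for y, a in zip(wyears, anom)]
        return series, pd.DataFrame(weather_rows)

    def test_cardinality(self):
        series, annual = self.batch_inputs()
        effects, skipped = effect_batch(series, annual)
        assert len(effects) == 8  # 4 records x 2 variables
        assert not skipped

    def test_missing_weather_year_skips_record(self):
        series, annual = self.batch_inputs(n_missing=3)
        effects, skipped = effect_batch(series, annual, variables=("temp",))
        assert len(effects) == 3
        assert skipped[0]["record_id"] == "rec0"

    def test_degenerate_driver_logged(self):
        series, annual = self.batch_inputs(zero_anom=True)
        effects, skipped = effect_batch(series, annual, variables=("precip",))
        assert any("degenerate" in s["reason"] for s in skipped)
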