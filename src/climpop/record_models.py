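"""Per-record weather-effect estimators.

The primary estimator regresses annual population growth rates on an annual
weather driver with a linear coefficient omega, while absorbing the record's
long-term abundance trend with a low-rank penalized thin-plate-type spline on
year (basis dimension 5) and first-order autoregressive (AR(1)) residual
correlation.  The smoothing parameter and the AR(1) coefficient are chosen by
restricted maximum likelihood (REML): rho is profiled on a grid and refined by
golden-section search, the smoothing parameter by golden-section on its log.

Two alternative estimators cross-validate the approach: a linear-year-effect
AR(1) GLS fit, and a state-space model with explicit process and observation
error whose latent states are marginalized exactly by a Kalman filter and
whose three parameters are sampled with an affine-invariant ensemble sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = ["WeatherEffect", "WeatherGAMM", "WeatherLinearModel",
           "StateSpaceWeatherModel", "fit_weather_gamm", "fit_weather_linear",
           "fit_weather_statespace", "effect_batch"]


@dataclass
class WeatherEffect:
    """Stage-1 -> stage-2 currency: one record's weather coefficient."""

    record_id: str
    variable: str            # temperature | precipitation
    driver: str              # anomaly | variance
    omega: float
    se_omega: float
    intercept: float
    ar1_rho: float
    edf_trend: float
    converged: bool
    N: int                   # record length in years
    species: str = ""
    biome: str = ""
    lat: float = np.nan
    lon: float = np.nan


# ---------------------------------------------------------------------------
# penalized thin-plate-type basis (1-d, low rank)

def tps_basis(x, k=5):
    """Low-rank thin-plate-type spline basis on a 1-d covariate.

    Eigen-construction: the full radial basis |x_i - x_j|^3 is projected onto
    the complement of the polynomial null space {1, x}, its top (k-2)
    eigenvectors U are retained, and the design columns are E @ U with a
    diagonal penalty of the corresponding eigenvalues.  The linear null-space
    term is carried separately as an unpenalized column.

    Returns (B, penalty_diag): B of shape (n, k-2).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if k < 3:
        raise InvalidArgumentError("basis_dim must be >= 3")
    kk = min(k - 2, n - 2)
    E = np.abs(x[:, None] - x[None, :]) ** 3
    T = np.column_stack([np.ones(n), x])
    Q, _ = np.linalg.qr(T)
    P = np.eye(n) - Q @ Q.T
    Et = P @ E @ P
    Et = 0.5 * (Et + Et.T)
    w, U = np.linalg.eigh(Et)
    order = np.argsort(w)[::-1][:kk]
    lam = np.clip(w[order], 1e-12, None)
    B = P @ (E @ U[:, order])
    # scale columns so the penalty is O(1); keeps lambda search well ranged
    scale = np.sqrt(lam)
    return B / scale, np.ones(kk)


def _whiten(M, rho):
    """AR(1) whitening: rows -> innovations scaled to unit marginal variance."""
    out = np.empty_like(M)
    out[0] = M[0]
    c = 1.0 / np.sqrt(1.0 - rho ** 2)
    out[1:] = (M[1:] - rho * M[:-1]) * c
    return out


def _reml_fit(y, C, pen_diag, n_fixed, log_lam, rho):
    """Penalized AR(1) REML criterion and fit at fixed (lambda, rho).

    Returns (neg2_reml, beta, A_chol, sigma2, Ct).
    """
    n, p = C.shape
    yt = _whiten(y[:, None], rho)[:, 0]
    Ct = _whiten(C, rho)
    S = np.zeros(p)
    lam = np.exp(log_lam)
    S[n_fixed:] = lam * pen_diag
    A = Ct.T @ Ct + np.diag(S)
    try:
        Ach = cho_factor(A)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None, None
    b = cho_solve(Ach, Ct.T @ yt)
    presid = float(yt @ yt - b @ (Ct.T @ yt))
    presid = max(presid, 1e-300)
    df = n - n_fixed
    sigma2 = presid / df
    logdet_A = 2.0 * np.log(np.diag(Ach[0])).sum()
    k_pen = p - n_fixed
    logdet_S = k_pen * log_lam + np.log(pen_diag).sum() if k_pen else 0.0
    log_R = (n - 1) * np.log(1.0 - rho ** 2)
    neg2 = (df * (np.log(2 * np.pi * sigma2) + 1.0)
            + log_R + logdet_A - logdet_S)
    return neg2, b, Ach, sigma2, Ct


def _golden(f, lo, hi, tol=1e-3, max_iter=60):
    """Golden-section minimization on [lo, hi]."""
    g = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - g * (b - a), a + g * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(d)
    return (a + b) / 2


class _ARSplineBase(BaseEstimator):
    """Shared REML machinery for the spline and linear AR(1) estimators."""

    #: set by subclasses: whether a penalized smooth basis is included
    _smooth = True

    def _design(self, years, W):
        yr = np.asarray(years, dtype=float)
        span = yr.max() - yr.min()
        x = (yr - yr.min()) / (span if span > 0 else 1.0)
        xc = x - x.mean()
        fixed = np.column_stack([np.ones(yr.size), W, xc])
        if self._smooth:
            B, pen = tps_basis(x, k=self.basis_dim)
            return np.column_stack([fixed, B]), pen, 3
        return fixed, np.ones(0), 3

    def _fit_core(self, r, W, years):
        r = np.asarray(r, dtype=float)
        W = np.asarray(W, dtype=float)
        years = np.asarray(years)
        if not (r.size == W.size == years.size):
            raise InvalidArgumentError("r, W and years must share a length")
        min_n = (self.basis_dim + 2) if self._smooth else 4
        if r.size < min_n:
            raise InvalidArgumentError(
                f"need at least {min_n} observations, got {r.size}")
        if np.std(W) == 0:
            raise DegenerateInputError("constant weather driver")
        C, pen, n_fixed = self._design(years, W)

        def neg2_at(rho):
            if self._smooth:
                best = [np.inf, None]

                def f_lam(ll):
                    v = _reml_fit(r, C, pen, n_fixed, ll, rho)[0]
                    if v < best[0]:
                        best[0], best[1] = v, ll
                    return v
                _golden(f_lam, self.lam_range[0], self.lam_range[1], tol=0.05)
                return best[0], best[1]
            v = _reml_fit(r, C, pen, n_fixed, 0.0, rho)[0]
            return v, 0.0

        if self.rho is None:
            grid = np.arange(-0.9, 0.91, 0.1)
            vals = [neg2_at(rho)[0] for rho in grid]
            i = int(np.argmin(vals))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, grid.size - 1)]
            rho_hat = _golden(lambda rho: neg2_at(rho)[0], lo, hi, tol=1e-3)
        else:
            rho_hat = float(self.rho)
        _, log_lam = neg2_at(rho_hat)
        neg2, b, Ach, sigma2, Ct = _reml_fit(r, C, pen, n_fixed,
                                             log_lam, rho_hat)
        if b is None:
            raise DegenerateInputError("singular penalized design")
        Ainv = cho_solve(Ach, np.eye(C.shape[1]))
        Vb = sigma2 * Ainv
        F = Ainv @ (Ct.T @ Ct)
        edf = np.diag(F)
        self.coef_ = b
        self.omega_ = float(b[1])
        self.se_omega_ = float(np.sqrt(max(Vb[1, 1], 0.0)))
        self.intercept_ = float(b[0])
        self.rho_ = float(rho_hat)
        self.sigma2_ = float(sigma2)
        self.log_lambda_ = float(log_lam)
        #: effective df of the penalized smooth trend columns only; the
        #: unpenalized linear year term is reported separately
        self.edf_trend_ = float(edf[n_fixed:].sum())
        self.edf_linear_year_ = float(edf[2])
        self.reml_ = float(-0.5 * neg2)
        self.converged_ = True
        self.n_obs_ = int(r.size)
        self._design_cache = (C, years, W)
        return self

    def fit(self, X, y):
        """X: array (n, 2) with columns (year, weather driver); y: rates."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidArgumentError("X must have columns (year, weather)")
        return self._fit_core(y, X[:, 1], X[:, 0])

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        C_full, yrs, _ = self._design_cache
        if not np.array_equal(np.asarray(yrs, dtype=float), X[:, 0]):
            raise InvalidArgumentError(
                "prediction supported on the training years only")
        C = C_full.copy()
        C[:, 1] = X[:, 1]
        return C @ self.coef_

    def ci_omega(self, level=0.95):
        z = norm.ppf(0.5 + level / 2)
        return (self.omega_ - z * self.se_omega_,
                self.omega_ + z * self.se_omega_)

    def to_effect(self, record_id="", variable="temperature",
                  driver="anomaly", **meta) -> WeatherEffect:
        return WeatherEffect(
            record_id=record_id, variable=variable, driver=driver,
            omega=self.omega_, se_omega=self.se_omega_,
            intercept=self.intercept_, ar1_rho=self.rho_,
            edf_trend=self.edf_trend_, converged=self.converged_,
            N=self.n_obs_ + 1, **meta)


class WeatherGAMM(_ARSplineBase):
    """Penalized-spline AR(1) regression of growth rate on a weather driver.

    r_t = beta0 + omega * W_t + f(year_t) + e_t, with f a thin-plate-type
    penalized spline (basis dimension ``basis_dim``) plus an unpenalized
    linear year term, and e_t AR(1)-correlated.  ``rho=None`` estimates the
    AR(1) coefficient by REML profiling; a float fixes it.
    """

    _smooth = True

    def __init__(self, basis_dim=5, rho=None, lam_range=(-8.0, 12.0)):
        self.basis_dim = basis_dim
        self.rho = rho
        self.lam_range = lam_range


class WeatherLinearModel(_ARSplineBase):
    """AR(1) GLS fit of r_t = beta0 + omega*W_t + beta_y*year_t (no smooth)."""

    _smooth = False

    def __init__(self, rho=None):
        self.basis_dim = 0
        self.rho = rho
        self.lam_range = (0.0, 0.0)


# ---------------------------------------------------------------------------
# state-space alternative: Kalman-marginalized likelihood + ensemble MCMC

def _kalman_loglik(y, W, omega, sp2, so2, return_filter=False):
    """Exact log-likelihood of the local-level-with-covariate model.

    z_{t+1} = z_t + omega*W_t + N(0, sp2);  y_t = z_t + N(0, so2).
    Initial state: z_1 ~ N(y_1, var(y) + sp2 + so2) (weakly informative).
    """
    T = y.size
    m = y[0]
    P = np.var(y) + sp2 + so2 + 1e-8
    ll = 0.0
    ms = np.empty(T)
    Ps = np.empty(T)
    mp = np.empty(T)
    Pp = np.empty(T)
    for t in range(T):
        if t > 0:
            m = m + omega * W[t - 1]
            P = P + sp2
        mp[t] = m
        Pp[t] = P
        S = P + so2 + 1e-12
        v = y[t] - m
        ll += -0.5 * (np.log(2 * np.pi * S) + v * v / S)
        K = P / S
        m = m + K * v
        P = (1 - K) * P
        ms[t] = m
        Ps[t] = P
    if return_filter:
        return ll, (ms, Ps, mp, Pp)
    return ll


def _rts_smoother(y, W, omega, sp2, so2):
    """Rauch-Tung-Striebel smoothed state means."""
    _, (ms, Ps, mp, Pp) = _kalman_loglik(y, W, omega, sp2, so2,
                                         return_filter=True)
    T = y.size
    sm = ms.copy()
    for t in range(T - 2, -1, -1):
        G = Ps[t] / Pp[t + 1] if Pp[t + 1] > 0 else 0.0
        sm[t] = ms[t] + G * (sm[t + 1] - mp[t + 1])
    return sm


class StateSpaceWeatherModel(BaseEstimator):
    """Bayesian state-space estimate of the weather effect on growth.

    The latent log(abundance+1) follows a random walk with a linear weather
    effect and process noise; observations add measurement noise.  The latent
    path is marginalized exactly (Kalman filter) so only (omega, log sigma_p,
    log sigma_o) are sampled, with an affine-invariant ensemble sampler.
    Convergence is declared when split-R-hat over walker sub-chains < 1.05.
    """

    def __init__(self, n_walkers=16, n_steps=1200, n_burn=600, seed=0,
                 prior_omega_sd=2.0, prior_sigma_sd=1.0):
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.seed = seed
        self.prior_omega_sd = prior_omega_sd
        self.prior_sigma_sd = prior_sigma_sd

    def _log_post(self, theta, y, W):
        omega, lsp, lso = theta
        if abs(omega) > 50 or lsp < -12 or lsp > 4 or lso < -12 or lso > 4:
            return -np.inf
        sp = np.exp(lsp)
        so = np.exp(lso)
        ll = _kalman_loglik(y, W, omega, sp * sp, so * so)
        # half-normal priors on the sds (log-parameterized, + Jacobian)
        lp = (-0.5 * (omega / self.prior_omega_sd) ** 2
              - 0.5 * (sp / self.prior_sigma_sd) ** 2 + lsp
              - 0.5 * (so / self.prior_sigma_sd) ** 2 + lso)
        return ll + lp

    def fit(self, X, y=None):
        """X: array (n, 2) with columns (abundance, weather driver W_t for the
        transition t -> t+1; the last W is unused)."""
        import emcee

        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidArgumentError("X must have columns (abundance, W)")
        abund = X[:, 0]
        W = X[:, 1]
        if abund.size < 6:
            raise InvalidArgumentError("need at least 6 observations")
        if np.std(W[:-1]) == 0:
            raise DegenerateInputError("constant weather driver")
        yobs = np.log(abund + 1.0)
        rng = np.random.default_rng(self.seed)
        # initialize at the OLS solution of the growth-rate regression so the
        # ensemble starts near the likelihood ridge (matters in the
        # near-deterministic limit where the posterior is extremely sharp)
        dy = np.diff(yobs)
        Wt = W[:-1]
        omega0 = float((Wt - Wt.mean()) @ (dy - dy.mean())
                       / ((Wt - Wt.mean()) @ (Wt - Wt.mean())))
        sd0 = max(float(np.std(dy - omega0 * Wt)), 1e-3)
        p0 = np.column_stack([
            omega0 + rng.normal(0, 0.05 + 0.1 * sd0, self.n_walkers),
            np.log(sd0) + rng.normal(0, 0.3, self.n_walkers),
            np.log(sd0) + rng.normal(0, 0.3, self.n_walkers),
        ])
        sampler = emcee.EnsembleSampler(
            self.n_walkers, 3, self._log_post, args=(yobs, W))
        sampler.random_state = np.random.RandomState(self.seed)
        sampler.run_mcmc(p0, self.n_steps, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain()[self.n_burn:]          # (draws, walkers, 3)
        draws = np.moveaxis(chain, 0, 1)                   # (walkers, draws, 3)
        self.draws_ = draws
        self.omega_ = float(draws[..., 0].mean())
        self.se_omega_ = float(draws[..., 0].std())
        self.sigma_process_ = float(np.exp(draws[..., 1]).mean())
        self.sigma_obs_ = float(np.exp(draws[..., 2]).mean())
        self.rhat_ = self._rhat(draws[..., 0])
        self.converged_ = bool(self.rhat_ < 1.05)
        self._data = (yobs, W)
        self.n_obs_ = int(abund.size)
        return self

    @staticmethod
    def _rhat(x):
        import arviz as az
        return float(az.rhat(az.convert_to_dataset(x))["x"].values)

    def predict(self, X=None):
        """Posterior-mean smoothed abundance (fit-to-sample prediction)."""
        yobs, W = self._data
        sm = _rts_smoother(yobs, W, self.omega_,
                           self.sigma_process_ ** 2, self.sigma_obs_ ** 2)
        return np.exp(sm) - 1.0

    def fit_to_sample(self):
        """Pearson correlation of smoothed predictions with observations."""
        yobs, _ = self._data
        sm = _rts_smoother(yobs, self._data[1], self.omega_,
                           self.sigma_process_ ** 2, self.sigma_obs_ ** 2)
        return float(np.corrcoef(sm, yobs)[0, 1])

    def to_effect(self, record_id="", variable="temperature",
                  driver="anomaly", **meta) -> WeatherEffect:
        return WeatherEffect(
            record_id=record_id, variable=variable, driver=driver,
            omega=self.omega_, se_omega=self.se_omega_, intercept=0.0,
            ar1_rho=0.0, edf_trend=0.0, converged=self.converged_,
            N=self.n_obs_, **meta)


# ---------------------------------------------------------------------------
# functional wrappers and batch driver

def fit_weather_gamm(r, W, years, basis_dim=5, rho=None) -> WeatherEffect:
    est = WeatherGAMM(basis_dim=basis_dim, rho=rho)
    est._fit_core(r, W, years)
    return est.to_effect()


def fit_weather_linear(r, W, years, rho=None) -> WeatherEffect:
    est = WeatherLinearModel(rho=rho)
    est._fit_core(r, W, years)
    return est.to_effect()


def fit_weather_statespace(abundance, W, mcmc=None) -> WeatherEffect:
    est = StateSpaceWeatherModel(**(mcmc or {}))
    est.fit(np.column_stack([abundance, W]))
    return est.to_effect()


def effect_batch(growth_series, annual_weather, records_meta=None,
                 variables=("temp", "precip"), driver="anomaly",
                 basis_dim=5, estimator="gamm"):
    """One WeatherEffect per record x variable for a batch of growth series.

    ``growth_series``: list of GrowthRateSeries; ``annual_weather``: long
    frame (record_id, variable, year, anomaly, variance); ``records_meta``:
    optional dict record_id -> dict(species=..., biome=..., lat=..., lon=...).
    Records whose weather is missing for some year, or whose driver is
    degenerate, are skipped and logged.  Returns (effects, skip_log).
    """
    var_name = {"temp": "temperature", "precip": "precipitation"}
    col = "anomaly" if driver == "anomaly" else "variance"
    effects, skipped = [], []
    wx = annual_weather.set_index(
        ["record_id", "variable", "year"])[col].sort_index()
    for gs in growth_series:
        base_rid = gs.record_id.split("_b")[0]
        for var in variables:
            try:
                W = wx.loc[(base_rid, var)].reindex(gs.years).to_numpy()
            except KeyError:
                skipped.append({"record_id": gs.record_id, "variable": var,
                                "reason": "no weather for record"})
                continue
            if np.any(~np.isfinite(W)):
                skipped.append({"record_id": gs.record_id, "variable": var,
                                "reason": "missing weather year"})
                continue
            if driver == "variance":
                sd = W.std(ddof=1)
                if sd == 0:
                    skipped.append({"record_id": gs.record_id, "variable": var,
                                    "reason": "degenerate driver"})
                    continue
                W = (W - W.mean()) / sd
            meta = (records_meta or {}).get(base_rid, {})
            try:
                if estimator == "gamm":
                    eff = fit_weather_gamm(gs.r, W, gs.years,
                                           basis_dim=basis_dim)
                else:
                    eff = fit_weather_linear(gs.r, W, gs.years)
            except DegenerateInputError as exc:
                skipped.append({"record_id": gs.record_id, "variable": var,
                                "reason": f"degenerate input: {exc}"})
                continue
            eff.record_id = gs.record_id
            eff.variable = var_name.get(var, var)
            eff.driver = driver
            eff.N = gs.n_years
            for k, v in meta.items():
                setattr(eff, k, v)
            effects.append(eff)
    for s in skipped:
        logger.info("skipped %(record_id)s/%(variable)s: %(reason)s", s)
    return effects, skipped
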