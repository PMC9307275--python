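"""Synthetic data generator: phylogeny, life history, weather, abundance and
ground-truth weather effects with known parameters.

The generator emulates the structure of a global mammal-abundance compilation
paired with gridded monthly weather: ≥10-year annual abundance records with
AR(1)/density-dependent dynamics and a linear weather forcing, monthly weather
with period-12 seasonality, a slow trend and injected anomalies, log-normal
life-history traits with the fast-slow correlation pattern (longevity rises
with body mass, falls with litter size), and record-level true weather effects
drawn from the hierarchical phylogenetic meta-regression structure that the
inference modules are later asked to recover.  Every ground-truth quantity is
stored alongside the generated data so recovery tests never re-derive truth
from outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, NumericFailureError

__all__ = [
    "WorldConfig", "TrueEffects", "SyntheticWorld",
    "simulate_phylogeny", "simulate_life_history", "simulate_monthly_weather",
    "simulate_true_effects", "simulate_abundance", "simulate_growth_series",
    "simulate_world",
]

#: default trait correlations on the log scale (fast-slow continuum pattern)
DEFAULT_TRAIT_CORR = {
    ("longevity", "body_mass"): 0.7,
    ("longevity", "litter_size"): -0.5,
    ("body_mass", "litter_size"): -0.4,
}


@dataclass
class WorldConfig:
    """Parameters of one synthetic world.

    Effect-structure parameters mirror the meta-regression: record effect
    omega_i = alpha_bar + g_phylo[species] + a_species[species]
    + beta_N * N_z + eps_i, with g_phylo ~ MVN(0, sigma_phylo^2 V),
    a_species ~ N(0, sigma_species^2) and eps ~ N(0, effect_resid_sd^2).
    """

    n_species: int = 157
    records_per_species: tuple = (1, 5)      # uniform int range, mean ~3
    years_per_record: tuple = (10, 35)       # support; lengths are 10+geometric
    record_length_p: float = 0.18            # geometric p; mean length ~15
    weather_years: tuple = (1979, 2013)
    alpha_bar: float = 0.02
    sigma_phylo: float = 0.1                 # sd; variance 0.01
    sigma_species: float = 0.447             # sd; variance ~0.2
    effect_resid_sd: float = 0.85            # record-level residual sd
    beta_N: float = 0.12                     # record-length slope (z-scored N)
    lh_slopes: tuple = (-0.20, 0.16, -0.02)  # longevity, litter, body mass
    gamma_intercept: float = -0.25           # log-scale intercept, |omega| model
    gamma_beta_N: float = -0.30
    gamma_shape: float = 1.5
    gamma_sigma_phylo: float = 0.1
    gamma_sigma_species: float = 0.3
    dd_strength: float = 0.0
    process_sd: float = 0.2
    obs_sd: float = 0.0
    base_abundance: float = 200.0
    seasonal_amp: float = 1.0
    trend_slope: float = 0.002               # per month, pre-z-scoring units
    anomaly_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_phylo, self.sigma_species, self.effect_resid_sd,
               self.process_sd, self.obs_sd, self.anomaly_sd) < 0:
            raise InvalidArgumentError("standard deviations must be >= 0")
        if not 0 <= self.dd_strength < 1:
            raise InvalidArgumentError("dd_strength must be in [0, 1)")
        if self.years_per_record[0] < 2:
            raise InvalidArgumentError("years_per_record min must be >= 2")


@dataclass
class TrueEffects:
    """Ground-truth record effects and their hierarchical components."""

    record_id: list
    species: list
    n_years: np.ndarray
    omega: np.ndarray               # per-record true effect
    phylo_deviation: np.ndarray     # per-record g_phylo[species]
    species_intercept: np.ndarray   # per-record a_species[species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "record_id": self.record_id, "species": self.species,
            "n_years": self.n_years, "omega": self.omega,
            "phylo_deviation": self.phylo_deviation,
            "species_intercept": self.species_intercept,
        })


def simulate_phylogeny(n_species, seed=0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with tips sp_001..sp_N, depth 1.

    Lineages split at exponential waiting times until ``n_species`` are
    reached; all tips extend to the present and the root-to-tip depth is
    normalized to 1.
    """
    if n_species < 2:
        raise InvalidArgumentError("need at least 2 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages: (node, birth_time)
    root = tree.seed_node
    t = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t))
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(len(active))
        node, birth = active.pop(k)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_final = t + rng.exponential(1.0 / len(active))
    labels = [f"sp_{i + 1:03d}" for i in range(n_species)]
    rng.shuffle(labels)
    for (node, birth), label in zip(active, labels):
        node.edge.length = t_final - birth
        node.taxon = taxa.new_taxon(label)
    # normalize root-to-tip depth to 1
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_final
    return tree


def simulate_life_history(tree, seed=0, corr=None, n_species=None,
                          log_means=(4.2, 1.0, 7.0), log_sds=(1.0, 0.6, 2.0)):
    """Correlated log-normal life-history traits per species.

    Traits: maximum longevity (months), mean litter size (count, floored at
    1), adult body mass (g).  ``corr`` maps trait pairs to log-scale
    correlations (defaults follow the fast-slow pattern).  Returns a frame
    with raw traits and z-scored-log traits (columns ``z_*``).
    """
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter()) \
        if tree is not None else [f"sp_{i + 1:03d}" for i in range(n_species)]
    if len(species) < 2:
        raise InvalidArgumentError("need at least 2 species")
    corr = dict(DEFAULT_TRAIT_CORR) if corr is None else dict(corr)
    order = ["longevity", "litter_size", "body_mass"]
    C = np.eye(3)
    for (a, b), rho in corr.items():
        i, j = order.index(a), order.index(b)
        C[i, j] = C[j, i] = rho
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError(
            "requested trait correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(species), 3)) @ L.T
    mu = np.array([log_means[0], log_means[1], log_means[2]])
    sd = np.array([log_sds[0], log_sds[1], log_sds[2]])
    logs = mu + sd * z
    longevity = np.exp(logs[:, 0])
    litter = np.maximum(1.0, np.exp(logs[:, 1]))
    mass = np.exp(logs[:, 2])
    df = pd.DataFrame({"species": species, "longevity_mo": longevity,
                       "litter_size": litter, "body_mass_g": mass})
    for col, name in [("longevity_mo", "z_longevity"),
                      ("litter_size", "z_litter"),
                      ("body_mass_g", "z_body_mass")]:
        lx = np.log(df[col].to_numpy())
        df[name] = (lx - lx.mean()) / lx.std(ddof=1)
    return df


@dataclass
class MonthlyWeather:
    """One synthetic monthly series plus its injected ground truth."""

    years: np.ndarray
    months: np.ndarray
    values: np.ndarray
    true_annual_anomaly: np.ndarray   # per-year mean of injected noise
    annual_years: np.ndarray


def simulate_monthly_weather(years, seasonal_amp=1.0, trend_slope=0.002,
                             anomaly_sd=1.0, base_mean=10.0, seed=0
                             ) -> MonthlyWeather:
    """Monthly series = mean + seasonal sine + linear trend + iid anomalies.

    ``years`` is either an int (number of years) or a (first, last) calendar
    interval.  The per-year means of the injected anomaly draws are stored as
    ground truth for recovery tests.
    """
    if anomaly_sd < 0:
        raise InvalidArgumentError("anomaly_sd must be >= 0")
    if np.isscalar(years):
        yr = np.arange(2000, 2000 + int(years))
    else:
        yr = np.arange(years[0], years[1] + 1)
    if yr.size < 10:
        raise InvalidArgumentError("need at least 10 years of weather")
    n = yr.size * 12
    year_col = np.repeat(yr, 12)
    month_col = np.tile(np.arange(1, 13), yr.size)
    t = np.arange(n)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, anomaly_sd, n) if anomaly_sd > 0 else np.zeros(n)
    values = (base_mean + seasonal_amp * np.sin(2 * np.pi * month_col / 12)
              + trend_slope * t + noise)
    true_anom = noise.reshape(yr.size, 12).mean(axis=1)
    return MonthlyWeather(years=year_col, months=month_col, values=values,
                          true_annual_anomaly=true_anom, annual_years=yr)


def _species_effects(V, sigma_phylo, sigma_species, n_species, rng):
    """Draw per-species phylogenetic deviations and intercepts."""
    if V is None:
        V = np.eye(n_species)
    w, U = np.linalg.eigh(V)
    if w.min() < -1e-8:
        raise NumericFailureError("phylogenetic correlation matrix is not PSD")
    L = U * np.sqrt(np.clip(w, 0.0, None))
    g = sigma_phylo * (L @ rng.standard_normal(n_species))
    a = sigma_species * rng.standard_normal(n_species)
    return g, a


def simulate_true_effects(layout, config: WorldConfig, V=None,
                          species_order=None, traits=None, model="gaussian",
                          rng=None) -> TrueEffects:
    """Draw ground-truth record effects from the hierarchical structure.

    ``layout`` is a frame with record_id, species, n_years.  With
    ``model='gaussian'`` the signed effect is alpha_bar + g + a + beta_N*N_z
    + resid.  With ``model='gamma'`` the magnitude |omega| is Gamma with
    log-mean gamma_intercept + lh_slopes . traits + gamma_beta_N*N_z + g + a,
    and a random sign is attached.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    species = sorted(layout["species"].unique()) if species_order is None \
        else list(species_order)
    sp_idx = layout["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    n_rec = len(layout)
    n_years = layout["n_years"].to_numpy()
    n_sd = n_years.std(ddof=1) if n_rec > 1 else 0.0
    N_z = (n_years - n_years.mean()) / (n_sd if n_sd > 0 else 1.0)
    if model == "gaussian":
        g, a = _species_effects(V, config.sigma_phylo, config.sigma_species,
                                len(species), rng)
        omega = (config.alpha_bar + g[sp_idx] + a[sp_idx]
                 + config.beta_N * N_z
                 + config.effect_resid_sd * rng.standard_normal(n_rec))
    elif model == "gamma":
        g, a = _species_effects(V, config.gamma_sigma_phylo,
                                config.gamma_sigma_species, len(species), rng)
        log_mu = config.gamma_intercept + g[sp_idx] + a[sp_idx] \
            + config.gamma_beta_N * N_z
        if traits is not None:
            tr = traits.set_index("species").loc[
                layout["species"], ["z_longevity", "z_litter", "z_body_mass"]
            ].to_numpy()
            log_mu = log_mu + tr @ np.asarray(config.lh_slopes)
        mu = np.exp(log_mu)
        mag = rng.gamma(config.gamma_shape, mu / config.gamma_shape)
        omega = np.where(rng.random(n_rec) < 0.5, -1.0, 1.0) * mag
    else:
        raise InvalidArgumentError(f"unknown effect model {model!r}")
    return TrueEffects(
        record_id=list(layout["record_id"]), species=list(layout["species"]),
        n_years=n_years, omega=omega, phylo_deviation=g[sp_idx],
        species_intercept=a[sp_idx])


def simulate_abundance(T, true_omega, anomalies, dd_strength=0.0,
                       process_sd=0.0, obs_model="none", obs_sd=0.0,
                       x0=np.log(200.0), seed=0, rng=None):
    """Log-abundance random walk with weather forcing and optional
    mean-reverting density dependence (Gompertz-type pullback).

    x_{t+1} = x_t - dd_strength*(x_t - x0) + true_omega*W_t + N(0, process_sd^2)

    ``obs_model='lognormal_round'`` adds log-normal observation noise and
    rounds to the nearest non-negative integer (zeros possible); ``'none'``
    reports exp(x) exactly.  Returns (abundance, latent_log_abundance).
    """
    anomalies = np.asarray(anomalies, dtype=float)
    if T < 2:
        raise InvalidArgumentError("need T >= 2")
    if anomalies.size < T - 1:
        raise InvalidArgumentError("need at least T-1 anomaly values")
    if process_sd < 0 or obs_sd < 0:
        raise InvalidArgumentError("noise sds must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    x = np.empty(T)
    x[0] = x0
    shocks = rng.normal(0.0, process_sd, T - 1) if process_sd > 0 else np.zeros(T - 1)
    for t in range(T - 1):
        x[t + 1] = (x[t] - dd_strength * (x[t] - x0)
                    + true_omega * anomalies[t] + shocks[t])
    if obs_model == "none":
        abundance = np.exp(x)
    elif obs_model == "lognormal_round":
        noisy = np.exp(x + rng.normal(0.0, obs_sd, T))
        abundance = np.maximum(0.0, np.round(noisy))
    else:
        raise InvalidArgumentError(f"unknown obs_model {obs_model!r}")
    return abundance, x


def simulate_growth_series(T, omega=1.0, noise_sd=0.2, rho=0.0, seed=0,
                           rng=None, weather_sd=1.0):
    """Directly simulate a growth-rate series r_t = omega*W_t + AR(1) noise.

    Estimator-calibration harness: W_t are iid standard-normal-ish annual
    anomalies (sd ``weather_sd``), the noise is a stationary AR(1) with
    marginal sd ``noise_sd`` and lag-1 correlation ``rho``.  Returns
    (years, W, r).
    """
    if not -1 < rho < 1:
        raise InvalidArgumentError("rho must be in (-1, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    W = rng.normal(0.0, weather_sd, T)
    e = np.empty(T)
    e[0] = rng.normal(0.0, noise_sd)
    innov_sd = noise_sd * np.sqrt(1 - rho ** 2)
    for t in range(1, T):
        e[t] = rho * e[t - 1] + rng.normal(0.0, innov_sd)
    years = np.arange(2000, 2000 + T)
    return years, W, omega * W + e


#: biome labels used by the synthetic world (13 categories)
BIOMES = [f"biome_{i:02d}" for i in range(1, 14)]


@dataclass
class SyntheticWorld:
    """A complete generated dataset plus its ground truth."""

    config: WorldConfig
    tree: dendropy.Tree
    traits: pd.DataFrame
    records: pd.DataFrame      # record_id, species, biome, lat, lon, year, abundance
    weather: pd.DataFrame      # record_id, year, month, temp, precip
    truth: dict = field(default_factory=dict)

    def write(self, outdir):
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.weather.to_csv(outdir / "weather.csv", index=False)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        self.tree.write(path=str(outdir / "tree.nwk"), schema="newick")
        truth = {k: (v.to_dict(orient="list") if isinstance(v, pd.DataFrame)
                     else v) for k, v in self.truth.items()}
        truth["config"] = asdict(self.config)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)


def _record_layout(config: WorldConfig, rng) -> pd.DataFrame:
    lo, hi = config.records_per_species
    tmin, tmax = config.years_per_record
    rows = []
    rid = 0
    for i in range(config.n_species):
        sp = f"sp_{i + 1:03d}"
        for _ in range(int(rng.integers(lo, hi + 1))):
            rid += 1
            T = int(min(tmax, tmin + rng.geometric(config.record_length_p) - 1))
            rows.append({"record_id": f"rec_{rid:04d}", "species": sp,
                         "n_years": T})
    return pd.DataFrame(rows)


def simulate_world(config: WorldConfig, effect_model="gaussian") -> SyntheticWorld:
    """Generate a full dataset: tree, traits, per-record weather, abundance.

    Each record gets its own monthly weather over the full weather window;
    abundance is forced by the record's *standardized* true annual anomalies
    (anomaly divided by its sd), so the generative omega is expressed per
    standardized anomaly unit, the same scale on which it is later estimated.
    """
    from .phylo import brownian_correlation

    rng = np.random.default_rng(config.seed)
    tree = simulate_phylogeny(config.n_species,
                              seed=rng.integers(2 ** 31))
    traits = simulate_life_history(tree, seed=rng.integers(2 ** 31))
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    V = brownian_correlation(tree, species).V
    layout = _record_layout(config, rng)
    effects = simulate_true_effects(layout, config, V=V,
                                    species_order=species, traits=traits,
                                    model=effect_model, rng=rng)
    y0, y1 = config.weather_years
    rec_rows, weather_rows = [], []
    anomaly_truth = {}
    for k in range(len(layout)):
        rid = layout["record_id"].iloc[k]
        T = int(layout["n_years"].iloc[k])
        start = int(rng.integers(y0, y1 - T + 2))
        yrs = np.arange(start, start + T)
        temp = simulate_monthly_weather(
            (y0, y1), seasonal_amp=config.seasonal_amp,
            trend_slope=config.trend_slope, anomaly_sd=config.anomaly_sd,
            base_mean=rng.normal(10, 8), seed=rng.integers(2 ** 31))
        precip = simulate_monthly_weather(
            (y0, y1), seasonal_amp=0.6 * config.seasonal_amp,
            trend_slope=0.0, anomaly_sd=config.anomaly_sd,
            base_mean=rng.normal(80, 20), seed=rng.integers(2 ** 31))
        anom_sd = temp.true_annual_anomaly.std(ddof=1)
        W_std = temp.true_annual_anomaly / (anom_sd if anom_sd > 0 else 1.0)
        sel = np.isin(temp.annual_years, yrs[:-1])
        abundance, x = simulate_abundance(
            T, effects.omega[k], W_std[sel],
            dd_strength=config.dd_strength, process_sd=config.process_sd,
            obs_model="lognormal_round" if config.obs_sd > 0 else "none",
            obs_sd=config.obs_sd, x0=np.log(config.base_abundance), rng=rng)
        biome = BIOMES[int(rng.integers(len(BIOMES)))]
        lat = float(rng.uniform(-60, 70))
        lon = float(rng.uniform(-180, 180))
        for y, ab in zip(yrs, abundance):
            rec_rows.append({"record_id": rid, "species": layout["species"].iloc[k],
                             "biome": biome, "lat": lat, "lon": lon,
                             "year": int(y), "abundance": float(ab)})
        weather_rows.append(pd.DataFrame({
            "record_id": rid, "year": temp.years, "month": temp.months,
            "temp": temp.values, "precip": precip.values}))
        anomaly_truth[rid] = {"years": temp.annual_years.tolist(),
                              "annual_anomaly": temp.true_annual_anomaly.tolist()}
    records = pd.DataFrame(rec_rows)
    weather = pd.concat(weather_rows, ignore_index=True)
    truth = {"effects": effects.to_frame(), "anomalies": anomaly_truth}
    return SyntheticWorld(config=config, tree=tree, traits=traits,
                          records=records, weather=weather, truth=truth)
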