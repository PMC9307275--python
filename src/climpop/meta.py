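"""Bayesian phylogenetic meta-regressions over record-level weather effects.

Stage 2 of the framework.  The *directional* question — is the average
population response to weather anomalies different from zero? — is addressed
with a Gaussian model of the (z-scored) record coefficients omega:

    omega_i ~ Normal(mu_i, sigma_resid)
    mu_i = alpha_bar + a_SPECIES[j(i)] + g_PHYLO[j(i)] + beta_BIOME[b(i)] + beta_N N_i
    g_PHYLO ~ MVNormal(0, sigma2_phylo V),   a_SPECIES ~ Normal(0, sigma2_species)

with V the Brownian phylogenetic correlation matrix.  The *magnitude*
question — does life history predict how strongly a population responds,
regardless of direction? — uses a Gamma model with a log link on |omega|,
with linear z-scored-log life-history terms chosen by PSIS-LOO model
selection.  Both posteriors are sampled by Hamiltonian Monte Carlo with
analytic gradients and non-centered random effects (Cholesky factor of V).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .errors import DegenerateInputError, InvalidArgumentError
from .hmc import sample_hmc

__all__ = [
    "PriorSet", "MetaDataset", "ModelSpec", "PosteriorSummary",
    "ModelComparison", "standardize_effects", "build_meta_dataset",
    "GaussianMetaRegression", "GammaMetaRegression", "candidate_models",
    "fit_gaussian_meta", "fit_gamma_meta", "loo_compare", "prior_predictive",
    "diagnostics", "morans_i", "marginal_predictions", "fold_change",
]

TRAITS = ("longevity", "litter", "body_mass")
_TRAIT_COL = {"longevity": "z_longevity", "litter": "z_litter",
              "body_mass": "z_body_mass"}


@dataclass
class PriorSet:
    """Regularizing priors; rates follow the rate parameterization
    (Exponential(8) has mean 1/8)."""

    alpha_bar_sd: float = 0.3
    beta_biome_sd: float = 0.3
    beta_N_sd: float = 0.5
    beta_lh_sd: float = 0.2
    sigma2_phylo_rate: float = 8.0
    sigma2_species_rate: float = 8.0
    resid_sd_rate: float = 8.0
    eta_shape: float = 2.0
    eta_rate: float = 0.6

    @classmethod
    def gaussian_default(cls):
        return cls()

    @classmethod
    def gamma_default(cls):
        return cls(beta_N_sd=0.2, sigma2_phylo_rate=11.0)


@dataclass
class ModelSpec:
    """A life-history model: main-effect traits and 2-way interactions."""

    name: str
    terms: tuple = ()
    interactions: tuple = ()   # tuples of trait-name pairs

    def columns(self):
        cols = [_TRAIT_COL[t] for t in self.terms]
        cols += [f"{_TRAIT_COL[a]}:{_TRAIT_COL[b]}" for a, b in self.interactions]
        return cols

    def design(self, lh_z: pd.DataFrame) -> np.ndarray:
        cols = [lh_z[_TRAIT_COL[t]].to_numpy() for t in self.terms]
        cols += [lh_z[_TRAIT_COL[a]].to_numpy() * lh_z[_TRAIT_COL[b]].to_numpy()
                 for a, b in self.interactions]
        if not cols:
            return np.empty((len(lh_z), 0))
        return np.column_stack(cols)


def candidate_models(traits=TRAITS):
    """The default 10-model set: base, 3 univariate, 3 pairwise-additive,
    full additive, and 2 interaction models."""
    L, S, M = traits
    specs = [
        ModelSpec("base"),
        ModelSpec("longevity", (L,)),
        ModelSpec("litter", (S,)),
        ModelSpec("body_mass", (M,)),
        ModelSpec("longevity+litter", (L, S)),
        ModelSpec("longevity+body_mass", (L, M)),
        ModelSpec("litter+body_mass", (S, M)),
        ModelSpec("additive", (L, S, M)),
        ModelSpec("longevity_x_litter", (L, S), ((L, S),)),
        ModelSpec("additive_interactions", (L, S, M), ((L, S), (L, M), (S, M))),
    ]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise InvalidArgumentError("duplicate model specs")
    return specs


@dataclass
class MetaDataset:
    """Stage-2 input: effects with species, biome, record length, traits, V."""

    omega: np.ndarray            # response (z-scored for the default pipeline)
    abs_omega: np.ndarray        # |omega| floored at 1e-8, Gamma response
    species: list                # unique species order matching V
    species_idx: np.ndarray
    biome_levels: list
    biome_idx: np.ndarray
    N_z: np.ndarray
    lh_z: pd.DataFrame           # per record: z_longevity, z_litter, z_body_mass
    V: np.ndarray
    coords: np.ndarray = None    # (n, 2) lat, lon
    record_id: list = field(default_factory=list)

    @property
    def n_records(self):
        return self.omega.size

    @property
    def n_species(self):
        return len(self.species)

    def biome_design(self):
        """Treatment coding, most frequent biome as reference."""
        counts = np.bincount(self.biome_idx, minlength=len(self.biome_levels))
        ref = int(np.argmax(counts))
        others = [i for i in range(len(self.biome_levels)) if i != ref]
        B = np.zeros((self.n_records, len(others)))
        for k, lev in enumerate(others):
            B[self.biome_idx == lev, k] = 1.0
        names = [f"beta_biome[{self.biome_levels[i]}]" for i in others]
        return B, names, self.biome_levels[ref]


def standardize_effects(omega, floor=1e-8):
    """z-score effects across records; |z| floored for the Gamma response."""
    omega = np.asarray(omega, dtype=float)
    if omega.size < 2:
        raise DegenerateInputError("need at least 2 effects")
    sd = omega.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant effects cannot be standardized")
    z = (omega - omega.mean()) / sd
    return z, np.maximum(np.abs(z), floor)


def build_meta_dataset(effects_df: pd.DataFrame, traits: pd.DataFrame,
                       phylo, synonym_map=None, standardize=True) -> MetaDataset:
    """Assemble a MetaDataset from an effects table (one weather variable).

    ``effects_df`` columns: record_id, species, biome, omega, N (+ lat, lon).
    ``phylo`` is a PhyloCorrelation covering (at least) the species present.
    """
    from .phylo import brownian_correlation  # noqa: F401  (doc pointer)
    from .phylo import match_species

    df = effects_df.reset_index(drop=True)
    full_idx = match_species(df["species"], phylo, synonym_map)
    present = sorted(set(full_idx))
    sub_pos = {p: k for k, p in enumerate(present)}
    species = [phylo.species_order[p] for p in present]
    V = phylo.V[np.ix_(present, present)]
    species_idx = np.array([sub_pos[p] for p in full_idx])
    omega_raw = df["omega"].to_numpy(dtype=float)
    if standardize:
        omega, abs_omega = standardize_effects(omega_raw)
    else:
        omega = omega_raw
        abs_omega = np.maximum(np.abs(omega_raw), 1e-8)
    N = df["N"].to_numpy(dtype=float)
    N_z = (N - N.mean()) / (N.std(ddof=1) if N.std(ddof=1) > 0 else 1.0)
    biome_levels = sorted(df["biome"].astype(str).unique())
    biome_idx = df["biome"].astype(str).map(
        {b: i for i, b in enumerate(biome_levels)}).to_numpy()
    tr = traits.set_index("species")
    lh_cols = ["z_longevity", "z_litter", "z_body_mass"]
    resolved = df["species"].map(lambda s: (synonym_map or {}).get(s, s))
    lh_z = tr.reindex(resolved)[lh_cols].reset_index(drop=True)
    coords = (df[["lat", "lon"]].to_numpy(dtype=float)
              if {"lat", "lon"} <= set(df.columns) else None)
    return MetaDataset(
        omega=omega, abs_omega=abs_omega, species=species,
        species_idx=species_idx, biome_levels=biome_levels,
        biome_idx=biome_idx, N_z=N_z, lh_z=lh_z, V=V, coords=coords,
        record_id=list(df["record_id"]))


@dataclass
class PosteriorSummary:
    """Posterior means, sds, 95% credible intervals and diagnostics."""

    table: pd.DataFrame          # index: parameter; mean, sd, q2.5, q97.5, rhat, ess
    idata: object                # arviz InferenceData (draws + log_likelihood)
    converged: bool
    model: str = ""
    spec: ModelSpec = None

    def __getitem__(self, name):
        return self.table.loc[name]

    def mean(self, name):
        return float(self.table.loc[name, "mean"])

    def ci(self, name, level=0.95):
        lo = f"q{100 * (0.5 - level / 2):g}"
        hi = f"q{100 * (0.5 + level / 2):g}"
        return float(self.table.loc[name, lo]), float(self.table.loc[name, hi])


def _summarize(idata, converged, model, spec=None) -> PosteriorSummary:
    post = idata.posterior
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(post)
        es = az.ess(post)
    for name in post.data_vars:
        arr = post[name].values  # (chain, draw, ...) or (chain, draw)
        flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
        for k in range(flat.shape[1]):
            pname = name if flat.shape[1] == 1 else f"{name}[{k}]"
            x = flat[:, k]
            rv = np.atleast_1d(rh[name].values)[k]
            ev = np.atleast_1d(es[name].values)[k]
            rows.append({"parameter": pname, "mean": x.mean(), "sd": x.std(),
                         "q2.5": np.quantile(x, 0.025),
                         "q97.5": np.quantile(x, 0.975),
                         "rhat": float(rv), "ess": float(ev)})
    table = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(table=table, idata=idata, converged=converged,
                            model=model, spec=spec)


def _chol_V(V, jitter=1e-10):
    try:
        return np.linalg.cholesky(V + jitter * np.eye(V.shape[0]))
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(V)
        raise DegenerateInputError(
            f"V is not positive semi-definite (min eigenvalue {w.min():.3g})")


class _MetaBase:
    """Shared packing/posterior plumbing for the two meta-regressions."""

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self._param_names:
                raise InvalidArgumentError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _sample(self, logp_and_grad, init, dim):
        res = sample_hmc(
            logp_and_grad, init, n_chains=self.n_chains,
            n_warmup=self.n_warmup, n_draws=self.n_draws, seed=self.seed,
            target_accept=self.target_accept, traj_length=self.traj_length,
            max_steps=self.max_steps)
        return res


@dataclass
class _Layout:
    names: list
    slices: dict

    @classmethod
    def build(cls, blocks):
        names, slices, pos = [], {}, 0
        for name, size in blocks:
            slices[name] = slice(pos, pos + size)
            names.append(name)
            pos += size
        lay = cls(names=names, slices=slices)
        lay.dim = pos
        return lay

    def get(self, theta, name):
        return theta[..., self.slices[name]]


class GaussianMetaRegression(_MetaBase):
    """Directional weather-effect meta-regression (Gaussian response).

    Fits omega ~ Normal(mu, sigma_resid) with a global intercept, biome
    effects (treatment coding), a record-length slope, a non-phylogenetic
    species intercept and a Brownian phylogenetic species effect.  Priors and
    sampler settings are constructor parameters; results are exposed as
    ``summary_`` (PosteriorSummary) after :meth:`fit`.
    """

    _param_names = ["priors", "include_biome", "n_chains", "n_warmup",
                    "n_draws", "seed", "target_accept", "traj_length",
                    "max_steps"]

    def __init__(self, priors=None, include_biome=True, n_chains=3,
                 n_warmup=1000, n_draws=1000, seed=0, target_accept=0.9,
                 traj_length=2.0, max_steps=64):
        self.priors = priors or PriorSet.gaussian_default()
        self.include_biome = include_biome
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed
        self.target_accept = target_accept
        self.traj_length = traj_length
        self.max_steps = max_steps

    def fit(self, data: MetaDataset):
        pr = self.priors
        y = data.omega
        n = y.size
        S = data.n_species
        sp = data.species_idx
        Lv = _chol_V(data.V)
        if self.include_biome and len(data.biome_levels) > 1:
            B, biome_names, ref = data.biome_design()
        else:
            B = np.zeros((n, 0))
            biome_names, ref = [], None
        nb = B.shape[1]
        Nz = data.N_z
        lay = _Layout.build([
            ("alpha_bar", 1), ("beta_biome", nb), ("beta_N", 1),
            ("log_v_phylo", 1), ("log_v_species", 1), ("log_sigma_resid", 1),
            ("z_phylo", S), ("z_species", S)])

        a_sd2 = pr.alpha_bar_sd ** 2
        b_sd2 = pr.beta_biome_sd ** 2
        n_sd2 = pr.beta_N_sd ** 2

        def logp_and_grad(th):
            alpha = th[lay.slices["alpha_bar"]][0]
            bb = th[lay.slices["beta_biome"]]
            bN = th[lay.slices["beta_N"]][0]
            pP = th[lay.slices["log_v_phylo"]][0]
            pS = th[lay.slices["log_v_species"]][0]
            pR = th[lay.slices["log_sigma_resid"]][0]
            zP = th[lay.slices["z_phylo"]]
            zS = th[lay.slices["z_species"]]
            vP, vS = np.exp(pP), np.exp(pS)
            sR = np.exp(pR)
            sP, sS = np.sqrt(vP), np.sqrt(vS)
            LzP = Lv @ zP
            sp_eff = sP * LzP + sS * zS
            mu = alpha + B @ bb + bN * Nz + sp_eff[sp]
            resid = y - mu
            inv2 = 1.0 / (sR * sR)
            ll = -0.5 * n * np.log(2 * np.pi * sR * sR) \
                - 0.5 * inv2 * resid @ resid
            lp = ll \
                - 0.5 * alpha * alpha / a_sd2 \
                - 0.5 * bb @ bb / b_sd2 \
                - 0.5 * bN * bN / n_sd2 \
                - pr.sigma2_phylo_rate * vP + pP \
                - pr.sigma2_species_rate * vS + pS \
                - pr.resid_sd_rate * sR + pR \
                - 0.5 * zP @ zP - 0.5 * zS @ zS
            g = np.empty_like(th)
            r = resid * inv2
            s_r = np.bincount(sp, weights=r, minlength=S)
            g[lay.slices["alpha_bar"]] = r.sum() - alpha / a_sd2
            g[lay.slices["beta_biome"]] = B.T @ r - bb / b_sd2
            g[lay.slices["beta_N"]] = Nz @ r - bN / n_sd2
            g[lay.slices["z_phylo"]] = sP * (Lv.T @ s_r) - zP
            g[lay.slices["z_species"]] = sS * s_r - zS
            g[lay.slices["log_v_phylo"]] = (
                0.5 * sP * (s_r @ LzP) - pr.sigma2_phylo_rate * vP + 1.0)
            g[lay.slices["log_v_species"]] = (
                0.5 * sS * (s_r @ zS) - pr.sigma2_species_rate * vS + 1.0)
            g[lay.slices["log_sigma_resid"]] = (
                -n + inv2 * resid @ resid) - pr.resid_sd_rate * sR + 1.0
            return lp, g

        init = np.zeros(lay.dim)
        init[lay.slices["log_v_phylo"]] = np.log(0.05)
        init[lay.slices["log_v_species"]] = np.log(0.05)
        init[lay.slices["log_sigma_resid"]] = np.log(max(y.std(), 0.1))
        res = self._sample(logp_and_grad, init, lay.dim)
        self._finalize(res, lay, data, y, Lv, B, biome_names, ref)
        return self

    def _finalize(self, res, lay, data, y, Lv, B, biome_names, ref):
        d = res.draws  # (chain, draw, dim)
        nc, nd, _ = d.shape
        sp = data.species_idx
        post = {
            "alpha_bar": lay.get(d, "alpha_bar")[..., 0],
            "beta_N": lay.get(d, "beta_N")[..., 0],
            "sigma2_phylo": np.exp(lay.get(d, "log_v_phylo")[..., 0]),
            "sigma2_species": np.exp(lay.get(d, "log_v_species")[..., 0]),
            "sigma_resid": np.exp(lay.get(d, "log_sigma_resid")[..., 0]),
        }
        if B.shape[1]:
            post["beta_biome"] = lay.get(d, "beta_biome")
        # pointwise log-likelihood for LOO
        zP = lay.get(d, "z_phylo")
        zS = lay.get(d, "z_species")
        sp_eff = (np.sqrt(post["sigma2_phylo"])[..., None]
                  * np.einsum("st,cdt->cds", Lv, zP)
                  + np.sqrt(post["sigma2_species"])[..., None] * zS)
        mu = (post["alpha_bar"][..., None]
              + np.einsum("nk,cdk->cdn", B, lay.get(d, "beta_biome"))
              + post["beta_N"][..., None] * data.N_z[None, None, :]
              + sp_eff[..., sp])
        sR = post["sigma_resid"][..., None]
        loglik = (-0.5 * np.log(2 * np.pi * sR ** 2)
                  - 0.5 * ((y[None, None, :] - mu) / sR) ** 2)
        idata = az.from_dict(posterior=post,
                             log_likelihood={"omega": loglik})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat_max = float(az.rhat(idata.posterior).to_array().max())
        self.summary_ = _summarize(idata, converged=rhat_max < 1.05,
                                   model="gaussian")
        self.idata_ = idata
        self.rhat_max_ = rhat_max
        self.converged_ = rhat_max < 1.05
        self.biome_names_ = biome_names
        self.reference_biome_ = ref
        self.accept_rate_ = res.accept_rate
        self.divergences_ = res.divergences
        if not self.converged_:
            warnings.warn(f"max R-hat {rhat_max:.3f} >= 1.05: "
                          "chains may not have converged")


class GammaMetaRegression(_MetaBase):
    """Life-history meta-regression on |omega| (Gamma response, log link).

    |omega| ~ Gamma(shape eta, mean mu); log mu = alpha_bar + LH terms
    + beta_N N + species and phylogenetic effects.  The life-history design
    is given by a :class:`ModelSpec`.
    """

    _param_names = ["spec", "priors", "n_chains", "n_warmup", "n_draws",
                    "seed", "target_accept", "traj_length", "max_steps"]

    def __init__(self, spec=None, priors=None, n_chains=3, n_warmup=1000,
                 n_draws=1000, seed=0, target_accept=0.8, traj_length=1.0,
                 max_steps=48):
        self.spec = spec or ModelSpec("base")
        self.priors = priors or PriorSet.gamma_default()
        self.n_chains = n_chains
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.seed = seed
        self.target_accept = target_accept
        self.traj_length = traj_length
        self.max_steps = max_steps

    def fit(self, data: MetaDataset):
        pr = self.priors
        y = data.abs_omega
        if np.any(y <= 0):
            raise InvalidArgumentError("Gamma response must be positive")
        n = y.size
        S = data.n_species
        sp = data.species_idx
        Lv = _chol_V(data.V)
        X = self.spec.design(data.lh_z)
        if np.any(~np.isfinite(X)):
            raise InvalidArgumentError("life-history design has missing values")
        k = X.shape[1]
        Nz = data.N_z
        lay = _Layout.build([
            ("alpha_bar", 1), ("beta_lh", k), ("beta_N", 1),
            ("log_v_phylo", 1), ("log_v_species", 1), ("log_eta", 1),
            ("z_phylo", S), ("z_species", S)])
        a_sd2 = pr.alpha_bar_sd ** 2
        l_sd2 = pr.beta_lh_sd ** 2
        n_sd2 = pr.beta_N_sd ** 2
        logy = np.log(y)

        def logp_and_grad(th):
            alpha = th[lay.slices["alpha_bar"]][0]
            bl = th[lay.slices["beta_lh"]]
            bN = th[lay.slices["beta_N"]][0]
            pP = th[lay.slices["log_v_phylo"]][0]
            pS = th[lay.slices["log_v_species"]][0]
            pE = th[lay.slices["log_eta"]][0]
            zP = th[lay.slices["z_phylo"]]
            zS = th[lay.slices["z_species"]]
            vP, vS, eta = np.exp(pP), np.exp(pS), np.exp(pE)
            sP, sS = np.sqrt(vP), np.sqrt(vS)
            LzP = Lv @ zP
            sp_eff = sP * LzP + sS * zS
            eta_lin = alpha + X @ bl + bN * Nz + sp_eff[sp]
            y_over_mu = y * np.exp(-eta_lin)
            # Gamma(shape eta, rate eta/mu) log-density
            ll = (n * (eta * np.log(eta) - gammaln(eta))
                  + (eta - 1) * logy.sum()
                  - eta * (eta_lin.sum() + y_over_mu.sum()))
            lp = ll \
                - 0.5 * alpha * alpha / a_sd2 \
                - 0.5 * bl @ bl / l_sd2 \
                - 0.5 * bN * bN / n_sd2 \
                - pr.sigma2_phylo_rate * vP + pP \
                - pr.sigma2_species_rate * vS + pS \
                + (pr.eta_shape - 1) * pE - pr.eta_rate * eta + pE \
                - 0.5 * zP @ zP - 0.5 * zS @ zS
            g = np.empty_like(th)
            r = eta * (y_over_mu - 1.0)      # dll / d eta_lin
            s_r = np.bincount(sp, weights=r, minlength=S)
            g[lay.slices["alpha_bar"]] = r.sum() - alpha / a_sd2
            g[lay.slices["beta_lh"]] = X.T @ r - bl / l_sd2
            g[lay.slices["beta_N"]] = Nz @ r - bN / n_sd2
            g[lay.slices["z_phylo"]] = sP * (Lv.T @ s_r) - zP
            g[lay.slices["z_species"]] = sS * s_r - zS
            g[lay.slices["log_v_phylo"]] = (
                0.5 * sP * (s_r @ LzP) - pr.sigma2_phylo_rate * vP + 1.0)
            g[lay.slices["log_v_species"]] = (
                0.5 * sS * (s_r @ zS) - pr.sigma2_species_rate * vS + 1.0)
            dll_deta = (n * (np.log(eta) + 1 - digamma(eta))
                        + logy.sum() - eta_lin.sum() - y_over_mu.sum())
            g[lay.slices["log_eta"]] = (
                eta * (dll_deta - pr.eta_rate) + pr.eta_shape)
            return lp, g

        init = np.zeros(lay.dim)
        init[lay.slices["alpha_bar"]] = np.log(max(y.mean(), 1e-3))
        init[lay.slices["log_v_phylo"]] = np.log(0.05)
        init[lay.slices["log_v_species"]] = np.log(0.05)
        init[lay.slices["log_eta"]] = 0.0
        res = self._sample(logp_and_grad, init, lay.dim)
        self._finalize(res, lay, data, y, Lv, X)
        return self

    def _finalize(self, res, lay, data, y, Lv, X):
        d = res.draws
        sp = data.species_idx
        post = {
            "alpha_bar": lay.get(d, "alpha_bar")[..., 0],
            "beta_N": lay.get(d, "beta_N")[..., 0],
            "sigma2_phylo": np.exp(lay.get(d, "log_v_phylo")[..., 0]),
            "sigma2_species": np.exp(lay.get(d, "log_v_species")[..., 0]),
            "eta": np.exp(lay.get(d, "log_eta")[..., 0]),
        }
        for j, cname in enumerate(self.spec.columns()):
            post[f"beta_{cname}"] = lay.get(d, "beta_lh")[..., j]
        zP = lay.get(d, "z_phylo")
        zS = lay.get(d, "z_species")
        sp_eff = (np.sqrt(post["sigma2_phylo"])[..., None]
                  * np.einsum("st,cdt->cds", Lv, zP)
                  + np.sqrt(post["sigma2_species"])[..., None] * zS)
        eta_lin = (post["alpha_bar"][..., None]
                   + np.einsum("nk,cdk->cdn", X, lay.get(d, "beta_lh"))
                   + post["beta_N"][..., None] * data.N_z[None, None, :]
                   + sp_eff[..., sp])
        eta = post["eta"][..., None]
        loglik = (eta * np.log(eta) - eta * eta_lin - gammaln(eta)
                  + (eta - 1) * np.log(y)[None, None, :]
                  - eta * y[None, None, :] * np.exp(-eta_lin))
        idata = az.from_dict(posterior=post,
                             log_likelihood={"abs_omega": loglik})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat_max = float(az.rhat(idata.posterior).to_array().max())
        self.summary_ = _summarize(idata, converged=rhat_max < 1.05,
                                   model=f"gamma:{self.spec.name}",
                                   spec=self.spec)
        self.idata_ = idata
        self.rhat_max_ = rhat_max
        self.converged_ = rhat_max < 1.05
        self.accept_rate_ = res.accept_rate
        self.divergences_ = res.divergences
        if not self.converged_:
            warnings.warn(f"max R-hat {rhat_max:.3f} >= 1.05: "
                          "chains may not have converged")


def fit_gaussian_meta(data, priors=None, **mcmc) -> PosteriorSummary:
    est = GaussianMetaRegression(priors=priors, **mcmc)
    est.fit(data)
    return est.summary_


def fit_gamma_meta(data, spec=None, priors=None, **mcmc) -> PosteriorSummary:
    est = GammaMetaRegression(spec=spec, priors=priors, **mcmc)
    est.fit(data)
    return est.summary_


@dataclass
class ModelComparison:
    """PSIS-LOO comparison of candidate models against a base model."""

    table: pd.DataFrame   # index model; elpd, se_elpd, delta_elpd, se_delta, pareto_k_max

    def delta(self, name):
        return float(self.table.loc[name, "delta_elpd"])


def loo_compare(fits, base="base") -> ModelComparison:
    """PSIS-LOO elpd per fitted model and differences against ``base``.

    ``fits``: mapping name -> PosteriorSummary (with log_likelihood group).
    All fits must share the same response vector length.
    """
    if base not in fits:
        raise InvalidArgumentError(f"base model {base!r} not in fits")
    pointwise = {}
    loos = {}
    for name, f in fits.items():
        idata = f.idata if hasattr(f, "idata") else f
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loo = az.loo(idata, pointwise=True)
        loos[name] = loo
        pointwise[name] = np.asarray(loo.loo_i)
    n = {len(v) for v in pointwise.values()}
    if len(n) != 1:
        raise InvalidArgumentError("models were fit to different responses")
    n = n.pop()
    rows = []
    base_pw = pointwise[base]
    for name, f in fits.items():
        pw = pointwise[name]
        diff = pw - base_pw
        rows.append({
            "model": name,
            "elpd": float(pw.sum()),
            "se_elpd": float(np.sqrt(n * np.var(pw))),
            "delta_elpd": float(diff.sum()),
            "se_delta": float(np.sqrt(n * np.var(diff))) if name != base else 0.0,
            "pareto_k_max": float(np.max(np.asarray(loos[name].pareto_k))),
        })
    table = pd.DataFrame(rows).set_index("model")
    table = table.sort_values("delta_elpd", ascending=False)
    return ModelComparison(table=table)


def prior_predictive(model="gaussian", priors=None, spec=None, n_draws=1000,
                     n_lh=0, data_range=(-4.0, 4.0), seed=0):
    """Draws of the response from the priors alone, plus a range check.

    Simulates parameters from the prior (no data), covariates at zero except
    ``n_lh`` standard-normal life-history columns, and a single observation
    per draw.  ``check_pass`` is True when the central 95% of draws lies
    within ``data_range``.
    """
    pr = priors or (PriorSet.gaussian_default() if model == "gaussian"
                    else PriorSet.gamma_default())
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0, pr.alpha_bar_sd, n_draws)
    vP = rng.exponential(1 / pr.sigma2_phylo_rate, n_draws)
    vS = rng.exponential(1 / pr.sigma2_species_rate, n_draws)
    sp_eff = (np.sqrt(vP) * rng.standard_normal(n_draws)
              + np.sqrt(vS) * rng.standard_normal(n_draws))
    lh = np.zeros(n_draws)
    for _ in range(n_lh):
        lh += rng.normal(0, pr.beta_lh_sd, n_draws) * rng.standard_normal(n_draws)
    lin = alpha + sp_eff + lh
    if model == "gaussian":
        sR = rng.exponential(1 / pr.resid_sd_rate, n_draws)
        draws = lin + sR * rng.standard_normal(n_draws)
    elif model == "gamma":
        eta = rng.gamma(pr.eta_shape, 1 / pr.eta_rate, n_draws)
        draws = rng.gamma(eta, np.exp(lin) / eta)
    else:
        raise InvalidArgumentError(f"unknown model {model!r}")
    lo, hi = np.quantile(draws, [0.025, 0.975])
    check = bool(lo >= data_range[0] and hi <= data_range[1])
    return {"draws": draws, "q2.5": float(lo), "q97.5": float(hi),
            "check_pass": check, "data_range": tuple(data_range),
            "mu_draws": lin, "alpha_draws": alpha}


def diagnostics(fit) -> dict:
    """Split-R-hat and ESS per parameter; pass iff max R-hat < 1.05."""
    idata = fit.idata if hasattr(fit, "idata") else fit
    post = idata.posterior
    if post.sizes["chain"] < 2:
        raise InvalidArgumentError("diagnostics need at least 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(post)
        es = az.ess(post)
    rhat_max = float(rh.to_array().max())
    return {"rhat": rh, "ess": es, "rhat_max": rhat_max,
            "ess_min": float(es.to_array().min()),
            "pass": bool(rhat_max < 1.05)}


def _great_circle_km(coords):
    """Pairwise haversine distances (km) for (lat, lon) degrees."""
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2)
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(effects, coords, n_perm=999, seed=0, alternative="greater"):
    """Moran's I with inverse great-circle-distance weights and a
    permutation p-value.

    Returns (I, p_value).  The null expectation is -1/(n-1).
    """
    x = np.asarray(effects, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 10:
        raise DegenerateInputError("need at least 10 located records")
    D = _great_circle_km(coords)
    if np.all(D[~np.eye(n, dtype=bool)] == 0):
        raise DegenerateInputError("all coordinates identical")
    with np.errstate(divide="ignore"):
        Wm = 1.0 / np.maximum(D, 1e-6)
    np.fill_diagonal(Wm, 0.0)
    s0 = Wm.sum()

    def moran(v):
        zc = v - v.mean()
        return n / s0 * (zc @ Wm @ zc) / (zc @ zc)

    I_obs = moran(x)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for k in range(n_perm):
        perm[k] = moran(rng.permutation(x))
    e0 = -1.0 / (n - 1)
    if alternative == "greater":
        p = (1 + np.sum(perm >= I_obs)) / (n_perm + 1)
    elif alternative == "two-sided":
        p = (1 + np.sum(np.abs(perm - e0) >= abs(I_obs - e0))) / (n_perm + 1)
    else:
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    return float(I_obs), float(p)


def fold_change(slope, delta_z):
    """Predicted multiplicative change in E|omega| across ``delta_z``
    standardized trait units under a log link: exp(slope * delta_z)."""
    return float(np.exp(slope * delta_z))


def marginal_predictions(fit: PosteriorSummary, trait, grid=None,
                         interval=0.80, n_pred_draws=4000, seed=0):
    """Posterior-predictive |omega| along one z-scored trait.

    Other covariates are held at 0 and the species-level varying effects are
    integrated over their population distribution.  The mean curve is the
    posterior mean of E[|omega| | z] = exp(alpha + beta z + (v_P + v_S)/2)
    (exact log-normal correction); intervals are quantiles of posterior-
    predictive draws.  Returns a DataFrame (z, mean, lo, hi).
    """
    spec = fit.spec
    if spec is None or trait not in spec.terms:
        raise InvalidArgumentError(
            f"trait {trait!r} is not a term of the fitted model")
    col = _TRAIT_COL[trait]
    post = fit.idata.posterior
    alpha = post["alpha_bar"].values.ravel()
    beta = post[f"beta_{col}"].values.ravel()
    vP = post["sigma2_phylo"].values.ravel()
    vS = post["sigma2_species"].values.ravel()
    eta = post["eta"].values.ravel()
    grid = np.linspace(-2.5, 2.5, 21) if grid is None else np.asarray(grid)
    rng = np.random.default_rng(seed)
    idx = rng.integers(alpha.size, size=n_pred_draws)
    g = np.sqrt(vP[idx]) * rng.standard_normal(n_pred_draws)
    a = np.sqrt(vS[idx]) * rng.standard_normal(n_pred_draws)
    rows = []
    qlo, qhi = 0.5 - interval / 2, 0.5 + interval / 2
    for z in grid:
        mean_curve = np.mean(np.exp(alpha + beta * z + (vP + vS) / 2))
        mu = np.exp(alpha[idx] + beta[idx] * z + g + a)
        y = rng.gamma(eta[idx], mu / eta[idx])
        rows.append({"z": float(z), "mean": float(mean_curve),
                     "lo": float(np.quantile(y, qlo)),
                     "hi": float(np.quantile(y, qhi))})
    return pd.DataFrame(rows)
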