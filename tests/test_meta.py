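"""Meta-regression components: standardization, candidate models, priors,
diagnostics, Moran's I, LOO bookkeeping, marginal predictions, and the
reduction of the Gaussian model to a plain random-intercept regression."""

import arviz as az
import numpy as np
import pandas as pd
import pytest

from climpop import (GaussianMetaRegression, MetaDataset, ModelSpec, PriorSet,
                     candidate_models, diagnostics, fold_change, loo_compare,
                     marginal_predictions, morans_i, prior_predictive,
                     standardize_effects)
from climpop.errors import DegenerateInputError, InvalidArgumentError
from climpop.meta import PosteriorSummary


class TestStandardize:
    def test_symmetric_triple_unchanged(self):
        z, absz = standardize_effects([-1.0, 0.0, 1.0])
        assert np.allclose(z, [-1, 0, 1])
        assert np.allclose(absz, [1.0, 1e-8, 1.0])  # zero floored

    def test_mean_zero(self, rng):
        z, _ = standardize_effects(rng.normal(3, 2, 100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_abs_after_zscore(self):
        z, absz = standardize_effects([-3.0, -1.0, 1.0, 3.0])
        assert np.allclose(absz, np.abs(z))
        assert absz.min() >= 1e-8

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize_effects([2.0, 2.0, 2.0])


class TestCandidateModels:
    def test_default_set_of_ten(self):
        specs = candidate_models()
        assert len(specs) == 10
        assert sum(1 for s in specs if not s.terms and not s.interactions) == 1

    def test_base_design_is_empty(self):
        lh = pd.DataFrame({"z_longevity": [1.0], "z_litter": [2.0],
                           "z_body_mass": [3.0]})
        base = next(s for s in candidate_models() if s.name == "base")
        assert base.design(lh).shape == (1, 0)

    def test_interaction_contains_product_column(self):
        lh = pd.DataFrame({"z_longevity": [2.0], "z_litter": [3.0],
                           "z_body_mass": [0.5]})
        spec = next(s for s in candidate_models()
                    if s.name == "longevity_x_litter")
        X = spec.design(lh)
        assert X.shape == (1, 3)
        assert X[0, 2] == pytest.approx(6.0)


class TestPriorPredictive:
    def test_intercept_prior_scale(self):
        pp = prior_predictive("gaussian", n_draws=20000, seed=1)
        assert np.std(pp["alpha_draws"]) == pytest.approx(0.3, abs=0.01)

    def test_default_priors_give_plausible_range(self):
        pp = prior_predictive("gaussian", n_draws=10000, seed=2)
        assert pp["check_pass"]
        assert pp["q2.5"] >= -4 and pp["q97.5"] <= 4

    def test_pathological_prior_flagged(self):
        wide = PriorSet(alpha_bar_sd=50.0)
        pp = prior_predictive("gaussian", priors=wide, n_draws=5000, seed=3)
        assert not pp["check_pass"]

    def test_gamma_draws_positive(self):
        pp = prior_predictive("gamma", n_draws=5000, seed=4)
        assert (pp["draws"] > 0).all()


class TestDiagnostics:
    def fake_fit(self, draws):
        idata = az.from_dict(posterior={"x": draws})
        return idata

    def test_identical_chains_rhat_one(self):
        # duplicated chains have zero between-chain variance; split-R-hat is
        # then sqrt((n-1)/n), i.e. 1 to within 1/n, and must pass
        half = np.random.default_rng(0).normal(size=250)
        draws = np.tile(np.concatenate([half, half]), (3, 1))
        d = diagnostics(self.fake_fit(draws))
        assert d["rhat_max"] == pytest.approx(1.0, abs=0.01)
        assert d["pass"]

    def test_disjoint_chains_fail(self):
        rng = np.random.default_rng(1)
        draws = np.stack([rng.normal(0, 1, 400), rng.normal(50, 1, 400)])
        d = diagnostics(self.fake_fit(draws))
        assert d["rhat_max"] > 1.05
        assert not d["pass"]

    def test_single_chain_rejected(self):
        with pytest.raises(InvalidArgumentError):
            diagnostics(self.fake_fit(np.zeros((1, 100))))


class TestMoransI:
    def coords(self, n, rng):
        return np.column_stack([rng.uniform(-60, 60, n),
                                rng.uniform(-170, 170, n)])

    def test_null_expectation(self):
        rng = np.random.default_rng(0)
        n = 40
        c = self.coords(n, rng)
        vals = []
        p_ok = 0
        for s in range(10):
            x = rng.normal(0, 1, n)
            I, p = morans_i(x, c, n_perm=199, seed=s)
            vals.append(I)
            p_ok += p > 0.05
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)
        assert p_ok >= 9

    def test_latitudinal_clustering_detected(self):
        rng = np.random.default_rng(2)
        c = self.coords(60, rng)
        I, p = morans_i(c[:, 0], c, n_perm=999, seed=1)
        assert I > 0
        assert p <= 0.001

    def test_too_few_records(self):
        with pytest.raises(DegenerateInputError):
            morans_i([1.0, 2.0], np.zeros((2, 2)))

    def test_identical_coordinates_rejected(self):
        with pytest.raises(DegenerateInputError):
            morans_i(np.arange(12.0), np.zeros((12, 2)))


def make_gamma_summary(alpha=0.0, beta=-0.2, vP=0.01, vS=0.04, eta=2.0,
                       n=400, jitter=0.0, seed=0):
    """A controlled Gamma-model posterior for prediction-identity tests."""
    rng = np.random.default_rng(seed)
    shape = (2, n)

    def c(v):
        return np.full(shape, v) + jitter * rng.normal(size=shape)

    post = {"alpha_bar": c(alpha), "beta_z_longevity": c(beta),
            "sigma2_phylo": np.abs(c(vP)), "sigma2_species": np.abs(c(vS)),
            "eta": np.abs(c(eta)), "beta_N": c(0.0)}
    idata = az.from_dict(posterior=post)
    table = pd.DataFrame({"mean": [alpha]}, index=["alpha_bar"])
    return PosteriorSummary(table=table, idata=idata, converged=True,
                            model="gamma:longevity",
                            spec=ModelSpec("longevity", ("longevity",)))


class TestMarginalPredictions:
    def test_zero_slope_gives_flat_curve(self):
        fit = make_gamma_summary(beta=0.0)
        out = marginal_predictions(fit, "longevity", grid=[-2, 0, 2])
        assert out["mean"].nunique() == 1

    def test_negative_slope_strictly_decreasing(self):
        fit = make_gamma_summary(beta=-0.3, jitter=0.02, seed=1)
        out = marginal_predictions(fit, "longevity",
                                   grid=np.linspace(-2, 2, 9))
        assert np.all(np.diff(out["mean"]) < 0)

    def test_log_link_ratio_identity(self):
        fit = make_gamma_summary(beta=-0.2)
        dz = 4.293
        out = marginal_predictions(fit, "longevity", grid=[0.0, dz])
        ratio = out["mean"].iloc[0] / out["mean"].iloc[1]
        assert ratio == pytest.approx(np.exp(0.2 * dz), rel=1e-9)

    def test_intervals_cover_mean(self):
        fit = make_gamma_summary(beta=-0.2, jitter=0.05, seed=2)
        out = marginal_predictions(fit, "longevity", grid=[0.0],
                                   n_pred_draws=8000, seed=3)
        assert out["lo"].iloc[0] < out["mean"].iloc[0] < out["hi"].iloc[0]

    def test_absent_trait_rejected(self):
        fit = make_gamma_summary()
        with pytest.raises(InvalidArgumentError):
            marginal_predictions(fit, "litter")


class TestFoldChange:
    def test_longevity_fold_change_identity(self):
        # a -0.20 slope across 4.293 standardized units of log-longevity
        # implies a 2.36-fold decrease in expected |omega|
        assert fold_change(0.20, 4.293) == pytest.approx(2.36, abs=0.005)
        assert fold_change(-0.20, 4.293) == pytest.approx(1 / 2.36, abs=0.001)


def small_meta_dataset(n_species=80, reps=3, seed=0, alpha=0.3, sdS=0.45,
                       resid=0.6):
    rng = np.random.default_rng(seed)
    S = n_species
    species = [f"s{i}" for i in range(S)]
    a_sp = rng.normal(0, sdS, S)
    sp_idx = np.repeat(np.arange(S), reps)
    n = sp_idx.size
    omega = alpha + a_sp[sp_idx] + rng.normal(0, resid, n)
    lh = pd.DataFrame({"z_longevity": np.zeros(n), "z_litter": np.zeros(n),
                       "z_body_mass": np.zeros(n)})
    return MetaDataset(omega=omega, abs_omega=np.abs(omega) + 1e-8,
                       species=species, species_idx=sp_idx,
                       biome_levels=["b"], biome_idx=np.zeros(n, dtype=int),
                       N_z=np.zeros(n), lh_z=lh, V=np.eye(S)), a_sp


class TestGaussianReduction:
    def test_matches_random_intercept_oracle(self):
        """With V = I and a negligible phylogenetic component the model is a
        plain random-intercept regression; the posterior intercept must match
        a REML mixed-model fit of the same data."""
        import statsmodels.formula.api as smf

        data, _ = small_meta_dataset(seed=3)
        m = GaussianMetaRegression(n_warmup=600, n_draws=600, seed=1).fit(data)
        df = pd.DataFrame({"omega": data.omega,
                           "species": np.asarray(data.species)[data.species_idx]})
        ml = smf.mixedlm("omega ~ 1", df, groups=df["species"]).fit(reml=True)
        assert m.summary_.mean("alpha_bar") == pytest.approx(
            ml.params["Intercept"], abs=0.05)
        # combined species-level variance is shared between the phylo and
        # species components; their sum should match the REML estimate
        tot = (m.summary_.mean("sigma2_species")
               + m.summary_.mean("sigma2_phylo"))
        assert tot == pytest.approx(float(ml.cov_re.iloc[0, 0]), abs=0.08)

    def test_null_data_centered_on_zero(self):
        data, _ = small_meta_dataset(seed=5, alpha=0.0, sdS=0.2, resid=1.0)
        m = GaussianMetaRegression(n_warmup=400, n_draws=400, seed=2).fit(data)
        lo, hi = m.summary_.ci("alpha_bar")
        assert lo < 0 < hi


class TestLooBookkeeping:
    def fits(self):
        data, _ = small_meta_dataset(n_species=30, reps=2, seed=9)
        from climpop import GammaMetaRegression
        f = {}
        for name, spec in [("base", ModelSpec("base")),
                           ("longevity", ModelSpec("longevity", ("longevity",)))]:
            f[name] = GammaMetaRegression(
                spec=spec, n_warmup=300, n_draws=300, seed=4).fit(data).summary_
        return f

    def test_self_delta_zero_and_order_invariance(self):
        f = self.fits()
        cmp1 = loo_compare({"base": f["base"], "longevity": f["longevity"]})
        cmp2 = loo_compare({"longevity": f["longevity"], "base": f["base"]})
        assert cmp1.delta("base") == 0.0
        assert cmp1.delta("longevity") == pytest.approx(
            cmp2.delta("longevity"), abs=1e-9)
        same = loo_compare({"base": f["base"], "other": f["base"]})
        assert same.delta("other") == pytest.approx(0.0, abs=1e-9)

    def test_unknown_base_rejected(self):
        f = self.fits()
        with pytest.raises(InvalidArgumentError):
            loo_compare(f, base="nope")
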