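import numpy as np
import pandas as pd
import pytest

from phenopred.design import DesignSpec, IncidenceMap
from phenopred.gibbs import (
    ModelSpec,
    MultiKernelGibbs,
    build_model,
    gibbs_fit,
    predict_records,
)
from phenopred.kernels import RelationshipKernel


def random_psd(n, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    return A @ A.T / n * scale


def mme_blup(y_obs, obs_idx, C, s2e, n):
    """Mixed-model-equation oracle: conditional mean of mu + u at all
    records given observed y, with total genetic covariance C fixed."""
    o = obs_idx
    V = C[np.ix_(o, o)] + s2e * np.eye(len(o))
    Vi = np.linalg.inv(V)
    one = np.ones(len(o))
    mu = (one @ Vi @ y_obs) / (one @ Vi @ one)
    # GLS-projected BLUP of u at every record
    P = Vi - Vi @ np.outer(one, one) @ Vi / (one @ Vi @ one)
    return mu + C[:, o] @ P @ y_obs


class TestModelSpec:
    def test_role_composition(self):
        assert ModelSpec("GP", "single").roles == ("f-GCA", "m-GCA", "SCA")
        assert ModelSpec("PP", "combined").roles == ("phenomic", "environment", "NIRxE")
        # GP+PP combined: f, m, SCA, environment, fxE, mxE, SCAxE, phenomic,
        # NIRxE -> nine variance terms plus the residual
        assert len(ModelSpec("GP+PP", "combined").roles) == 9

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("XX")
        with pytest.raises(ValueError):
            ModelSpec("GP", n_iter=100, burn_in=200)


class TestBuildModel:
    @pytest.fixture()
    def setup(self):
        design = DesignSpec(3, 3, {"E1": 1, "E2": 1})
        frame = design.plot_frame().drop(columns="replicate")
        inc = IncidenceMap(frame, ["female", "male", "hybrid", "environment"])
        kernels = {
            "f-GCA": RelationshipKernel(random_psd(3, 1), design.females),
            "m-GCA": RelationshipKernel(random_psd(3, 2), design.males),
            "SCA": RelationshipKernel(random_psd(9, 3), design.hybrids),
            "phenomic": RelationshipKernel(
                random_psd(18, 4), [f"R{i}" for i in range(18)]
            ),
        }
        return inc, kernels

    def test_gp_single_has_three_kernels(self, setup):
        inc, kernels = setup
        stack = build_model(ModelSpec("GP", "single"), kernels, inc)
        assert set(stack) == {"f-GCA", "m-GCA", "SCA"}

    def test_pp_combined_stack(self, setup):
        inc, kernels = setup
        stack = build_model(ModelSpec("PP", "combined"), kernels, inc)
        assert set(stack) == {"phenomic", "environment", "NIRxE"}

    def test_gp_pp_combined_stack_is_complete(self, setup):
        inc, kernels = setup
        stack = build_model(ModelSpec("GP+PP", "combined"), kernels, inc)
        assert set(stack) == {
            "f-GCA", "m-GCA", "SCA", "environment",
            "fxE", "mxE", "SCAxE", "phenomic", "NIRxE",
        }

    def test_missing_kernel_rejected(self, setup):
        inc, kernels = setup
        del kernels["phenomic"]
        with pytest.raises(KeyError):
            build_model(ModelSpec("PP", "single"), kernels, inc)

    def test_environment_block_is_indicator(self, setup):
        inc, kernels = setup
        stack = build_model(ModelSpec("GP", "combined"), kernels, inc)
        env = inc.records["environment"].to_numpy()
        assert np.array_equal(
            stack["environment"], (env[:, None] == env[None, :]).astype(float)
        )


class TestGibbsSampler:
    def test_matches_ridge_blup_with_identity_kernel(self):
        """Fixed-variance posterior mean equals the ridge/BLUP shrinkage
        estimator on an identity kernel."""
        rng = np.random.default_rng(0)
        n = 30
        y = 2.0 + rng.standard_normal(n)
        s2g, s2e = 1.5, 0.8
        est = MultiKernelGibbs(
            kernels={"g": np.eye(n)},
            n_iter=50000,
            burn_in=5000,
            thin=5,
            fixed_variances={"g": s2g, "e": s2e},
            seed=1,
        ).fit(y)
        oracle = mme_blup(y, np.arange(n), s2g * np.eye(n), s2e, n)
        assert np.corrcoef(est.fitted_, oracle)[0, 1] > 0.999

    def test_near_zero_variances_shrink_to_grand_mean(self):
        rng = np.random.default_rng(2)
        y = 5.0 + rng.standard_normal(40)
        est = MultiKernelGibbs(
            kernels={"g": random_psd(40, 3)},
            n_iter=2000,
            burn_in=500,
            thin=2,
            fixed_variances={"g": 1e-10, "e": 1.0},
            seed=4,
        ).fit(y)
        assert np.allclose(est.fitted_, y.mean(), atol=0.05)

    def test_variance_recovery_single_kernel(self):
        """Posterior mean of the kernel variance covers the generating value."""
        rng = np.random.default_rng(5)
        n = 200
        K = random_psd(n, 6)
        w, V = np.linalg.eigh(K)
        g = (V * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n) * np.sqrt(2.0)
        y = g + rng.standard_normal(n)
        est = MultiKernelGibbs(
            kernels={"g": K}, n_iter=4000, burn_in=1000, thin=3, seed=7
        ).fit(y)
        post_mean = est.variance_components_["g"]
        post_sd = est.posterior_.variance_sds["g"]
        assert abs(post_mean - 2.0) < 2 * post_sd + 0.2

    def test_female_male_exchange_invariance(self):
        """Swapping the f and m labels together with their kernels leaves
        predictions unchanged up to Monte-Carlo error."""
        design = DesignSpec(4, 4, {"E1": 1})
        frame = design.plot_frame().drop(columns="replicate")
        inc = IncidenceMap(frame, ["female", "male", "hybrid"])
        Kf, Km = random_psd(4, 8), random_psd(4, 9)
        Vf = Kf[np.ix_(inc.indices("female"), inc.indices("female"))]
        Vm = Km[np.ix_(inc.indices("male"), inc.indices("male"))]
        rng = np.random.default_rng(10)
        y = rng.standard_normal(16)
        a = MultiKernelGibbs(
            kernels={"f": Vf, "m": Vm}, n_iter=8000, burn_in=2000, thin=2, seed=11
        ).fit(y)
        b = MultiKernelGibbs(
            kernels={"f": Vm, "m": Vf}, n_iter=8000, burn_in=2000, thin=2, seed=12
        ).fit(y)
        assert np.corrcoef(a.fitted_, b.fitted_)[0, 1] > 0.99

    def test_gp_equals_pp_when_kernels_coincide(self):
        """A phenomic kernel equal to the genomic hybrid kernel gives the
        same predictions under either model label."""
        n = 50
        K = random_psd(n, 13)
        rng = np.random.default_rng(14)
        y = rng.standard_normal(n)
        y[::5] = np.nan
        gp = MultiKernelGibbs(
            kernels={"SCA": K}, n_iter=6000, burn_in=1500, thin=2, seed=15
        ).fit(y)
        pp = MultiKernelGibbs(
            kernels={"phenomic": K}, n_iter=6000, burn_in=1500, thin=2, seed=15
        ).fit(y)
        np.testing.assert_allclose(gp.fitted_, pp.fitted_, atol=1e-12)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(16)
        y = rng.standard_normal(25)
        kw = dict(kernels={"g": random_psd(25, 17)}, n_iter=500, burn_in=100, thin=2)
        a = MultiKernelGibbs(**kw, seed=3).fit(y)
        b = MultiKernelGibbs(**kw, seed=3).fit(y)
        np.testing.assert_array_equal(a.fitted_, b.fitted_)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            MultiKernelGibbs(kernels={"g": np.eye(4)}).fit(np.full(4, np.nan))

    def test_non_psd_kernel_rejected(self):
        y = np.zeros(3)
        with pytest.raises(ValueError):
            MultiKernelGibbs(kernels={"g": np.diag([1.0, -0.5, 1.0])}, n_iter=10, burn_in=5).fit(y)


class TestPrediction:
    def test_exact_interpolation_of_duplicated_entity(self):
        """In a near-noiseless toy with duplicated entities, the masked
        duplicate's prediction equals the observed duplicate's value."""
        n_ent = 8
        rng = np.random.default_rng(18)
        K_ent = random_psd(n_ent, 19, scale=2.0)
        # two records per entity
        idx = np.repeat(np.arange(n_ent), 2)
        K = K_ent[np.ix_(idx, idx)]
        w, V = np.linalg.eigh(K_ent)
        g = (V * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n_ent)
        y = g[idx].astype(float)
        y[1::2][:4] = np.nan  # mask one duplicate of the first four entities
        est = MultiKernelGibbs(
            kernels={"g": K},
            n_iter=20000,
            burn_in=4000,
            thin=4,
            fixed_variances={"g": 1.0, "e": 1e-8},
            seed=20,
        ).fit(y)
        for ent in range(4):
            observed = y[2 * ent]
            predicted = est.fitted_[2 * ent + 1]
            assert predicted == pytest.approx(observed, abs=1e-3)

    def test_cv3_style_prediction_matches_mme_oracle(self):
        """Hybrid-and-environment-unobserved records are predicted through
        kernel relatedness alone, matching the mixed-model equations."""
        design = DesignSpec(5, 2, {"E1": 1, "E2": 1})
        frame = design.plot_frame().drop(columns="replicate")
        inc = IncidenceMap(frame, ["female", "male", "hybrid", "environment"])
        n = len(frame)  # 20 records
        Kh = random_psd(10, 21, scale=1.5)
        Vh = Kh[np.ix_(inc.indices("hybrid"), inc.indices("hybrid"))]
        rng = np.random.default_rng(22)
        w, V = np.linalg.eigh(Vh)
        u = (V * np.sqrt(np.clip(w, 0, None))) @ rng.standard_normal(n)
        s2e = 0.3
        y_full = 1.0 + u + rng.standard_normal(n) * np.sqrt(s2e)
        y = y_full.copy()
        # mask one hybrid everywhere and one environment entirely
        mask = (frame["hybrid"] == "F01xM01") | (frame["environment"] == "E2")
        y[mask.to_numpy()] = np.nan
        obs = ~np.isnan(y)
        est = MultiKernelGibbs(
            kernels={"h": Vh},
            n_iter=30000,
            burn_in=5000,
            thin=5,
            fixed_variances={"h": 1.0, "e": s2e},
            seed=23,
        ).fit(y)
        oracle = mme_blup(y[obs], np.where(obs)[0], Vh, s2e, n)
        assert np.corrcoef(est.fitted_[~obs], oracle[~obs])[0, 1] > 0.995
        assert np.max(np.abs(est.fitted_ - oracle)) < 0.1

    def test_predict_records_lookup(self):
        rng = np.random.default_rng(24)
        y = pd.Series(rng.standard_normal(10), index=[f"r{i}" for i in range(10)])
        fit = gibbs_fit(
            {"g": random_psd(10, 25)},
            y,
            ModelSpec("GP", "single", n_iter=400, burn_in=100, thin=2, seed=26),
        )
        preds = predict_records(fit, ["r3", "r7"])
        assert list(preds.index) == ["r3", "r7"]
        assert preds["r3"] == fit.fitted[3]
        with pytest.raises(KeyError):
            predict_records(fit, ["nonexistent"])
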