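import numpy as np
import pandas as pd
import pytest

from phenopred.design import DesignSpec
from phenopred.simulate import GRAIN_YIELD_COMPONENTS
from phenopred.varcomp import (
    FactorialREML,
    PlotRecordTable,
    blues_table,
    cve,
    fit_blues,
    heritability_combined,
    heritability_single,
    lrt_all_terms,
    lrt_term,
    reml_combined,
    reml_single_env,
)

from conftest import iid_records

ZERO = {k: 0.0 for k in ("f", "m", "fm", "s", "fs", "ms", "fms", "r_s", "e")}


class TestPlotRecordTable:
    def test_duplicate_plot_rows_rejected(self, small_design):
        frame = small_design.plot_frame()
        frame["trait"] = 1.0
        dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            PlotRecordTable(dup)

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            PlotRecordTable(pd.DataFrame({"environment": ["E1"], "trait": [1.0]}))


class TestFitBlues:
    def test_balanced_blues_equal_plot_means(self, small_design):
        rec = iid_records(small_design, {**ZERO, "f": 0.5, "e": 0.2}, seed=1)
        blues = fit_blues(rec, "E1", "trait")
        sub = rec.frame[rec.frame["environment"] == "E1"]
        means = sub.groupby("hybrid")["trait"].mean()
        assert np.allclose(blues.sort_index(), means.sort_index(), atol=1e-8)

    def test_unbalanced_matches_bruteforce_gls(self):
        """With one missing plot, BLUEs equal the GLS solve assembled from
        scratch at the same variance estimates."""
        design = DesignSpec(3, 1, {"E1": 2})
        rec = iid_records(design, {**ZERO, "f": 1.0, "r_s": 0.4, "e": 0.3}, seed=2)
        frame = rec.frame.drop(index=0).reset_index(drop=True)  # one missing cell
        blues = fit_blues(frame, "E1", "trait")
        # brute-force: estimate variances with the same REML machinery, then
        # assemble V and the GLS normal equations independently
        from phenopred.varcomp import _reml_dense

        sub = frame[frame["environment"] == "E1"]
        y = sub["trait"].to_numpy()
        hybs = np.sort(sub["hybrid"].unique())
        X = (sub["hybrid"].to_numpy()[:, None] == hybs[None, :]).astype(float)
        rcodes, _ = pd.factorize(sub["replicate"])
        est, _, _ = _reml_dense(y, X, [rcodes])
        Zr = (rcodes[:, None] == np.arange(rcodes.max() + 1)[None, :]).astype(float)
        V = est[0] * Zr @ Zr.T + max(est[1], 1e-12) * np.eye(len(y))
        beta = np.linalg.solve(X.T @ np.linalg.solve(V, X), X.T @ np.linalg.solve(V, y))
        assert np.allclose(blues.to_numpy(), beta, atol=1e-6)

    def test_hybrid_without_observations_rejected(self, small_design):
        rec = iid_records(small_design, {**ZERO, "e": 1.0}, seed=3)
        frame = rec.frame[
            ~((rec.frame["environment"] == "E1") & (rec.frame["hybrid"] == "F01xM01"))
        ]
        with pytest.raises((ValueError, KeyError)):
            fit_blues(frame, "E1", "trait")

    def test_blues_table_layout(self, small_design):
        rec = iid_records(small_design, {**ZERO, "f": 0.3, "e": 0.1}, seed=4)
        tab = blues_table(rec, "trait")
        assert len(tab) == small_design.n_hybrids * small_design.n_environments
        assert set(tab.columns) == {"hybrid", "female", "male", "environment", "value"}


class TestREMLRoutes:
    def test_spectral_and_dense_routes_agree(self, small_design):
        """The balanced fast route and the generic dense route are the same
        REML optimum (estimates and restricted log-likelihood)."""
        rec = iid_records(small_design, GRAIN_YIELD_COMPONENTS, seed=5)
        vs = FactorialREML(model="combined").fit(rec, "trait").decomposition_
        vd = (
            FactorialREML(model="combined", force_dense=True)
            .fit(rec, "trait")
            .decomposition_
        )
        for k in vs.estimates:
            assert vs.estimates[k] == pytest.approx(vd.estimates[k], abs=2e-3)
        assert vs.loglik == pytest.approx(vd.loglik, abs=1e-4)

    def test_single_env_routes_agree(self, small_design):
        design = DesignSpec(4, 4, {"E1": 3})
        rec = iid_records(design, {**ZERO, "f": 1.0, "m": 0.8, "fm": 0.3, "e": 0.5}, seed=6)
        vs = reml_single_env(rec, "trait")
        vd = FactorialREML(model="single", force_dense=True).fit(rec, "trait").decomposition_
        for k in vs.estimates:
            assert vs.estimates[k] == pytest.approx(vd.estimates[k], abs=2e-3)

    def test_constant_response_gives_all_zero_components(self, small_design):
        frame = small_design.plot_frame()
        frame["trait"] = 4.2
        vc = reml_combined(frame, "trait")
        assert all(v == 0.0 for v in vc.estimates.values())

    def test_single_environment_routes_to_single_model(self, small_design):
        design = DesignSpec(4, 4, {"E1": 2})
        rec = iid_records(design, {**ZERO, "f": 1.0, "e": 0.5}, seed=7)
        vc = reml_combined(rec, "trait")
        assert vc.model == "single"

    def test_shuffle_and_shift_invariance(self, small_design):
        rec = iid_records(small_design, GRAIN_YIELD_COMPONENTS, seed=8)
        base = reml_combined(rec, "trait")
        shuffled = rec.frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
        vs = reml_combined(shuffled, "trait")
        shifted = rec.frame.assign(trait=rec.frame["trait"] + 100.0)
        vt = reml_combined(shifted, "trait")
        for k in base.estimates:
            assert vs.estimates[k] == pytest.approx(base.estimates[k], abs=1e-6)
            assert vt.estimates[k] == pytest.approx(base.estimates[k], abs=1e-6)

    def test_percent_of_total_sums_to_100(self, small_design):
        rec = iid_records(small_design, GRAIN_YIELD_COMPONENTS, seed=9)
        vc = reml_combined(rec, "trait")
        assert sum(vc.percents.values()) == pytest.approx(100.0, abs=0.2)

    def test_simulation_recovery_single_env(self):
        """Mean REML estimates over repeated single-environment datasets
        recover the generating components.

        The replicate component (1 contrast df at r=2) is boundary-dominated
        and is only checked for non-degeneracy; the identifiable components
        are held to a simultaneous 95% Monte-Carlo band.
        """
        design = DesignSpec(10, 10, {"E1": 2})
        truth = {"f": 4.0, "m": 4.0, "fm": 1.0, "e": 2.0}
        n_rep = 120
        rows = []
        for i in range(n_rep):
            rec = iid_records(
                design,
                {**ZERO, "f": 4.0, "m": 4.0, "fm": 1.0, "r_s": 0.5, "e": 2.0},
                seed=500 + i,
            )
            rows.append(reml_single_env(rec, "trait").estimates)
        est = pd.DataFrame(rows)
        for k, true_val in truth.items():
            mean, se = est[k].mean(), est[k].std(ddof=1) / np.sqrt(n_rep)
            # Sidak simultaneous 95% critical value for 4 comparisons
            assert abs(mean - true_val) < 2.5 * se + 0.02 * true_val, (k, mean, se)
        assert est["r"].mean() > 0.0

    def test_null_components_hit_zero_boundary(self):
        """With no genetic signal the GCA/SCA estimates pile on the zero
        boundary in a large share of replicates (about half asymptotically)."""
        design = DesignSpec(6, 6, {"E1": 2})
        hits = 0
        n_rep = 80
        for i in range(n_rep):
            rec = iid_records(design, {**ZERO, "r_s": 0.2, "e": 1.0}, seed=900 + i)
            vc = reml_single_env(rec, "trait")
            hits += vc.estimates["f"] == 0.0
        assert hits / n_rep >= 0.40

    def test_dropping_environment_terms_inflates_residual(self, full_design):
        """Omitting all environment-level terms pushes the environmental
        variance into the remaining components, chiefly the residual."""
        truth = {**ZERO, "s": 2.0, "e": 0.5}
        rows = []
        for i in range(30):
            rec = iid_records(full_design, truth, seed=1300 + i)
            vc = (
                FactorialREML(
                    model="combined", drop=("s", "fs", "ms", "fms", "r_s")
                )
                .fit(rec, "trait")
                .decomposition_
            )
            rows.append(vc.estimates["e"])
        mean_e = np.mean(rows)
        assert mean_e > truth["e"] + 0.5 * truth["s"]


class TestLRT:
    def test_identical_fits_give_zero_statistic(self, small_design):
        rec = iid_records(small_design, {**ZERO, "f": 1.0, "e": 0.5}, seed=10)
        full = FactorialREML(model="combined").fit(rec, "trait")
        # dropping a term whose estimate is exactly 0 changes nothing
        vc = full.decomposition_
        zero_terms = [k for k, v in vc.estimates.items() if v == 0.0 and k != "e"]
        if not zero_terms:
            pytest.skip("no boundary term in this draw")
        red = FactorialREML(model="combined", drop=(zero_terms[0],)).fit(rec, "trait")
        stat, p = lrt_term(full, red)
        assert stat == pytest.approx(0.0, abs=1e-5)
        assert p > 0.99

    def test_non_nested_pair_rejected(self, small_design):
        rec = iid_records(small_design, {**ZERO, "f": 1.0, "e": 0.5}, seed=11)
        a = FactorialREML(model="combined", drop=("fs",)).fit(rec, "trait")
        b = FactorialREML(model="combined", drop=("ms",)).fit(rec, "trait")
        with pytest.raises(ValueError):
            lrt_term(a, b)

    def test_type_I_error_conservative_at_boundary(self):
        """Testing a truly-zero variance term rejects at most the nominal
        rate (the boundary makes the plain chi2(1) reference conservative)."""
        design = DesignSpec(8, 8, {"E1": 2})
        rejections = 0
        n_rep = 150
        for i in range(n_rep):
            rec = iid_records(design, {**ZERO, "m": 0.5, "r_s": 0.1, "e": 1.0}, seed=2000 + i)
            full = FactorialREML(model="single").fit(rec, "trait")
            red = FactorialREML(model="single", drop=("f",)).fit(rec, "trait")
            _, p = lrt_term(full, red)
            rejections += p < 0.05
        # allow binomial slack around the conservative target
        assert rejections / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_power_for_large_effect(self):
        design = DesignSpec(8, 8, {"E1": 2})
        n_rep = 40
        hits = 0
        for i in range(n_rep):
            rec = iid_records(design, {**ZERO, "f": 5.0, "e": 1.0}, seed=3000 + i)
            full = FactorialREML(model="single").fit(rec, "trait")
            red = FactorialREML(model="single", drop=("f",)).fit(rec, "trait")
            _, p = lrt_term(full, red)
            hits += p < 0.001
        assert hits / n_rep >= 0.95

    def test_lrt_all_terms_attaches_pvalues(self, small_design):
        rec = iid_records(small_design, GRAIN_YIELD_COMPONENTS, seed=12)
        vc = lrt_all_terms(rec, "trait", model="combined")
        assert set(vc.lrt_pvalues) == set(vc.estimates) - {"e"}
        assert all(0.0 <= p <= 1.0 for p in vc.lrt_pvalues.values())


class TestHeritability:
    def test_single_env_no_error_variance_gives_one(self):
        hr = heritability_single({"f": 1.0, "m": 1.0, "fm": 0.5, "e": 0.0}, r=2)
        assert hr.H2 == pytest.approx(1.0)

    def test_single_env_arithmetic(self):
        hr = heritability_single({"g": 2.0, "e": 2.0}, r=2)
        assert hr.H2 == pytest.approx(2.0 / 3.0)

    def test_narrow_sense_components_add_up(self):
        hr = heritability_single({"f": 0.7, "m": 0.4, "fm": 0.2, "e": 1.0}, r=3)
        assert hr.h2 == pytest.approx(hr.h2_f + hr.h2_m)

    def test_combined_zero_interaction_and_error_gives_one(self):
        hr = heritability_combined({"g": 3.0, "gs": 0.0, "e": 0.0}, t=8, r=2)
        assert hr.H2 == pytest.approx(1.0)

    def test_combined_ordering_invariant(self):
        comp = {"f": 1.0, "m": 0.8, "fm": 0.4, "fs": 0.3, "ms": 0.2, "fms": 0.1, "e": 1.5}
        hr = heritability_combined(comp, t=4, r=2)
        assert hr.H2 >= hr.h2 >= max(hr.h2_f, hr.h2_m)

    def test_missing_components_rejected(self):
        with pytest.raises(KeyError):
            heritability_combined({"g": 1.0, "e": 0.5}, t=4, r=2)


class TestCVe:
    def test_arithmetic(self):
        assert cve({"e": 1.0}, 10.0) == pytest.approx(10.0)

    def test_zero_error_gives_zero(self):
        assert cve({"e": 0.0}, 5.0) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cve({"e": 1.0}, 0.0)
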