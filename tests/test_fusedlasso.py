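"""Tests for the grouped fused LASSO: solver, CV, selection, bootstrap."""

import numpy as np
import pytest
from scipy.optimize import minimize

from krillab import fusedlasso as fl
from krillab import synthetic as syn
from krillab.errors import ConfigurationError, InputError


def convex_oracle(design, lam, tau):
    """Independent minimizer: variable splitting a = p - q, bounded L-BFGS-B."""
    X, y = design.X, design.y
    m, p = X.shape
    starts, ends = design.block_bounds

    def obj(z):
        a0, pq = z[0], z[1:]
        a = pq[:p] - pq[p:]
        r = y - a0 - X @ a
        J = 0.5 * (r @ r) / m + lam * np.sum(pq)
        for s, e in zip(starts, ends):
            d = np.diff(a[s:e])
            J += tau * (d @ d)
        return J

    res = minimize(
        obj, np.zeros(1 + 2 * p), method="L-BFGS-B",
        bounds=[(None, None)] + [(0, None)] * (2 * p),
        options={"maxiter": 50000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.fun


def synthetic_design(seed=0, cohort="L"):
    cfg = syn.SyntheticConfig(seed=seed)
    env = syn.gen_environment(cfg)
    truth = syn.gen_anomalies(env, cfg)
    years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
    values = truth.anomalies.delta_L if cohort == "L" else truth.anomalies.delta_J
    return fl.build_design(values, years, env), truth


class TestObjective:
    def test_zero_coefficients(self, toy_design):
        design, _ = toy_design
        yc = design.y - design.y.mean()
        d2 = fl.FactorDesign(
            X=design.X, y=yc, years=design.years, factors=design.factors,
            offsets=design.offsets, means=design.means, sds=design.sds,
        )
        J = fl.fused_lasso_objective(0.0, np.zeros(6), d2, 0.3, 0.2)
        assert J == pytest.approx(0.5 * np.sum(yc**2) / len(yc))

    def test_reduces_to_ols_objective(self, toy_design):
        design, _ = toy_design
        a = np.array([0.5, -0.2, 0.1, 0.0, 0.3, -0.1])
        J = fl.fused_lasso_objective(0.1, a, design, 0.0, 0.0)
        r = design.y - 0.1 - design.X @ a
        assert J == pytest.approx(0.5 * (r @ r) / len(design.y))

    def test_hand_arithmetic_small_instance(self):
        X = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, -1.0],
                      [1.0, 1.0, 0.0], [2.0, -1.0, 1.0]])
        y = np.array([1.0, 2.0, 0.0, -1.0])
        des = fl.FactorDesign(
            X=X, y=y, years=np.arange(4), factors=("F",), offsets=(0, 1, 2),
            means=np.zeros(3), sds=np.ones(3),
        )
        a = np.array([0.5, -1.0, 0.25])
        resid = y - 0.2 - X @ a
        expected = (
            np.sum(resid**2) / 8.0
            + 0.1 * (0.5 + 1.0 + 0.25)
            + 0.3 * ((-1.0 - 0.5) ** 2 + (0.25 + 1.0) ** 2)
        )
        assert fl.fused_lasso_objective(0.2, a, des, 0.1, 0.3) == pytest.approx(expected)

    def test_fusion_is_within_block_only(self, toy_design):
        design, _ = toy_design
        a = np.array([1.0, -1.0, 2.0, 0.5, 0.5, 0.5])
        J = fl.fused_lasso_objective(0.0, a, design, 0.0, 1.0)
        # swapping whole blocks leaves the fusion term unchanged
        a_sw = np.concatenate([a[3:], a[:3]])
        des_sw = fl.FactorDesign(
            X=np.concatenate([design.X[:, 3:], design.X[:, :3]], axis=1),
            y=design.y, years=design.years, factors=("B", "A"),
            offsets=design.offsets, means=design.means, sds=design.sds,
        )
        assert fl.fused_lasso_objective(0.0, a_sw, des_sw, 0.0, 1.0) == pytest.approx(J)
        # permuting months inside a block changes it
        a_perm = a[[1, 2, 0, 3, 4, 5]]
        J_perm = (
            fl.fused_lasso_objective(0.0, a_perm, design, 0.0, 1.0)
            - 0.5 * np.sum((design.y - design.X @ a_perm) ** 2) / len(design.y)
        )
        J_fuse = J - 0.5 * np.sum((design.y - design.X @ a) ** 2) / len(design.y)
        assert J_perm != pytest.approx(J_fuse)


class TestFit:
    @pytest.mark.parametrize(
        "lam,tau", [(0.05, 0.1), (0.3, 0.01), (1e-8, 0.0), (0.0, 100.0), (0.02, 1.0)]
    )
    def test_matches_convex_oracle(self, toy_design, lam, tau):
        design, _ = toy_design
        mod = fl.fit(design, lam, tau)
        assert mod.objective == pytest.approx(convex_oracle(design, lam, tau), abs=1e-6)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            m = 10
            X = rng.normal(size=(m, 6))
            y = rng.normal(size=m)
            des = fl.FactorDesign(
                X=X, y=y, years=np.arange(m), factors=("A", "B"), offsets=(0, 1, 2),
                means=np.zeros(6), sds=np.ones(6),
            )
            lam, tau = rng.uniform(0.01, 0.5), rng.uniform(0.0, 0.5)
            mod = fl.fit(des, lam, tau)
            assert mod.objective == pytest.approx(convex_oracle(des, lam, tau), abs=1e-4)

    def test_ols_limit(self, toy_design):
        design, _ = toy_design
        mod = fl.fit(design, 1e-10, 0.0)
        Xi = np.column_stack([np.ones(len(design.y)), design.X])
        beta = np.linalg.lstsq(Xi, design.y, rcond=None)[0]
        assert np.allclose(
            np.concatenate([[mod.intercept], mod.coef]), beta, atol=1e-4
        )
        assert mod.r2 == pytest.approx(1.0, abs=0.05)

    def test_large_lambda_gives_intercept_only(self, toy_design):
        design, _ = toy_design
        mod = fl.fit(design, 100.0, 0.0)
        assert np.all(mod.coef == 0.0)
        assert mod.intercept == pytest.approx(design.y.mean(), abs=1e-5)

    def test_large_fusion_equalizes_blocks(self, toy_design):
        design, _ = toy_design
        mod = fl.fit(design, 1e-6, 1e5)
        for f in design.factors:
            block = mod.block_coef(f)
            assert np.ptp(block) < 1e-3

    def test_solution_improves_on_zero_and_ols(self, toy_design):
        design, _ = toy_design
        lam, tau = 0.1, 0.05
        mod = fl.fit(design, lam, tau)
        J_zero = fl.fused_lasso_objective(0.0, np.zeros(6), design, lam, tau)
        Xi = np.column_stack([np.ones(len(design.y)), design.X])
        beta = np.linalg.lstsq(Xi, design.y, rcond=None)[0]
        J_ols = fl.fused_lasso_objective(beta[0], beta[1:], design, lam, tau)
        assert mod.objective <= J_zero + 1e-12
        assert mod.objective <= J_ols + 1e-12

    def test_path_continuity_under_lambda_perturbation(self, toy_design):
        design, _ = toy_design
        m1 = fl.fit(design, 0.05, 0.05)
        m2 = fl.fit(design, 0.05 * 1.01, 0.05)
        assert np.linalg.norm(m2.coef - m1.coef) < 0.05 * np.linalg.norm(m1.coef) + 1e-9


class TestCrossValidate:
    def test_fold_bookkeeping_leave_one_out(self, toy_design):
        design, _ = toy_design
        cv = fl.cross_validate(design, [0.1], [0.1], K=len(design.y))
        assert np.isfinite(cv.cv_error)

    def test_invalid_K(self, toy_design):
        design, _ = toy_design
        with pytest.raises(ConfigurationError):
            fl.cross_validate(design, [0.1], [0.1], K=1)
        with pytest.raises(ConfigurationError):
            fl.cross_validate(design, [0.1], [0.1], K=len(design.y) + 1)

    def test_no_signal_diagnostic_fires_on_noise(self):
        # pure-noise response: CV error decreases with lambda in most replicates
        lam_grid = np.logspace(-3, 1, 6)
        tau_grid = [1e-3, 0.1]
        fired = 0
        n_rep = 9
        for rep in range(n_rep):
            cfg = syn.SyntheticConfig(seed=400 + rep)
            env = syn.gen_environment(cfg)
            years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
            rng = np.random.default_rng(rep)
            noise = rng.normal(size=cfg.n_years)
            des = fl.build_design(noise, years, env, factors=("Chl", "SAM"))
            cv = fl.cross_validate(des, lam_grid, tau_grid, K=3)
            fired += cv.no_signal
        assert fired > n_rep / 2

    def test_signal_beats_intercept_only(self):
        des, truth = synthetic_design(seed=31)
        lam_grid = np.logspace(-3, 1, 6)
        cv = fl.cross_validate(des, lam_grid, [0.01, 0.3], K=3)
        # intercept-only error ~ variance of the response under huge lambda
        surface = cv.surface
        intercept_err = surface[surface.lambda_l1 == surface.lambda_l1.max()].cv_error.min()
        assert cv.cv_error < intercept_err
        assert not cv.no_signal


class TestSubsetSelection:
    def test_enumerates_15_subsets_once(self):
        des, _ = synthetic_design(seed=32)
        sel = fl.subset_model_selection(
            des, K=3, lambda_grid=[0.01, 0.3], tau_grid=[0.05], seed=0
        )
        assert len(sel.report) == 15
        assert sel.report["subset"].nunique() == 15

    def test_recovers_driving_factor(self):
        des, truth = synthetic_design(seed=33)
        sel = fl.subset_model_selection(
            des, K=9, lambda_grid=np.logspace(-4, 1, 8),
            tau_grid=np.logspace(-4, 1, 6), seed=0,
        )
        assert "SAM" in sel.selected_factors

    def test_tie_broken_toward_fewer_factors(self):
        # duplicated factor blocks: the superset cannot beat the subset by
        # more than noise, so the fewer-factor model must win
        rng = np.random.default_rng(3)
        m, k = 18, 3
        Xa = rng.normal(size=(m, k))
        X = np.hstack([Xa, Xa])  # factor B identical to factor A
        y = Xa @ np.array([0.8, 0.5, 0.2]) + 0.05 * rng.normal(size=m)
        des = fl.FactorDesign(
            X=X, y=y, years=np.arange(m), factors=("A", "B"), offsets=(0, 1, 2),
            means=np.zeros(2 * k), sds=np.ones(2 * k),
        )
        sel = fl.subset_model_selection(
            des, K=3, lambda_grid=[0.01, 0.1], tau_grid=[0.0], seed=0
        )
        assert len(sel.selected_factors) == 1


class TestFactorImportance:
    def test_null_factor_scores_low_and_driver_high(self):
        des, truth = synthetic_design(seed=34)
        sel = fl.subset_model_selection(
            des, K=3, lambda_grid=[0.01, 0.1, 1.0], tau_grid=[0.05], seed=0
        )
        imp = fl.factor_importance(sel.models)
        assert imp.idxmax() == "SAM"

    def test_all_zero_coefficients(self):
        des, _ = synthetic_design(seed=35)
        models = {}
        for sub in [("Chl",), ("Chl", "SAM")]:
            mod = fl.fit(des.subset(sub), 1e3, 0.0)  # everything shrunk to 0
            models[sub] = mod
        imp = fl.factor_importance(models, factors=("Chl", "SAM"))
        assert (imp == 0).all()


class TestBootstrap:
    def test_rejects_tiny_B(self, toy_design):
        design, _ = toy_design
        with pytest.raises(InputError):
            fl.bootstrap_bands(design, 0.01, 0.01, B=1)

    def test_noise_free_bands_contain_truth_tightly(self):
        rng = np.random.default_rng(8)
        m = 24
        X = rng.normal(size=(m, 4))
        a_true = np.array([0.7, 0.7, -0.3, 0.0])
        y = 0.1 + X @ a_true  # exact linear, no noise
        des = fl.FactorDesign(
            X=X, y=y, years=np.arange(m), factors=("A", "B"), offsets=(0, 1),
            means=np.zeros(4), sds=np.ones(4),
        )
        bands = fl.bootstrap_bands(des, 1e-8, 0.0, B=200, seed=0)
        width = bands["ci_high"] - bands["ci_low"]
        assert (width < 1e-3).all()
        assert ((bands["ci_low"] - 1e-4 <= a_true)
                & (a_true <= bands["ci_high"] + 1e-4)).all()

    def test_coverage_near_nominal(self):
        # known-coefficient simulation: ~90% coverage of per-coefficient bands
        rng = np.random.default_rng(99)
        m, p = 27, 4
        a_true = np.array([0.6, 0.4, -0.5, 0.0])
        covered = total = 0
        for rep in range(60):
            X = rng.normal(size=(m, p))
            y = 0.2 + X @ a_true + 0.4 * rng.normal(size=m)
            des = fl.FactorDesign(
                X=X, y=y, years=np.arange(m), factors=("A", "B"), offsets=(0, 1),
                means=np.zeros(p), sds=np.ones(p),
            )
            bands = fl.bootstrap_bands(des, 1e-4, 1e-4, B=400, seed=rep)
            covered += int(
                ((bands["ci_low"] <= a_true) & (a_true <= bands["ci_high"])).sum()
            )
            total += p
        rate = covered / total
        assert 0.80 <= rate <= 0.97


class TestPredictAndScore:
    def test_mean_predictors_give_intercept(self):
        des, _ = synthetic_design(seed=36)
        mod = fl.fit(des, 0.05, 0.05)
        pred = fl.predict_and_score(mod, des.means[None, :])
        assert pred[0] == pytest.approx(mod.intercept, abs=1e-10)

    def test_saturated_unpenalized_training_r2_is_one(self):
        # with p + intercept >= m the unpenalized fit interpolates
        rng = np.random.default_rng(12)
        m = 6
        X = rng.normal(size=(m, 6))
        y = rng.normal(size=m)
        des = fl.FactorDesign(
            X=X, y=y, years=np.arange(m), factors=("A", "B"), offsets=(0, 1, 2),
            means=np.zeros(6), sds=np.ones(6),
        )
        mod = fl.fit(des, 1e-12, 0.0)
        _, r2 = fl.predict_and_score(mod, fl.design_raw_matrix(des), y)
        assert r2 == pytest.approx(1.0, abs=1e-3)

    def test_wrong_width_rejected(self, toy_design):
        design, _ = toy_design
        mod = fl.fit(design, 0.05, 0.05)
        with pytest.raises(InputError):
            fl.predict_and_score(mod, np.zeros((2, 99)))

    def test_standardization_round_trip_invariance(self):
        # affine rescaling of raw inputs leaves destandardized predictions alone
        cfg = syn.SyntheticConfig(seed=37)
        env = syn.gen_environment(cfg)
        truth = syn.gen_anomalies(env, cfg)
        years = np.arange(cfg.start_year, cfg.start_year + cfg.n_years)
        des1 = fl.build_design(truth.anomalies.delta_L, years, env, factors=("T",))
        env2 = env.copy()
        env2.loc[env2["factor"] == "T", "value"] = (
            env2.loc[env2["factor"] == "T", "value"] * 2.5 - 3.0
        )
        des2 = fl.build_design(truth.anomalies.delta_L, years, env2, factors=("T",))
        m1 = fl.fit(des1, 0.05, 0.05)
        m2 = fl.fit(des2, 0.05, 0.05)
        p1 = fl.predict_and_score(m1, fl.design_raw_matrix(des1))
        p2 = fl.predict_and_score(m2, fl.design_raw_matrix(des2))
        assert np.allclose(p1, p2, atol=1e-6)

    def test_default_generator_r2_in_calibrated_band(self):
        # at the generator's default signal-to-noise the training R^2 of the
        # single-true-factor model falls in a moderate band
        r2s = []
        for seed in range(5):
            des, truth = synthetic_design(seed=500 + seed)
            sub = des.subset(("SAM",))
            mod = fl.fit(sub, 0.01, 0.1)
            _, r2 = fl.predict_and_score(mod, fl.design_raw_matrix(sub), sub.y)
            r2s.append(r2)
        assert 0.4 <= np.mean(r2s) <= 0.9
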