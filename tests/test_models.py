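"""Spatial econometric engine: OLS baseline, LM diagnostics, ML fits
against dense-matrix oracles, effect decomposition, placebo permutation."""

import numpy as np
import pytest

import fsispace as f
from fsispace import models, synth, weights


@pytest.fixture(scope="module")
def ring10():
    adj = synth.generate_adjacency("ring_lattice", 10)
    return f.row_standardize(f.contiguity_weights(adj))


def sar_dgp(wm, rho, beta, T, seed, theta=None, sigma=1.0):
    """Year-major draws from the (Durbin) spatial-lag reduced form."""
    rng = np.random.default_rng(seed)
    n = wm.n
    A_inv = np.linalg.inv(np.eye(n) - rho * wm.w)
    X = rng.normal(0, 1, (T, n))
    Y = np.empty((T, n))
    for t in range(T):
        signal = beta * X[t]
        if theta is not None:
            signal = signal + theta * (wm.w @ X[t])
        Y[t] = A_inv @ (signal + rng.normal(0, sigma, n))
    y = Y.ravel()
    Xd = np.column_stack([np.ones(T * n), X.ravel()])
    return y, Xd, ["const", "x1"]


class TestOLS:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ np.array([1.0, 2.0])
        fit = f.ols_fit(y, X, ["const", "x"])
        assert fit.r_squared == pytest.approx(1.0)
        assert np.abs(fit.resid).max() < 1e-10

    def test_intercept_only_gives_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = f.ols_fit(y, np.ones((3, 1)), ["const"])
        assert fit.coef("const") == pytest.approx(y.mean())

    def test_calibrated_coverage(self):
        hits, reps = 0, 200
        for r in range(reps):
            rng = np.random.default_rng(r)
            X = np.column_stack([np.ones(50), rng.normal(size=50)])
            y = X @ np.array([0.5, 1.5]) + rng.normal(size=50)
            fit = f.ols_fit(y, X, ["const", "x"])
            hits += abs(fit.coef("x") - 1.5) < 3 * fit.se("x")
        assert hits / reps >= 0.99

    def test_collinear_design_named(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            f.ols_fit(np.zeros(10), X, ["const", "a", "b"])


class TestLMTests:
    def test_statistics_nonnegative(self, china_wm):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(403), rng.normal(size=403)])
        y = rng.normal(size=403)
        lm = f.lm_tests(f.ols_fit(y, X, ["const", "x"]), china_wm)
        assert lm.lm_lag[0] >= 0 and lm.lm_error[0] >= 0

    def test_power_under_spatial_lag(self, china_wm):
        y, X, names = sar_dgp(china_wm, rho=0.5, beta=0.3, T=13, seed=1)
        lm = f.lm_tests(f.ols_fit(y, X, names), china_wm)
        assert lm.lm_lag[1] < 0.01

    def test_requires_ols_fit(self, china_wm, ring10):
        y, X, names = sar_dgp(ring10, rho=0.2, beta=0.3, T=2, seed=0)
        fit = f.sar_fit(y, X, ring10, names, compute_se=False)
        with pytest.raises(ValueError, match="OLS"):
            f.lm_tests(fit, ring10)


class TestSpatialML:
    def test_sdm_reduces_to_ols_when_no_spatial_process(self, ring10):
        rng = np.random.default_rng(5)
        n, T = 10, 30
        X = np.column_stack([np.ones(n * T), rng.normal(size=n * T)])
        y = X @ np.array([0.5, 1.0]) + rng.normal(0, 0.5, n * T)
        sdm = f.sdm_fit(y, X, ring10, ["const", "x1"])
        ols = f.ols_fit(y, X, ["const", "x1"])
        assert abs(sdm.rho) < 0.15
        assert sdm.coef("x1") == pytest.approx(ols.coef("x1"), abs=0.05)

    def test_sem_reduces_to_ols_when_no_error_process(self, ring10):
        rng = np.random.default_rng(6)
        n, T = 10, 30
        X = np.column_stack([np.ones(n * T), rng.normal(size=n * T)])
        y = X @ np.array([0.5, 1.0]) + rng.normal(0, 0.5, n * T)
        sem = f.sem_fit(y, X, ring10, ["const", "x1"])
        assert abs(sem.lambda_err) < 0.2
        assert sem.coef("x1") == pytest.approx(1.0, abs=0.1)

    def test_concentrated_loglik_matches_dense_oracle(self, ring10):
        """n <= 20: the eigenvalue-based concentrated likelihood equals a
        literal dense-matrix evaluation at the ML estimate."""
        for model, fitter in (("SAR", f.sar_fit), ("SDM", f.sdm_fit)):
            y, X, names = sar_dgp(ring10, rho=0.4, beta=0.8, T=2, seed=8,
                                  theta=0.3 if model == "SDM" else None)
            fit = fitter(y, X, ring10, names)
            kz = len(fit.param_names) - 2
            dense = models.dense_loglik(
                y, X, ring10, fit.rho, fit.params[:kz], fit.sigma2, model
            )
            assert fit.loglik == pytest.approx(dense, abs=1e-8)

    def test_logdet_monotone_decreasing_in_rho(self, china_wm):
        ev = np.linalg.eigvals(china_wm.w)
        grid = np.linspace(0.0, 0.95, 40)
        vals = [np.sum(np.log(1 - r * ev)).real for r in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sar_recovers_published_magnitude_rho(self, china_wm):
        """rho = 0.347 planted (the published SAR value) is recovered on
        average across replicates."""
        est = []
        for r in range(20):
            y, X, names = sar_dgp(china_wm, 0.347, 0.5, 13, 100 + r)
            est.append(f.sar_fit(y, X, china_wm, names, compute_se=False).rho)
        assert np.mean(est) == pytest.approx(0.347, abs=0.05)

    def test_aic_ranks_sdm_best_on_sdm_data(self, china_wm):
        wins, reps = 0, 25
        for r in range(reps):
            y, X, names = sar_dgp(china_wm, rho=0.35, beta=0.6, T=13,
                                  seed=900 + r, theta=0.4)
            fits = [
                f.ols_fit(y, X, names),
                f.sar_fit(y, X, china_wm, names, compute_se=False),
                f.sem_fit(y, X, china_wm, names, compute_se=False),
                f.sdm_fit(y, X, china_wm, names, compute_se=False),
            ]
            best = min(fits, key=lambda m: m.aic)
            wins += best.model == "SDM"
        assert wins / reps >= 0.8

    def test_aic_identity(self, ring10):
        y, X, names = sar_dgp(ring10, 0.3, 0.5, 3, seed=2)
        fit = f.sar_fit(y, X, ring10, names)
        k = len(names) + 1
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)


class TestEffects:
    def test_identity_multiplier_at_rho_zero(self, ring10):
        """With rho = 0 and no Durbin terms the direct effect is beta and
        the indirect effect vanishes."""
        rng = np.random.default_rng(11)
        n, T = 10, 20
        X = np.column_stack([np.ones(n * T), rng.normal(size=n * T)])
        y = X @ np.array([0.2, 0.7]) + rng.normal(0, 0.3, n * T)
        fit = f.sar_fit(y, X, ring10, ["const", "x1"])
        eff = f.effects_decomposition(fit, ring10, n_draws=200, seed=0)
        row = eff.row("x1")
        assert row["direct"] == pytest.approx(fit.coef("x1"), abs=0.02)
        assert row["indirect"] == pytest.approx(0.0, abs=0.05)

    def test_dense_inverse_oracle_n5(self):
        """Effects from the closed-form trace/row-sum formulas equal a
        literal dense-matrix evaluation on a 5-unit system."""
        adj = synth.generate_adjacency("ring_lattice", 5)
        wm = f.row_standardize(f.contiguity_weights(adj))
        rho, beta, theta = 0.3, 1.0, 0.5
        n = 5
        S = np.linalg.inv(np.eye(n) - rho * wm.w) @ (np.eye(n) * beta + wm.w * theta)
        direct_o = np.trace(S) / n
        total_o = S.sum() / n
        direct, indirect, total = models._effects_point(wm, rho, beta, theta)
        assert direct == pytest.approx(direct_o, abs=1e-12)
        assert total == pytest.approx(total_o, abs=1e-12)
        assert indirect == pytest.approx(total_o - direct_o, abs=1e-12)

    def test_additivity_exact(self, china_wm, recovery_panel):
        panel, truth = recovery_panel
        s = synth.truth_scores(truth)
        sp = f.PanelDataset(
            panel.data.merge(s.rename("fsi").reset_index(), on=["unit", "year"])
        )
        y, X, names = f.panel_arrays(sp, "fsi", list(synth.COVARIATES), china_wm,
                                     year_dummies=False)
        fit = f.sdm_fit(y, X, china_wm, names)
        eff = f.effects_decomposition(fit, china_wm, n_draws=100, seed=0)
        for _, row in eff.table.iterrows():
            assert row["direct"] + row["indirect"] == pytest.approx(
                row["total"], abs=1e-10
            )

    def test_requires_spatial_lag_fit(self, ring10):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        fit = f.ols_fit(rng.normal(size=20), X, ["const", "x"])
        with pytest.raises(ValueError, match="SAR/SDM"):
            f.effects_decomposition(fit, ring10)


class TestPlacebo:
    def _data(self, wm, effect, seed=0):
        rng = np.random.default_rng(seed)
        n, T = wm.n, 13
        A_inv = np.linalg.inv(np.eye(n) - 0.3 * wm.w)
        X1 = rng.normal(0, 1, (T, n))
        X2 = rng.normal(0, 1, (T, n))
        Y = np.array(
            [A_inv @ (0.4 * X1[t] + effect * X2[t] + rng.normal(0, 1, n))
             for t in range(T)]
        )
        Xd = np.column_stack([np.ones(T * n), X1.ravel(), X2.ravel()])
        return Y.ravel(), Xd, ["const", "x1", "x2"]

    def test_null_effect_high_p(self, china_wm):
        y, X, names = self._data(china_wm, effect=0.0, seed=4)
        res = f.placebo_test(y, X, china_wm, "x2", names, n_perm=49, seed=1)
        assert res.p_value > 0.05

    def test_strong_effect_low_p(self, china_wm):
        y, X, names = self._data(china_wm, effect=0.6, seed=4)
        res = f.placebo_test(y, X, china_wm, "x2", names, n_perm=49, seed=1)
        assert res.p_value < 0.05

    def test_deterministic_under_seed(self, china_wm):
        y, X, names = self._data(china_wm, effect=0.0, seed=4)
        r1 = f.placebo_test(y, X, china_wm, "x2", names, n_perm=25, seed=9)
        r2 = f.placebo_test(y, X, china_wm, "x2", names, n_perm=25, seed=9)
        assert r1.permuted == r2.permuted

    def test_too_few_permutations_rejected(self, china_wm):
        y, X, names = self._data(china_wm, effect=0.0)
        with pytest.raises(ValueError, match="20"):
            f.placebo_test(y, X, china_wm, "x2", names, n_perm=5)
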