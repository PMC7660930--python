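import numpy as np
import pytest

from tgen.synthetic import SimConfig, simulate_dataset, simulate_panel
from tgen.types import AnnotationMatrix, PriorConfig, SnpRecord
from tgen.vb import (
    annotation_filter_fit,
    fit_elnt,
    fit_grid,
    fit_single_theta,
    fit_vb_baseline,
    logistic_prior,
    predict_expression,
)

from .conftest import make_panel
from .oracles import exact_pip, two_model_pip

THETA = (0.25, 4.0, 1.0)  # sigma2, sigma_beta2, eta


def _toy_regression(seed, n=120, p=6, causal=0, beta=1.0, noise=0.5, ld=0.3):
    panel = simulate_panel(SimConfig(n_train=n, p=p, ld_rho=ld, seed=seed))
    X = panel.dosages - panel.dosages.mean(axis=0)
    b = np.zeros(p)
    b[causal] = beta
    rng = np.random.default_rng(seed + 1000)
    Y = X @ b + rng.normal(0, noise, n)
    return X, Y - Y.mean()


class TestLogisticPrior:
    def test_zero_linear_predictor_is_half(self):
        assert logistic_prior(np.zeros(3), np.zeros(4)) == pytest.approx(0.5)

    def test_closed_form_sigmoid(self):
        # intercept 2, no slopes -> sigmoid(2)
        assert logistic_prior(np.zeros(1), np.array([2.0, 0.0])) == pytest.approx(
            0.8808, abs=1e-4
        )

    def test_monotone_in_annotation(self):
        omega = np.array([-1.0, 1.5])
        vals = [logistic_prior(np.array([a]), omega) for a in (0.0, 0.5, 1.0, 3.0)]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            logistic_prior(np.array([np.nan]), np.array([0.0, 1.0]))


class TestFitSingleTheta:
    def test_matches_exact_enumeration(self):
        """Mean-field alpha tracks the exact posterior inclusion (p=8)."""
        X, Y = _toy_regression(seed=11, n=300, p=8, beta=1.0, noise=0.5)
        st = fit_single_theta(
            X, Y, AnnotationMatrix.empty(8), THETA,
            update_omega=False, tol=1e-8, max_iter=1000,
        )
        pip = exact_pip(X, Y, THETA[0], THETA[1], pi0=0.1)
        r = np.corrcoef(st.alpha, pip)[0, 1]
        assert r >= 0.95
        assert np.abs(st.alpha - pip).max() <= 0.15

    def test_null_data_alphas_below_prior(self, rng):
        """Y orthogonal to X leaves inclusion at or below the prior level."""
        X, _ = _toy_regression(seed=21, n=100, p=5)
        noise = rng.normal(size=100)
        proj = X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        Y = noise - proj  # exactly orthogonal to the columns of X
        st = fit_single_theta(X, Y, AnnotationMatrix.empty(5), THETA)
        from scipy.special import expit

        prior = expit(st.omega_mean[0])
        assert np.all(st.alpha <= prior + 0.05)

    def test_elbo_monotone(self):
        X, Y = _toy_regression(seed=31, n=80, p=10, beta=0.5)
        A = AnnotationMatrix(
            track_names=["m"], values=np.abs(np.sin(np.arange(10.0)))[:, None]
        )
        st = fit_single_theta(X, Y, A, THETA, tol=1e-10, max_iter=300)
        diffs = np.diff(st.elbo_trace)
        assert diffs.min() >= -1e-8

    def test_nonfinite_input_rejected(self):
        X, Y = _toy_regression(seed=41)
        Y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_single_theta(X, Y, AnnotationMatrix.empty(X.shape[1]), THETA)

    def test_nonconvergence_flagged(self):
        X, Y = _toy_regression(seed=51, n=200, p=20)
        with pytest.warns(UserWarning, match="did not converge"):
            st = fit_single_theta(
                X, Y, AnnotationMatrix.empty(20), THETA, tol=1e-14, max_iter=3
            )
        assert not st.converged


class TestFitGrid:
    def test_single_point_grid_pps_equals_alpha(self):
        X, Y = _toy_regression(seed=61, p=5)
        cfg = PriorConfig(theta_grid=[THETA])
        fit, model = fit_grid(X, Y, AnnotationMatrix.empty(5), config=cfg)
        np.testing.assert_allclose(model.pps, fit.states[0].alpha, atol=1e-12)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_duplicate_grid_points_weighted_equally(self):
        X, Y = _toy_regression(seed=71, p=4)
        cfg = PriorConfig(theta_grid=[THETA, THETA])
        fit, _ = fit_grid(X, Y, AnnotationMatrix.empty(4), config=cfg)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-10)

    def test_zero_annotation_reduces_to_vb(self):
        ds = simulate_dataset(SimConfig(n_train=150, p=25, seed=81))
        X, Y = ds.panel.dosages, ds.expression.values
        zeroA = AnnotationMatrix(
            track_names=["m0", "m1"], values=np.zeros((25, 2))
        )
        _, tg = fit_grid(X, Y, zeroA, seed=1)
        vb = fit_vb_baseline(X, Y, seed=1)
        np.testing.assert_allclose(tg.pps, vb.pps, atol=1e-6)
        np.testing.assert_allclose(tg.beta_hat, vb.beta_hat, atol=1e-6)

    def test_weights_on_simplex_and_pps_in_unit_interval(self):
        ds = simulate_dataset(SimConfig(n_train=100, p=15, seed=91))
        fit, model = fit_grid(
            ds.panel.dosages, ds.expression.values, ds.annotations
        )
        assert np.exp(fit.log_weights).sum() == pytest.approx(1.0)
        assert np.all((model.pps >= 0) & (model.pps <= 1))

    def test_snp_permutation_equivariance(self):
        X, Y = _toy_regression(seed=101, n=100, p=8, beta=0.8)
        A = AnnotationMatrix(
            track_names=["m"],
            values=np.abs(np.cos(np.arange(8.0)))[:, None],
        )
        cfg = PriorConfig(theta_grid=[THETA])
        _, m1 = fit_grid(X, Y, A, config=cfg)
        perm = np.array([3, 1, 4, 0, 7, 5, 2, 6])
        Ap = AnnotationMatrix(track_names=["m"], values=A.values[perm])
        _, m2 = fit_grid(X[:, perm], Y, Ap, config=cfg)
        # coordinate ascent visits SNPs in storage order, so orders differ
        # transiently; converged solutions must agree up to the permutation
        np.testing.assert_allclose(m2.pps, m1.pps[perm], atol=1e-3)
        np.testing.assert_allclose(m2.beta_hat, m1.beta_hat[perm], atol=1e-3)

    def test_scale_equivariance(self):
        X, Y = _toy_regression(seed=111, n=150, p=6, beta=0.7)
        c = 3.0
        cfg1 = PriorConfig(theta_grid=[(0.25, 4.0, 1.0)])
        cfg2 = PriorConfig(theta_grid=[(0.25 * c**2, 4.0, 1.0)])
        _, m1 = fit_grid(X, Y, AnnotationMatrix.empty(6), config=cfg1)
        _, m2 = fit_grid(X, c * Y, AnnotationMatrix.empty(6), config=cfg2)
        np.testing.assert_allclose(m2.pps, m1.pps, atol=1e-8)
        np.testing.assert_allclose(m2.beta_hat, c * m1.beta_hat, rtol=1e-6)


class TestVbBaseline:
    def test_p1_matches_two_model_bayes_factor(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.3, 200).astype(float)
        x = x - x.mean()
        y = 0.4 * x + rng.normal(0, 0.5, 200)
        y = y - y.mean()
        st = fit_single_theta(
            x[:, None], y, AnnotationMatrix.empty(1), THETA,
            update_omega=False, tol=1e-12, max_iter=500,
        )
        exact = two_model_pip(x, y, THETA[0], THETA[1], pi0=0.1)
        assert st.alpha[0] == pytest.approx(exact, abs=1e-6)

    def test_pure_noise_mean_alpha_near_prior(self):
        """Average inclusion under null data stays at the fixed prior level."""
        tot, cnt = 0.0, 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            X = rng.binomial(2, 0.3, (100, 10)).astype(float)
            X = X - X.mean(axis=0)
            y = rng.normal(size=100)
            st = fit_single_theta(
                X, y - y.mean(), AnnotationMatrix.empty(10),
                (1.0, 0.1, 1.0), update_omega=False,
            )
            tot += st.alpha.mean()
            cnt += 1
        assert tot / cnt == pytest.approx(0.1, abs=0.05)


class TestAnnotationFilterFit:
    def _data(self, seed=121, p=12):
        ds = simulate_dataset(SimConfig(n_train=120, p=p, seed=seed))
        return ds.panel.dosages, ds.expression.values, ds.annotations, ds.panel.snps

    def test_zero_annotation_snps_absent(self):
        X, Y, A, snps = self._data()
        model = annotation_filter_fit(X, Y, A, base="vb", snps=snps)
        surviving = np.any(A.values > 0, axis=1)
        expected = {s.snp_id for s, keep in zip(snps, surviving) if keep}
        assert set(model.snp_ids) == expected

    def test_strictly_positive_annotation_keeps_all(self):
        X, Y, A, snps = self._data()
        Apos = AnnotationMatrix(
            track_names=A.track_names, values=A.values + 0.5
        )
        model = annotation_filter_fit(X, Y, Apos, base="vb", snps=snps)
        assert model.snp_ids == [s.snp_id for s in snps]

    def test_all_filtered_returns_flagged_empty_model(self):
        X, Y, A, snps = self._data()
        Azero = AnnotationMatrix(track_names=["m"], values=np.zeros((12, 1)))
        with pytest.warns(UserWarning, match="all SNPs removed"):
            model = annotation_filter_fit(X, Y, Azero, base="vb", snps=snps)
        assert model.snps == []

    def test_elnt_base_runs(self):
        X, Y, A, snps = self._data()
        model = annotation_filter_fit(X, Y, A, base="elnt", snps=snps)
        assert model.method_tag == "elnt.annot"


class TestPredictExpression:
    def test_zero_beta_gives_zero_vector(self, small_panel):
        model = fit_vb_baseline(
            small_panel.dosages,
            np.random.default_rng(0).normal(size=small_panel.n_samples),
            snps=small_panel.snps,
        )
        model.beta_hat[:] = 0.0
        np.testing.assert_array_equal(
            predict_expression(model, small_panel), np.zeros(small_panel.n_samples)
        )

    def test_single_snp_closed_form(self):
        dos = np.array([[0.0], [1.0], [2.0], [1.0]])
        panel = make_panel(dos)
        from tgen.types import ImputationModel

        model = ImputationModel(
            gene_id="g", tissue="t", snps=panel.snps,
            beta_hat=np.array([2.0]), pps=np.array([1.0]),
            train_mean=np.array([1.0]), omega_hat=np.zeros(1),
        )
        np.testing.assert_allclose(
            predict_expression(model, panel), 2.0 * (dos[:, 0] - 1.0)
        )

    def test_matches_independent_matrix_product(self, small_panel, rng):
        from tgen.types import ImputationModel

        k = 5
        beta = rng.normal(size=k)
        means = small_panel.dosages[:, :k].mean(axis=0)
        model = ImputationModel(
            gene_id="g", tissue="t", snps=small_panel.snps[:k],
            beta_hat=beta, pps=np.ones(k), train_mean=means,
            omega_hat=np.zeros(1),
        )
        expected = (small_panel.dosages[:, :k] - means) @ beta
        np.testing.assert_allclose(
            predict_expression(model, small_panel), expected, atol=1e-12
        )

    def test_missing_snp_contributes_zero_with_warning(self, small_panel):
        from tgen.types import ImputationModel, SnpRecord

        ghost = SnpRecord("rs_ghost", "1", 999, "A", "G", 0.2)
        model = ImputationModel(
            gene_id="g", tissue="t",
            snps=[small_panel.snps[0], ghost],
            beta_hat=np.array([1.0, 5.0]), pps=np.ones(2),
            train_mean=np.array([small_panel.dosages[:, 0].mean(), 1.0]),
            omega_hat=np.zeros(1),
        )
        with pytest.warns(UserWarning, match="absent"):
            pred = predict_expression(model, small_panel)
        expected = small_panel.dosages[:, 0] - small_panel.dosages[:, 0].mean()
        np.testing.assert_allclose(pred, expected)


class TestElbow:
    def test_elbo_monotone_many_random_instances(self):
        """Coordinate ascent never decreases the bound (spot check, 20 runs)."""
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p = 40 + seed, 5 + (seed % 6)
            X = rng.normal(size=(n, p))
            X = X - X.mean(axis=0)
            Y = rng.normal(size=n)
            A = AnnotationMatrix(
                track_names=["m"], values=rng.exponential(1, (p, 1))
            )
            st = fit_single_theta(X, Y, A, (1.0, 0.5, 2.0), tol=1e-10, max_iter=200)
            worst = min(worst, float(np.diff(st.elbo_trace).min()))
        assert worst >= -1e-8
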