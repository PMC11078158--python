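import numpy as np
import pytest

from seqglm import ConvergenceError, family_terms, fit_null, get_family, glm_fit

FAMILIES = ["gaussian", "logistic", "poisson"]


class TestFamilyTerms:
    def test_logistic_at_zero(self):
        t = family_terms("logistic", 0.0)
        assert t["b"] == pytest.approx(np.log(2.0))
        assert t["b1"] == pytest.approx(0.5)
        assert t["b2"] == pytest.approx(0.25)

    def test_poisson_at_zero(self):
        t = family_terms("poisson", 0.0)
        assert (t["b"], t["b1"], t["b2"]) == (1.0, 1.0, 1.0)

    def test_gaussian_terms(self):
        t = family_terms("gaussian", 2.0, y=0.0, phi=1.0)
        assert t["b"] == pytest.approx(2.0)
        assert (t["a"], t["a1"], t["a2"]) == (1.0, 1.0, 0.0)

    def test_gaussian_dc_dphi_matches_finite_difference(self):
        # analytic: y^2/(2 phi^2) - 1/(2 phi) = 9/8 - 1/4
        t = family_terms("gaussian", 0.0, y=3.0, phi=2.0)
        assert t["dc_dphi"] == pytest.approx(0.875)

        def c(phi, y=3.0):
            return -(y**2) / (2 * phi) - 0.5 * np.log(2 * np.pi * phi)

        h = 1e-6
        fd1 = (c(2 + h) - c(2 - h)) / (2 * h)
        fd2 = (c(2 + h) - 2 * c(2.0) + c(2 - h)) / h**2
        assert t["dc_dphi"] == pytest.approx(fd1, rel=1e-6)
        assert t["d2c_dphi2"] == pytest.approx(fd2, rel=1e-4)

    @pytest.mark.parametrize("name", FAMILIES)
    def test_b_derivatives_match_finite_differences(self, name):
        fam = get_family(name)
        eta = np.linspace(-10, 10, 81)
        h = 1e-6
        fd1 = (fam.b(eta + h) - fam.b(eta - h)) / (2 * h)
        h2 = 1e-3  # larger step: second differences cancel catastrophically
        fd2 = (fam.b(eta + h2) - 2 * fam.b(eta) + fam.b(eta - h2)) / h2**2
        assert np.allclose(fam.b1(eta), fd1, rtol=1e-6, atol=1e-8)
        assert np.allclose(fam.b2(eta), fd2, rtol=1e-3, atol=1e-4)
        assert np.all(fam.b2(eta) >= 0)  # convexity of the cumulant

    def test_logistic_b_stable_for_large_eta(self):
        fam = get_family("logistic")
        assert np.isfinite(fam.b(800.0))
        assert fam.b(800.0) == pytest.approx(800.0)
        assert fam.b(-800.0) == pytest.approx(0.0, abs=1e-300)

    def test_dispersion_contract(self):
        with pytest.raises(ValueError):
            family_terms("logistic", 0.0, phi=1.0)
        with pytest.raises(ValueError):
            family_terms("gaussian", 0.0, y=0.0)  # phi missing
        with pytest.raises(ValueError):
            family_terms("gaussian", 0.0, y=0.0, phi=-1.0)
        with pytest.raises(ValueError):
            get_family("negative_binomial")


class TestFitNull:
    def test_gaussian_intercept_only(self):
        fit = fit_null(np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), "gaussian")
        assert fit.alpha_tilde[0] == pytest.approx(2.0)
        # MLE variance divides by N, not N-1
        assert fit.phi_tilde == pytest.approx(2.0 / 3.0)

    def test_logistic_intercept_only(self):
        fit = fit_null(np.array([0.0, 0.0, 1.0, 1.0]), np.ones((4, 1)), "logistic")
        assert fit.alpha_tilde[0] == pytest.approx(0.0, abs=1e-8)

    def test_poisson_intercept_only(self):
        fit = fit_null(np.array([1.0, 2.0, 3.0, 4.0]), np.ones((4, 1)), "poisson")
        assert fit.alpha_tilde[0] == pytest.approx(np.log(2.5), abs=1e-8)

    def test_gaussian_matches_closed_form_least_squares(self, rng):
        n = 50
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = x @ np.array([1.0, 2.0, -0.5]) + rng.standard_normal(n)
        fit = fit_null(y, x, "gaussian")
        beta_ls = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(fit.alpha_tilde, beta_ls, atol=1e-10)

    @pytest.mark.parametrize("name", FAMILIES)
    def test_score_vanishes_at_fit(self, name, rng):
        n = 80
        x = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n), rng.standard_normal(n)])
        eta = x @ np.array([0.0, 1.0, 1.0])
        fam = get_family(name)
        if name == "logistic":
            y = rng.binomial(1, fam.b1(eta)).astype(float)
        elif name == "poisson":
            y = rng.poisson(np.exp(eta)).astype(float)
        else:
            y = eta + rng.standard_normal(n)
        fit = fit_null(y, x, name)
        a = fit.phi_tilde if fam.has_dispersion else 1.0
        score = x.T @ (y - fit.mu) / a
        assert np.max(np.abs(score)) < 1e-8

    @pytest.mark.parametrize("name", FAMILIES)
    def test_invariant_to_column_reordering(self, name, rng):
        n = 60
        x = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n), rng.standard_normal(n)])
        eta = x @ np.array([0.2, 0.5, 0.5])
        fam = get_family(name)
        if name == "logistic":
            y = rng.binomial(1, fam.b1(eta)).astype(float)
        elif name == "poisson":
            y = rng.poisson(np.exp(eta)).astype(float)
        else:
            y = eta + rng.standard_normal(n)
        f1 = fit_null(y, x, name)
        f2 = fit_null(y, x[:, [2, 0, 1]], name)
        assert np.allclose(f1.eta, f2.eta, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 120
        x = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n), rng.standard_normal(n)])
        for name, smfam in [("logistic", sm.families.Binomial()), ("poisson", sm.families.Poisson())]:
            eta = x @ np.array([0.1, 0.8, -0.4])
            fam = get_family(name)
            y = (
                rng.binomial(1, fam.b1(eta)).astype(float)
                if name == "logistic"
                else rng.poisson(np.exp(eta)).astype(float)
            )
            ours = fit_null(y, x, name)
            theirs = sm.GLM(y, x, family=smfam).fit()
            assert np.allclose(ours.alpha_tilde, theirs.params, atol=1e-6)

    def test_rejects_bad_inputs(self, rng):
        y = rng.standard_normal(10)
        x = np.ones((10, 2))  # duplicated intercept: rank deficient
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_null(y, x, "gaussian")
        with pytest.raises(ValueError, match="intercept"):
            fit_null(y, rng.standard_normal((10, 1)), "gaussian")
        with pytest.raises(ValueError, match="0/1"):
            fit_null(np.array([0.0, 2.0, 1.0, 0.0]), np.ones((4, 1)), "logistic")

    def test_separation_is_diagnosed(self):
        x = np.column_stack([np.ones(10), np.r_[np.zeros(5), np.ones(5)]])
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(ConvergenceError, match="separation"):
            glm_fit(y, x, "logistic")
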