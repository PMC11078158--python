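import numpy as np
import pytest

from seqglm import (
    SitePosterior,
    beta_weights,
    fit_null,
    gl_from_pileup,
    js_test,
    observed_information_at_null,
    posterior_moments,
    score_at_null,
    vc_test,
)
from .conftest import (
    latent_loglik,
    numerical_gradient,
    numerical_hessian,
    small_instance,
)

FAMILIES = ["gaussian", "logistic", "poisson"]


def degenerate_posterior(g):
    """Posterior with all mass on the true genotypes."""
    return SitePosterior(eg=np.asarray(g, dtype=float), var=np.zeros(g.shape))


class TestBetaWeights:
    def test_equal_mafs_give_unit_weights(self):
        w = beta_weights([0.02, 0.02, 0.02]).w
        assert np.allclose(w, 1.0)

    def test_two_maf_closed_form(self):
        # Beta(1,25) density is 25 (1-x)^24; ratio (0.99/0.96)^24, sum 2
        w = beta_weights([0.01, 0.04]).w
        ratio = (0.99 / 0.96) ** 24
        expected = np.array([ratio, 1.0])
        expected *= 2.0 / expected.sum()
        assert np.allclose(w, expected, rtol=1e-12)
        assert w.sum() == pytest.approx(2.0)

    def test_single_marker_is_unit(self):
        assert beta_weights([0.003]).w[0] == pytest.approx(1.0)

    def test_zero_maf_rejected(self):
        with pytest.raises(ValueError):
            beta_weights([0.0, 0.01])


class TestScoreAtNull:
    def test_constant_posterior_zero_score(self):
        y = np.array([0.0, 1.0])
        x = np.ones((2, 1))
        post = SitePosterior(eg=np.full((2, 3), 0.6), var=np.full((2, 3), 0.2))
        nf = fit_null(y, x, "logistic")
        s = score_at_null(y, x, post, nf)
        assert np.allclose(s["s_beta"], 0.0, atol=1e-12)

    def test_degenerate_gaussian_matches_textbook_score(self, rng):
        n = 40
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.3, size=(n, 2))
        y = x @ [1.0, 0.5] + rng.standard_normal(n)
        nf = fit_null(y, x, "gaussian")
        s = score_at_null(y, x, degenerate_posterior(g), nf)
        expected = g.T @ (y - nf.eta) / nf.phi_tilde
        assert np.allclose(s["s_beta"], expected, atol=1e-10)

    def test_stale_nullfit_rejected(self, rng):
        n = 30
        x = np.ones((n, 1))
        y = rng.standard_normal(n)
        nf = fit_null(y, x, "gaussian")
        nf.mu = nf.mu + 1.0  # corrupt the fit
        post = SitePosterior(eg=np.full((n, 1), 0.5), var=np.full((n, 1), 0.3))
        with pytest.raises(ValueError, match="stale"):
            score_at_null(y, x, post, nf)


class TestOracleAgreement:
    """Score, information and statistic vs brute-force 3^dg enumeration."""

    @pytest.mark.parametrize("family", FAMILIES)
    def test_score_matches_numerical_gradient(self, family):
        y, x, n_ref, n_alt, f = small_instance(family)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        nf = fit_null(y, x, family)
        theta = np.concatenate(
            [nf.alpha_tilde, np.zeros(2)]
            + ([np.array([nf.phi_tilde])] if nf.phi_tilde else [])
        )
        num = numerical_gradient(
            lambda t: latent_loglik(t, y, x, gl, f, family), theta
        )
        s = score_at_null(y, x, post, nf)
        p = x.shape[1]
        assert np.allclose(s["s_beta"], num[p : p + 2], rtol=1e-6, atol=1e-7)
        assert np.max(np.abs(num[:p])) < 1e-6  # alpha score vanishes at MLE
        if nf.phi_tilde:
            assert abs(num[-1]) < 1e-6

    @pytest.mark.parametrize("family", FAMILIES)
    def test_information_matches_numerical_hessian(self, family):
        y, x, n_ref, n_alt, f = small_instance(family)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        nf = fit_null(y, x, family)
        theta = np.concatenate(
            [nf.alpha_tilde, np.zeros(2)]
            + ([np.array([nf.phi_tilde])] if nf.phi_tilde else [])
        )
        num = -numerical_hessian(
            lambda t: latent_loglik(t, y, x, gl, f, family), theta
        )
        ana = observed_information_at_null(y, x, post, nf)
        assert np.max(np.abs(num - ana) / (1.0 + np.abs(num))) < 1e-4

    def test_gaussian_alpha_phi_block_exactly_zero(self):
        y, x, n_ref, n_alt, f = small_instance("gaussian")
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        nf = fit_null(y, x, "gaussian")
        o = observed_information_at_null(y, x, post, nf)
        p = x.shape[1]
        assert np.all(o[:p, -1] == 0.0) and np.all(o[-1, :p] == 0.0)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_schur_statistic_equals_full_form(self, family):
        # equality of the Schur route and s^T o^{-1} s needs an invertible,
        # positive-definite o; use a moderate n so observed info is PD
        y, x, n_ref, n_alt, f = small_instance(family, n=60)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        nf = fit_null(y, x, family)
        res = js_test(y, x, post, family, nullfit=nf)
        o = observed_information_at_null(y, x, post, nf)
        s = np.zeros(o.shape[0])
        p = x.shape[1]
        s[p : p + 2] = score_at_null(y, x, post, nf)["s_beta"]
        full = float(s @ np.linalg.pinv(o) @ s)
        assert res.statistic == pytest.approx(full, rel=1e-8)


class TestJsTest:
    def test_zero_score_gives_p_one(self):
        y = np.array([0.0, 1.0])
        x = np.ones((2, 1))
        post = SitePosterior(eg=np.full((2, 2), 0.8), var=np.zeros((2, 2)))
        with pytest.warns(UserWarning):
            res = js_test(y, x, post, "logistic")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_invariant_to_likelihood_rescaling(self, rng):
        y, x, n_ref, n_alt, f = small_instance("logistic", n=40)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        r1 = js_test(y, x, posterior_moments(gl, f), "logistic")
        scaled = gl * rng.uniform(0.1, 10.0, size=(40, 2, 1))
        r2 = js_test(y, x, posterior_moments(scaled, f), "logistic")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-10)

    def test_monomorphic_sites_dropped(self, rng):
        n = 50
        x = np.ones((n, 1))
        y = rng.binomial(1, 0.5, n).astype(float)
        eg = np.column_stack([rng.uniform(0, 2, n), np.zeros(n)])
        var = np.column_stack([rng.uniform(0.01, 0.3, n), np.zeros(n)])
        with pytest.warns(UserWarning, match="monomorphic"):
            res = js_test(y, x, SitePosterior(eg=eg, var=var), "logistic")
        assert res.df == 1 and res.n_sites_used == 1

    def test_gaussian_close_to_classical_score_large_n(self, rng):
        # dispersion coupling is an O(1/N) effect: 2% agreement at N=1000
        n = 1000
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, [0.2, 0.4, 0.3], size=(n, 3))
        y = x @ [0.5, 1.0] + rng.standard_normal(n)
        nf = fit_null(y, x, "gaussian")
        res = js_test(y, x, degenerate_posterior(g), "gaussian", nullfit=nf)
        # classical score chi-square on the residualized genotype design
        r = y - nf.eta
        gc = g - x @ np.linalg.lstsq(x, g.astype(float), rcond=None)[0]
        s = gc.T @ r / nf.phi_tilde
        info = gc.T @ gc / nf.phi_tilde
        classical = float(s @ np.linalg.solve(info, s))
        assert res.statistic == pytest.approx(classical, rel=0.02)


class TestVcTest:
    def test_single_marker_equals_js(self):
        y, x, n_ref, n_alt, f = small_instance("logistic", dg=1)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        js = js_test(y, x, post, "logistic")
        vc = vc_test(y, x, post, [1.0], "logistic")
        assert vc.statistic == pytest.approx(js.statistic, abs=1e-12)
        assert vc.df == 1

    def test_weight_scale_invariance(self):
        y, x, n_ref, n_alt, f = small_instance("poisson", n=30, dg=3)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        r1 = vc_test(y, x, post, [2.0, 2.0, 2.0], "poisson")
        r2 = vc_test(y, x, post, [1.0, 1.0, 1.0], "poisson")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_matches_burden_score_test_on_hard_genotypes(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, [0.02, 0.04, 0.03], size=(n, 3))
        y = rng.binomial(1, 0.5, n).astype(float)
        res = vc_test(y, x, degenerate_posterior(g), np.ones(3), "logistic")
        ag = g.sum(axis=1).astype(float)
        null = sm.GLM(y, x, family=sm.families.Binomial()).fit()
        stat = null.model.score_test(null.params, exog_extra=ag[:, None])[0]
        stat = float(np.asarray(stat).ravel()[0])
        assert res.statistic == pytest.approx(stat, rel=1e-6)

    def test_rejects_nonpositive_weights(self):
        y, x, n_ref, n_alt, f = small_instance("logistic", dg=2)
        gl = gl_from_pileup(n_ref, n_alt, 0.01)
        post = posterior_moments(gl, f)
        with pytest.raises(ValueError):
            vc_test(y, x, post, [1.0, -1.0], "logistic")
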