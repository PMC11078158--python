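"""Exponential-family building blocks of the phenotype model.

The phenotype ``y_i`` given covariates ``x_i`` and genotypes ``g_i`` is
modelled by a generalized linear model with canonical link,

    p(y | eta, phi) = exp{ (y*eta - b(eta)) / a(phi) + c(y, phi) },

where ``eta = alpha x^T + beta g^T`` is the linear predictor.  Three response
types are supported:

* gaussian  -- a(phi) = phi (= sigma^2), b(eta) = eta^2 / 2,
               c(y, phi) = -y^2/(2 phi) - ln(2 pi phi)/2;
* logistic  -- a = 1, b(eta) = ln(1 + e^eta), c = 0;
* poisson   -- a = 1, b(eta) = e^eta, c(y) = -ln(y!).

Only the gaussian family carries a dispersion parameter; for the other two
``a`` and ``c`` are free of phi and the parameter vector shrinks to
``(alpha, beta)``.  The score and observed-information formulas used by the
group tests need the derivatives b', b'', a', a'' and the phi-derivatives of
c, all of which are exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special


class GLMFamily:
    """Base class for the supported exponential families.

    Subclasses provide the cumulant function ``b`` and its first two
    derivatives, the dispersion function ``a`` and derivatives, the
    phi-derivatives of ``c``, and the log-likelihood.
    """

    name: str = ""
    has_dispersion: bool = False

    # -- cumulant function ------------------------------------------------
    def b(self, eta):
        raise NotImplementedError

    def b1(self, eta):
        """Mean function b'(eta)."""
        raise NotImplementedError

    def b2(self, eta):
        """Variance function b''(eta); convex b means b2 >= 0."""
        raise NotImplementedError

    # -- dispersion -------------------------------------------------------
    def a(self, phi=None):
        return 1.0

    def a1(self, phi=None):
        return 0.0

    def a2(self, phi=None):
        return 0.0

    def dc_dphi(self, y, phi=None):
        return np.zeros_like(np.asarray(y, dtype=float))

    def d2c_dphi2(self, y, phi=None):
        return np.zeros_like(np.asarray(y, dtype=float))

    # -- likelihood -------------------------------------------------------
    def loglik(self, y, eta, phi=None):
        raise NotImplementedError

    def validate_response(self, y):
        pass

    def __repr__(self):  # pragma: no cover
        return f"GLMFamily({self.name!r})"


class Gaussian(GLMFamily):
    name = "gaussian"
    has_dispersion = True

    def b(self, eta):
        return np.asarray(eta, dtype=float) ** 2 / 2.0

    def b1(self, eta):
        return np.asarray(eta, dtype=float)

    def b2(self, eta):
        return np.ones_like(np.asarray(eta, dtype=float))

    def a(self, phi=None):
        return phi

    def a1(self, phi=None):
        return 1.0

    def a2(self, phi=None):
        return 0.0

    def dc_dphi(self, y, phi=None):
        y = np.asarray(y, dtype=float)
        return y**2 / (2.0 * phi**2) - 1.0 / (2.0 * phi)

    def d2c_dphi2(self, y, phi=None):
        y = np.asarray(y, dtype=float)
        return -(y**2) / phi**3 + 1.0 / (2.0 * phi**2)

    def loglik(self, y, eta, phi=None):
        y = np.asarray(y, dtype=float)
        eta = np.asarray(eta, dtype=float)
        return float(
            np.sum(-((y - eta) ** 2) / (2.0 * phi) - 0.5 * np.log(2.0 * np.pi * phi))
        )


class Logistic(GLMFamily):
    name = "logistic"
    has_dispersion = False

    def b(self, eta):
        # log(1 + e^eta) via log-sum-exp; stable for |eta| >> 30
        return np.logaddexp(0.0, np.asarray(eta, dtype=float))

    def b1(self, eta):
        return special.expit(np.asarray(eta, dtype=float))

    def b2(self, eta):
        p = special.expit(np.asarray(eta, dtype=float))
        return p * (1.0 - p)

    def loglik(self, y, eta, phi=None):
        y = np.asarray(y, dtype=float)
        eta = np.asarray(eta, dtype=float)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def validate_response(self, y):
        y = np.asarray(y)
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("logistic family requires a 0/1 response")


class Poisson(GLMFamily):
    name = "poisson"
    has_dispersion = False

    def b(self, eta):
        return np.exp(np.asarray(eta, dtype=float))

    def b1(self, eta):
        return np.exp(np.asarray(eta, dtype=float))

    def b2(self, eta):
        return np.exp(np.asarray(eta, dtype=float))

    def dc_dphi(self, y, phi=None):
        return np.zeros_like(np.asarray(y, dtype=float))

    def loglik(self, y, eta, phi=None):
        y = np.asarray(y, dtype=float)
        eta = np.asarray(eta, dtype=float)
        return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1.0)))

    def validate_response(self, y):
        y = np.asarray(y)
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("poisson family requires non-negative integer response")


_FAMILIES = {
    "gaussian": Gaussian(),
    "logistic": Logistic(),
    "poisson": Poisson(),
}


def get_family(family) -> GLMFamily:
    """Resolve a family name or instance to a :class:`GLMFamily`."""
    if isinstance(family, GLMFamily):
        return family
    try:
        return _FAMILIES[str(family).lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; expected one of {sorted(_FAMILIES)}"
        ) from None


def family_terms(family, eta, y=None, phi=None) -> dict:
    """Evaluate b, b', b'', a, a', a'' and the phi-derivatives of c.

    Parameters
    ----------
    family : str or GLMFamily
    eta : array_like
        Linear predictor values.
    y : array_like, optional
        Response; required for the gaussian family (its ``c`` depends on y).
    phi : float, optional
        Dispersion.  Must be supplied (and positive) exactly when the family
        has a dispersion parameter.
    """
    fam = get_family(family)
    if fam.has_dispersion:
        if phi is None:
            raise ValueError(f"family {fam.name!r} requires a dispersion phi")
        if phi <= 0:
            raise ValueError("dispersion phi must be > 0")
        if y is None:
            raise ValueError(f"family {fam.name!r} requires y for the c-terms")
    elif phi is not None:
        raise ValueError(f"family {fam.name!r} has no dispersion; phi must be absent")
    eta = np.asarray(eta, dtype=float)
    yy = eta * 0.0 if y is None else np.asarray(y, dtype=float)
    return {
        "b": fam.b(eta),
        "b1": fam.b1(eta),
        "b2": fam.b2(eta),
        "a": fam.a(phi) if fam.has_dispersion else 1.0,
        "a1": fam.a1(phi) if fam.has_dispersion else 0.0,
        "a2": fam.a2(phi) if fam.has_dispersion else 0.0,
        "dc_dphi": fam.dc_dphi(yy, phi),
        "d2c_dphi2": fam.d2c_dphi2(yy, phi),
    }


@dataclass
class NullFit:
    """Constrained MLE of the null model (no genetic effects).

    The phenotype is regressed on the covariates only; the resulting
    ``alpha_tilde`` (and, for gaussian, ``phi_tilde`` = RSS/N, the MLE
    denominator) is the point at which score and observed information of the
    full latent-genotype likelihood are evaluated.
    """

    alpha_tilde: np.ndarray
    phi_tilde: float | None
    loglik: float
    family: GLMFamily
    eta: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    n_iter: int = 0


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries a diagnostic message."""


def glm_fit(y, X, family, max_iter=100, tol=1e-10):
    """Fit a canonical-link GLM by iteratively reweighted least squares.

    Returns ``(beta, loglik, mu, n_iter)``.  For the gaussian family the
    returned log-likelihood is profiled over the dispersion (phi = RSS/N),
    so differences of two fits give the usual N*ln(RSS0/RSS1) statistic.

    Raises :class:`ConvergenceError` on non-convergence, with a separation
    diagnostic for the logistic family when fitted probabilities are pinned
    at 0 or 1.
    """
    fam = get_family(family)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape

    if fam.name == "gaussian":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        eta = X @ beta
        rss = float(np.sum((y - eta) ** 2))
        phi = rss / n
        ll = -0.5 * n * (np.log(2.0 * np.pi * phi) + 1.0)
        return beta, ll, eta, 1

    # start from the intercept-only solution direction
    beta = np.zeros(p)
    mean_y = float(np.clip(np.mean(y), 1e-8, None))
    # put the pulled-back mean on whichever column is constant (intercept)
    const_cols = np.where(np.ptp(X, axis=0) == 0)[0]
    if const_cols.size:
        j = const_cols[0]
        c = X[0, j]
        if fam.name == "logistic":
            m = float(np.clip(mean_y, 1e-8, 1 - 1e-8))
            beta[j] = np.log(m / (1 - m)) / c
        else:
            beta[j] = np.log(mean_y) / c

    ll = fam.loglik(y, X @ beta)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = fam.b1(eta)
        w = np.maximum(fam.b2(eta), 1e-12)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        ll_new = fam.loglik(y, X @ beta_new)
        # step-halve if the Newton step overshoots
        step = 0
        while ll_new < ll - 1e-12 and step < 20:
            beta_new = 0.5 * (beta_new + beta)
            ll_new = fam.loglik(y, X @ beta_new)
            step += 1
        done = abs(ll_new - ll) < tol * (1.0 + abs(ll_new))
        beta, ll = beta_new, ll_new
        if done:
            mu = fam.b1(X @ beta)
            if fam.name == "logistic" and (
                np.min(mu) < 1e-10 or np.max(mu) > 1 - 1e-10
            ):
                raise ConvergenceError(
                    "logistic fitted probabilities pinned at 0/1 (separation)"
                )
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < 1e-8:
                return beta, ll, X @ beta, it
    mu = fam.b1(X @ beta)
    if fam.name == "logistic" and (np.min(mu) < 1e-8 or np.max(mu) > 1 - 1e-8):
        raise ConvergenceError(
            "logistic fit did not converge: fitted probabilities pinned at 0/1 "
            "(separation)"
        )
    score = X.T @ (y - mu)
    if np.max(np.abs(score)) < 1e-8:
        return beta, ll, X @ beta, max_iter
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(max |score| = {np.max(np.abs(score)):.3e})"
    )


def fit_null(y, x, family, max_iter=100, tol=1e-10) -> NullFit:
    """Constrained MLE of the null model: phenotype on covariates only.

    ``x`` must be of full column rank and contain an intercept in its column
    span.  For the gaussian family the dispersion MLE uses the N denominator
    (not N - p): the score test evaluates at the exact constrained maximum.
    """
    fam = get_family(family)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.shape[0]:
        raise ValueError("y must be (N,), x must be (N, p) with matching N")
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need N > {p} observations, got {n}")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("covariate matrix x is rank-deficient")
    ones = np.ones(n)
    coef, *_ = np.linalg.lstsq(x, ones, rcond=None)
    if np.max(np.abs(ones - x @ coef)) > 1e-8:
        raise ValueError("x must include an intercept column (or span one)")
    fam.validate_response(y)

    beta, ll, eta, n_iter = glm_fit(y, x, fam, max_iter=max_iter, tol=tol)
    phi = None
    if fam.has_dispersion:
        phi = float(np.sum((y - eta) ** 2)) / n
        if phi <= 0:
            raise ValueError("degenerate gaussian fit: zero residual variance")
        ll = fam.loglik(y, eta, phi)
    mu = fam.b1(eta)
    return NullFit(
        alpha_tilde=beta,
        phi_tilde=phi,
        loglik=float(ll),
        family=fam,
        eta=eta,
        mu=mu,
        n_iter=n_iter,
    )
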