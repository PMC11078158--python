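"""Score tests for a group of markers computed from genotype likelihoods.

Both tests evaluate the score and observed information of the latent-
genotype log-likelihood

    l(theta) = sum_i ln sum_{g in {0,1,2}^dg} f(y_i | x_i, g; theta) h(g, D_i)

at the constrained MLE theta~ of the null model (no genetic effects), where
h(g, D_i) multiplies the read likelihood by the HWE prior.  At theta~ the
alpha- and phi-components of the score vanish by the first-order condition,
and all genotype dependence enters only through the posterior moments
E[g|D_i] and E[g^T g|D_i]:

* joint significance (JS) test: H0: beta = 0 jointly; statistic
  R = s^T o^{-1} s, chi-square with df = dg;
* variable collapse (VC) test: effects constrained to beta = beta0 * W for a
  positive weight vector W (normalized to sum dg); the chain rule projects
  the JS score and information through W, giving a 1-df chi-square.  This is
  the likelihood-uncertainty analogue of the burden test.

The statistic is computed via the Schur complement of the beta-block,
R = s_b^T [o_bb - o_bg o_gg^{-1} o_gb]^{-1} s_b with g collecting
(alpha[, phi]); algebraically identical to the full form with zero-padded
score, numerically safer.  Observed (not expected) information can be
indefinite in finite samples: eigenvalues at or below 1e-10 of the largest
are truncated (pseudo-inverse), the effective rank is reported, and the
degrees of freedom are kept at dg (or 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .families import NullFit, family_terms, fit_null, get_family
from .read_model import SitePosterior

_EIG_RTOL = 1e-10


@dataclass
class WeightVector:
    """Positive per-marker weights, normalized so that sum(w) = dg.

    The normalization is the identification constraint of the collapsed
    model (beta = beta0 * W); the test statistic is invariant to the overall
    scale of the input weights.
    """

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D vector")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        self.w = w * (w.size / w.sum())


@dataclass
class ScoreTestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    score_beta: np.ndarray | None = None
    info: np.ndarray | None = None
    rank: int = 0
    n_sites_used: int = 0
    notes: dict = field(default_factory=dict)


def beta_weights(mafs) -> WeightVector:
    """Beta(1, 25)-density weights, the standard rare-variant up-weighting.

    w_j is proportional to 25 (1 - MAF_j)^24 and renormalized to sum dg.
    A zero MAF is rejected (the weight target is undefined for a
    monomorphic marker).
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs >= 1):
        raise ValueError("MAFs must lie strictly in (0, 1)")
    return WeightVector(stats.beta.pdf(mafs, 1.0, 25.0))


def _as_moments(posterior):
    if isinstance(posterior, SitePosterior):
        eg, var = posterior.eg, posterior.var
    else:
        eg, var = posterior
        eg = np.asarray(eg, dtype=float)
        var = np.asarray(var, dtype=float)
    if eg.ndim != 2 or eg.shape != var.shape:
        raise ValueError("posterior moments must be (N, dg) arrays")
    return eg, var


def _check_nullfit(y, x, nullfit: NullFit):
    fam = nullfit.family
    r = np.asarray(y, dtype=float) - nullfit.mu
    a = fam.a(nullfit.phi_tilde) if fam.has_dispersion else 1.0
    s_alpha = x.T @ r / a
    if np.max(np.abs(s_alpha)) > 1e-6:
        raise ValueError(
            "stale null fit: score w.r.t. alpha is "
            f"{np.max(np.abs(s_alpha)):.3e}, expected ~0"
        )
    return r, a


def _blocks(y, x, eg, var, nullfit: NullFit):
    """Score vector and observed-information blocks at the null fit."""
    fam = nullfit.family
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    r, a = _check_nullfit(y, x, nullfit)
    tf = family_terms(
        fam,
        nullfit.eta,
        y=y if fam.has_dispersion else None,
        phi=nullfit.phi_tilde,
    )
    b2 = tf["b2"]
    s_beta = (r / a) @ eg
    o_aa = x.T @ (b2[:, None] * x) / a
    o_ab = x.T @ (b2[:, None] * eg) / a
    # o_bb = sum_i (b2_i/a) E[g^T g] - (r_i/a)^2 (E[g^T g] - E[g]^T E[g]);
    # the bracketed difference is diag(var_i) under cross-site factorization
    o_bb = eg.T @ (b2[:, None] * eg) / a + np.diag((b2 / a - (r / a) ** 2) @ var)
    out = {"s_beta": s_beta, "o_aa": o_aa, "o_ab": o_ab, "o_bb": o_bb}
    if fam.has_dispersion:
        a1, a2 = tf["a1"], tf["a2"]
        out["o_bphi"] = (a1 / a**2) * (r @ eg)
        dev = y * nullfit.eta - tf["b"]
        out["o_pp"] = -float(
            np.sum(dev * (2.0 * a1**2 / a**3 - a2 / a**2) + tf["d2c_dphi2"])
        )
    if not all(np.all(np.isfinite(v)) for v in out.values()):
        raise ValueError("non-finite entries in score/information blocks")
    return out


def score_at_null(y, x, posterior, nullfit: NullFit) -> dict:
    """Score of the latent-genotype likelihood at the constrained MLE.

    The alpha (and phi) components vanish by the first-order condition of
    the null fit; they are asserted, not recomputed.  The beta component is
    s_beta = sum_i (y_i - b'(alpha~ x_i^T)) / a(phi~) * E[g|D_i].
    """
    eg, var = _as_moments(posterior)
    bl = _blocks(y, x, eg, var, nullfit)
    out = {"s_beta": bl["s_beta"], "s_alpha": np.zeros(np.asarray(x).shape[1])}
    if nullfit.family.has_dispersion:
        out["s_phi"] = 0.0
    return out


def observed_information_at_null(y, x, posterior, nullfit: NullFit):
    """Full observed information at theta~, ordered (alpha, beta[, phi]).

    The alpha-phi block is exactly zero in the dispersion branch.
    """
    eg, var = _as_moments(posterior)
    bl = _blocks(y, x, eg, var, nullfit)
    p = np.asarray(x).shape[1]
    dg = eg.shape[1]
    if nullfit.family.has_dispersion:
        k = p + dg + 1
        o = np.zeros((k, k))
        o[:p, :p] = bl["o_aa"]
        o[:p, p : p + dg] = bl["o_ab"]
        o[p : p + dg, :p] = bl["o_ab"].T
        o[p : p + dg, p : p + dg] = bl["o_bb"]
        o[p : p + dg, -1] = bl["o_bphi"]
        o[-1, p : p + dg] = bl["o_bphi"]
        o[-1, -1] = bl["o_pp"]
        return o
    k = p + dg
    o = np.zeros((k, k))
    o[:p, :p] = bl["o_aa"]
    o[:p, p:] = bl["o_ab"]
    o[p:, :p] = bl["o_ab"].T
    o[p:, p:] = bl["o_bb"]
    return o


def _informative_sites(eg, var):
    """Sites with any posterior uncertainty or between-individual variation."""
    return (var.max(axis=0) > 1e-12) | (np.ptp(eg, axis=0) > 1e-12)


def _schur(bl):
    """Schur complement of the beta block w.r.t. (alpha[, phi])."""
    o_ab = bl["o_ab"]
    s = bl["o_bb"] - o_ab.T @ np.linalg.solve(bl["o_aa"], o_ab)
    if "o_pp" in bl:
        s = s - np.outer(bl["o_bphi"], bl["o_bphi"]) / bl["o_pp"]
    return s


def _quadratic_form(s_beta, schur):
    """R = s^T pinv(schur) s with eigenvalue truncation; returns (R, rank)."""
    lam, u = np.linalg.eigh((schur + schur.T) / 2.0)
    lmax = lam.max() if lam.size else 0.0
    if lmax <= 0:
        return 0.0, 0
    keep = lam > _EIG_RTOL * lmax
    t = u.T @ s_beta
    return float(np.sum(t[keep] ** 2 / lam[keep])), int(keep.sum())


def _prepare(y, x, posterior, family, nullfit, warn_small=True):
    fam = get_family(family)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    eg, var = _as_moments(posterior)
    if eg.shape[0] != y.shape[0]:
        raise ValueError("posterior moments and phenotype disagree on N")
    if nullfit is None:
        nullfit = fit_null(y, x, fam)
    elif nullfit.family.name != fam.name:
        raise ValueError("null fit family does not match requested family")
    keep = _informative_sites(eg, var)
    dropped = np.where(~keep)[0]
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} monomorphic site(s) from the group: "
            f"{dropped.tolist()}",
            stacklevel=3,
        )
    dg_kept = int(keep.sum())
    if warn_small and y.shape[0] <= x.shape[1] + dg_kept:
        warnings.warn(
            "sample size is not larger than the parameter count; the "
            "chi-square approximation may be poor",
            stacklevel=3,
        )
    return y, x, eg[:, keep], var[:, keep], nullfit, keep, dropped


def js_test(y, x, posterior, family, nullfit=None) -> ScoreTestResult:
    """Joint significance score test of H0: beta = 0 for all dg markers.

    ``posterior`` is a :class:`SitePosterior` (or an ``(eg, var)`` pair of
    (N, dg) arrays).  ``nullfit`` may be supplied to reuse a constrained MLE
    across several tests on the same phenotype and covariates.
    """
    y, x, eg, var, nullfit, keep, dropped = _prepare(y, x, posterior, family, nullfit)
    dg = eg.shape[1]
    if dg == 0:
        return ScoreTestResult(
            statistic=0.0, df=0, p_value=1.0, method="js", rank=0,
            n_sites_used=0, notes={"dropped_sites": dropped.tolist()},
        )
    bl = _blocks(y, x, eg, var, nullfit)
    schur = _schur(bl)
    stat, rank = _quadratic_form(bl["s_beta"], schur)
    notes = {"dropped_sites": dropped.tolist()}
    if rank < dg:
        notes["rank_deficient"] = True
        warnings.warn(
            f"information matrix has effective rank {rank} < dg = {dg}; "
            "pseudo-inverse used, df kept at dg",
            stacklevel=2,
        )
    p = float(stats.chi2.sf(stat, dg)) if stat > 0 else 1.0
    return ScoreTestResult(
        statistic=stat, df=dg, p_value=p, method="js",
        score_beta=bl["s_beta"], info=schur, rank=rank,
        n_sites_used=dg, notes=notes,
    )


def vc_test(y, x, posterior, weights, family, nullfit=None) -> ScoreTestResult:
    """Variable collapse score test: H0: beta0 = 0 with beta = beta0 * W.

    Projects the JS score and information through the weight vector, giving
    a 1-df chi-square; with dg = 1 and w = (1) it coincides with
    :func:`js_test`.
    """
    y, x, eg, var, nullfit, keep, dropped = _prepare(y, x, posterior, family, nullfit)
    if not isinstance(weights, WeightVector):
        weights = WeightVector(np.asarray(weights, dtype=float))
    if weights.w.shape[0] != keep.shape[0]:
        raise ValueError("weights length must equal the number of sites")
    dg = eg.shape[1]
    notes = {"dropped_sites": dropped.tolist()}
    if dg == 0:
        return ScoreTestResult(
            statistic=0.0, df=1, p_value=1.0, method="vc", rank=0,
            n_sites_used=0, notes=notes,
        )
    w = WeightVector(weights.w[keep]).w  # renormalize over retained sites
    bl = _blocks(y, x, eg, var, nullfit)
    schur = _schur(bl)
    s0 = float(w @ bl["s_beta"])
    denom = float(w @ schur @ w)
    if denom <= 0:
        notes["rank_deficient"] = True
        return ScoreTestResult(
            statistic=0.0, df=1, p_value=1.0, method="vc", rank=0,
            score_beta=bl["s_beta"], n_sites_used=dg, notes=notes,
        )
    stat = s0**2 / denom
    return ScoreTestResult(
        statistic=stat, df=1, p_value=float(stats.chi2.sf(stat, 1)), method="vc",
        score_beta=bl["s_beta"], info=schur, rank=1, n_sites_used=dg, notes=notes,
    )
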