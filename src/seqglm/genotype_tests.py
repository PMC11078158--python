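"""Genotype-based comparator tests on hard genotype calls.

These are the classical methods the likelihood-based tests are benchmarked
against: a group likelihood-ratio chi-square test (with an exact-F variant
for the gaussian family) of the phenotype on called genotypes, and the
weighted burden test regressing the phenotype on the weighted rare-allele
sum.  Calls are typically produced by MAP calling under a HWE prior with
two-step allele frequencies (:func:`seqglm.allele_freq.two_step_af`).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, stats

from .families import get_family, glm_fit
from .group_tests import ScoreTestResult, WeightVector


def _validate(y, x, calls):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    calls = np.asarray(calls, dtype=float)
    if calls.ndim != 2 or calls.shape[0] != y.shape[0] or x.shape[0] != y.shape[0]:
        raise ValueError("y, x and calls disagree on the number of individuals")
    if not np.all(np.isin(calls, (0.0, 1.0, 2.0))):
        raise ValueError("calls must take values in {0, 1, 2}")
    return y, x, calls


def _independent_columns(x, block):
    """Columns of ``block`` independent of x and of each other (QR pivot)."""
    coef, *_ = np.linalg.lstsq(x, block, rcond=None)
    resid = block - x @ coef
    if not np.any(np.abs(resid) > 1e-10):
        return np.array([], dtype=int)
    _, r, piv = linalg.qr(resid, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(resid.shape) * np.finfo(float).eps * 1e3
    k = int(np.sum(d > tol))
    return np.sort(piv[:k])


def _lrt(y, x, extra, family, method):
    """2*(loglik_full - loglik_null) for the GLM with ``extra`` columns."""
    fam = get_family(family)
    fam.validate_response(y)
    sel = _independent_columns(x, extra)
    notes: dict = {"n_extra_columns": int(sel.size)}
    if sel.size == 0:
        return ScoreTestResult(
            statistic=0.0, df=0, p_value=1.0, method=method,
            n_sites_used=extra.shape[1], notes=notes,
        )
    x_full = np.column_stack([x, extra[:, sel]])
    _, ll0, eta0, _ = glm_fit(y, x, fam)
    _, ll1, eta1, _ = glm_fit(y, x_full, fam)
    df = int(sel.size)
    stat = max(2.0 * (ll1 - ll0), 0.0)
    if fam.name == "gaussian":
        n = y.shape[0]
        rss0 = float(np.sum((y - eta0) ** 2))
        rss1 = float(np.sum((y - eta1) ** 2))
        p_full = x_full.shape[1]
        fstat = ((rss0 - rss1) / df) / (rss1 / (n - p_full))
        notes["f_statistic"] = fstat
        notes["f_pvalue"] = float(stats.f.sf(fstat, df, n - p_full))
    return ScoreTestResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)),
        method=method, rank=df, n_sites_used=extra.shape[1], notes=notes,
    )


def genotype_group_test(y, x, calls, family) -> ScoreTestResult:
    """Group chi-square (LRT) test of phenotype on called genotypes.

    Fits the GLM of y on [x | calls] against the null of y on x; df is the
    rank of the calls block after projection on x.  For the gaussian family
    the exact F statistic and its p-value are reported in ``notes``.
    """
    y, x, calls = _validate(y, x, calls)
    return _lrt(y, x, calls, family, "genotype_chisq")


def burden_test(y, x, calls, weights, family) -> ScoreTestResult:
    """Weighted burden test: 1-df LRT on the weighted rare-allele sum.

    AG_i = sum_j w_j g_ij with weights normalized to sum dg; a constant
    burden across individuals yields statistic 0 and p = 1 with a warning.
    """
    y, x, calls = _validate(y, x, calls)
    if not isinstance(weights, WeightVector):
        weights = WeightVector(np.asarray(weights, dtype=float))
    if weights.w.shape[0] != calls.shape[1]:
        raise ValueError("weights length must match the number of markers")
    ag = calls @ weights.w
    if np.ptp(ag) < 1e-12:
        warnings.warn("burden score is constant across individuals", stacklevel=2)
        return ScoreTestResult(
            statistic=0.0, df=1, p_value=1.0, method="burden",
            n_sites_used=calls.shape[1], notes={"constant_burden": True},
        )
    res = _lrt(y, x, ag[:, None], family, "burden")
    res.n_sites_used = calls.shape[1]
    return res
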