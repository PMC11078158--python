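"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's fast paths: posterior
moments by explicit enumeration of the 3^dg genotype vector space, and the
latent-genotype log-likelihood summed the same way, differentiated
numerically.  They are the ground truth the O(dg) implementations are
checked against.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from seqglm.read_model import hwe_prior


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enumerate_posterior_moments(gl, f):
    """E[g|D] and E[g^T g|D] by explicit sum over {0,1,2}^dg.

    ``gl`` is (dg, 3) for one individual; returns (eg, egg) with egg the
    full dg x dg second-moment matrix.
    """
    gl = np.asarray(gl, dtype=float)
    dg = gl.shape[0]
    prior = hwe_prior(np.asarray(f, dtype=float))
    num_eg = np.zeros(dg)
    num_egg = np.zeros((dg, dg))
    denom = 0.0
    for g in itertools.product((0, 1, 2), repeat=dg):
        gv = np.array(g, dtype=float)
        h = float(np.prod([gl[j, g[j]] * prior[j, g[j]] for j in range(dg)]))
        denom += h
        num_eg += gv * h
        num_egg += np.outer(gv, gv) * h
    return num_eg / denom, num_egg / denom


def latent_loglik(theta, y, x, gl, f, family_name):
    """Log-likelihood of (y, D) with latent genotypes, brute-force 3^dg sum."""
    p = x.shape[1]
    dg = gl.shape[1]
    alpha = theta[:p]
    beta = theta[p : p + dg]
    phi = theta[p + dg] if family_name == "gaussian" else None
    prior = hwe_prior(np.asarray(f, dtype=float))
    total = 0.0
    for i in range(len(y)):
        acc = 0.0
        for g in itertools.product((0, 1, 2), repeat=dg):
            gv = np.array(g, dtype=float)
            h = float(
                np.prod([gl[i, j, g[j]] * prior[j, g[j]] for j in range(dg)])
            )
            eta = float(x[i] @ alpha + gv @ beta)
            if family_name == "gaussian":
                fy = stats.norm.pdf(y[i], eta, np.sqrt(phi))
            elif family_name == "logistic":
                pr = 1.0 / (1.0 + np.exp(-eta))
                fy = pr ** y[i] * (1.0 - pr) ** (1.0 - y[i])
            elif family_name == "poisson":
                fy = stats.poisson.pmf(y[i], np.exp(eta))
            else:  # pragma: no cover
                raise ValueError(family_name)
            acc += fy * h
        total += np.log(acc)
    return total


def numerical_gradient(fn, theta, h=1e-5):
    g = np.zeros_like(theta)
    for k in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        g[k] = (fn(tp) - fn(tm)) / (2.0 * h)
    return g


def numerical_hessian(fn, theta, h=1e-4):
    k = theta.size
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[a] += h
            tpp[b] += h
            tpm[a] += h
            tpm[b] -= h
            tmp[a] -= h
            tmp[b] += h
            tmm[a] -= h
            tmm[b] -= h
            out[a, b] = (fn(tpp) - fn(tpm) - fn(tmp) + fn(tmm)) / (4.0 * h * h)
    return out


def small_instance(family_name, seed=42, n=6, dg=2):
    """A tiny reads + phenotype instance for the brute-force oracles."""
    rg = np.random.default_rng(seed)
    x = np.column_stack([np.ones(n), rg.standard_normal(n)])
    f = rg.uniform(0.1, 0.4, size=dg)
    g = rg.binomial(2, f, size=(n, dg))
    tot = rg.poisson(2.0, size=(n, dg))
    p_alt = 0.01 + g / 2.0 * 0.98
    n_alt = rg.binomial(tot, p_alt)
    n_ref = tot - n_alt
    if family_name == "logistic":
        # fixed interleaved pattern: avoids separation at tiny n
        y = np.resize([1.0, 0.0, 1.0, 0.0, 0.0, 1.0], n)
    elif family_name == "poisson":
        y = rg.poisson(2.0, size=n).astype(float)
    else:
        y = rg.standard_normal(n) + 1.0
    return y, x, n_ref, n_alt, f
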