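"""Allele-frequency estimation from genotype likelihoods.

Two estimators are provided, mirroring common practice with low-coverage
sequencing data:

* the one-step maximum-likelihood estimator, maximizing per site
  sum_i ln sum_g p(D_i|g) HWE(g|f) by EM with the update
  f <- (1/2N) sum_i E[g_i | D_i, f];
* the two-step genotype-based estimator: call genotypes by MAP under a HWE
  prior, then count alleles.  Calling starts from a flat f = 0.5 prior and
  performs one refinement round (recount, recall, recount).

Hard genotype calls for the genotype-based comparator tests also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .read_model import hwe_prior

_G = np.array([0.0, 1.0, 2.0])


@dataclass
class AlleleFrequencies:
    """Per-site allele frequencies with estimator provenance."""

    f: np.ndarray
    method: str
    degenerate: np.ndarray = field(default=None)
    n_iter: int = 0

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if np.any(self.f < 0) or np.any(self.f > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.f.shape, dtype=bool)


class EMConvergenceError(RuntimeError):
    """EM hit max_iter; the last iterate is attached as ``last_f``."""

    def __init__(self, msg, last_f):
        super().__init__(msg)
        self.last_f = last_f


def _normalized_gl(gl):
    gl = np.asarray(gl, dtype=float)
    if gl.ndim == 2:
        gl = gl[None]
    if gl.ndim != 3 or gl.shape[-1] != 3:
        raise ValueError(f"gl must have shape (N, M, 3); got {gl.shape}")
    mx = gl.max(axis=-1, keepdims=True)
    if np.any(mx <= 0):
        raise ValueError("every likelihood triple needs a positive entry")
    return gl / mx


def af_em(gl, tol=1e-6, max_iter=200, f0=0.5) -> AlleleFrequencies:
    """One-step MLE of allele frequencies by per-site EM.

    Sites whose likelihoods are flat for every individual (e.g. nobody has
    any reads) carry no information about f; they are returned at the
    initialization value with a ``degenerate`` flag.  The EM objective is
    asserted non-decreasing at every iteration.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    gl = _normalized_gl(gl)
    n, m, _ = gl.shape
    flat = np.all(np.ptp(gl, axis=-1) < 1e-12, axis=0)  # (M,)
    f = np.full(m, float(f0))
    ll_prev = -np.inf
    for it in range(1, max_iter + 1):
        w = gl * hwe_prior(f)[None, :, :]
        tot = w.sum(axis=-1)
        if np.any(tot <= 0):
            raise ValueError("zero posterior mass during EM")
        ll = float(np.log(tot).sum())
        assert ll >= ll_prev - 1e-8 * (1.0 + abs(ll)), "EM log-likelihood decreased"
        ll_prev = ll
        eg = (w @ _G) / tot
        f_new = np.clip(eg.mean(axis=0) / 2.0, 0.0, 1.0)
        f_new[flat] = f0
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return AlleleFrequencies(f=f, method="em_mle", degenerate=flat, n_iter=it)
    raise EMConvergenceError(
        f"allele-frequency EM did not converge in {max_iter} iterations", last_f=f
    )


def call_genotypes(gl, f):
    """MAP genotype calls under the HWE prior; ties break toward smaller g."""
    gl = _normalized_gl(gl)
    f = np.broadcast_to(np.asarray(f, dtype=float), (gl.shape[1],))
    post = gl * hwe_prior(f)[None, :, :]
    return np.argmax(post, axis=-1).astype(np.int8)  # argmax: first max wins


def af_from_calls(calls) -> AlleleFrequencies:
    """Allele frequencies as mean(g)/2 over hard calls."""
    calls = np.asarray(calls)
    if not np.all(np.isin(calls, (0, 1, 2))):
        raise ValueError("calls must take values in {0, 1, 2}")
    return AlleleFrequencies(f=calls.mean(axis=0) / 2.0, method="two_step")


def two_step_af(gl):
    """Two-step genotype-based allele frequencies.

    Call with a flat f = 0.5 HWE prior, recount, re-call once with the
    updated frequencies, recount again, freeze.  Returns
    ``(AlleleFrequencies, calls)`` where calls are the final MAP calls.
    """
    gl = _normalized_gl(gl)
    calls0 = call_genotypes(gl, np.full(gl.shape[1], 0.5))
    f1 = calls0.mean(axis=0) / 2.0
    calls1 = call_genotypes(gl, f1)
    af = af_from_calls(calls1)
    flat = np.all(np.ptp(gl, axis=-1) < 1e-12, axis=0)
    af.degenerate = flat
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} site(s) carry no read information; "
            "two-step frequencies there reflect the prior mode only",
            stacklevel=2,
        )
    return af, calls1
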