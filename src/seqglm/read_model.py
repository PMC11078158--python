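"""From sequencing reads to posterior genotype moments.

At a biallelic site the reads of individual i are summarised by counts of
reference and alternate alleles.  Under independent reads with a symmetric
per-base error rate e, a read shows the alternate allele with probability

    p(alt | g) = (g/2) (1 - e) + (1 - g/2) e,      g in {0, 1, 2},

so the genotype likelihood is L(g) = p_alt(g)^n_alt * (1 - p_alt(g))^n_ref
(the binomial coefficient is a g-free constant and is dropped; likelihoods
are defined up to positive scale).  Combining L with the Hardy-Weinberg
prior ((1-f)^2, 2f(1-f), f^2) at allele frequency f gives the per-site
posterior over {0,1,2}, whose first two moments E[g|D] and E[g g^T|D] are
everything the association tests consume.

Because both the read likelihood and the HWE prior factorize across sites,
the joint posterior over the genotype vector space {0,1,2}^dg factorizes
too: per-site moments are exact, and cross-site second moments are products
of means.  This is an exact O(dg) reformulation of the 3^dg enumeration
(verified against brute force in the test suite), not an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_G = np.array([0.0, 1.0, 2.0])


def _check_error_rate(error_rate):
    if not (0.0 < error_rate < 0.5):
        raise ValueError(f"error_rate must be in (0, 0.5), got {error_rate}")


def site_likelihood(n_ref, n_alt, error_rate):
    """Genotype likelihood triple (L0, L1, L2) from read counts at one site.

    Zero total reads gives the flat triple (1, 1, 1).
    """
    _check_error_rate(error_rate)
    if n_ref < 0 or n_alt < 0:
        raise ValueError("read counts must be non-negative")
    p_alt = error_rate + _G / 2.0 * (1.0 - 2.0 * error_rate)
    return p_alt**n_alt * (1.0 - p_alt) ** n_ref


def gl_from_pileup(n_ref, n_alt, error_rate):
    """Vectorized genotype likelihoods, shape ``(..., 3)``, max-normalized.

    Computed in log space so deep pileups (hundreds of reads) do not
    underflow; each cell is rescaled to max 1, which is immaterial because
    likelihoods are scale-free.
    """
    _check_error_rate(error_rate)
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    if np.any(n_ref < 0) or np.any(n_alt < 0):
        raise ValueError("read counts must be non-negative")
    p_alt = error_rate + _G / 2.0 * (1.0 - 2.0 * error_rate)
    logl = n_alt[..., None] * np.log(p_alt) + n_ref[..., None] * np.log1p(-p_alt)
    logl -= logl.max(axis=-1, keepdims=True)
    return np.exp(logl)


def hwe_prior(f):
    """Hardy-Weinberg genotype prior ((1-f)^2, 2f(1-f), f^2), shape (..., 3)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("allele frequency must be in [0, 1]")
    return np.stack([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2], axis=-1)


@dataclass
class SitePosterior:
    """Posterior genotype moments per individual.

    ``eg`` holds E[g|D] and ``var`` the per-site posterior variances
    Var[g|D]; the second-moment matrix E[g^T g|D] of an individual is then
    eg^T eg + diag(var) (cross-site posterior independence).
    """

    eg: np.ndarray
    var: np.ndarray

    @property
    def egg_diag(self):
        """Diagonal of E[g^T g | D]: E[g^2|D] per site."""
        return self.var + self.eg**2

    def egg(self, i=None):
        """Full dg x dg second-moment matrix E[g^T g|D] for individual i.

        With 1-D moments (a single individual) ``i`` is ignored.
        """
        eg = self.eg if self.eg.ndim == 1 else self.eg[i]
        var = self.var if self.var.ndim == 1 else self.var[i]
        return np.outer(eg, eg) + np.diag(var)


def posterior_moments(gl, f) -> SitePosterior:
    """Posterior genotype moments from likelihoods and allele frequencies.

    Parameters
    ----------
    gl : array, shape (N, dg, 3) or (dg, 3)
        Genotype likelihood triples (any positive scaling).
    f : array, shape (dg,)
        Allele frequencies of the HWE prior.

    Raises ``ValueError`` when likelihood and prior put no mass on any
    genotype at some site (disjoint support).
    """
    gl = np.asarray(gl, dtype=float)
    single = gl.ndim == 2
    if single:
        gl = gl[None]
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if gl.ndim != 3 or gl.shape[-1] != 3 or gl.shape[1] != f.shape[0]:
        raise ValueError(
            f"gl shape {gl.shape} incompatible with {f.shape[0]} allele frequencies"
        )
    if np.any(gl < 0):
        raise ValueError("genotype likelihoods must be non-negative")
    w = gl * hwe_prior(f)[None, :, :]
    total = w.sum(axis=-1)
    if np.any(total <= 0):
        i, j = np.argwhere(total <= 0)[0]
        raise ValueError(
            f"zero posterior mass for individual {i} at site {j}: "
            "likelihood and HWE prior have disjoint support"
        )
    post = w / total[..., None]
    eg = post @ _G
    eg2 = post @ _G**2
    var = np.maximum(eg2 - eg**2, 0.0)
    if single:
        return SitePosterior(eg=eg[0], var=var[0])
    return SitePosterior(eg=eg, var=var)
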