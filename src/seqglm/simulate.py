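"""Synthetic low-coverage sequencing studies.

The generator emulates the benchmark design the tests were developed for:

* biallelic markers with MAFs drawn uniformly from (0.05, 0.5) for common
  variants or (0.005, 0.05) for rare variants (the common/rare split is at
  MAF 0.05), genotypes ~ Binomial(2, MAF) per individual;
* per-site read counts ~ Poisson(mean depth) with depths of interest 1X,
  2X, 4X and 10X, each read flipping allele with per-base error 0.5%;
* covariates X1 ~ Bernoulli(0.5) and X2 ~ N(0, 1);
* phenotypes from the generative models
  binary:  logit P(y=1) = b0 + b1 X1 + b2 X2 + sum_j beta_gj G_j + eps,
           eps ~ N(0,1) (the latent-logit noise is part of the stated
           design for binary traits; toggle with ``include_eta_noise``),
  count:   y ~ Poisson(exp(eta)) with no eta-noise,
  gaussian: y ~ N(eta, 1),
  with b0 = 0, b1 = b2 = 1;
* causal architectures drawing the causal count uniformly from {2..5}
  (common) or {2..10} (rare), splitting a total effect of
  0.2 x magnitude (magnitude on a 0..5 grid) equally across causal sites,
  all effects positive by default.

An optional AR(1) Gaussian-copula haplotype mode couples adjacent sites
(``ld_rho``); it is off by default since the tests' operating
characteristics depend on depth, error, MAF and effect size rather than
fine-grained linkage structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

COMMON_MAF_RANGE = (0.05, 0.5)
RARE_MAF_RANGE = (0.005, 0.05)
CAUSAL_COUNT_RANGE = {"common": (2, 5), "rare": (2, 10)}
DEFAULT_GROUP_SIZE = {"common": 5, "rare": 10}


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset."""

    n_individuals: int
    n_markers: int
    variant_class: str = "common"  # 'common' | 'rare'
    maf_range: tuple | None = None  # overrides the class default
    depth: float = 1.0
    error_rate: float = 0.005
    family: str = "logistic"
    magnitude: float = 0.0  # 0..5; total genetic effect = effect_scale * magnitude
    effect_scale: float = 0.2
    direction: str = "positive"  # 'positive' | 'mixed'
    include_eta_noise: bool | None = None  # None: on for logistic only
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.variant_class not in ("common", "rare"):
            raise ValueError("variant_class must be 'common' or 'rare'")
        if self.include_eta_noise is None:
            self.include_eta_noise = self.family == "logistic"


@dataclass
class SimulatedDataset:
    genotypes: np.ndarray
    n_ref: np.ndarray
    n_alt: np.ndarray
    covariates: np.ndarray  # (N, 3): intercept, X1, X2
    phenotype: np.ndarray
    true_afs: np.ndarray
    effects: np.ndarray
    causal_indices: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)


def draw_mafs(rng, n_markers, variant_class="common", maf_range=None):
    """Per-site MAFs, uniform on the class range (split at 0.05)."""
    lo, hi = maf_range or (
        COMMON_MAF_RANGE if variant_class == "common" else RARE_MAF_RANGE
    )
    return rng.uniform(lo, hi, size=n_markers)


def simulate_genotypes(rng, n_individuals, mafs, ld_rho=0.0):
    """Genotypes ~ Binomial(2, MAF); optional AR(1)-copula LD across sites."""
    mafs = np.asarray(mafs, dtype=float)
    if ld_rho == 0.0:
        return rng.binomial(2, mafs, size=(n_individuals, mafs.size)).astype(np.int8)
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    m = mafs.size
    z = np.empty((n_individuals, 2, m))
    z[:, :, 0] = rng.standard_normal((n_individuals, 2))
    scale = np.sqrt(1.0 - ld_rho**2)
    for j in range(1, m):
        z[:, :, j] = ld_rho * z[:, :, j - 1] + scale * rng.standard_normal(
            (n_individuals, 2)
        )
    hap = z < stats.norm.ppf(mafs)[None, None, :]
    return hap.sum(axis=1).astype(np.int8)


def simulate_reads(rng, genotypes, depth, error_rate=0.005):
    """Read pileups: totals ~ Poisson(depth), alt reads flip with error e.

    Returns ``(n_ref, n_alt)`` count matrices.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    g = np.asarray(genotypes)
    total = rng.poisson(depth, size=g.shape)
    p_alt = error_rate + g / 2.0 * (1.0 - 2.0 * error_rate)
    n_alt = rng.binomial(total, p_alt)
    return total - n_alt, n_alt


def simulate_covariates(rng, n_individuals):
    """Design matrix [1, X1, X2] with X1 ~ Bernoulli(0.5), X2 ~ N(0,1)."""
    x1 = rng.binomial(1, 0.5, size=n_individuals)
    x2 = rng.standard_normal(n_individuals)
    return np.column_stack([np.ones(n_individuals), x1, x2]).astype(float)


def draw_causal_architecture(
    rng, n_markers, variant_class="common", magnitude=0.0,
    effect_scale=0.2, direction="positive",
):
    """Effects vector: causal count uniform on the class range, equal split.

    The total effect is ``effect_scale * magnitude`` (0.2 x magnitude, so a
    magnitude grid of 0..5 spans total effects 0..1), divided equally among
    the causal sites; ``direction='mixed'`` randomizes signs.
    """
    effects = np.zeros(n_markers)
    if magnitude == 0:
        return effects
    lo, hi = CAUSAL_COUNT_RANGE[variant_class]
    hi = min(hi, n_markers)
    if n_markers < lo:
        raise ValueError(f"need at least {lo} markers for a causal draw")
    n_causal = int(rng.integers(lo, hi + 1))
    idx = rng.choice(n_markers, size=n_causal, replace=False)
    per = effect_scale * magnitude / n_causal
    effects[idx] = per
    if direction == "mixed":
        effects[idx] *= rng.choice([-1.0, 1.0], size=n_causal)
    elif direction != "positive":
        raise ValueError("direction must be 'positive' or 'mixed'")
    return effects


def simulate_phenotype(
    rng, genotypes, covariates, effects, family="logistic",
    include_eta_noise=None, betas=(0.0, 1.0, 1.0),
):
    """Phenotype from the generative GLM with eta = x beta + G effects."""
    g = np.asarray(genotypes, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if include_eta_noise is None:
        include_eta_noise = family == "logistic"
    eta = x @ np.asarray(betas, dtype=float) + g @ np.asarray(effects, dtype=float)
    if include_eta_noise:
        eta = eta + rng.standard_normal(eta.shape[0])
    if family == "logistic":
        return rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    if family == "poisson":
        if np.any(eta > 30):
            raise ValueError(
                "poisson mean overflow (eta > 30); reduce effects or covariates"
            )
        return rng.poisson(np.exp(eta)).astype(float)
    if family == "gaussian":
        return eta + rng.standard_normal(eta.shape[0])
    raise ValueError(f"unknown family {family!r}")


def simulate_dataset(config: SimulationConfig, rng=None) -> SimulatedDataset:
    """End-to-end draw: MAFs, genotypes, reads, covariates, phenotype.

    Fully determined by ``config`` (including its seed) unless an external
    generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mafs = draw_mafs(rng, config.n_markers, config.variant_class, config.maf_range)
    g = simulate_genotypes(rng, config.n_individuals, mafs, config.ld_rho)
    n_ref, n_alt = simulate_reads(rng, g, config.depth, config.error_rate)
    x = simulate_covariates(rng, config.n_individuals)
    effects = draw_causal_architecture(
        rng, config.n_markers, config.variant_class, config.magnitude,
        config.effect_scale, config.direction,
    )
    y = simulate_phenotype(
        rng, g, x, effects, config.family, config.include_eta_noise
    )
    return SimulatedDataset(
        genotypes=g, n_ref=n_ref, n_alt=n_alt, covariates=x, phenotype=y,
        true_afs=mafs, effects=effects,
        causal_indices=np.flatnonzero(effects), config=config,
    )
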