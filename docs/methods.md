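# Methods

## Model

For individual i with phenotype y_i, covariate row x_i (intercept plus dx
covariates) and latent genotype row g_i over dg biallelic markers
(values 0/1/2), the response follows an exponential-family GLM with
canonical link:

    p(y | η, φ) = exp{ (yη − b(η)) / a(φ) + c(y, φ) },   η = α x′ + β g′.

Three families are built in: gaussian (a = φ = σ², b = η²/2), logistic
(a = 1, b = ln(1 + e^η)) and Poisson (a = 1, b = e^η). Only the gaussian
family carries a dispersion parameter; the parameter vector is (α, β, φ)
or (α, β) accordingly, and every formula below has both branches.

Genotypes are never observed. The sequencing reads D_i enter through

    p(y_i, D_i | x_i) = Σ_{g ∈ {0,1,2}^dg} f(y_i | x_i, g) h(g, D_i),
    h(g, D_i) = p(D_i | g) · HWE(g | f̂),

with a symmetric per-base error model p(alt read | g) = (g/2)(1−e) +
(1−g/2)e, independent reads, and the Hardy–Weinberg prior
((1−f)², 2f(1−f), f²) at allele frequency f̂ per site. Likelihoods may
also be supplied externally (BEAGLE-GL text; VCF GL = log10 likelihoods or
PL = phred, converted via 10^GL and 10^(−PL/10)); only biallelic records
are accepted.

**Cross-site factorization.** The read likelihood and the HWE prior both
factorize over sites, so the genotype posterior factorizes too: the 3^dg
sum collapses to per-site moments, with E[g_j g_k | D] = E[g_j|D]E[g_k|D]
for j ≠ k. This is an exact O(dg) reformulation, not an approximation; the
test suite verifies it against explicit 3^dg enumeration to 1e−12.
Sites with zero coverage keep the flat likelihood (1,1,1) — the prior
speaks — and are never dropped.

## The score tests

Both tests evaluate the score and the **observed** information (negative
Hessian) of the latent-genotype log-likelihood at the constrained MLE
θ̃ = (α̃, 0[, φ̃]) of the null model, obtained by IRLS of y on x alone
(gaussian φ̃ = RSS/N — the N-denominator MLE, because the score test
expands around the exact constrained maximum). At θ̃ the α- and
φ-components of the score vanish by the first-order condition; the
β-component is

    s_β = Σ_i (y_i − b′(α̃x_i′)) / a(φ̃) · E[g | D_i].

The information blocks at θ̃ reduce to expressions in b″(α̃x_i′), the
residuals, and the posterior moments; in the dispersion branch the α–φ
block is exactly zero and the β–φ block equals s_β·a′/a.

* **Joint significance (JS):** R = sᵀ o⁻¹ s with s zero-padded outside β,
  computed via the Schur complement
  R = s_β′ [o_ββ − o_βγ o_γγ⁻¹ o_γβ]⁻¹ s_β (γ = α[, φ]) — algebraically
  identical, numerically safer. Reference distribution χ²(dg).
* **Variable collapse (VC):** effects constrained to β = β₀W, W > 0
  normalized to Σw_j = dg (identification). By the chain rule the score
  and information project through W, giving R = (W s_β)² / (W S W′) with S
  the JS Schur complement; χ²(1). With dg = 1 and w = 1 the VC and JS
  statistics coincide. Weights: equal, or Beta(1,25)-density in the MAF
  (w_j ∝ 25(1−MAF_j)^24), the standard rare-variant up-weighting.

Numerical choices: observed information can be indefinite in finite
samples; eigenvalues ≤ 1e−10 of the largest are truncated
(pseudo-inverse), the effective rank is reported, and df stays at dg
(resp. 1). Monomorphic sites (zero posterior variance for everyone and no
between-individual variation) are dropped with a warning and dg reflects
the retained count. P-values use the χ² survival function, no continuity
correction. IRLS converges on relative log-likelihood change < 1e−10
(≤100 iterations) and guarantees max-abs α-score < 1e−8; logistic
separation (fitted probabilities pinned at 0/1) is a diagnostic error.

## Allele frequencies and comparators

* **One-step EM MLE:** per site, f ← (1/2N) Σ_i E[g_i | D_i, f] from
  f₀ = 0.5, tol 1e−6 on |Δf|, ≤200 iterations; the EM objective is
  asserted non-decreasing every step. Sites with flat likelihoods for all
  individuals are returned at 0.5 with a degenerate flag and excluded from
  tests.
* **Two-step:** MAP calls under HWE with a flat f = 0.5 prior, recount,
  one re-call/recount refinement, freeze.
* **Genotype-based comparators:** group chi-square as the LRT of y on
  [x | calls] vs y on x (df = rank of the calls block after projection on
  x; gaussian also reports the exact F), and the weighted burden test —
  1-df LRT on AG_i = Σ_j w_j g_ij. LRT was chosen over score/Wald as the
  standard group-significance chi-square in GLM practice.

## Synthetic data

The generator emulates a low-coverage association study: MAFs uniform on
(0.05, 0.5) (common) or (0.005, 0.05) (rare) — split at 0.05; genotypes
Binomial(2, MAF) i.i.d. per individual; read totals Poisson(depth) with
depths of interest 1–10X and per-base error 0.5%; covariates
X1 ~ Bernoulli(0.5), X2 ~ N(0,1) with coefficients β₀ = 0, β₁ = β₂ = 1;
binary phenotypes from a logistic model **with latent-logit noise
ε ~ N(0,1)** (part of the stated binary design; toggleable, off for
Poisson/gaussian); count phenotypes Poisson(e^η); gaussian N(η, 1).
Alternatives draw a causal count uniform on {2..5} (common) or {2..10}
(rare) and split a total effect of 0.2 × magnitude (grid 0..5, hence total
effects up to 1.0) equally, all positive by default. Group sizes default
to 5 common / 10 rare markers per tested group — a reproduction
assumption, as no canonical value exists. An optional AR(1)
Gaussian-copula haplotype mode introduces linkage between adjacent sites
(off by default): the tests' operating characteristics depend on depth,
error, MAF and effect size rather than fine-grained linkage.

What a green simulation test does *not* establish: behavior under real LD
patterns, heterogeneous per-individual depths, base-quality variation,
mapping error, population structure, or multi-allelic sites — none of
which the generator emulates.

The experiment harness derives every replicate's random stream from
(master seed, cell index, replicate index), so tables are bit-identical
under any execution order; a method failing on more than 1% of a cell's
replicates aborts the cell (silent skipping would bias estimates), rarer
failures are excluded from the denominator and counted in the output.

## Known limitations

* The observed (rather than expected) information makes the statistics
  exact to the printed derivation but noisy in finite samples: its β-block
  subtracts (y−b′)²/a² · Var(g|D), a zero-mean term whose noise grows with
  the residual's fourth moment and the posterior variance. For Poisson
  responses with λ spanning e^{−3}..e^{4} at 1X depth this makes the JS
  test measurably anti-conservative (empirical size ≈ 0.09 at N = 300);
  the 1-df VC projection damps the effect (≈ 0.06). At depth ≥ 4X, or for
  logistic responses (bounded residuals), calibration holds.
* In the gaussian branch the β–φ observed-information block at θ̃ equals
  s_β/φ — perfectly correlated with the score — so the Schur complement
  subtracts (2/N)ss′ and inflates R by a factor ≈ 1 + 2R/N; an O(1/N)
  anti-conservatism (size ≈ 0.065 at N = 300) that vanishes as N grows.
* MAP calling concordance at 10X is ≈ 98% for MAF-rich common sites (a
  het miscalls when all t reads draw one allele, probability 2·(1/2)^t),
  ≈ 99.9% for rare groups.
* No SKAT-style variance-component analogue; no dominant/recessive/
  heterogeneous effect encodings (the additive dosage model only); no
  per-read quality weighting (a single error rate stands in).
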