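"""Allele-frequency estimation from low-coverage reads.

Compares the two estimators on the same simulated pileups at 1X and 10X
mean depth: the two-step approach (call genotypes by MAP under a HWE
prior, then count alleles) and the one-step EM maximizing the read
likelihood directly.  At low depth hard calling is biased toward the prior
mode, while the EM keeps the full uncertainty.
"""

import numpy as np

from seqglm import SimulationConfig, af_em, gl_from_pileup, simulate_dataset, two_step_af

for depth in (1, 10):
    cfg = SimulationConfig(
        n_individuals=1000, n_markers=6, variant_class="common",
        depth=depth, seed=3,
    )
    data = simulate_dataset(cfg)
    gl = gl_from_pileup(data.n_ref, data.n_alt, cfg.error_rate)
    sample_f = data.genotypes.mean(axis=0) / 2  # truth in this cohort
    ts = two_step_af(gl)[0].f
    em = af_em(gl).f
    print(f"depth {depth}X  (mean abs error: two-step "
          f"{np.abs(ts - sample_f).mean():.4f}, EM {np.abs(em - sample_f).mean():.4f})")
    for j in range(6):
        print(f"  site {j}: sample {sample_f[j]:.3f}  two-step {ts[j]:.3f}  EM {em[j]:.3f}")

print("\nAt 1X the EM tracks the cohort frequency much more closely; by 10X "
      "both estimators agree with the truth.")
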