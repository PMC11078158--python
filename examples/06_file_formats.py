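"""Round-tripping the exchange formats.

Writes simulated genotype likelihoods to a BEAGLE-GL text file plus a
group-definition and phenotype TSV, reads everything back, and runs the
joint significance test on one group — the workflow for data arriving from
an external likelihood caller instead of the built-in simulator.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from seqglm import (
    SimulationConfig,
    af_em,
    gl_from_pileup,
    js_test,
    posterior_moments,
    read_beagle,
    read_groups,
    read_phenotypes,
    simulate_dataset,
    write_beagle,
)

cfg = SimulationConfig(n_individuals=200, n_markers=4, depth=4, seed=13)
data = simulate_dataset(cfg)
gl = gl_from_pileup(data.n_ref, data.n_alt, cfg.error_rate)

workdir = Path(tempfile.mkdtemp())
markers = [f"1:{1000 + 10 * j}" for j in range(4)]
samples = [f"ind{i}" for i in range(200)]

write_beagle(workdir / "study.beagle", gl, markers, samples)
pd.DataFrame({"group_id": "geneA", "site_id": markers}).to_csv(
    workdir / "groups.tsv", sep="\t", index=False
)
pd.DataFrame({
    "id": samples, "y": data.phenotype,
    "x1": data.covariates[:, 1], "x2": data.covariates[:, 2],
}).to_csv(workdir / "pheno.tsv", sep="\t", index=False)

gl2, markers2, _ = read_beagle(workdir / "study.beagle")
groups = read_groups(workdir / "groups.tsv")
y, x, _ = read_phenotypes(workdir / "pheno.tsv")

cols = [markers2.index(s) for s in groups["geneA"]]
f = af_em(gl2[:, cols]).f
res = js_test(y, x, posterior_moments(gl2[:, cols], f), "logistic")
print(f"group geneA ({len(cols)} sites): R = {res.statistic:.3f}, "
      f"df = {res.df}, p = {res.p_value:.3f}")
print(f"files under {workdir}")
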