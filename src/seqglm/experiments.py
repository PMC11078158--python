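"""Type I error and power studies over the (N x depth x family) grid.

One replicate simulates a marker group, low-coverage reads, covariates and
a phenotype, then computes p-values for every requested method on the same
data:

* ``js1`` / ``js2`` / ``js3`` -- likelihood-based joint significance test
  using true / two-step / EM-MLE allele frequencies;
* ``vc1`` / ``vc2`` / ``vc3`` -- likelihood-based variable collapse test
  (equal weights) with the same three frequency sources;
* ``genotype_chisq`` -- group LRT on MAP genotype calls;
* ``burden`` -- weighted burden LRT on MAP genotype calls.

Each replicate derives its random stream from (master seed, cell index,
replicate index), so tables are reproducible under any execution order.  A
method erroring on more than 1% of a cell's replicates aborts the cell
(silent skipping would bias the estimate); rarer failures are excluded
from the denominator and counted in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_freq import af_em, call_genotypes, two_step_af
from .families import fit_null
from .genotype_tests import burden_test, genotype_group_test
from .group_tests import js_test, vc_test
from .read_model import gl_from_pileup, posterior_moments
from .simulate import (
    DEFAULT_GROUP_SIZE,
    draw_causal_architecture,
    draw_mafs,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotype,
    simulate_reads,
)

METHODS = (
    "js1", "js2", "js3", "vc1", "vc2", "vc3", "genotype_chisq", "burden",
)


@dataclass
class ExperimentGrid:
    """Study design: which cells to run and with how many replicates."""

    sample_sizes: tuple = (300, 500, 1000)
    depths: tuple = (1, 2, 4, 10)
    families: tuple = ("logistic",)
    methods: tuple = ("js1", "js2", "js3", "genotype_chisq")
    variant_class: str = "common"
    n_markers: int | None = None  # default: 5 common / 10 rare
    n_replicates: int = 9000
    alpha: float = 0.05
    error_rate: float = 0.005
    effect_grid: tuple = (0, 1, 2, 3, 4, 5)
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
        if self.n_markers is None:
            self.n_markers = DEFAULT_GROUP_SIZE[self.variant_class]


def replicate_pvalues(
    rng, n, n_markers, depth, family, methods,
    variant_class="common", error_rate=0.005, magnitude=0.0,
    include_eta_noise=None,
):
    """Simulate one replicate and return {method: p_value}.

    All random draws happen before any testing, in a fixed order, so the
    simulated data do not depend on which methods are requested.
    """
    mafs = draw_mafs(rng, n_markers, variant_class)
    g = simulate_genotypes(rng, n, mafs)
    n_ref, n_alt = simulate_reads(rng, g, depth, error_rate)
    x = simulate_covariates(rng, n)
    effects = draw_causal_architecture(rng, n_markers, variant_class, magnitude)
    y = simulate_phenotype(rng, g, x, effects, family, include_eta_noise)
    gl = gl_from_pileup(n_ref, n_alt, error_rate)

    nullfit = fit_null(y, x, family)
    equal_w = np.ones(n_markers)
    out: dict[str, float] = {}

    f_by_source: dict[str, np.ndarray] = {}
    calls = None
    sources = {m[-1] for m in methods if m[0] in "jv"}
    need_two_step = "2" in sources or "genotype_chisq" in methods or "burden" in methods
    f_by_source["1"] = mafs
    if need_two_step:
        af_ts, _ = two_step_af(gl)
        f_by_source["2"] = af_ts.f
        calls = call_genotypes(gl, af_ts.f)
    if "3" in sources:
        f_by_source["3"] = af_em(gl).f

    posteriors = {
        src: posterior_moments(gl, f_by_source[src]) for src in sorted(sources)
    }
    for m in methods:
        if m == "genotype_chisq":
            out[m] = genotype_group_test(y, x, calls, family).p_value
        elif m == "burden":
            out[m] = burden_test(y, x, calls, equal_w, family).p_value
        elif m.startswith("js"):
            out[m] = js_test(y, x, posteriors[m[-1]], family, nullfit=nullfit).p_value
        else:
            out[m] = vc_test(
                y, x, posteriors[m[-1]], equal_w, family, nullfit=nullfit
            ).p_value
    return out


def _run_cell(
    n, depth, family, methods, variant_class, n_markers, n_replicates,
    alpha, error_rate, seed, cell_index, magnitude=0.0,
):
    """Rejection fractions for one grid cell; returns per-method rows."""
    rejections = {m: 0 for m in methods}
    errors = {m: 0 for m in methods}
    valid = {m: 0 for m in methods}
    max_err = max(1, int(0.01 * n_replicates))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, cell_index, rep])
            )
            try:
                pvals = replicate_pvalues(
                    rng, n, n_markers, depth, family, methods,
                    variant_class, error_rate, magnitude,
                )
            except Exception as exc:
                for m in methods:
                    errors[m] += 1
                    if errors[m] > max_err:
                        raise RuntimeError(
                            f"cell (N={n}, depth={depth}, {family}) failed on "
                            f">1% of replicates; last error: {exc}"
                        ) from exc
                continue
            for m in methods:
                valid[m] += 1
                if pvals[m] < alpha:
                    rejections[m] += 1
    rows = []
    for m in methods:
        est = rejections[m] / valid[m] if valid[m] else np.nan
        rows.append(
            {
                "sample_size": n, "depth": depth, "method": m, "family": family,
                "estimate": est,
                "mc_stderr": float(np.sqrt(est * (1 - est) / valid[m]))
                if valid[m]
                else np.nan,
                "n_replicates": valid[m], "n_errors": errors[m],
            }
        )
    return rows


def run_type1(grid: ExperimentGrid) -> pd.DataFrame:
    """Empirical Type I error per (sample size, depth, family, method)."""
    rows = []
    cell = 0
    for family in grid.families:
        for n in grid.sample_sizes:
            for depth in grid.depths:
                for r in _run_cell(
                    n, depth, family, grid.methods, grid.variant_class,
                    grid.n_markers, grid.n_replicates, grid.alpha,
                    grid.error_rate, grid.seed, cell,
                ):
                    r["metric"] = "type1"
                    rows.append(r)
                cell += 1
    return pd.DataFrame(rows)


def run_power(grid: ExperimentGrid, effect_grid=None) -> pd.DataFrame:
    """Empirical power per grid cell and effect magnitude.

    The causal architecture is redrawn every replicate (random causal count
    and sites); magnitude 0 reduces to the Type I error estimate.
    """
    effect_grid = grid.effect_grid if effect_grid is None else effect_grid
    rows = []
    cell = 10_000  # disjoint from run_type1 cell indices
    for family in grid.families:
        for n in grid.sample_sizes:
            for depth in grid.depths:
                for mag in effect_grid:
                    for r in _run_cell(
                        n, depth, family, grid.methods, grid.variant_class,
                        grid.n_markers, grid.n_replicates, grid.alpha,
                        grid.error_rate, grid.seed, cell, magnitude=mag,
                    ):
                        r["metric"] = "power"
                        r["magnitude"] = mag
                        rows.append(r)
                    cell += 1
    return pd.DataFrame(rows)


def type1_cell(
    n, depth, family, method, n_replicates=2000, variant_class=None,
    n_markers=None, alpha=0.05, error_rate=0.005, seed=0, cell_index=0,
) -> dict:
    """Convenience single-cell Type I error estimate for one method.

    Returns ``{"estimate", "mc_stderr", "n_replicates", "n_errors"}``.
    """
    if variant_class is None:
        variant_class = "rare" if method.startswith(("vc", "burden")) else "common"
    if n_markers is None:
        n_markers = DEFAULT_GROUP_SIZE[variant_class]
    (row,) = _run_cell(
        n, depth, family, (method,), variant_class, n_markers,
        n_replicates, alpha, error_rate, seed, cell_index,
    )
    return {
        k: row[k] for k in ("estimate", "mc_stderr", "n_replicates", "n_errors")
    }
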