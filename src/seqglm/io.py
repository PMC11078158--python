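"""Readers and writers for the standard exchange formats.

* BEAGLE genotype-likelihood text: one row per marker, columns
  ``marker alleleA alleleB`` followed by three likelihood columns per
  individual (read and write).
* VCF with per-genotype GL (log10 likelihoods) or PL (phred-scaled)
  FORMAT fields, read via cyvcf2; biallelic records only.
* Group definitions: TSV of ``group_id`` and ``site_id``.
* Phenotype/covariate table: TSV with an id column, a phenotype column and
  any number of covariate columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def read_beagle(path):
    """Read a BEAGLE genotype-likelihood file.

    Returns ``(gl, markers, samples)`` with ``gl`` of shape (N, M, 3),
    marker ids as a list of length M, and sample ids of length N.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 6 or (df.shape[1] - 3) % 3 != 0:
        raise ValueError(
            "BEAGLE file must have marker, alleleA, alleleB plus 3 columns "
            f"per individual; got {df.shape[1]} columns"
        )
    markers = df.iloc[:, 0].astype(str).tolist()
    samples = [c for c in df.columns[3::3]]
    vals = df.iloc[:, 3:].to_numpy(dtype=float)  # (M, 3N)
    m = vals.shape[0]
    n = vals.shape[1] // 3
    gl = vals.reshape(m, n, 3).transpose(1, 0, 2)
    if np.any(gl < 0):
        raise ValueError("negative genotype likelihoods in BEAGLE file")
    return gl, markers, samples


def write_beagle(path, gl, markers, samples, alleles=None):
    """Write genotype likelihoods (N, M, 3) in BEAGLE text format."""
    gl = np.asarray(gl, dtype=float)
    n, m, three = gl.shape
    if three != 3 or len(markers) != m or len(samples) != n:
        raise ValueError("shape mismatch between gl, markers and samples")
    if alleles is None:
        alleles = [("0", "1")] * m
    cols = {"marker": markers}
    cols["alleleA"] = [a for a, _ in alleles]
    cols["alleleB"] = [b for _, b in alleles]
    df = pd.DataFrame(cols)
    flat = gl.transpose(1, 0, 2).reshape(m, 3 * n)
    header = []
    for s in samples:
        header += [s, f"{s}.1", f"{s}.2"]
    like = pd.DataFrame(flat, columns=header)
    pd.concat([df, like], axis=1).to_csv(path, sep=" ", index=False)


def read_vcf_gl(path):
    """Read genotype likelihoods from a VCF with GL or PL FORMAT fields.

    GL fields (log10 likelihoods) are converted via 10**GL; PL fields
    (phred-scaled) via 10**(-PL/10).  Multi-allelic records are rejected.

    Returns ``(gl, site_ids, samples)`` with site ids ``CHROM:POS``.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, sites = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "split or filter to biallelic sites first"
            )
        gl = var.format("GL")
        if gl is not None:
            lik = np.power(10.0, np.asarray(gl, dtype=float))
        else:
            pl = var.format("PL")
            if pl is None:
                raise ValueError(
                    f"record at {var.CHROM}:{var.POS} has neither GL nor PL"
                )
            lik = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
        if lik.shape != (len(samples), 3):
            raise ValueError(
                f"expected 3 likelihoods per sample at {var.CHROM}:{var.POS}"
            )
        rows.append(lik)
        sites.append(f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError("no variant records in VCF")
    gl = np.stack(rows, axis=1)  # (N, M, 3)
    return gl, sites, samples


def read_groups(path):
    """Read group definitions (TSV: group_id, site_id) into an ordered dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"group_id", "site_id"}.issubset(df.columns):
        if df.shape[1] < 2:
            raise ValueError("group file needs columns group_id and site_id")
        df = df.iloc[:, :2]
        df.columns = ["group_id", "site_id"]
    groups: dict[str, list[str]] = {}
    for gid, sid in zip(df["group_id"], df["site_id"]):
        groups.setdefault(gid, []).append(sid)
    return groups


def read_phenotypes(path, id_col="id", pheno_col="y"):
    """Read a phenotype/covariate TSV; returns (y, x_with_intercept, ids).

    All columns other than ``id_col`` and ``pheno_col`` are treated as
    covariates, in file order, after a prepended intercept.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (id_col, pheno_col):
        if col not in df.columns:
            raise ValueError(f"phenotype file lacks required column {col!r}")
    ids = df[id_col].astype(str).tolist()
    y = df[pheno_col].to_numpy(dtype=float)
    covs = df.drop(columns=[id_col, pheno_col]).to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(df)), covs]) if covs.size else np.ones((len(df), 1))
    return y, x, ids
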