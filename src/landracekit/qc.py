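"""SNP- and sample-level quality filters for allele-dosage matrices.

The filters mirror standard practice for high-multiplexing SNP genotyping of
germplasm collections: drop loci with too much missing data, monomorphic
loci, and loci below a minor-allele-frequency floor; then drop samples whose
residual missingness is too high.  Missing data is never imputed.

Removal of a locus is attributed to the *first* failing filter, in the order
missing -> monomorphic -> MAF, so the report's counts partition the removed
loci unambiguously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class QCReport:
    """Counts and per-locus diagnostics from one QC pass."""

    n_snps_in: int = 0
    n_removed_missing: int = 0
    n_removed_monomorphic: int = 0
    n_removed_maf: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_removed: int = 0
    n_samples_out: int = 0
    locus_missing: pd.Series | None = None
    locus_maf: pd.Series | None = None
    removed_loci: dict[str, list[str]] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)

    def check(self) -> None:
        assert (
            self.n_snps_in
            - self.n_removed_missing
            - self.n_removed_monomorphic
            - self.n_removed_maf
            == self.n_snps_out
        ), "QC locus counts do not reconcile"
        assert self.n_samples_in - self.n_samples_removed == self.n_samples_out

    def to_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_monomorphic": self.n_removed_monomorphic,
            "n_removed_maf": self.n_removed_maf,
            "n_snps_out": self.n_snps_out,
            "n_samples_in": self.n_samples_in,
            "n_samples_removed": self.n_samples_removed,
            "n_samples_out": self.n_samples_out,
            "removed_samples": list(self.removed_samples),
        }


def locus_allele_frequency(G: GenotypeMatrix) -> pd.Series:
    """Alternate-allele frequency per locus, p = sum(g) / (2 * n_called)."""
    called = (~G.missing_mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(G.dosage, axis=0) / (2.0 * called)
    p[called == 0] = np.nan
    return pd.Series(p, index=G.locus_ids, name="allele_frequency")


def filter_snps(
    G: GenotypeMatrix, max_missing: float = 0.05, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop loci by missingness, monomorphy and minor-allele frequency.

    A locus is monomorphic when every non-missing call is the same
    *homozygous* dosage (all 0 or all 2); an all-heterozygote locus carries
    both alleles and is kept.  MAF is computed on allele frequency from
    dosages, ``min(p, 1-p)`` with ``p = sum(g)/(2 n_called)``.
    """
    if G.n_loci == 0 or G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    X = G.dosage
    nan = np.isnan(X)
    miss_frac = nan.mean(axis=0)
    called = (~nan).sum(axis=0)
    p = locus_allele_frequency(G).to_numpy()
    maf = np.minimum(p, 1.0 - p)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_min = np.nanmin(np.where(nan, np.inf, X), axis=0)
        col_max = np.nanmax(np.where(nan, -np.inf, X), axis=0)
    mono = (called > 0) & (col_min == col_max) & np.isin(col_min, (0.0, 2.0))

    fail_missing = miss_frac > max_missing
    fail_mono = mono & ~fail_missing
    with np.errstate(invalid="ignore"):
        fail_maf = (maf < min_maf) & ~fail_missing & ~fail_mono
    keep = ~(fail_missing | fail_mono | fail_maf)

    loci = np.asarray(G.locus_ids)
    out = G.subset(loci=list(loci[keep]))
    if out.n_loci == 0:
        warnings.warn("all loci removed by SNP filters", stacklevel=2)
    report = QCReport(
        n_snps_in=G.n_loci,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_monomorphic=int(fail_mono.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_snps_out=out.n_loci,
        n_samples_in=G.n_samples,
        n_samples_removed=0,
        n_samples_out=G.n_samples,
        locus_missing=pd.Series(miss_frac, index=G.locus_ids),
        locus_maf=pd.Series(maf, index=G.locus_ids),
        removed_loci={
            "missing": list(loci[fail_missing]),
            "monomorphic": list(loci[fail_mono]),
            "maf": list(loci[fail_maf]),
        },
    )
    report.check()
    return out, report


def filter_samples(
    G: GenotypeMatrix, max_missing: float = 0.055
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose missing-call fraction exceeds ``max_missing``."""
    if G.n_loci == 0 or G.n_samples == 0:
        raise ValueError("empty genotype matrix")
    frac = G.sample_missing_fraction()
    removed = list(frac.index[frac > max_missing])
    out = G.subset(samples=[s for s in G.sample_ids if s not in set(removed)])
    report = QCReport(
        n_snps_in=G.n_loci,
        n_snps_out=G.n_loci,
        n_samples_in=G.n_samples,
        n_samples_removed=len(removed),
        n_samples_out=out.n_samples,
        removed_samples=removed,
    )
    report.check()
    return out, report


def run_qc(
    G: GenotypeMatrix,
    max_snp_missing: float = 0.05,
    min_maf: float = 0.05,
    max_sample_missing: float = 0.055,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP filters first, then the sample filter (no iteration to a fixed point)."""
    G1, snp_rep = filter_snps(G, max_missing=max_snp_missing, min_maf=min_maf)
    G2, samp_rep = filter_samples(G1, max_missing=max_sample_missing)
    report = QCReport(
        n_snps_in=snp_rep.n_snps_in,
        n_removed_missing=snp_rep.n_removed_missing,
        n_removed_monomorphic=snp_rep.n_removed_monomorphic,
        n_removed_maf=snp_rep.n_removed_maf,
        n_snps_out=snp_rep.n_snps_out,
        n_samples_in=samp_rep.n_samples_in,
        n_samples_removed=samp_rep.n_samples_removed,
        n_samples_out=samp_rep.n_samples_out,
        locus_missing=snp_rep.locus_missing,
        locus_maf=snp_rep.locus_maf,
        removed_loci=snp_rep.removed_loci,
        removed_samples=samp_rep.removed_samples,
    )
    report.check()
    return G2, report
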