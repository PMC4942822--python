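"""SNP quality-control filters for RIL genotype matrices.

The production pipeline applies, in order: the missing-rate filter
(drop SNPs whose missing fraction exceeds the threshold) and the
segregation-distortion filter (chi-square goodness of fit of the two
homozygote counts against the expected 1:1 ratio in a biparental RIL
population).  A minor-allele-frequency filter is provided but disabled
by default; in a balanced biparental cross MAF is an outcome of the
design (close to 0.5), not a screening criterion.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["QcReport", "filter_missing_rate", "filter_segregation_distortion", "filter_maf", "apply_qc"]


@dataclasses.dataclass
class QcReport:
    n_input: int
    n_removed_missing: int = 0
    n_removed_segregation: int = 0
    n_removed_maf: int = 0
    removed_missing: list[str] = dataclasses.field(default_factory=list)
    removed_segregation: list[str] = dataclasses.field(default_factory=list)
    removed_maf: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_removed_missing + self.n_removed_segregation + self.n_removed_maf

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def merge(self, other: "QcReport") -> "QcReport":
        """Chain reports from sequential filters (input count from the first)."""
        return QcReport(
            n_input=self.n_input,
            n_removed_missing=self.n_removed_missing + other.n_removed_missing,
            n_removed_segregation=self.n_removed_segregation + other.n_removed_segregation,
            n_removed_maf=self.n_removed_maf + other.n_removed_maf,
            removed_missing=self.removed_missing + other.removed_missing,
            removed_segregation=self.removed_segregation + other.removed_segregation,
            removed_maf=self.removed_maf + other.removed_maf,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_removed_missing": self.n_removed_missing,
                    "n_removed_segregation": self.n_removed_segregation,
                    "n_removed_maf": self.n_removed_maf,
                    "n_retained": self.n_retained,
                    "removed_missing": self.removed_missing,
                    "removed_segregation": self.removed_segregation,
                    "removed_maf": self.removed_maf,
                },
                fh,
                indent=2,
            )


def filter_missing_rate(geno: GenotypeMatrix, max_rate: float = 0.05) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs whose missing fraction strictly exceeds ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    keep = geno.missing_rate() <= max_rate
    report = QcReport(
        n_input=geno.n_snps,
        n_removed_missing=int((~keep).sum()),
        removed_missing=[s for s, k in zip(geno.snp_ids, keep) if not k],
    )
    return geno.take_snps(np.flatnonzero(keep)), report


def segregation_chi2(geno: GenotypeMatrix) -> np.ndarray:
    """Pearson chi-square (1 df, no continuity correction) of homozygote
    counts against 1:1; +inf where a SNP has zero non-missing calls."""
    n_pat, n_mat = geno.allele_counts()
    tot = n_pat + n_mat
    exp = tot / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(tot > 0, (n_pat - exp) ** 2 / np.where(exp > 0, exp, 1) * 2.0, np.inf)
    return chi2


def filter_segregation_distortion(geno: GenotypeMatrix, alpha: float = 0.01) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs whose genotype frequency deviates from 1:1 at level ``alpha``.

    SNPs with zero non-missing calls are removed and flagged alongside.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.isf(alpha, df=1)
    chi2 = segregation_chi2(geno)
    keep = chi2 <= crit
    report = QcReport(
        n_input=geno.n_snps,
        n_removed_segregation=int((~keep).sum()),
        removed_segregation=[s for s, k in zip(geno.snp_ids, keep) if not k],
    )
    return geno.take_snps(np.flatnonzero(keep)), report


def filter_maf(geno: GenotypeMatrix, min_maf: float) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs with minor allele frequency below ``min_maf`` (optional filter)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = geno.maf()
    keep = ~(maf < min_maf)  # NaN MAF (no calls) passes through here
    report = QcReport(
        n_input=geno.n_snps,
        n_removed_maf=int((~keep).sum()),
        removed_maf=[s for s, k in zip(geno.snp_ids, keep) if not k],
    )
    return geno.take_snps(np.flatnonzero(keep)), report


def apply_qc(
    geno: GenotypeMatrix,
    max_missing_rate: float = 0.05,
    segregation_alpha: float = 0.01,
    min_maf: float | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the standard filter sequence: missing rate, then segregation, then
    (optionally) MAF."""
    geno, rep = filter_missing_rate(geno, max_missing_rate)
    geno, rep2 = filter_segregation_distortion(geno, segregation_alpha)
    rep = rep.merge(rep2)
    if min_maf is not None:
        geno, rep3 = filter_maf(geno, min_maf)
        rep = rep.merge(rep3)
    return geno, rep
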