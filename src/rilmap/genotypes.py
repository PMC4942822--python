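"""Genotype containers and I/O for biparental inbred-line populations.

Calls are stored as a dense ``lines x SNPs`` float array coded +1 for the
paternal homozygote, -1 for the maternal homozygote and NaN for missing.
The +1/-1 coding is the additive coefficient used throughout the mapping
model, so the container is the in-memory home of the design columns.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SnpRecord", "GenotypeMatrix", "read_genotypes", "write_vcf", "write_coded_tsv"]

MISSING = np.nan


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with its genomic location and parental alleles."""

    snp_id: str
    chromosome: str
    position_bp: int  # 1-based, as in VCF
    paternal_allele: str = "A"
    maternal_allele: str = "C"

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if self.paternal_allele == self.maternal_allele:
            raise ValueError(f"{self.snp_id}: parental alleles must differ")


class GenotypeMatrix:
    """Lines x SNPs matrix of +1/-1/NaN additive codes with SNP metadata."""

    def __init__(self, line_ids: Sequence[str], snps: Sequence[SnpRecord], calls: np.ndarray):
        calls = np.asarray(calls, dtype=float)
        if len(line_ids) < 2:
            raise ValueError("a genotype matrix needs at least two lines")
        if calls.shape != (len(line_ids), len(snps)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(line_ids)} lines x {len(snps)} SNPs"
            )
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        ok = np.isnan(calls) | (calls == 1.0) | (calls == -1.0)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(f"call at line {line_ids[bad[0]]}, SNP {ids[bad[1]]} not in {{+1,-1,NaN}}")
        self.line_ids = list(line_ids)
        self.snps = list(snps)
        self.calls = calls

    # -- basic properties -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<GenotypeMatrix {self.n_lines} lines x {self.n_snps} SNPs>"

    # -- derived statistics ----------------------------------------------
    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return np.isnan(self.calls).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(paternal, maternal) homozygote counts per SNP on non-missing calls."""
        n_pat = np.nansum(self.calls == 1.0, axis=0)
        n_mat = np.nansum(self.calls == -1.0, axis=0)
        return n_pat.astype(int), n_mat.astype(int)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP; NaN where no calls."""
        n_pat, n_mat = self.allele_counts()
        tot = n_pat + n_mat
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, n_pat / np.where(tot > 0, tot, 1), np.nan)
        return np.minimum(f, 1.0 - f)

    def imputed_calls(self) -> np.ndarray:
        """Calls with per-SNP mean imputation of missing values."""
        x = self.calls.copy()
        miss = np.isnan(x)
        if miss.any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
        return x

    # -- subsetting -------------------------------------------------------
    def take_snps(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix(self.line_ids, [self.snps[i] for i in idx], self.calls[:, idx])

    def select_snp_ids(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return self.take_snps([pos[s] for s in ids])

    def take_lines(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix([self.line_ids[i] for i in idx], self.snps, self.calls[idx, :])

    # -- dataframe view ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.line_ids, columns=self.snp_ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(
    path,
    format: str = "vcf",
    parent_assignment: str = "ref-paternal",
    het_policy: str = "missing",
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF 4.x or coded TSV.

    Parameters
    ----------
    parent_assignment
        ``"ref-paternal"`` (REF allele belongs to the paternal line) or
        ``"alt-paternal"``.  TSV input is already coded and ignores this.
    het_policy
        How heterozygous VCF calls are treated: ``"missing"`` (default) or
        ``"error"``.
    """
    if format == "tsv":
        return read_coded_tsv(path)
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")
    if parent_assignment not in ("ref-paternal", "alt-paternal"):
        raise ValueError(f"unknown parent_assignment {parent_assignment!r}")
    import pysam

    vf = pysam.VariantFile(str(path))
    line_ids = list(vf.header.samples)
    snps: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    bad: list[str] = []
    for rec in vf.fetch() if vf.index is not None else vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"multiallelic or ALT-less site at {rec.chrom}:{rec.pos}")
        ref, alt = rec.ref, rec.alts[0]
        pat, mat = (ref, alt) if parent_assignment == "ref-paternal" else (alt, ref)
        snp_id = rec.id or f"{rec.chrom}_{rec.pos}"
        snps.append(SnpRecord(snp_id, str(rec.chrom), rec.pos, pat, mat))
        col = np.full(len(line_ids), MISSING)
        for j, sample in enumerate(line_ids):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            alleles = set(gt)
            if alleles == {0}:
                col[j] = 1.0 if parent_assignment == "ref-paternal" else -1.0
            elif alleles == {1}:
                col[j] = -1.0 if parent_assignment == "ref-paternal" else 1.0
            else:
                if het_policy == "error":
                    bad.append(f"{snp_id} line {sample}: heterozygous call {gt}")
                # het_policy == "missing": leave as NaN
        rows.append(col)
    vf.close()
    if bad:
        raise ValueError("unexpected calls:\n" + "\n".join(bad[:20]))
    calls = np.column_stack(rows) if rows else np.empty((len(line_ids), 0))
    return GenotypeMatrix(line_ids, snps, calls)


def read_coded_tsv(path) -> GenotypeMatrix:
    """Read the coded TSV layout: rows = lines, columns = SNP ids, values in {1,-1,NA}.

    SNP metadata rows ``#chromosome`` and ``#position`` may precede the data.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment=None)
    meta_rows = [r for r in df.index if str(r).startswith("#")]
    meta = df.loc[meta_rows]
    data = df.drop(index=meta_rows)
    snps = []
    for j, snp_id in enumerate(df.columns):
        chrom = str(meta.loc["#chromosome", snp_id]) if "#chromosome" in meta.index else "1"
        pos = int(float(meta.loc["#position", snp_id])) if "#position" in meta.index else j + 1
        snps.append(SnpRecord(str(snp_id), chrom, pos))
    return GenotypeMatrix([str(i) for i in data.index], snps, data.to_numpy(dtype=float))


def write_coded_tsv(geno: GenotypeMatrix, path) -> None:
    df = geno.to_frame()
    header = pd.DataFrame(
        [[s.chromosome for s in geno.snps], [s.position_bp for s in geno.snps]],
        index=["#chromosome", "#position"],
        columns=geno.snp_ids,
    )
    out = pd.concat([header, df])
    out.to_csv(path, sep="\t", na_rep="NA")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal uncompressed VCF 4.2 with homozygous GT calls."""
    chroms: dict[str, int] = {}
    for s in geno.snps:
        chroms[s.chromosome] = max(chroms.get(s.chromosome, 0), s.position_bp)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rilmap\n")
        for c, ln in chroms.items():
            fh.write(f"##contig=<ID={c},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.line_ids) + "\n")
        for j, s in enumerate(geno.snps):
            col = geno.calls[:, j]
            gts = ["0/0" if v == 1.0 else "1/1" if v == -1.0 else "./." for v in col]
            fh.write(
                f"{s.chromosome}\t{s.position_bp}\t{s.snp_id}\t{s.paternal_allele}\t"
                f"{s.maternal_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
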