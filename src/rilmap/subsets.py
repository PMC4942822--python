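"""SNP-set construction for the three mapping strategies.

The genome-wide strategy (GWA) uses every QC-passing SNP; the QTL-based
strategy (QBA) keeps SNPs inside previously mapped QTL intervals supplied
as BED; the gene-based strategy (GBA) keeps SNPs inside annotated gene
spans (UTRs, exons and introns, i.e. the full gene footprint) supplied as
GFF3.  Coordinate conventions: SNP positions are 1-based (VCF); BED is
0-based half-open; GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "IntervalSet",
    "GeneModelSet",
    "read_bed",
    "read_gff3_genes",
    "subset_by_intervals",
    "subset_by_gene_models",
]


@dataclasses.dataclass
class IntervalSet:
    """Genomic intervals in BED convention (0-based half-open)."""

    intervals: pd.DataFrame  # columns chromosome, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals
        if len(df) and (df["start"] > df["end"]).any():
            raise ValueError("interval start > end")

    def __len__(self) -> int:
        return len(self.intervals)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(
            pd.concat([self.intervals, other.intervals], ignore_index=True)
        )


@dataclasses.dataclass
class GeneModelSet:
    """Gene spans in GFF3 convention (1-based inclusive)."""

    genes: pd.DataFrame  # columns gene_id, chromosome, start, end

    def __post_init__(self) -> None:
        df = self.genes
        if df["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if len(df) and (df["start"] > df["end"]).any():
            raise ValueError("gene span start > end")

    def __len__(self) -> int:
        return len(self.genes)


def read_bed(path) -> IntervalSet:
    """Read a BED3/BED4+ file of intervals (extra columns ignored)."""
    rows = []
    with open(path) as fh:
        for k, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{k}: BED line needs >= 3 columns")
            label = parts[3] if len(parts) > 3 else f"interval{k}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    return IntervalSet(pd.DataFrame(rows, columns=["chromosome", "start", "end", "label"]))


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.intervals.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path, feature_type: str = "gene") -> GeneModelSet:
    """Extract gene spans from a GFF3 file via gffutils (in-memory db)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils wraps parse failures
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    rows = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end))
    return GeneModelSet(pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"]))


def _membership(
    geno: GenotypeMatrix, table: pd.DataFrame, lo_col: str, hi_col: str,
    one_based_inclusive: bool, label_col: str, warn_unknown: bool,
) -> tuple[np.ndarray, dict[str, list[str]]]:
    chroms = geno.chromosomes
    pos = geno.positions
    known = set(chroms)
    keep = np.zeros(geno.n_snps, dtype=bool)
    hits: dict[str, list[str]] = {}
    for rec in table.itertuples(index=False):
        chrom = str(getattr(rec, "chromosome"))
        if chrom not in known:
            if warn_unknown:
                warnings.warn(f"interval on unknown chromosome {chrom!r} skipped", stacklevel=3)
            continue
        lo, hi = getattr(rec, lo_col), getattr(rec, hi_col)
        if one_based_inclusive:
            inside = (chroms == chrom) & (pos >= lo) & (pos <= hi)
        else:  # BED: 0-based half-open [lo, hi) -> 1-based [lo+1, hi]
            inside = (chroms == chrom) & (pos >= lo + 1) & (pos <= hi)
        keep |= inside
        label = str(getattr(rec, label_col))
        for i in np.flatnonzero(inside):
            hits.setdefault(geno.snp_ids[i], []).append(label)
    return keep, hits


def subset_by_intervals(
    geno: GenotypeMatrix, intervals: IntervalSet, return_hits: bool = False
):
    """SNPs falling inside any BED interval; order preserved, kept once even
    when several intervals overlap the position."""
    keep, hits = _membership(
        geno, intervals.intervals, "start", "end",
        one_based_inclusive=False, label_col="label", warn_unknown=True,
    )
    sub = geno.take_snps(np.flatnonzero(keep))
    return (sub, hits) if return_hits else sub


def subset_by_gene_models(
    geno: GenotypeMatrix, genes: GeneModelSet, return_hits: bool = False
):
    """SNPs falling inside any annotated gene span (1-based inclusive ends)."""
    keep, hits = _membership(
        geno, genes.genes, "start", "end",
        one_based_inclusive=True, label_col="gene_id", warn_unknown=True,
    )
    sub = geno.take_snps(np.flatnonzero(keep))
    return (sub, hits) if return_hits else sub
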