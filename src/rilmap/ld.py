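"""Pairwise linkage disequilibrium, binned decay curves and half-decay distance.

LD between two SNPs is the squared Pearson correlation of their +1/-1
additive codes across lines non-missing at both SNPs.  Pairs are formed
within chromosomes up to a maximum physical distance (default 1 Mb); the
decay curve averages r^2 in consecutive distance bins (default 1 kb) and
the decay rate is summarised by the distance at which the binned mean
first drops to half of its maximum.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["LdPairSet", "LdDecayCurve", "pairwise_r2", "ld_decay_curve", "half_decay_distance"]


@dataclasses.dataclass
class LdPairSet:
    """Same-chromosome SNP pairs with physical distance and r^2."""

    pairs: pd.DataFrame  # columns snp_i, snp_j, distance_bp, r2
    n_skipped_monomorphic: int = 0

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class LdDecayCurve:
    """Binned mean r^2 by distance; bins are half-open [k*w, (k+1)*w)."""

    bins: pd.DataFrame  # columns bin_start_bp, mean_r2, n_pairs
    bin_width_bp: int

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation on jointly non-missing entries; NaN if
    either column is monomorphic there."""
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    if len(xs) < 2:
        return np.nan
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    c = np.corrcoef(xs, ys)[0, 1]
    return float(c * c)


def pairwise_r2(
    geno: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    max_neighbors: int | None = None,
) -> LdPairSet:
    """All same-chromosome pairs within ``max_dist_bp``.

    ``max_neighbors`` restricts each SNP to its k nearest downstream
    neighbours (the window-count mode of common LD tools); the default uses
    every pair in the distance window.  Pairs involving a monomorphic SNP
    are skipped and counted.
    """
    chroms = geno.chromosomes
    positions = geno.positions
    recs: list[tuple[str, str, int, float]] = []
    skipped = 0
    any_pairable = False
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        idx = idx[np.argsort(positions[idx], kind="stable")]
        any_pairable = True
        pos = positions[idx]
        calls = geno.calls[:, idx]
        no_missing = not np.isnan(calls).any()
        if no_missing:
            mu = calls.mean(axis=0)
            sd = calls.std(axis=0)
            z = (calls - mu) / np.where(sd > 0, sd, 1.0)
        for a in range(len(idx)):
            b_hi = len(idx)
            if max_neighbors is not None:
                b_hi = min(b_hi, a + 1 + max_neighbors)
            for b in range(a + 1, b_hi):
                d = int(pos[b] - pos[a])
                if d > max_dist_bp:
                    break
                if no_missing:
                    if sd[a] == 0 or sd[b] == 0:
                        skipped += 1
                        continue
                    c = float(z[:, a] @ z[:, b]) / calls.shape[0]
                    r2 = c * c
                else:
                    r2 = _pair_r2(calls[:, a], calls[:, b])
                    if np.isnan(r2):
                        skipped += 1
                        continue
                sa, sb = geno.snps[idx[a]], geno.snps[idx[b]]
                recs.append((sa.snp_id, sb.snp_id, d, min(r2, 1.0)))
    if not any_pairable:
        raise ValueError("need at least 2 SNPs on some chromosome")
    df = pd.DataFrame(recs, columns=["snp_i", "snp_j", "distance_bp", "r2"])
    return LdPairSet(df, n_skipped_monomorphic=skipped)


def ld_decay_curve(pairs: LdPairSet, bin_width_bp: int = 1_000) -> LdDecayCurve:
    """Average r^2 in half-open distance bins of width ``bin_width_bp``."""
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    if bin_width_bp <= 0:
        raise ValueError("bin width must be positive")
    df = pairs.pairs
    binned = (
        df.assign(bin_start_bp=(df["distance_bp"] // bin_width_bp) * bin_width_bp)
        .groupby("bin_start_bp")["r2"]
        .agg(mean_r2="mean", n_pairs="size")
        .reset_index()
        .sort_values("bin_start_bp", ignore_index=True)
    )
    return LdDecayCurve(binned, bin_width_bp=bin_width_bp)


def half_decay_distance(
    curve: LdDecayCurve, smooth_window: int | None = None
) -> float | None:
    """Start distance of the first bin whose mean r^2 is at most half the
    maximum bin mean; ``None`` when the curve never drops that far.

    ``smooth_window`` optionally applies a centred moving average (in bins)
    before the search; default off.
    """
    bins = curve.bins
    if len(bins) == 0:
        raise ValueError("empty decay curve")
    means = bins["mean_r2"].to_numpy(dtype=float)
    if smooth_window is not None and smooth_window > 1:
        means = (
            pd.Series(means).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
        )
    half = means.max() / 2.0
    below = np.flatnonzero(means <= half)
    if len(below) == 0:
        return None
    return float(bins["bin_start_bp"].iloc[below[0]])
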