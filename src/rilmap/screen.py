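"""Fast F-statistic pre-screening of SNPs and SNP pairs.

Mixed-model mapping with permutation thresholds is too expensive to run on
hundreds of thousands of SNPs, so large SNP sets are first reduced to a
candidate list.  The screen ranks SNPs by the one-way F statistic of the
line-mean phenotype on the +1/-1 genotype (1D) and SNP pairs by the
partial F of the product term added to both marginals (2D), keeping the
``top_m`` of each.  Screening is a pure filter: with ``top_m`` equal to
the number of SNPs the downstream mapping result is unchanged.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeTable

__all__ = ["CandidateSet", "marginal_screen", "pairwise_screen", "merge_candidates"]


@dataclasses.dataclass
class CandidateSet:
    """SNPs and SNP pairs retained by a screen, with their scores."""

    snps: list[str] = dataclasses.field(default_factory=list)
    pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    snp_scores: dict[str, float] = dataclasses.field(default_factory=dict)
    pair_scores: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    trait: str | None = None
    environment: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP ids in candidate set")
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"pair ({i},{j}) must reference distinct SNPs")

    def to_tsv(self, path) -> None:
        rows = [("snp", s, "", self.snp_scores.get(s, np.nan)) for s in self.snps]
        rows += [("pair", i, j, self.pair_scores.get((i, j), np.nan)) for i, j in self.pairs]
        pd.DataFrame(rows, columns=["kind", "id1", "id2", "score"]).assign(
            trait=self.trait, environment=self.environment
        ).to_csv(path, sep="\t", index=False)


def _aligned_line_means(geno: GenotypeMatrix, pheno: PhenotypeTable, trait, environment):
    means = pheno.line_means(trait, environment)
    common = [lid for lid in geno.line_ids if lid in means.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 lines shared between genotypes and phenotypes")
    rows = [geno.line_ids.index(lid) for lid in common]
    x = geno.imputed_calls()[rows, :]
    y = means.loc[common].to_numpy(dtype=float)
    return x, y


def marginal_screen(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    environment: str | None = None,
    top_m: int = 1000,
) -> CandidateSet:
    """Rank SNPs by the one-way F statistic of line means on genotype.

    ``environment=None`` pools line means over all environments.
    Monomorphic SNPs have no defined score and are excluded.
    """
    x, y = _aligned_line_means(geno, pheno, trait, environment)
    n = len(y)
    yc = y - y.mean()
    syy = float(yc @ yc)
    xc = x - x.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    poly = sxx > 0
    if syy == 0:
        warnings.warn("constant phenotype: all screening scores are 0", stacklevel=2)
        f = np.zeros(x.shape[1])
    else:
        sxy = xc.T @ yc
        with np.errstate(invalid="ignore", divide="ignore"):
            ssr = np.where(poly, sxy**2 / np.where(poly, sxx, 1.0), np.nan)
            sse = syy - ssr
            f = np.where(sse > 1e-12 * syy, ssr / (sse / max(n - 2, 1)), np.inf)
    f = np.where(poly, f, np.nan)
    order = [int(i) for i in np.argsort(-np.nan_to_num(f, nan=-np.inf), kind="stable") if poly[i]]
    order = order[: int(top_m)]
    ids = geno.snp_ids
    return CandidateSet(
        snps=[ids[i] for i in order],
        snp_scores={ids[i]: float(f[i]) for i in order},
        trait=trait,
        environment=environment,
    )


def pairwise_screen(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    environment: str | None = None,
    top_m: int = 1000,
    universe: list[str] | None = None,
    universe_m: int = 2000,
) -> CandidateSet:
    """Rank SNP pairs by the partial F of the interaction (product) term.

    For each pair the model ``y ~ 1 + x_i + x_j + x_i*x_j`` on line means is
    compared against the marginal-only model.  The pair universe defaults
    to all pairs among the ``universe_m`` top marginally ranked SNPs (set
    ``universe`` explicitly for an exhaustive or custom screen).  Pairs
    whose members are perfectly correlated are skipped.
    """
    if universe is None:
        universe = marginal_screen(geno, pheno, trait, environment, top_m=universe_m).snps
    sub = geno.select_snp_ids(universe)
    x, y = _aligned_line_means(sub, pheno, trait, environment)
    n = len(y)
    ids = sub.snp_ids
    scores: dict[tuple[str, str], float] = {}
    n_skipped = 0
    ones = np.ones(n)
    for a, b in itertools.combinations(range(len(ids)), 2):
        xi, xj = x[:, a], x[:, b]
        if np.std(xi) == 0 or np.std(xj) == 0:
            n_skipped += 1
            continue
        r = np.corrcoef(xi, xj)[0, 1]
        if abs(r) >= 1.0 - 1e-12:
            n_skipped += 1
            continue
        base = np.column_stack([ones, xi, xj])
        full = np.column_stack([base, xi * xj])
        sse_base = _sse(base, y)
        sse_full, rank_full = _sse_rank(full, y)
        if rank_full < 4:  # product collinear with the marginal design
            n_skipped += 1
            continue
        df = n - 4
        if df <= 0:
            continue
        num = sse_base - sse_full
        scores[(ids[a], ids[b])] = float(np.inf) if sse_full <= 1e-12 * max(sse_base, 1.0) else float(
            num / (sse_full / df)
        )
    top = sorted(scores, key=lambda p: (-scores[p], p))[: int(top_m)]
    cs = CandidateSet(
        pairs=top,
        pair_scores={p: scores[p] for p in top},
        trait=trait,
        environment=environment,
    )
    cs.n_skipped = n_skipped
    return cs


def _sse(design: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ beta
    return float(r @ r)


def _sse_rank(design: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ beta
    return float(r @ r), int(rank)


def merge_candidates(sets: list[CandidateSet]) -> CandidateSet:
    """Union of SNPs and pairs across screens (e.g. per-environment runs).

    Scores keep the maximum across sets; pair orientation is normalised.
    """
    snps: list[str] = []
    snp_scores: dict[str, float] = {}
    pairs: list[tuple[str, str]] = []
    pair_scores: dict[tuple[str, str], float] = {}
    for cs in sets:
        for s in cs.snps:
            sc = cs.snp_scores.get(s, np.nan)
            if s not in snp_scores:
                snps.append(s)
                snp_scores[s] = sc
            else:
                snp_scores[s] = np.nanmax([snp_scores[s], sc])
        for p in cs.pairs:
            key = tuple(sorted(p))
            sc = cs.pair_scores.get(p, np.nan)
            if key not in pair_scores:
                pairs.append(key)
                pair_scores[key] = sc
            else:
                pair_scores[key] = np.nanmax([pair_scores[key], sc])
    traits = {cs.trait for cs in sets}
    envs = {cs.environment for cs in sets}
    return CandidateSet(
        snps=snps,
        pairs=pairs,
        snp_scores=snp_scores,
        pair_scores=pair_scores,
        trait=traits.pop() if len(traits) == 1 else None,
        environment=envs.pop() if len(envs) == 1 else None,
    )
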