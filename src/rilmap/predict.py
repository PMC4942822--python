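"""Breeding-value prediction from estimated QTS effects.

Given a fitted genetic architecture, the total genetic value of a
genotype is G = sum a_i x_i + sum aa_ij x_i x_j and its predicted
phenotype is mu + G (QTS-by-environment terms, when absent from the
model, leave G constant across environments).  The module evaluates the
two parental genotypes (all +1 / all -1), ranks the observed lines to
find the best line (BL), and searches the space of homozygous genotypes
for the superior line (SL) with the highest attainable G.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping

import numpy as np
import pandas as pd

from .effects import GeneticEffects
from .genotypes import GenotypeMatrix

__all__ = [
    "genetic_value",
    "best_line",
    "superior_line",
    "GeneticValueReport",
    "build_report",
]

EXHAUSTIVE_LIMIT = 20


def _as_effects(model) -> GeneticEffects:
    if isinstance(model, GeneticEffects):
        return model
    if hasattr(model, "effects"):
        return model.effects
    raise TypeError("expected GeneticEffects or a fitted results object")


def genetic_value(model, genotype: Mapping[str, float]) -> float:
    """Total genetic value G of a genotype over the model's loci."""
    return _as_effects(model).genetic_value(genotype)


def best_line(model, geno: GenotypeMatrix) -> tuple[str, float, bool]:
    """The observed line with the highest genetic value.

    Missing calls at model loci are mean-imputed.  Returns
    ``(line_id, G, tied)``; ties keep the first line in input order.
    """
    eff = _as_effects(model)
    if geno.n_lines == 0:
        raise ValueError("no lines")
    sub = geno.select_snp_ids(eff.loci)
    calls = sub.imputed_calls()
    values = np.array(
        [eff.genetic_value(dict(zip(sub.snp_ids, row))) for row in calls]
    )
    best = int(np.argmax(values))
    tied = bool(np.sum(np.isclose(values, values[best], rtol=0, atol=1e-12)) > 1)
    return geno.line_ids[best], float(values[best]), tied


def superior_line(
    model,
    method: str = "auto",
    seed: int | None = None,
    n_restarts: int = 50,
) -> tuple[dict[str, int], float]:
    """Homozygous genotype in {-1,+1}^k maximising the genetic value.

    Purely additive models are solved directly (x_i = sign(a_i), so
    G = sum |a_i|).  With epistasis, ``method="exhaustive"`` enumerates all
    2^k genotypes (k <= 20) and ``method="anneal"`` runs seeded simulated
    annealing with restarts; ``"auto"`` picks enumeration when feasible.
    """
    eff = _as_effects(model)
    loci = eff.loci
    k = len(loci)
    if k < 1:
        raise ValueError("model has no loci")
    if method not in ("auto", "exhaustive", "anneal"):
        raise ValueError(f"unknown method {method!r}")
    if not eff.epistatic:
        x = {q: (1 if eff.additive.get(q, 0.0) >= 0 else -1) for q in loci}
        return x, eff.genetic_value(x)
    if method == "exhaustive" and k > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{k} loci exceed the exhaustive limit of {EXHAUSTIVE_LIMIT}; use method='anneal'"
        )
    if method == "auto":
        method = "exhaustive" if k <= EXHAUSTIVE_LIMIT else "anneal"
    a = np.array([eff.additive.get(q, 0.0) for q in loci])
    pos = {q: i for i, q in enumerate(loci)}
    pair_idx = np.array([(pos[i], pos[j]) for i, j in eff.epistatic], dtype=int)
    aa = np.array(list(eff.epistatic.values()))

    def value(x: np.ndarray) -> float:
        return float(a @ x + aa @ (x[pair_idx[:, 0]] * x[pair_idx[:, 1]]))

    if method == "exhaustive":
        best_x, best_g = None, -np.inf
        for bits in itertools.product((-1, 1), repeat=k):
            x = np.array(bits)
            g = value(x)
            if g > best_g:
                best_x, best_g = x, g
        return dict(zip(loci, (int(v) for v in best_x))), best_g

    # simulated annealing with restarts and a geometric temperature ladder;
    # single-locus flips are scored incrementally:
    # delta_i = -2 x_i (a_i + sum_j aa_ij x_j)
    rng = np.random.default_rng(seed)
    neighbors: list[list[tuple[int, float]]] = [[] for _ in range(k)]
    for (pi, pj), w in zip(pair_idx, aa):
        neighbors[pi].append((pj, float(w)))
        neighbors[pj].append((pi, float(w)))
    scale = max(float(np.abs(a).sum() + np.abs(aa).sum()), 1.0)

    def flip_delta(x: np.ndarray, i: int) -> float:
        field = a[i] + sum(w * x[j] for j, w in neighbors[i])
        return -2.0 * x[i] * field

    best_x, best_g = None, -np.inf
    for _ in range(n_restarts):
        x = rng.choice([-1, 1], size=k)
        g = value(x)
        t = 0.5 * scale
        while t > 1e-4 * scale:
            for i in rng.integers(0, k, size=4 * k):
                d = flip_delta(x, i)
                if d >= 0 or rng.random() < np.exp(d / t):
                    x[i] = -x[i]
                    g += d
            t *= 0.9
        # greedy polish: flip while improving
        improved = True
        while improved:
            improved = False
            for i in range(k):
                d = flip_delta(x, i)
                if d > 1e-12:
                    x[i] = -x[i]
                    g += d
                    improved = True
        if g > best_g:
            best_x, best_g = x.copy(), float(g)
    return dict(zip(loci, (int(v) for v in best_x))), best_g


@dataclasses.dataclass
class GeneticValueReport:
    """Population mean plus G and mu+G for parents, BL and SL."""

    mean: float
    entries: pd.DataFrame  # index: entry, columns: G, predicted_phenotype
    bl_line_id: str
    sl_genotype: dict[str, int]

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        df.insert(0, "entry", df.index)
        df.to_csv(path, sep="\t", index=False)


def build_report(
    model,
    geno: GenotypeMatrix,
    method: str = "auto",
    seed: int | None = None,
    parent_labels: tuple[str, str] = ("paternal_parent", "maternal_parent"),
) -> GeneticValueReport:
    """Evaluate parents (all +1 / all -1), the best observed line and the
    predicted superior line on a fitted model."""
    eff = _as_effects(model)
    g_pat = eff.genetic_value({q: 1 for q in eff.loci})
    g_mat = eff.genetic_value({q: -1 for q in eff.loci})
    bl_id, g_bl, _ = best_line(eff, geno)
    sl_x, g_sl = superior_line(eff, method=method, seed=seed)
    rows = {
        parent_labels[0]: g_pat,
        parent_labels[1]: g_mat,
        "BL": g_bl,
        "SL": g_sl,
    }
    entries = pd.DataFrame(
        {
            "G": pd.Series(rows),
            "predicted_phenotype": pd.Series({k: eff.mean + v for k, v in rows.items()}),
        }
    )
    return GeneticValueReport(eff.mean, entries, bl_id, sl_x)
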