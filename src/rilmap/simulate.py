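"""Synthetic RIL genotypes and phenotypes with known ground truth.

Genotypes are produced by forward simulation of single seed descent (SSD):
an F1 between two fully homozygous inbred parents is selfed for a configured
number of generations, advancing one random progeny per line per generation.
Crossovers follow the Haldane model (no interference): per meiosis, adjacent
markers at distance ``d`` cM recombine with probability
``r = (1 - exp(-2d/100)) / 2``, independently across intervals and meioses.

Phenotypes follow the saturated genetic model for multi-environment trials:

    y_hk = mu + sum_i a_i x_ik + sum_ij aa_ij x_ik x_jk
           + e_h + sum_i ae_hi x_ik + sum_ij aae_hij x_ik x_jk + eps_hk

with the environment main effect ``e_h`` and all interaction terms drawn
normal with the configured standard deviations.  Fixed effects (``a``,
``aa``) and their true values are recorded so parameter recovery can be
tested against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genmap import GeneticMap, haldane_r
from .genotypes import GenotypeMatrix, SnpRecord
from .phenotypes import PhenotypeTable

__all__ = [
    "SimulationConfig",
    "TrueModel",
    "simulate_ril_genotypes",
    "simulate_phenotypes",
    "write_true_model",
    "read_true_model",
]


@dataclasses.dataclass
class SimulationConfig:
    """Population design for the SSD simulation.

    ``n_selfing_generations`` counts selfings after the F1, so the default
    of 12 yields F13 lines.  ``het_policy`` resolves residual heterozygotes:
    ``"force-homozygous"`` assigns them to a parental class by fair coin
    flip, ``"code-missing"`` records them as missing calls.
    """

    n_lines: int = 138
    n_selfing_generations: int = 12
    seed: int | None = None
    het_policy: str = "force-homozygous"
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.n_selfing_generations < 1:
            raise ValueError("need at least 1 selfing generation")
        if self.het_policy not in ("force-homozygous", "code-missing"):
            raise ValueError(f"unknown het_policy {self.het_policy!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclasses.dataclass
class TrueModel:
    """Ground-truth generative parameters for the phenotype model."""

    population_mean: float
    additive_effects: Mapping[str, float] = dataclasses.field(default_factory=dict)
    epistatic_effects: Mapping[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    env_effect_sd: float = 0.0
    ae_sd: float = 0.0
    aae_sd: float = 0.0
    residual_sd: float = 1.0
    n_environments: int = 2
    n_replicates: int = 2
    trait: str = "trait"

    def __post_init__(self) -> None:
        for name in ("env_effect_sd", "ae_sd", "aae_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for i, j in self.epistatic_effects:
            if i == j:
                raise ValueError(f"epistatic pair ({i},{j}) must reference distinct loci")
        if self.n_environments < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 environment and replicate")

    @property
    def qts_ids(self) -> list[str]:
        ids = list(self.additive_effects)
        for i, j in self.epistatic_effects:
            for s in (i, j):
                if s not in ids:
                    ids.append(s)
        return ids


def _meiosis(h1: np.ndarray, h2: np.ndarray, rs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per line from parental haplotype pair (n_lines x n_markers)."""
    n, m = h1.shape
    start = rng.integers(0, 2, size=(n, 1))
    if m > 1:
        co = rng.random((n, m - 1)) < rs
        parity = np.concatenate([np.zeros((n, 1), dtype=int), np.cumsum(co, axis=1)], axis=1)
    else:
        parity = np.zeros((n, 1), dtype=int)
    strand = (start + parity) % 2
    return np.where(strand == 0, h1, h2)


def simulate_ril_genotypes(gmap: GeneticMap, config: SimulationConfig) -> GenotypeMatrix:
    """Simulate a biparental SSD RIL population on the given genetic map.

    Returns calls coded +1 (paternal homozygote) / -1 (maternal homozygote),
    with residual heterozygotes resolved per ``config.het_policy`` and
    missing calls injected uniformly at ``config.missing_rate``.
    """
    if not gmap.chromosomes or gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    snps: list[SnpRecord] = []
    blocks: list[np.ndarray] = []
    for chrom in gmap:
        m = chrom.n_markers
        rs = haldane_r(np.diff(chrom.genetic_pos_cM)) if m > 1 else np.empty(0)
        # haplotypes coded 0 = paternal allele, 1 = maternal; F1 is 0/1 everywhere
        h1 = np.zeros((n, m), dtype=np.int8)
        h2 = np.ones((n, m), dtype=np.int8)
        for _ in range(config.n_selfing_generations):
            g1 = _meiosis(h1, h2, rs, rng)
            g2 = _meiosis(h1, h2, rs, rng)
            h1, h2 = g1, g2
        calls = np.where(h1 == h2, np.where(h1 == 0, 1.0, -1.0), np.nan)
        het = np.isnan(calls)
        if config.het_policy == "force-homozygous" and het.any():
            calls[het] = rng.integers(0, 2, size=int(het.sum())) * 2.0 - 1.0
        blocks.append(calls)
        for mid, pos in zip(chrom.marker_ids, chrom.physical_pos_bp):
            snps.append(SnpRecord(mid, chrom.chrom_id, int(pos)))
    calls = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = np.nan
    line_ids = [f"RIL{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(line_ids, snps, calls)


def simulate_phenotypes(geno: GenotypeMatrix, model: TrueModel, seed: int | None = None) -> PhenotypeTable:
    """Draw replicated multi-environment phenotypes under the saturated model."""
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(geno.snp_ids)}
    unknown = [q for q in model.qts_ids if q not in idx]
    if unknown:
        raise KeyError(f"unknown QTS ids in model: {unknown}")
    x = geno.calls[:, [idx[q] for q in model.qts_ids]]
    if np.isnan(x).any():
        # model loci must be complete; fall back to per-SNP mean imputation
        x = geno.imputed_calls()[:, [idx[q] for q in model.qts_ids]]
    col = {q: k for k, q in enumerate(model.qts_ids)}

    g_fixed = np.full(geno.n_lines, model.population_mean)
    for q, a in model.additive_effects.items():
        g_fixed = g_fixed + a * x[:, col[q]]
    for (qi, qj), aa in model.epistatic_effects.items():
        g_fixed = g_fixed + aa * x[:, col[qi]] * x[:, col[qj]]

    rows = []
    for h in range(model.n_environments):
        env = f"E{h + 1}"
        e_h = rng.normal(0.0, model.env_effect_sd) if model.env_effect_sd > 0 else 0.0
        g_env = g_fixed + e_h
        if model.ae_sd > 0:
            for q in model.additive_effects:
                g_env = g_env + rng.normal(0.0, model.ae_sd) * x[:, col[q]]
        if model.aae_sd > 0:
            for qi, qj in model.epistatic_effects:
                g_env = g_env + rng.normal(0.0, model.aae_sd) * x[:, col[qi]] * x[:, col[qj]]
        for rep in range(1, model.n_replicates + 1):
            eps = rng.normal(0.0, model.residual_sd, size=geno.n_lines) if model.residual_sd > 0 else 0.0
            y = g_env + eps
            rows.append(
                pd.DataFrame(
                    {
                        "line_id": geno.line_ids,
                        "environment": env,
                        "replicate": rep,
                        "trait": model.trait,
                        "value": y,
                    }
                )
            )
    return PhenotypeTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------

def write_true_model(model: TrueModel, path) -> None:
    d = dataclasses.asdict(model)
    d["epistatic_effects"] = {f"{i}|{j}": v for (i, j), v in model.epistatic_effects.items()}
    d["additive_effects"] = dict(model.additive_effects)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)


def read_true_model(path) -> TrueModel:
    with open(path) as fh:
        d = json.load(fh)
    d["epistatic_effects"] = {tuple(k.split("|")): v for k, v in d["epistatic_effects"].items()}
    return TrueModel(**d)
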