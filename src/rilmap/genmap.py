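"""Genetic maps linking marker genetic (cM) and physical (bp) positions."""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["ChromosomeMap", "GeneticMap", "build_genetic_map", "haldane_r", "haldane_d"]


def haldane_r(d_cM: np.ndarray | float):
    """Haldane map function: recombination fraction for a distance in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0)) / 2.0


def haldane_d(r: np.ndarray | float):
    """Inverse Haldane: cM distance giving recombination fraction ``r``."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclasses.dataclass
class ChromosomeMap:
    chrom_id: str
    marker_ids: list[str]
    genetic_pos_cM: np.ndarray
    physical_pos_bp: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genetic_pos_cM, dtype=float)
        p = np.asarray(self.physical_pos_bp, dtype=int)
        if len(self.marker_ids) != len(g) or len(g) != len(p):
            raise ValueError("marker arrays must have equal length")
        if (g < 0).any() or (p < 1).any():
            raise ValueError("genetic positions must be >= 0 cM, physical >= 1 bp")
        # genetic positions may tie (fully linked markers, r = 0) but never decrease
        if len(g) > 1 and (np.diff(g) < 0).any():
            raise ValueError(f"{self.chrom_id}: genetic positions must be non-decreasing")
        if len(p) > 1 and (np.diff(p) <= 0).any():
            raise ValueError(f"{self.chrom_id}: physical positions must be strictly increasing")
        self.genetic_pos_cM = g
        self.physical_pos_bp = p

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclasses.dataclass
class GeneticMap:
    chromosomes: list[ChromosomeMap]

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)


def build_genetic_map(
    n_chrom: int, markers_per_chrom: int, spacing_cM: float, bp_per_cM: float
) -> GeneticMap:
    """Evenly spaced markers: cM positions 0, s, 2s, ...; bp = 1 + cM * bp_per_cM."""
    if n_chrom <= 0 or markers_per_chrom <= 0 or spacing_cM <= 0 or bp_per_cM <= 0:
        raise ValueError("all map parameters must be positive")
    chroms = []
    for c in range(1, n_chrom + 1):
        g = spacing_cM * np.arange(markers_per_chrom, dtype=float)
        p = (1 + np.round(g * bp_per_cM)).astype(int)
        ids = [f"c{c}m{j + 1}" for j in range(markers_per_chrom)]
        chroms.append(ChromosomeMap(str(c), ids, g, p))
    return GeneticMap(chroms)
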