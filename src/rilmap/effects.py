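"""Point-estimate genetic architecture: mean, additive and epistatic effects.

`GeneticEffects` is the minimal object breeding-value prediction needs: a
population mean, per-QTS additive effects (paternal-homozygote coding, so
the maternal homozygote contributes the opposite sign) and optional
additive-by-additive epistatic effects keyed by locus pair.  It can come
from a fitted model or be built directly from published estimates.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

__all__ = ["GeneticEffects"]


@dataclasses.dataclass(frozen=True)
class GeneticEffects:
    mean: float
    additive: Mapping[str, float]
    epistatic: Mapping[tuple[str, str], float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j in self.epistatic:
            if i == j:
                raise ValueError(f"epistatic pair ({i},{j}) must reference distinct loci")

    @property
    def loci(self) -> list[str]:
        ids = list(self.additive)
        for i, j in self.epistatic:
            for s in (i, j):
                if s not in ids:
                    ids.append(s)
        return ids

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def genetic_value(self, genotype: Mapping[str, float]) -> float:
        """Total genetic value G = sum a_i x_i + sum aa_ij x_i x_j.

        ``genotype`` maps every locus of the model to its +1/-1 code
        (non-integer codes from mean imputation are accepted).
        """
        missing = [q for q in self.loci if q not in genotype]
        if missing:
            raise KeyError(f"genotype missing loci: {missing}")
        g = 0.0
        for q, a in self.additive.items():
            g += a * genotype[q]
        for (qi, qj), aa in self.epistatic.items():
            g += aa * genotype[qi] * genotype[qj]
        return g

    def predicted_phenotype(self, genotype: Mapping[str, float]) -> float:
        return self.mean + self.genetic_value(genotype)
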