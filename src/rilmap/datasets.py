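"""Published QTS effect estimates for the XQZB x ZH9308 rice RIL population.

Reported additive-effect estimates (paternal-homozygote coding), per-QTS
heritabilities and population means for plant height (PH, cm) and heading
date (HD, days) under the three SNP-set strategies: genome-wide (GWA),
QTL-region (QBA) and gene-based (GBA) association.  These serve as worked
inputs for breeding-value prediction and as fixtures for consistency
checks of the heritability convention; no raw genotype or phenotype data
are included.

Each record is ``(snp_id, chromosome, additive_effect, h2_percent)``.
"""

from __future__ import annotations

from .effects import GeneticEffects

__all__ = ["QTS_TABLE", "POPULATION_MEANS", "TOTAL_H2", "effects_for", "strategies"]

QTS_TABLE: dict[tuple[str, str], list[tuple[str, str, float, float]]] = {
    ("PH", "GWA"): [
        ("rs25397447", "1", 2.61, 8.91),
        ("rs2745731", "3", 3.03, 11.99),
        ("rs36929057", "3", 2.50, 8.21),
        ("rs8819284", "6", 1.88, 4.62),
        ("rs14788399", "7", -1.83, 4.37),
        ("rs4468159", "11", -2.40, 7.53),
    ],
    ("PH", "QBA"): [
        ("rs37194796", "3", 2.85, 9.89),
        ("rs9040677", "6", 2.34, 6.69),
        ("rs9669459", "6", 2.24, 6.10),
        ("rs14788399", "7", -2.72, 9.04),
        ("rs4468159", "11", -2.12, 5.50),
    ],
    ("PH", "GBA"): [
        ("rs24562025", "1", 2.20, 5.72),
        ("rs10179007", "6", 3.01, 10.63),
        ("rs7478190", "8", 2.31, 6.29),
        ("rs489068", "12", 2.63, 8.14),
        ("rs10809004", "12", -2.83, 9.41),
    ],
    ("HD", "GWA"): [
        ("rs12807091", "1", 1.58, 4.67),
        ("rs22665688", "1", 2.29, 9.71),
        ("rs26023433", "1", 1.41, 3.71),
        ("rs3033880", "6", -2.49, 11.53),
        ("rs17909546", "10", 2.53, 11.94),
    ],
    ("HD", "QBA"): [
        ("rs14583697", "1", 2.28, 9.53),
        ("rs4139855", "4", 2.22, 9.03),
        ("rs2083119", "5", -1.94, 6.88),
        ("rs3070122", "6", -2.51, 11.55),
        ("rs14516781", "7", 2.02, 7.46),
        ("rs13634598", "10", 1.78, 5.78),
        ("rs17462383", "10", 1.77, 5.72),
    ],
    ("HD", "GBA"): [
        ("rs22139712", "1", 1.91, 7.08),
        ("rs32347548", "4", 1.66, 5.36),
        ("rs3112796", "6", -1.78, 6.19),
        ("rs12634148", "10", 1.45, 4.09),
        ("rs17909546", "10", 2.24, 9.79),
        ("rs457324", "12", 1.61, 5.02),
    ],
}

# estimated population means (mu) per trait and strategy
POPULATION_MEANS: dict[tuple[str, str], float] = {
    ("PH", "GWA"): 81.55,
    ("PH", "QBA"): 81.40,
    ("PH", "GBA"): 80.61,
    ("HD", "GWA"): 98.49,
    ("HD", "QBA"): 98.33,
    ("HD", "GBA"): 99.46,
}

# reported total heritability (%) per trait and strategy
TOTAL_H2: dict[tuple[str, str], float] = {
    ("PH", "GWA"): 45.63,
    ("PH", "QBA"): 37.22,
    ("PH", "GBA"): 40.19,
    ("HD", "GWA"): 41.56,
    ("HD", "QBA"): 55.95,
    ("HD", "GBA"): 37.53,
}


def strategies() -> list[tuple[str, str]]:
    """All (trait, strategy) combinations in the published tables."""
    return list(QTS_TABLE)


def effects_for(trait: str, strategy: str) -> GeneticEffects:
    """Build a `GeneticEffects` model from the published estimates.

    All reported effects are additive (no epistasis or QTS-by-environment
    interaction was declared for either trait).
    """
    key = (trait, strategy)
    if key not in QTS_TABLE:
        raise KeyError(f"no published estimates for {key}")
    additive = {snp: a for snp, _, a, _ in QTS_TABLE[key]}
    return GeneticEffects(POPULATION_MEANS[key], additive)
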