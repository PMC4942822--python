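import numpy as np
import pandas as pd
import pytest

from rilmap import (
    GenotypeMatrix,
    PhenotypeTable,
    SimulationConfig,
    SnpRecord,
    build_genetic_map,
    simulate_ril_genotypes,
)


def make_geno(columns, line_prefix="L", chrom="1", positions=None, ids=None):
    """Build a GenotypeMatrix from a dict/list of per-SNP call columns."""
    if isinstance(columns, dict):
        ids = list(columns)
        cols = [columns[s] for s in ids]
    else:
        cols = list(columns)
        ids = ids or [f"snp{j + 1}" for j in range(len(cols))]
    calls = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    n = calls.shape[0]
    positions = positions or [100 * (j + 1) for j in range(len(ids))]
    snps = [SnpRecord(s, chrom, int(p)) for s, p in zip(ids, positions)]
    return GenotypeMatrix([f"{line_prefix}{i + 1}" for i in range(n)], snps, calls)


def make_pheno(values_by_line, environment="E1", replicate=1, trait="trait"):
    rows = [
        {"line_id": lid, "environment": environment, "replicate": replicate,
         "trait": trait, "value": v}
        for lid, v in values_by_line.items()
    ]
    return PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_ril():
    """138-line RIL population on a compact 2-chromosome map."""
    gmap = build_genetic_map(2, 25, 4.0, 250_000)
    geno = simulate_ril_genotypes(gmap, SimulationConfig(n_lines=138, seed=11))
    return geno
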