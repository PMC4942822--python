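"""Replicated multi-environment phenotype observations."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["PhenotypeTable"]

COLUMNS = ["line_id", "environment", "replicate", "trait", "value"]


class PhenotypeTable:
    """Trait observations indexed by line x environment x replicate.

    Thin wrapper over a tidy DataFrame with columns
    ``line_id, environment, replicate, trait, value``.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        if len(data) == 0:
            raise ValueError("empty phenotype table")
        if not np.isfinite(data["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite phenotype values")
        self.data = data[COLUMNS].reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].astype(str).unique())

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.data["line_id"].astype(str).unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if len(sub) == 0:
            raise KeyError(f"trait {trait!r} not present (have {self.traits})")
        return sub

    def line_means(self, trait: str, environment=None) -> pd.Series:
        """Mean trait value per line, optionally within one environment."""
        sub = self.for_trait(trait)
        if environment is not None:
            sub = sub[sub["environment"] == environment]
            if len(sub) == 0:
                raise KeyError(f"environment {environment!r} not present")
        return sub.groupby("line_id")["value"].mean()

    def line_env_means(self, trait: str) -> pd.DataFrame:
        """Line x environment mean table (replicates averaged)."""
        sub = self.for_trait(trait)
        return sub.groupby(["line_id", "environment"])["value"].mean().unstack()

    def phenotypic_variance(self, trait: str) -> float:
        """Sample variance of the line x environment means.

        This is the V_P used to express per-QTS variance contributions as
        heritability percentages.
        """
        m = self.line_env_means(trait).to_numpy().ravel()
        m = m[~np.isnan(m)]
        if len(m) < 2:
            raise ValueError("need >= 2 line x environment means for V_P")
        v = float(np.var(m, ddof=1))
        if v == 0:
            raise ValueError("phenotypic variance is zero")
        return v

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PhenotypeTable {len(self.data)} obs, traits={self.traits}, "
            f"environments={self.environments}>"
        )
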