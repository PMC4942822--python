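"""Two-step mixed-model association mapping with permutation thresholds.

The engine follows the two-step strategy used for QTS mapping in RIL
populations:

1. *Individual locus detection.*  Each SNP is F-tested for its additive
   term in a fixed-effects model ``y = mu + environment + a x`` on
   replicate-level observations.  An experiment-wise threshold F* is the
   empirical (1 - alpha) quantile of the max-F distribution over
   permutations that shuffle line labels within each environment.
2. *Epistasis detection.*  With the step-1 SNPs as covariates, each SNP
   pair is F-tested for its product term (both marginals included), again
   against a permutation max-F threshold.

Candidate loci and pairs then go through forward-backward stepwise
selection, and the selected model is estimated by Gibbs sampling under the
saturated mixed model: fixed mean, additive and epistatic effects; random
environment main effect and QTS-by-environment interactions; posterior
means/sds give estimates and standard errors, and per-QTS heritabilities
are expressed against the variance of line-by-environment mean phenotypes.

`AssociationModel` is constructed from a genotype matrix and phenotype
table; `fit()` returns an `AssociationResults` with the estimates and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import GeneticEffects
from .genotypes import GenotypeMatrix
from .phenotypes import PhenotypeTable

__all__ = [
    "PermutationConfig",
    "ScanResult",
    "SelectedTerms",
    "AssociationModel",
    "AssociationResults",
    "compute_heritability",
]

_LOG10 = np.log(10.0)


@dataclasses.dataclass
class PermutationConfig:
    """Permutation scheme for experiment-wise F thresholds."""

    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("need >= 100 permutations for a stable threshold")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")


@dataclasses.dataclass
class ScanResult:
    """Per-unit F statistics from a 1D or 2D scan."""

    kind: str  # "1D" or "2D"
    units: list  # SNP ids (1D) or (snp_i, snp_j) tuples (2D)
    f: np.ndarray
    df_num: int
    df_den: int
    threshold: float | None = None
    n_skipped: int = 0

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return stats.f.sf(self.f, self.df_num, self.df_den)

    @property
    def significant_units(self) -> list:
        if self.threshold is None:
            raise ValueError("no permutation threshold attached to this scan")
        ok = np.nan_to_num(self.f, nan=-np.inf) > self.threshold
        return [u for u, s in zip(self.units, ok) if s]

    def to_frame(self) -> pd.DataFrame:
        if self.kind == "1D":
            df = pd.DataFrame({"snp": self.units, "F": self.f, "p": self.pvalues})
        else:
            df = pd.DataFrame(
                {
                    "snp_i": [u[0] for u in self.units],
                    "snp_j": [u[1] for u in self.units],
                    "F": self.f,
                    "p": self.pvalues,
                }
            )
        df["threshold"] = self.threshold
        return df


@dataclasses.dataclass
class SelectedTerms:
    """Model terms chosen by stepwise selection."""

    snps: list[str] = dataclasses.field(default_factory=list)
    pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.snps or self.pairs)


class AssociationModel:
    """Association mapping model for one trait on a RIL population.

    Aligns replicate-level phenotype observations with the genotype matrix
    (lines present in both, genotype order), mean-imputes missing calls,
    and exposes the two-step scan, permutation thresholding, stepwise
    selection, and the final Gibbs fit.
    """

    def __init__(self, geno: GenotypeMatrix, pheno: PhenotypeTable, trait: str):
        self.geno = geno
        self.pheno = pheno
        self.trait = trait
        obs = pheno.for_trait(trait)
        geno_lines = set(geno.line_ids)
        obs = obs[obs["line_id"].isin(geno_lines)].reset_index(drop=True)
        if len(obs) == 0:
            raise ValueError("no overlapping lines between genotypes and phenotypes")
        self.lines = [lid for lid in geno.line_ids if lid in set(obs["line_id"])]
        line_pos = {lid: i for i, lid in enumerate(self.lines)}
        rows = [geno.line_ids.index(lid) for lid in self.lines]
        self.X = geno.imputed_calls()[rows, :]  # n_lines x n_snps
        self.snp_ids = geno.snp_ids
        self._snp_pos = {s: i for i, s in enumerate(self.snp_ids)}
        self.y = obs["value"].to_numpy(dtype=float)
        self.line_idx = obs["line_id"].map(line_pos).to_numpy(dtype=int)
        envs = sorted(obs["environment"].astype(str).unique())
        self.environments = envs
        env_pos = {e: h for h, e in enumerate(envs)}
        self.env_idx = obs["environment"].astype(str).map(env_pos).to_numpy(dtype=int)
        self.n_obs = len(self.y)
        self.n_env = len(envs)
        self._env_obs = [np.flatnonzero(self.env_idx == h) for h in range(self.n_env)]

    # ------------------------------------------------------------------
    # helpers
    # ------------------------------------------------------------------
    def _cols(self, snp_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._snp_pos[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from exc

    def _env_center(self, v: np.ndarray) -> np.ndarray:
        """Residualize columns (or a vector) on the environment block."""
        out = np.array(v, dtype=float, copy=True)
        for idx in self._env_obs:
            out[idx] -= out[idx].mean(axis=0)
        return out

    def _permuted_line_idx(self, rng: np.random.Generator) -> np.ndarray:
        """Shuffle line labels of the phenotypes within each environment."""
        new = self.line_idx.copy()
        for idx in self._env_obs:
            present = np.unique(self.line_idx[idx])
            perm = rng.permutation(present)
            lut = np.empty(self.line_idx.max() + 1, dtype=int)
            lut[present] = perm
            new[idx] = lut[self.line_idx[idx]]
        return new

    # ------------------------------------------------------------------
    # step 1: additive scan
    # ------------------------------------------------------------------
    def _scan_additive_f(
        self, cols: np.ndarray, line_idx: np.ndarray
    ) -> tuple[np.ndarray, int]:
        yc = self._env_center(self.y)
        syy = float(yc @ yc)
        Xobs = self.X[line_idx][:, cols]
        Xc = self._env_center(Xobs)
        sxx = np.einsum("ij,ij->j", Xc, Xc)
        poly = sxx > 1e-12
        sxy = Xc.T @ yc
        df_den = self.n_obs - self.n_env - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            ssr = np.where(poly, sxy**2 / np.where(poly, sxx, 1.0), np.nan)
            sse = syy - ssr
            f = np.where(
                sse > 1e-10 * max(syy, 1.0), ssr / (sse / df_den), np.inf
            )
        if syy == 0:
            f = np.zeros(len(cols))
        f = np.where(poly, f, np.nan)
        return f, df_den

    def scan_additive(self, snp_ids: Sequence[str] | None = None) -> ScanResult:
        """F statistic of the additive term for each SNP, with the
        environment as a fixed block, on replicate-level observations."""
        ids = list(snp_ids) if snp_ids is not None else list(self.snp_ids)
        f, df_den = self._scan_additive_f(self._cols(ids), self.line_idx)
        return ScanResult("1D", ids, f, 1, df_den, n_skipped=int(np.isnan(f).sum()))

    def _fast_scan_state(self, cols: np.ndarray) -> dict | None:
        """Sufficient statistics for permutation scans on balanced designs.

        When every line has the same number of replicates within each
        environment, the within-environment column means and sums of
        squares are invariant under line-label permutation, so each
        permutation only has to permute the per-line phenotype sums and
        redo one matrix-vector product per environment.
        """
        per_env = []
        for idx in self._env_obs:
            lines, counts = np.unique(self.line_idx[idx], return_counts=True)
            if len(np.unique(counts)) != 1:
                return None  # unbalanced: fall back to the generic path
            r = int(counts[0])
            s = np.zeros(len(lines))
            lut = {l: i for i, l in enumerate(lines)}
            for o in idx:
                s[lut[self.line_idx[o]]] += self.y[o]
            Xh = self.X[lines][:, cols]
            n_h = r * len(lines)
            xbar = Xh.mean(axis=0)
            per_env.append(
                {
                    "Xh": Xh,
                    "s": s,
                    "r": r,
                    "n_h": n_h,
                    "xbar": xbar,
                    "ybar": float(s.sum() / n_h),
                    "sxx": r * (Xh**2).sum(axis=0) - n_h * xbar**2,
                }
            )
        yc = self._env_center(self.y)
        syy = float(yc @ yc)
        sxx = np.sum([e["sxx"] for e in per_env], axis=0)
        return {
            "per_env": per_env,
            "syy": syy,
            "sxx": sxx,
            "poly": sxx > 1e-12,
            "df_den": self.n_obs - self.n_env - 1,
        }

    def _fast_scan_f(self, state: dict, rng: np.random.Generator) -> np.ndarray:
        sxy = np.zeros(len(state["sxx"]))
        for e in state["per_env"]:
            s_perm = e["s"][rng.permutation(len(e["s"]))]
            sxy += e["Xh"].T @ s_perm - e["n_h"] * e["xbar"] * e["ybar"]
        sxx, syy, poly = state["sxx"], state["syy"], state["poly"]
        with np.errstate(invalid="ignore", divide="ignore"):
            ssr = np.where(poly, sxy**2 / np.where(poly, sxx, 1.0), np.nan)
            sse = syy - ssr
            f = np.where(sse > 1e-10 * max(syy, 1.0), ssr / (sse / state["df_den"]), np.inf)
        if syy == 0:
            f = np.zeros(len(sxx))
        return np.where(poly, f, np.nan)

    # ------------------------------------------------------------------
    # step 2: epistasis scan
    # ------------------------------------------------------------------
    def _scan_pairs_f(
        self,
        pairs: list[tuple[str, str]],
        covariate_cols: np.ndarray,
        line_idx: np.ndarray,
    ) -> tuple[np.ndarray, int, int]:
        # base design: environment block + covariate additive terms
        base_cols = [np.zeros((self.n_obs, 0))]
        if len(covariate_cols):
            base_cols.append(self.X[line_idx][:, covariate_cols])
        B = self._env_center(np.column_stack(base_cols)) if covariate_cols.size else None
        yc = self._env_center(self.y)
        if B is not None and B.shape[1]:
            Q, _ = np.linalg.qr(B)
            rank_base = int(np.linalg.matrix_rank(B))
            yr = yc - Q @ (Q.T @ yc)
        else:
            Q = None
            rank_base = 0
            yr = yc
        df_den = self.n_obs - self.n_env - rank_base - 3
        f = np.full(len(pairs), np.nan)
        n_skipped = 0
        Xl = self.X[line_idx]
        for k, (si, sj) in enumerate(pairs):
            ci, cj = self._snp_pos[si], self._snp_pos[sj]
            xi, xj = Xl[:, ci], Xl[:, cj]
            block = self._env_center(np.column_stack([xi, xj, xi * xj]))
            if Q is not None:
                block = block - Q @ (Q.T @ block)
            marg, prod = block[:, :2], block[:, 2]
            bm, *_ = np.linalg.lstsq(marg, yr, rcond=None)
            r0 = yr - marg @ bm
            full = block
            bf, _, rank_full, _ = np.linalg.lstsq(full, yr, rcond=None)
            rf = yr - full @ bf
            # the product column must add rank beyond the marginal design
            rank_marg = int(np.linalg.matrix_rank(marg))
            if rank_full <= rank_marg:
                n_skipped += 1
                continue
            sse0, sse1 = float(r0 @ r0), float(rf @ rf)
            if df_den <= 0:
                continue
            if sse1 <= 1e-10 * max(float(yr @ yr), 1.0):
                f[k] = np.inf
            else:
                f[k] = (sse0 - sse1) / (sse1 / df_den)
        return f, df_den, n_skipped

    def scan_epistasis(
        self,
        covariate_snps: Sequence[str] = (),
        pair_universe: list[tuple[str, str]] | None = None,
    ) -> ScanResult:
        """F statistic of the interaction (product) term for each SNP pair,
        conditioning on the environment block, the step-1 covariate SNPs and
        the pair's marginal terms."""
        if pair_universe is None:
            pair_universe = list(itertools.combinations(self.snp_ids, 2))
        cov = self._cols(covariate_snps)
        f, df_den, n_skipped = self._scan_pairs_f(pair_universe, cov, self.line_idx)
        return ScanResult("2D", list(pair_universe), f, 1, df_den, n_skipped=n_skipped)

    # ------------------------------------------------------------------
    # permutation threshold
    # ------------------------------------------------------------------
    def permutation_threshold(
        self,
        config: PermutationConfig,
        scan_kind: str = "1D",
        snp_ids: Sequence[str] | None = None,
        covariate_snps: Sequence[str] = (),
        pair_universe: list[tuple[str, str]] | None = None,
    ) -> float:
        """Empirical (1 - alpha) quantile of the permutation max-F
        distribution, shuffling line labels within each environment."""
        rng = np.random.default_rng(config.seed)
        max_f = np.empty(config.n_permutations)
        if scan_kind == "1D":
            cols = self._cols(snp_ids) if snp_ids is not None else np.arange(len(self.snp_ids))
            fast = self._fast_scan_state(cols)
            for b in range(config.n_permutations):
                if fast is not None:
                    f = self._fast_scan_f(fast, rng)
                else:
                    f, _ = self._scan_additive_f(cols, self._permuted_line_idx(rng))
                finite = f[np.isfinite(f)]
                max_f[b] = finite.max() if len(finite) else 0.0
        elif scan_kind == "2D":
            if pair_universe is None:
                raise ValueError("2D threshold needs a pair universe")
            cov = self._cols(covariate_snps)
            for b in range(config.n_permutations):
                f, _, _ = self._scan_pairs_f(pair_universe, cov, self._permuted_line_idx(rng))
                finite = f[np.isfinite(f)]
                max_f[b] = finite.max() if len(finite) else 0.0
        else:
            raise ValueError(f"unknown scan kind {scan_kind!r}")
        return float(np.quantile(max_f, 1.0 - config.alpha))

    # ------------------------------------------------------------------
    # stepwise selection
    # ------------------------------------------------------------------
    def _unit_block(self, unit, line_idx: np.ndarray) -> np.ndarray:
        kind, key = unit
        Xl = self.X[line_idx]
        if kind == "snp":
            return Xl[:, [self._snp_pos[key]]]
        xi, xj = Xl[:, self._snp_pos[key[0]]], Xl[:, self._snp_pos[key[1]]]
        return np.column_stack([xi, xj, xi * xj])

    @staticmethod
    def _max_column_corr(A: np.ndarray, B: np.ndarray) -> float:
        """Largest |correlation| between (already centered) column sets."""
        na = np.linalg.norm(A, axis=0)
        nb = np.linalg.norm(B, axis=0)
        ok_a, ok_b = na > 1e-12, nb > 1e-12
        if not ok_a.any() or not ok_b.any():
            return 0.0
        C = (A[:, ok_a] / na[ok_a]).T @ (B[:, ok_b] / nb[ok_b])
        return float(np.abs(C).max())

    def _unit_sort_key(self, unit):
        kind, key = unit
        sid = key if kind == "snp" else key[0]
        s = self.geno.snps[self._snp_pos[sid]]
        return (str(s.chromosome), int(s.position_bp))

    def stepwise_select(
        self,
        candidates: ScanResult | Sequence[str],
        candidate_pairs: ScanResult | Sequence[tuple[str, str]] | None = None,
        entry_alpha: float | None = None,
        stay_alpha: float | None = None,
        max_abs_corr: float = 0.9,
        max_steps: int = 200,
    ) -> SelectedTerms:
        """Forward-backward stepwise selection over candidate loci and
        epistasis pairs (each pair enters as a marginal+product block).

        At each forward step the unit with the smallest partial-F p-value
        below ``entry_alpha`` enters (ties: larger F, then smaller
        chromosome/position); backward steps drop units whose partial-F
        p-value exceeds ``stay_alpha``.  The default alphas are
        ``0.05 / n_candidate_units`` (Bonferroni over selection units), so
        the selection stage keeps family-wise control in the same spirit
        as the permutation threshold of the scans.

        ``max_abs_corr`` caps the absolute correlation between any column
        of an entering unit and the columns already in the design: in
        dense marker panels, markers tightly linked to a selected QTS can
        otherwise enter as near-collinear pairs with wildly inflated
        opposite-sign effects.  One representative per LD block is the
        intended behaviour; truly distinct loci in moderate LD still
        compete on their partial F.
        """
        snp_cands = candidates.units if isinstance(candidates, ScanResult) else list(candidates)
        if candidate_pairs is None:
            pair_cands = []
        elif isinstance(candidate_pairs, ScanResult):
            pair_cands = candidate_pairs.units
        else:
            pair_cands = list(candidate_pairs)
        units = [("snp", s) for s in snp_cands] + [("pair", tuple(p)) for p in pair_cands]
        if not units:
            raise ValueError("no candidate units for stepwise selection")
        if entry_alpha is None:
            entry_alpha = 0.05 / len(units)
        if stay_alpha is None:
            stay_alpha = 0.05 / len(units)

        yc = self._env_center(self.y)
        selected: list = []

        def design(sel):
            blocks = [self._unit_block(u, self.line_idx) for u in sel]
            if not blocks:
                return np.zeros((self.n_obs, 0))
            return self._env_center(np.column_stack(blocks))

        def sse_rank(D):
            if D.shape[1] == 0:
                return float(yc @ yc), 0
            beta, _, rank, _ = np.linalg.lstsq(D, yc, rcond=None)
            r = yc - D @ beta
            return float(r @ r), int(rank)

        for _ in range(max_steps):
            changed = False
            # forward
            D0 = design(selected)
            sse0, rank0 = sse_rank(D0)
            best = None
            for u in units:
                if u in selected:
                    continue
                block = self._env_center(self._unit_block(u, self.line_idx))
                if D0.shape[1] and max_abs_corr < 1.0:
                    if self._max_column_corr(D0, block) > max_abs_corr:
                        continue
                D1 = np.column_stack([D0, block]) if D0.shape[1] else block
                sse1, rank1 = sse_rank(D1)
                df_num = rank1 - rank0
                df_den = self.n_obs - self.n_env - rank1
                if df_num <= 0 or df_den <= 0:
                    continue
                if sse1 <= 1e-10 * max(float(yc @ yc), 1.0):
                    fstat, p = np.inf, 0.0
                else:
                    fstat = (sse0 - sse1) / df_num / (sse1 / df_den)
                    p = float(stats.f.sf(fstat, df_num, df_den))
                cand = (p, -fstat, self._unit_sort_key(u), u)
                if p < entry_alpha and (best is None or cand < best):
                    best = cand
            if best is not None:
                selected.append(best[3])
                changed = True
            # backward
            if len(selected) > 1 or (selected and best is None):
                Df = design(selected)
                ssef, rankf = sse_rank(Df)
                worst = None
                for u in selected:
                    rest = [v for v in selected if v != u]
                    Dr = design(rest)
                    sser, rankr = sse_rank(Dr)
                    df_num = rankf - rankr
                    df_den = self.n_obs - self.n_env - rankf
                    if df_num <= 0:
                        # unit adds no rank given the others: drop it
                        worst = (1.0, 0.0, self._unit_sort_key(u), u)
                        break
                    if ssef <= 1e-10 * max(float(yc @ yc), 1.0):
                        p = 0.0
                    else:
                        fstat = (sser - ssef) / df_num / (ssef / max(df_den, 1))
                        p = float(stats.f.sf(fstat, df_num, max(df_den, 1)))
                    if p > stay_alpha and (worst is None or p > worst[0]):
                        worst = (p, 0.0, self._unit_sort_key(u), u)
                if worst is not None:
                    selected.remove(worst[3])
                    changed = True
            if not changed:
                break

        return SelectedTerms(
            snps=[k for t, k in selected if t == "snp"],
            pairs=[k for t, k in selected if t == "pair"],
        )

    # ------------------------------------------------------------------
    # full model fit (Gibbs sampling)
    # ------------------------------------------------------------------
    def fit(
        self,
        selected: SelectedTerms | None = None,
        iterations: int = 20_000,
        burn_in: int | None = None,
        seed: int | None = None,
        keep_trace: bool = False,
    ) -> "AssociationResults":
        """Estimate the saturated mixed model on the selected terms.

        Fixed effects (mean, additive, epistatic) get diffuse normal priors;
        the environment main effect and QTS-by-environment interactions are
        random with scaled-inverse-chi-square variance priors.  Posterior
        means are the point estimates, posterior sds the standard errors.
        ``burn_in`` defaults to the first 25% of iterations.
        """
        from .mcmc import gibbs_fit

        if selected is None:
            selected = SelectedTerms(snps=list(self.snp_ids))
        if burn_in is None:
            burn_in = iterations // 4
        if not 0 <= burn_in < iterations:
            raise ValueError("burn_in must be in [0, iterations)")
        draws = gibbs_fit(self, selected, iterations, burn_in, seed, keep_trace)
        return AssociationResults(self, selected, draws, iterations, burn_in, seed)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

class AssociationResults:
    """Posterior summaries of the fitted QTS model.

    Attributes
    ----------
    params : pd.Series
        Posterior-mean estimates: ``mu``, ``a:<snp>`` and ``aa:<i>|<j>``.
    bse : pd.Series
        Posterior standard deviations (standard errors).
    pvalues, neglog10p : pd.Series
        Wald-type normal-approximation p-values on posterior mean/sd.
    varcomps : dict
        Posterior means of sigma2_e, sigma2_ae, sigma2_aae, sigma2_eps.
    h2, total_h2 : pd.Series, float
        Per-term heritability (%) and their sum.
    """

    def __init__(self, model, selected, draws, iterations, burn_in, seed):
        self.model = model
        self.selected = selected
        self.iterations = iterations
        self.burn_in = burn_in
        self.seed = seed
        self.params: pd.Series = draws["mean"]
        self.bse: pd.Series = draws["sd"]
        self.varcomps: dict[str, float] = draws["varcomps"]
        self.trace = draws.get("trace")
        z = np.abs(self.params / self.bse.replace(0.0, np.nan))
        logp = stats.norm.logsf(z) + np.log(2.0)
        self.pvalues = pd.Series(np.exp(logp), index=self.params.index)
        self.neglog10p = pd.Series(-logp / _LOG10, index=self.params.index)
        self._compute_h2()

    # -- genetic terms ---------------------------------------------------
    @property
    def mu(self) -> float:
        return float(self.params["mu"])

    @property
    def additive_effects(self) -> dict[str, float]:
        return {s: float(self.params[f"a:{s}"]) for s in self.selected.snps}

    @property
    def epistatic_effects(self) -> dict[tuple[str, str], float]:
        return {
            (i, j): float(self.params[f"aa:{i}|{j}"]) for i, j in self.selected.pairs
        }

    @property
    def effects(self) -> GeneticEffects:
        return GeneticEffects(self.mu, self.additive_effects, self.epistatic_effects)

    # -- heritability ----------------------------------------------------
    def _compute_h2(self) -> None:
        m = self.model
        self.v_p = m.pheno.phenotypic_variance(m.trait)
        rows = {}
        for s in self.selected.snps:
            x = m.X[:, m._snp_pos[s]]
            rows[f"a:{s}"] = 100.0 * self.params[f"a:{s}"] ** 2 * np.var(x, ddof=1) / self.v_p
        for i, j in self.selected.pairs:
            xij = m.X[:, m._snp_pos[i]] * m.X[:, m._snp_pos[j]]
            v = np.var(xij, ddof=1)
            rows[f"aa:{i}|{j}"] = 100.0 * self.params[f"aa:{i}|{j}"] ** 2 * v / self.v_p
        self.h2 = pd.Series(rows, dtype=float)
        self.total_h2 = float(self.h2.sum())

    # -- presentation ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        m = self.model
        rows = []
        for s in self.selected.snps:
            rec = m.geno.snps[m._snp_pos[s]]
            rows.append(
                {
                    "QTS": s,
                    "Chr": rec.chromosome,
                    "Allele": f"{rec.paternal_allele}/{rec.maternal_allele}",
                    "Effect type": "a",
                    "Effect": self.params[f"a:{s}"],
                    "SE": self.bse[f"a:{s}"],
                    "-log10(P)": self.neglog10p[f"a:{s}"],
                    "h2 (%)": self.h2[f"a:{s}"],
                }
            )
        for i, j in self.selected.pairs:
            rows.append(
                {
                    "QTS": f"{i} x {j}",
                    "Chr": "-",
                    "Allele": "-",
                    "Effect type": "aa",
                    "Effect": self.params[f"aa:{i}|{j}"],
                    "SE": self.bse[f"aa:{i}|{j}"],
                    "-log10(P)": self.neglog10p[f"aa:{i}|{j}"],
                    "h2 (%)": self.h2[f"aa:{i}|{j}"],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"QTS model for trait {self.model.trait!r} "
            f"({len(self.selected.snps)} loci, {len(self.selected.pairs)} pairs)",
            f"population mean mu = {self.mu:.4f}",
            f"total heritability = {self.total_h2:.2f}% (V_P = {self.v_p:.4f})",
            "variance components: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.varcomps.items()),
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}") if len(df) else "(no terms)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["total h2 (%)"] = self.total_h2
        df.to_csv(path, sep="\t", index=False)


def compute_heritability(results: AssociationResults) -> AssociationResults:
    """Recompute per-term heritabilities and the total on a results object.

    h2_i (%) = 100 a_i^2 var(x_i) / V_P, with V_P the sample variance of the
    line-by-environment mean phenotypes; epistatic terms use the variance of
    the product coefficient.  Totals are the sum of the individual values.
    """
    results._compute_h2()
    return results
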