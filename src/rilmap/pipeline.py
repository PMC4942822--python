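"""End-to-end orchestration: simulate/load -> QC -> LD -> subset -> screen
-> map -> predict.

`PipelineConfig` takes either input paths (genotypes + phenotypes, plus
BED for the QTL-region strategy or GFF3 for the gene-based strategy) or a
simulation spec; `run_pipeline` executes the stages in order, persists
stage outputs when an output directory is given, and returns the
artifacts.  All randomness (simulation, permutations, MCMC, annealing)
derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Any

import numpy as np

from . import __version__
from .association import AssociationModel, PermutationConfig, SelectedTerms
from .genmap import build_genetic_map
from .genotypes import GenotypeMatrix, read_genotypes, write_coded_tsv
from .ld import half_decay_distance, ld_decay_curve, pairwise_r2
from .phenotypes import PhenotypeTable
from .predict import build_report
from .qc import apply_qc
from .screen import marginal_screen, merge_candidates, pairwise_screen
from .simulate import SimulationConfig, TrueModel, simulate_phenotypes, simulate_ril_genotypes
from .subsets import read_bed, read_gff3_genes, subset_by_gene_models, subset_by_intervals

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STRATEGIES = ("GWA", "QBA", "GBA")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception | str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    # input data (exactly one of genotype_path / simulation must be set)
    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    bed_path: str | None = None
    gff3_path: str | None = None
    simulation: dict[str, Any] | None = None  # map/population/model keywords
    trait: str = "trait"
    strategy: str = "GWA"
    # QC
    max_missing_rate: float = 0.05
    segregation_alpha: float = 0.01
    min_maf: float | None = None
    # LD
    ld_max_dist_bp: int = 1_000_000
    ld_bin_width_bp: int = 1_000
    compute_ld: bool = True
    # screening
    screen_top_m: int | None = 1000
    screen_pairs: bool = False
    pair_top_m: int = 200
    # mapping
    n_permutations: int = 1000
    alpha: float = 0.05
    # stepwise alphas; None derives them from the permutation threshold so
    # a unit must clear the same experiment-wise F level to stay in the model
    entry_alpha: float | None = None
    stay_alpha: float | None = None
    detect_epistasis: bool = False
    mcmc_iterations: int = 20_000
    mcmc_burn_in: int | None = None
    # misc
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.genotype_path is None) == (self.simulation is None):
            raise ValueError("set exactly one of genotype_path / simulation")
        if self.genotype_path is not None and self.phenotype_path is None:
            raise ValueError("phenotype_path required with genotype_path")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.strategy == "QBA" and self.bed_path is None:
            raise ValueError("QBA strategy requires bed_path")
        if self.strategy == "GBA" and self.gff3_path is None:
            raise ValueError("GBA strategy requires gff3_path")


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def _simulate_inputs(spec: dict[str, Any], seeds) -> tuple[GenotypeMatrix, PhenotypeTable, TrueModel]:
    gmap = build_genetic_map(
        n_chrom=spec.get("n_chrom", 12),
        markers_per_chrom=spec.get("markers_per_chrom", 100),
        spacing_cM=spec.get("spacing_cM", 1.0),
        bp_per_cM=spec.get("bp_per_cM", 250_000),
    )
    config = SimulationConfig(
        n_lines=spec.get("n_lines", 138),
        n_selfing_generations=spec.get("n_selfing_generations", 12),
        seed=seeds[0],
        het_policy=spec.get("het_policy", "force-homozygous"),
        missing_rate=spec.get("missing_rate", 0.0),
    )
    geno = simulate_ril_genotypes(gmap, config)
    model_kwargs = dict(spec.get("true_model", {}))
    model_kwargs.setdefault("population_mean", 100.0)
    model = TrueModel(trait=spec.get("trait", "trait"), **model_kwargs)
    pheno = simulate_phenotypes(geno, model, seed=seeds[1])
    return geno, pheno, model


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the configured analysis; returns a dict of stage artifacts.

    Keys: ``geno``, ``pheno``, ``qc_report``, ``ld_curve``,
    ``ld_half_decay_bp``, ``candidates``, ``scan1d``, ``threshold_1d``,
    ``selected``, ``results``, ``prediction``, ``manifest`` (some are None
    when a stage is skipped or finds nothing).
    """
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("config", exc) from exc
    seeds = _child_seeds(config.seed, 6)
    out: dict[str, Any] = {"true_model": None}
    outdir = pathlib.Path(config.out_dir) if config.out_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs ---------------------------------------------------------
    try:
        if config.simulation is not None:
            geno, pheno, true_model = _simulate_inputs(config.simulation, seeds)
            out["true_model"] = true_model
            trait = true_model.trait
        else:
            geno = read_genotypes(config.genotype_path, format=config.genotype_format)
            pheno = PhenotypeTable.from_csv(config.phenotype_path)
            trait = config.trait
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    # --- QC -------------------------------------------------------------
    try:
        geno, qc_report = apply_qc(
            geno, config.max_missing_rate, config.segregation_alpha, config.min_maf
        )
    except Exception as exc:
        raise PipelineError("qc", exc) from exc
    out["qc_report"] = qc_report
    if outdir:
        qc_report.to_json(outdir / "qc_report.json")

    # --- LD -------------------------------------------------------------
    out["ld_curve"] = None
    out["ld_half_decay_bp"] = None
    if config.compute_ld:
        try:
            pairs = pairwise_r2(geno, max_dist_bp=config.ld_max_dist_bp)
            if len(pairs):
                curve = ld_decay_curve(pairs, bin_width_bp=config.ld_bin_width_bp)
                out["ld_curve"] = curve
                out["ld_half_decay_bp"] = half_decay_distance(curve)
                if outdir:
                    curve.to_tsv(outdir / "ld_decay.tsv")
        except Exception as exc:
            raise PipelineError("ld", exc) from exc

    # --- strategy subset -------------------------------------------------
    try:
        if config.strategy == "QBA":
            geno_s = subset_by_intervals(geno, read_bed(config.bed_path))
        elif config.strategy == "GBA":
            geno_s = subset_by_gene_models(geno, read_gff3_genes(config.gff3_path))
        else:
            geno_s = geno
        if geno_s.n_snps == 0:
            raise ValueError("strategy subset contains no SNPs")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("subset", exc) from exc
    out["geno"] = geno_s
    out["pheno"] = pheno
    if outdir:
        write_coded_tsv(geno_s, outdir / "genotypes_analysis.tsv")

    # --- screening -------------------------------------------------------
    candidates = None
    if config.screen_top_m is not None:
        try:
            per_env = [
                marginal_screen(geno_s, pheno, trait, env, top_m=config.screen_top_m)
                for env in pheno.environments
            ]
            candidates = merge_candidates(per_env)
            if config.screen_pairs:
                pair_sets = [
                    pairwise_screen(geno_s, pheno, trait, env, top_m=config.pair_top_m)
                    for env in pheno.environments
                ]
                candidates = merge_candidates([candidates] + pair_sets)
        except Exception as exc:
            raise PipelineError("screen", exc) from exc
    out["candidates"] = candidates
    snp_set = candidates.snps if candidates is not None else None

    # --- mapping ---------------------------------------------------------
    try:
        model = AssociationModel(geno_s, pheno, trait)
        scan1d = model.scan_additive(snp_set)
        perm = PermutationConfig(
            n_permutations=config.n_permutations, alpha=config.alpha, seed=seeds[2]
        )
        scan1d.threshold = model.permutation_threshold(perm, "1D", snp_ids=snp_set)
        sig_snps = scan1d.significant_units
        out["scan1d"] = scan1d
        out["threshold_1d"] = scan1d.threshold
        sig_pairs: list[tuple[str, str]] = []
        out["scan2d"] = None
        if config.detect_epistasis:
            universe = candidates.pairs if candidates is not None and candidates.pairs else None
            if universe is None:
                base = sig_snps if sig_snps else (snp_set or model.snp_ids)[:50]
                import itertools as _it

                universe = list(_it.combinations(base, 2))
            if universe:
                scan2d = model.scan_epistasis(sig_snps, universe)
                perm2 = PermutationConfig(
                    n_permutations=config.n_permutations, alpha=config.alpha, seed=seeds[3]
                )
                scan2d.threshold = model.permutation_threshold(
                    perm2, "2D", covariate_snps=sig_snps, pair_universe=universe
                )
                sig_pairs = scan2d.significant_units
                out["scan2d"] = scan2d
        results = None
        selected = SelectedTerms()
        if sig_snps or sig_pairs:
            from scipy import stats as _stats

            thr_alpha = float(
                _stats.f.sf(scan1d.threshold, 1, model.n_obs - model.n_env - 1)
            )
            entry = config.entry_alpha if config.entry_alpha is not None else thr_alpha
            stay = config.stay_alpha if config.stay_alpha is not None else thr_alpha
            selected = model.stepwise_select(
                sig_snps, sig_pairs, entry_alpha=entry, stay_alpha=stay
            )
            if selected:
                results = model.fit(
                    selected,
                    iterations=config.mcmc_iterations,
                    burn_in=config.mcmc_burn_in,
                    seed=seeds[4],
                )
        out["selected"] = selected
        out["results"] = results
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("map", exc) from exc
    if outdir and out.get("scan1d") is not None:
        out["scan1d"].to_frame().to_csv(outdir / "scan1d.tsv", sep="\t", index=False)
    if outdir and results is not None:
        results.to_tsv(outdir / "qts_model.tsv")

    # --- prediction -------------------------------------------------------
    out["prediction"] = None
    if results is not None:
        try:
            report = build_report(results, geno_s, seed=seeds[5])
            out["prediction"] = report
            if outdir:
                report.to_tsv(outdir / "genetic_values.tsv")
        except Exception as exc:
            raise PipelineError("predict", exc) from exc

    # --- manifest ---------------------------------------------------------
    manifest = {
        "rilmap_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "strategy": config.strategy,
        "trait": trait,
        "n_snps_input": qc_report.n_input,
        "n_snps_after_qc": qc_report.n_retained,
        "n_snps_strategy": geno_s.n_snps,
        "n_candidates": len(candidates.snps) if candidates is not None else None,
        "threshold_1d": out.get("threshold_1d"),
        "n_declared_1d": len(out["scan1d"].significant_units) if out.get("scan1d") else 0,
        "n_selected_snps": len(out["selected"].snps),
        "n_selected_pairs": len(out["selected"].pairs),
        "total_h2_pct": results.total_h2 if results is not None else None,
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "mcmc_iterations": config.mcmc_iterations,
    }
    out["manifest"] = manifest
    if outdir:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out
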