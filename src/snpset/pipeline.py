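"""End-to-end orchestration: (simulate|load) -> QC -> residualize -> screen
-> stepwise fit -> permutation -> bootstrap -> report.

A single root seed derives independent sub-seeds for simulation, the
permutation and bootstrap streams, and the Lilliefors Monte Carlo table;
every threshold and sub-seed is echoed into the JSON summary so a report is
fully reproducible from its own provenance block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import io as study_io
from .anova import AnovaResult, screen_loci
from .model import StepwiseModel
from .phenotype import ResidualPhenotype, covariate_screen, residualize_volume
from .qc import QCConfig, QCReport, run_qc
from .report import write_report
from .resample import (
    BootstrapResult,
    PermutationResult,
    ProcedureEngine,
    bootstrap_ci,
    permutation_test,
)
from .simulate import SimulationTruth, simulate_study
from .types import GenotypeMatrix, PhenotypeTable

log = logging.getLogger("snpset")


@dataclass
class PipelineConfig:
    """Everything a full run needs; maps 1:1 onto the YAML/JSON config."""

    genotypes: str | None = None
    genotype_format: str = "tsv"
    phenotypes: str | None = None
    simulate: dict | None = None
    out_dir: str = "snpset_out"
    qc: dict = field(default_factory=dict)
    screen_alpha: float = 0.05
    entry_alpha: float = 0.05
    removal_alpha: float = 0.10
    allow_removal: bool = True
    posthoc_method: str = "lsd"
    include_bai_bdi: bool = False
    n_perm: int = 1000
    n_boot: int = 1000
    tie_convention: str = "strict"
    bootstrap_fixed_model: bool = False
    seed: int = 0
    histogram: bool = False
    relatedness: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        errors = validate_config(d)
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
        return cls(**d)


def validate_config(d: dict) -> list[str]:
    """Range- and key-check a parsed config document; returns error strings."""
    errors: list[str] = []
    known = {f.name for f in dc_fields(PipelineConfig)}
    for k in d:
        if k not in known:
            errors.append(f"unknown config key {k!r}")
    for k, lo, hi in [
        ("screen_alpha", 0.0, 1.0),
        ("entry_alpha", 0.0, 1.0),
        ("removal_alpha", 0.0, 1.0),
    ]:
        if k in d and not (lo <= d[k] <= hi):
            errors.append(f"{k}={d[k]} outside [{lo}, {hi}]")
    for k in ("n_perm", "n_boot", "seed"):
        if k in d and (not isinstance(d[k], int) or d[k] < 0):
            errors.append(f"{k} must be a non-negative integer")
    if d.get("tie_convention", "strict") not in {"strict", "addone"}:
        errors.append("tie_convention must be 'strict' or 'addone'")
    if d.get("genotype_format", "tsv") not in study_io.GENOTYPE_FORMATS:
        errors.append(f"genotype_format must be one of {study_io.GENOTYPE_FORMATS}")
    if d.get("posthoc_method", "lsd") not in {"lsd", "tukey"}:
        errors.append("posthoc_method must be 'lsd' or 'tukey'")
    if d.get("simulate") is None:
        if not d.get("genotypes"):
            errors.append("missing 'genotypes' path (or a 'simulate' block)")
        if not d.get("phenotypes"):
            errors.append("missing 'phenotypes' path (or a 'simulate' block)")
    if "qc" in d:
        try:
            QCConfig(**d["qc"])
        except (TypeError, ValueError) as exc:
            errors.append(f"qc block: {exc}")
    if "simulate" in d and d["simulate"] is not None:
        try:
            SimulationTruth.from_dict(d["simulate"])
        except (TypeError, ValueError, KeyError) as exc:
            errors.append(f"simulate block: {exc}")
    return errors


@dataclass
class PipelineResult:
    """Bundle of every stage's output plus the paths written."""

    gm: GenotypeMatrix
    pheno: PhenotypeTable
    qc_report: QCReport
    residual: ResidualPhenotype
    covariate_tests: dict
    anova_results: list[AnovaResult]
    passing: list[str]
    model: StepwiseModel
    permutation: PermutationResult | None
    bootstrap: BootstrapResult | None
    paths: dict[str, Path]
    sub_seeds: dict[str, int]


def _derive_seeds(root: int) -> dict[str, int]:
    children = np.random.SeedSequence(root).spawn(4)
    names = ("simulation", "permutation", "bootstrap", "lilliefors")
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(names, children)
    }


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline per the config and write all artifacts."""
    seeds = _derive_seeds(config.seed)
    log.info("derived sub-seeds: %s", seeds)

    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", seeds["simulation"])
        truth = SimulationTruth.from_dict(sim)
        gm, pheno, truth = simulate_study(truth)
        log.info("simulated study: %d subjects x %d loci", gm.n_subjects, gm.n_loci)
    else:
        gm = study_io.read_genotypes(config.genotypes, config.genotype_format)
        pheno = study_io.read_phenotypes(config.phenotypes)
        gm = gm.with_sex_from(pheno)
        study_io.normalize_x_hemizygotes(gm)
        log.info("loaded %d subjects x %d loci", gm.n_subjects, gm.n_loci)

    unmatched = study_io.flag_unmatched_subjects(gm, pheno)
    for side, ids in unmatched.items():
        if ids:
            log.warning("%d subjects %s: %s ...", len(ids), side, ids[:5])

    qc_cfg = QCConfig(**config.qc)
    clean, groupings, qc_report = run_qc(gm, qc_cfg, relatedness=config.relatedness)
    log.info(
        "QC: %d/%d subjects, %d/%d loci retained",
        qc_report.retained_subjects,
        qc_report.input_subjects,
        qc_report.retained_loci,
        qc_report.input_loci,
    )

    # analysis set: genotyped subjects that also have a phenotype row
    have_pheno = set(pheno.subject_ids)
    keep = [i for i, s in enumerate(clean.subject_ids) if s in have_pheno]
    if len(keep) < clean.n_subjects:
        log.info("restricting to %d subjects with phenotypes", len(keep))
        clean = clean.take_subjects(keep)
        from .qc import make_grouping, minor_allele_index

        minor = minor_allele_index(clean)
        groupings = [make_grouping(clean, j, qc_cfg, minor) for j in range(clean.n_loci)]
        groupings = [g for g in groupings if not g.excluded]
        clean = clean.take_loci(
            [clean.locus_index(g.locus_id) for g in groupings]
        )
    pheno_aligned = pheno.aligned_to(clean.subject_ids)

    tests = covariate_screen(pheno_aligned)
    residual = residualize_volume(
        pheno_aligned,
        include_bai_bdi=config.include_bai_bdi,
        ks_seed=seeds["lilliefors"],
    )
    log.info(
        "residualized: skew=%.3f kurt=%.3f KS=%.3f (p=%.3f)",
        residual.skewness,
        residual.kurtosis_excess,
        residual.ks_stat,
        residual.ks_p,
    )

    passing, anova_results = screen_loci(
        clean,
        groupings,
        residual.residuals,
        alpha=config.screen_alpha,
        posthoc_method=config.posthoc_method,
    )
    log.info("ANOVA screen: %d of %d loci pass p<%g",
             len(passing), len(anova_results), config.screen_alpha)

    engine = ProcedureEngine(
        clean,
        groupings,
        screen_alpha=config.screen_alpha,
        entry_alpha=config.entry_alpha,
        removal_alpha=config.removal_alpha,
        allow_removal=config.allow_removal,
    )
    model = engine.run(residual.residuals)
    log.info(
        "stepwise: %d selected, R^2=%.4f (adj %.4f)",
        len(model.selected),
        model.r_squared,
        model.adj_r_squared,
    )

    permutation = None
    if config.n_perm > 0:
        permutation = permutation_test(
            clean,
            groupings,
            residual.residuals,
            n_perm=config.n_perm,
            seed=seeds["permutation"],
            tie_convention=config.tie_convention,
            engine=engine,
        )
        log.info("permutation p (strict/add-one): %.4f / %.4f",
                 permutation.p_r2_strict, permutation.p_r2_addone)
    bootstrap = None
    if config.n_boot > 0:
        bootstrap = bootstrap_ci(
            clean,
            groupings,
            residual.residuals,
            n_boot=config.n_boot,
            seed=seeds["bootstrap"],
            fixed_model=config.bootstrap_fixed_model,
            engine=engine,
        )
        log.info("bootstrap %g%% CI for R^2: [%.3f, %.3f]",
                 100 * bootstrap.level, *bootstrap.r2_ci)

    extra = {
        "config": {f.name: getattr(config, f.name) for f in dc_fields(config)},
        "sub_seeds": seeds,
        "covariate_screen": {
            k: {"F": t.f, "df1": t.df1, "df2": t.df2, "p": t.p, "n": t.n,
                "untestable": t.untestable}
            for k, t in tests.items()
        },
        "residual_diagnostics": {
            "skewness": residual.skewness,
            "kurtosis_excess": residual.kurtosis_excess,
            "kurtosis_convention": residual.kurtosis_convention,
            "ks_stat": residual.ks_stat,
            "ks_p": residual.ks_p,
        },
        "unmatched_subjects": unmatched,
    }
    paths = write_report(
        config.out_dir,
        anova_results,
        passing,
        model,
        permutation,
        bootstrap,
        qc_report,
        extra=extra,
        histogram=config.histogram,
    )
    return PipelineResult(
        gm=clean,
        pheno=pheno_aligned,
        qc_report=qc_report,
        residual=residual,
        covariate_tests=tests,
        anova_results=anova_results,
        passing=passing,
        model=model,
        permutation=permutation,
        bootstrap=bootstrap,
        paths=paths,
        sub_seeds=seeds,
    )
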