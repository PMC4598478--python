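"""Shared fixtures: small hand-built genotype matrices and simulated studies."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from snpset import (
    GenotypeMatrix,
    LocusRecord,
    default_truth,
    residualize_volume,
    run_qc,
    simulate_study,
)


def gm_from_dosages(
    dosages: np.ndarray,
    chromosomes: list[str] | None = None,
    sex: list[str] | None = None,
    positions: list[int] | None = None,
    quality: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Build a diploid matrix from minor-allele dosage columns (0/1/2,
    -1 = missing).  Allele index 1 is the dosed allele; with labels
    ("A", "G") a 50% frequency resolves "G" (index 1) as minor."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    chromosomes = chromosomes or ["1"] * m
    loci = [
        LocusRecord(
            locus_id=f"L{j:03d}",
            chromosome=chromosomes[j],
            position=(positions[j] if positions else 1000 + j),
            allele_labels=("A", "G"),
        )
        for j in range(m)
    ]
    a1 = np.where(dosages >= 1, 1, 0).astype(np.int8)
    a2 = np.where(dosages == 2, 1, 0).astype(np.int8)
    a1[dosages < 0] = -1
    a2[dosages < 0] = -1
    return GenotypeMatrix(
        subject_ids=[f"S{i:03d}" for i in range(n)],
        sex=np.asarray(sex if sex is not None else ["F"] * n),
        loci=loci,
        a1=a1,
        a2=a2,
        quality=quality,
    )


def dosage_column(n_major: int, n_het: int, n_minor: int) -> np.ndarray:
    return np.array([0] * n_major + [1] * n_het + [2] * n_minor)


@pytest.fixture(scope="session")
def planted_study():
    """One study-shaped simulation (417 x 99, planted R^2 = 0.08) carried
    through QC and residualization."""
    truth = default_truth(target_planted_r2=0.08, seed=7)
    gm, pheno, calibrated = simulate_study(truth)
    clean, groupings, report = run_qc(gm)
    pheno_aligned = pheno.aligned_to(clean.subject_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        residual = residualize_volume(pheno_aligned, ks_monte_carlo=2000)
    return {
        "truth": calibrated,
        "gm": gm,
        "pheno": pheno_aligned,
        "clean": clean,
        "groupings": groupings,
        "report": report,
        "residual": residual,
    }


@pytest.fixture(scope="session")
def null_study():
    """Same shape, no planted effects."""
    truth = default_truth(target_planted_r2=0.0, seed=19)
    gm, pheno, _ = simulate_study(truth)
    clean, groupings, report = run_qc(gm)
    pheno_aligned = pheno.aligned_to(clean.subject_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        residual = residualize_volume(pheno_aligned, ks_monte_carlo=2000)
    return {
        "gm": gm,
        "clean": clean,
        "groupings": groupings,
        "report": report,
        "residual": residual,
    }
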