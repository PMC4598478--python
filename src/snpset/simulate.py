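"""Synthetic study generator: genotypes with LD-block structure, covariates,
and a phenotype with planted additive effects.

The LD model is a haplotype-pool mixture: within a block, a haplotype is
comonotone across loci (all minor-allele indicators driven by one shared
uniform) with probability m, and independent otherwise.  Random pairing of
haplotypes then guarantees Hardy-Weinberg equilibrium by construction, and
the mixing weight m is solved from the requested within-block dosage r^2
(capped at the best achievable value when the block's allele frequencies
make the target unreachable).  Males carry a single X haplotype.

The phenotype is built as

    volume = baseline + sex_effect * I(male) + icv_slope * (ICV - mean ICV)
             + sum_j beta_j * (code_j - mean code_j) + noise,

with ICV drawn log-normal with sex-specific means and the planted betas
rescaled so their share of the covariate-free variance hits
``target_planted_r2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import code_genotypes
from .qc import minor_allele_index
from .types import HEMI, MISSING, GenotypeMatrix, LocusRecord, PhenotypeTable

_SNP_ALLELES = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class LocusPlan:
    """One planned marker: where it sits, its population minor-allele
    frequency, and which LD block it belongs to."""

    locus_id: str
    chromosome: str
    position: int
    maf: float
    block: int
    marker_kind: str = "SNP"
    allele_labels: tuple[str, str] | None = None

    def record(self) -> LocusRecord:
        labels = self.allele_labels
        if labels is None:
            labels = _SNP_ALLELES[self.position % len(_SNP_ALLELES)]
        return LocusRecord(
            locus_id=self.locus_id,
            chromosome=self.chromosome,
            position=self.position,
            marker_kind=self.marker_kind,
            allele_labels=labels,
        )


@dataclass
class SimulationTruth:
    """Complete description of a synthetic study; the seed fully determines
    the generated genotypes and phenotype."""

    n_subjects: int = 417
    n_male: int = 179
    loci_plan: list[LocusPlan] = field(default_factory=list)
    within_block_r2: float = 0.45
    block_r2: dict[int, float] = field(default_factory=dict)
    planted_effects: list[tuple[str, float]] = field(default_factory=list)
    target_planted_r2: float = 0.0
    sex_effect: float = 60.0  # mm^3, male minus female
    icv_slope: float = 7e-4  # mm^3 volume per mm^3 ICV
    baseline_volume: float = 1700.0  # mm^3
    noise_sd: float = 150.0  # mm^3
    missing_rate: float = 0.002
    low_quality_rate: float = 0.002
    related_pairs: list[str] = field(default_factory=list)  # "duplicate" | "parent_child"
    hwe_violator: str | None = None
    hwe_excess: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_male <= self.n_subjects:
            raise ValueError("n_male must be in [0, n_subjects]")
        ids = {p.locus_id for p in self.loci_plan}
        if len(ids) != len(self.loci_plan):
            raise ValueError("duplicate locus ids in plan")
        for p in self.loci_plan:
            if not 0.0 < p.maf <= 0.5:
                raise ValueError(f"{p.locus_id}: MAF {p.maf} outside (0, 0.5]")
        for lid, _ in self.planted_effects:
            if lid not in ids:
                raise ValueError(f"planted effect on unknown locus {lid}")
        if not 0.0 <= self.target_planted_r2 < 1.0:
            raise ValueError("target_planted_r2 must be in [0, 1)")
        for name in ("missing_rate", "low_quality_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must be in [0, 1]")
        for kind in self.related_pairs:
            if kind not in {"duplicate", "parent_child"}:
                raise ValueError(f"unknown relationship {kind!r}")
        if self.hwe_violator is not None and self.hwe_violator not in ids:
            raise ValueError(f"hwe_violator {self.hwe_violator} not in plan")

    @property
    def n_blocks(self) -> int:
        return len({p.block for p in self.loci_plan})

    # -- config (de)serialization --------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_male": self.n_male,
            "loci_plan": [
                {
                    "locus_id": p.locus_id,
                    "chromosome": p.chromosome,
                    "position": p.position,
                    "maf": p.maf,
                    "block": p.block,
                    "marker_kind": p.marker_kind,
                    "allele_labels": list(p.allele_labels) if p.allele_labels else None,
                }
                for p in self.loci_plan
            ],
            "within_block_r2": self.within_block_r2,
            "block_r2": {str(k): v for k, v in self.block_r2.items()},
            "planted_effects": [[l, b] for l, b in self.planted_effects],
            "target_planted_r2": self.target_planted_r2,
            "sex_effect": self.sex_effect,
            "icv_slope": self.icv_slope,
            "baseline_volume": self.baseline_volume,
            "noise_sd": self.noise_sd,
            "missing_rate": self.missing_rate,
            "low_quality_rate": self.low_quality_rate,
            "related_pairs": list(self.related_pairs),
            "hwe_violator": self.hwe_violator,
            "hwe_excess": self.hwe_excess,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        d["loci_plan"] = [
            LocusPlan(
                locus_id=p["locus_id"],
                chromosome=str(p["chromosome"]),
                position=int(p["position"]),
                maf=float(p["maf"]),
                block=int(p["block"]),
                marker_kind=p.get("marker_kind", "SNP"),
                allele_labels=tuple(p["allele_labels"]) if p.get("allele_labels") else None,
            )
            for p in d.get("loci_plan", [])
        ]
        d["block_r2"] = {int(k): float(v) for k, v in d.get("block_r2", {}).items()}
        d["planted_effects"] = [tuple(x) for x in d.get("planted_effects", [])]
        return cls(**d)


def default_loci_plan(
    n_loci: int = 99,
    block_size: int = 3,
    n_tight_blocks: int = 0,
    n_x_loci: int = 6,
    include_vntr: bool = True,
) -> list[LocusPlan]:
    """A deterministic plan mirroring the study's panel shape: LD blocks of
    a few loci spread over autosomes plus a handful of X markers (optionally
    one MAOA-style VNTR).  ``n_tight_blocks`` leading blocks get equal MAFs
    so a near-1 within-block r^2 is achievable (high-LD pairs for pruning)."""
    plan: list[LocusPlan] = []
    n_auto = n_loci - n_x_loci
    for i in range(n_auto):
        block = i // block_size
        # equal MAFs within a block so the within-block r2 target is
        # attainable by the comonotone haplotype coupling
        maf = 0.10 + 0.40 * ((7 * block) % 17) / 17.0
        if block < n_tight_blocks:
            maf = 0.15 + 0.05 * block
        chrom = str(2 + (block % 11))
        plan.append(
            LocusPlan(
                locus_id=f"rs{10000 + i}",
                chromosome=chrom,
                position=1_000_000 + 50_000 * i,
                maf=round(maf, 4),
                block=block,
            )
        )
    x_block = n_auto // block_size + 1
    for i in range(n_x_loci):
        kind = "VNTR" if include_vntr and i == n_x_loci - 1 else "SNP"
        plan.append(
            LocusPlan(
                locus_id="maoa_vntr" if kind == "VNTR" else f"rsX{100 + i}",
                chromosome="X",
                position=43_000_000 + 60_000 * i,
                maf=0.20 + 0.04 * i,
                block=x_block + i // block_size,
                marker_kind=kind,
                allele_labels=("3R", "4R") if kind == "VNTR" else None,
            )
        )
    return plan


def default_truth(
    target_planted_r2: float = 0.08,
    n_planted: int = 5,
    seed: int = 0,
    n_loci: int = 99,
    n_tight_blocks: int = 6,
    **kwargs,
) -> SimulationTruth:
    """Study-shaped defaults: 417 subjects (179 male), 99 loci in LD blocks
    with a few high-LD pairs, and ``n_planted`` loci in distinct blocks
    carrying equal planted weights summing to ``target_planted_r2`` of the
    covariate-free variance."""
    plan = default_loci_plan(n_loci=n_loci, n_tight_blocks=n_tight_blocks)
    planted: list[tuple[str, float]] = []
    if target_planted_r2 > 0 and n_planted > 0:
        blocks_seen: set[int] = set()
        for p in plan:
            # skip tight blocks so planted loci are not pruned away
            if p.block < n_tight_blocks or p.chromosome == "X":
                continue
            if p.block in blocks_seen:
                continue
            blocks_seen.add(p.block)
            planted.append((p.locus_id, 1.0))
            if len(planted) == n_planted:
                break
    return SimulationTruth(
        loci_plan=plan,
        planted_effects=planted,
        target_planted_r2=target_planted_r2,
        # tight blocks sit in near-perfect LD so the pruning stage has the
        # high-LD pairs the panel design implies
        block_r2={b: 0.97 for b in range(n_tight_blocks)},
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# haplotype machinery
# ---------------------------------------------------------------------------

def _comonotone_r(p: float, q: float) -> float:
    """Maximum correlation of two Bernoulli indicators with success
    probabilities p and q under comonotone coupling."""
    num = min(p, q) - p * q
    den = np.sqrt(p * (1 - p) * q * (1 - q))
    return num / den if den > 0 else 0.0


def _block_mixing_weight(mafs: Sequence[float], target_r2: float, block: int) -> float:
    if len(mafs) < 2 or target_r2 == 0.0:
        return 0.0
    r_max = min(
        _comonotone_r(mafs[i], mafs[j])
        for i in range(len(mafs))
        for j in range(i + 1, len(mafs))
    )
    if r_max <= 0:
        return 0.0
    m = np.sqrt(target_r2) / r_max
    if m > 1.0:
        warnings.warn(
            f"block {block}: within-block r2 target {target_r2:.3f} unreachable "
            f"for its allele frequencies (best achievable {r_max**2:.3f}); "
            "using the best-achievable coupling",
            stacklevel=3,
        )
        return 1.0
    return float(m)


def _sample_block_haplotypes(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, m: float
) -> np.ndarray:
    """(n_hap, len(mafs)) minor-allele indicators for one block."""
    shared = rng.random(n_hap)
    fresh = rng.random((n_hap, len(mafs)))
    coupled = rng.random(n_hap) < m
    u = np.where(coupled[:, None], shared[:, None], fresh)
    return (u < mafs[None, :]).astype(np.int8)


def _simulate_complete(truth: SimulationTruth) -> GenotypeMatrix:
    """Generate the complete (no-missing) genotype matrix, including injected
    related subjects appended after the base sample."""
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    n = truth.n_subjects
    sex = np.asarray(["M"] * truth.n_male + ["F"] * (n - truth.n_male))
    loci = [p.record() for p in truth.loci_plan]

    blocks: dict[int, list[int]] = {}
    for j, p in enumerate(truth.loci_plan):
        blocks.setdefault(p.block, []).append(j)

    m_loci = len(loci)
    # haplotype storage: hap[s, j, 0/1]; males carry only hap 0 on X
    hap = np.zeros((n, m_loci, 2), dtype=np.int8)
    for block_id, idx in sorted(blocks.items()):
        mafs = np.asarray([truth.loci_plan[j].maf for j in idx])
        target = truth.block_r2.get(block_id, truth.within_block_r2)
        m = _block_mixing_weight(list(mafs), target, block_id)
        h = _sample_block_haplotypes(rng, 2 * n, mafs, m)
        hap[:, idx, 0] = h[:n]
        hap[:, idx, 1] = h[n:]

    male = sex == "M"
    x_mask = np.asarray([l.is_x for l in loci])
    a1 = hap[:, :, 0].copy()
    a2 = hap[:, :, 1].astype(np.int8)
    a2 = np.where(male[:, None] & x_mask[None, :], HEMI, a2).astype(np.int8)

    if truth.hwe_violator is not None:
        j = next(i for i, l in enumerate(loci) if l.locus_id == truth.hwe_violator)
        diploid = a2[:, j] >= 0
        force = diploid & (rng.random(n) < truth.hwe_excess)
        a2[force, j] = a1[force, j]
        hap[force, j, 1] = hap[force, j, 0]

    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    sexes = list(sex)
    rows_a1, rows_a2 = [a1], [a2]
    for k, kind in enumerate(truth.related_pairs):
        template = k % n
        if kind == "duplicate":
            new_a1 = a1[template].copy()
            new_a2 = a2[template].copy()
            new_sex = sexes[template]
        else:  # parent_child: one haplotype from the parent, one fresh
            child = np.zeros((m_loci, 2), dtype=np.int8)
            for block_id, idx in sorted(blocks.items()):
                mafs = np.asarray([truth.loci_plan[j].maf for j in idx])
                target = truth.block_r2.get(block_id, truth.within_block_r2)
                m = _block_mixing_weight(list(mafs), target, block_id)
                which = 0 if (sexes[template] == "M" or rng.random() < 0.5) else 1
                child[idx, 0] = hap[template, idx, which]
                child[idx, 1] = _sample_block_haplotypes(rng, 1, mafs, m)[0]
            new_a1, new_a2 = child[:, 0], child[:, 1]
            new_sex = "F"  # a daughter always receives a parental X cleanly
        subject_ids.append(f"R{k + 1:03d}")
        sexes.append(new_sex)
        rows_a1.append(new_a1[None, :])
        rows_a2.append(new_a2[None, :])

    return GenotypeMatrix(
        subject_ids=subject_ids,
        sex=np.asarray(sexes),
        loci=loci,
        a1=np.vstack(rows_a1),
        a2=np.vstack(rows_a2),
    )


def _apply_missingness(gm: GenotypeMatrix, truth: SimulationTruth) -> GenotypeMatrix:
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 1)))
    out = gm.copy()
    shape = out.a1.shape
    miss = rng.random(shape) < truth.missing_rate
    out.a1[miss] = MISSING
    out.a2[miss] = MISSING
    quality = np.where(
        rng.random(shape) < truth.low_quality_rate,
        rng.uniform(0.0, 0.2499, shape),
        rng.uniform(0.7, 1.0, shape),
    )
    out.quality = quality
    return out


def simulate_genotypes(truth: SimulationTruth) -> GenotypeMatrix:
    """Generate the study's genotype matrix (with missing calls and per-call
    quality scores applied)."""
    return _apply_missingness(_simulate_complete(truth), truth)


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def _planted_term(gm: GenotypeMatrix, truth: SimulationTruth) -> np.ndarray:
    """Centered planted linear predictor sum_j beta_j code_j (mean-imputed
    missing codes), or zeros when nothing is planted."""
    if not truth.planted_effects:
        return np.zeros(gm.n_subjects)
    ids = [l.locus_id for l in gm.loci]
    for lid, _ in truth.planted_effects:
        if lid not in ids:
            raise ValueError(f"planted locus {lid} missing from genotype matrix")
    coded = code_genotypes(gm, minor_allele_index(gm))
    term = np.zeros(gm.n_subjects)
    for lid, beta in truth.planted_effects:
        c = coded.codes[:, ids.index(lid)]
        mu = np.nanmean(c)
        term += beta * (np.where(np.isnan(c), mu, c) - mu)
    return term


def calibrate_effect_sizes(
    truth: SimulationTruth, gm: GenotypeMatrix
) -> SimulationTruth:
    """Rescale planted betas by a common factor so the planted share of the
    covariate-free variance equals ``target_planted_r2``:

        Var(sum beta_j code_j) / (Var(...) + noise_sd^2) = target.

    Coding variances are empirical, from the supplied genotype matrix.
    """
    if truth.target_planted_r2 == 0.0 or not truth.planted_effects:
        return replace(
            truth, planted_effects=[(l, 0.0) for l, _ in truth.planted_effects]
        )
    term = _planted_term(gm, truth)
    v = float(term.var())
    if v == 0.0:
        raise ValueError("all planted loci are monomorphic; cannot calibrate")
    t = truth.target_planted_r2
    scale = truth.noise_sd * np.sqrt(t / (1.0 - t)) / np.sqrt(v)
    return replace(
        truth,
        planted_effects=[(l, b * scale) for l, b in truth.planted_effects],
    )


def simulate_phenotype(
    gm: GenotypeMatrix, truth: SimulationTruth
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Generate the phenotype table for a simulated genotype matrix.

    Betas are first calibrated to ``target_planted_r2`` (returned in the
    calibrated truth).  ICV is log-normal with sex-specific location; BAI
    and BDI are independent null scores included so the covariate screen has
    something to screen.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, 2)))
    n = gm.n_subjects
    male = gm.is_male
    icv = np.where(
        male,
        rng.lognormal(np.log(1.55e6), 0.065, n),
        rng.lognormal(np.log(1.40e6), 0.065, n),
    )
    calibrated = calibrate_effect_sizes(truth, gm) if truth.planted_effects else truth
    planted = _planted_term(gm, calibrated)
    volume = (
        truth.baseline_volume
        + truth.sex_effect * male.astype(float)
        + truth.icv_slope * (icv - icv.mean())
        + planted
        + rng.normal(0.0, truth.noise_sd, n)
    )
    volume = np.maximum(volume, 1.0)
    table = PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": gm.subject_ids,
                "amygdala_volume": volume,
                "sex": gm.sex,
                "icv": icv,
                "bai": rng.poisson(5.0, n),
                "bdi": rng.poisson(6.0, n),
            }
        )
    )
    return table, calibrated


def simulate_study(
    truth: SimulationTruth,
) -> tuple[GenotypeMatrix, PhenotypeTable, SimulationTruth]:
    """Generate a full study: genotypes (with missingness/quality applied)
    plus a phenotype computed from the complete calls, so planted effects do
    not leak imputation noise."""
    complete = _simulate_complete(truth)
    pheno, calibrated = simulate_phenotype(complete, truth)
    gm = _apply_missingness(complete, truth)
    return gm, pheno, calibrated
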