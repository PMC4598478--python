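"""Core in-memory containers for the association pipeline.

The pipeline's substrate is a subjects x loci genotype matrix with per-call
confidence scores, plus a phenotype table carrying the volumetric trait and
its covariates.  Alleles are stored as small integer indices into each
locus's two allele labels; this keeps QC, linkage-disequilibrium and coding
arithmetic vectorizable while the label strings stay authoritative for I/O.

Call encodings in ``GenotypeMatrix.a1``/``a2``:

* ``a1, a2 in {0, 1}`` -- an unordered diploid call,
* ``a1 in {0, 1}, a2 == HEMI`` -- a hemizygous call (male X),
* ``a1 == a2 == MISSING`` -- no call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
HEMI: int = -2

AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_sex(value: str) -> str:
    v = str(value).strip().lower()
    if v in {"m", "male", "1"}:
        return "M"
    if v in {"f", "female", "2"}:
        return "F"
    if v in {"u", "unknown", "0", "nan", ""}:
        return "U"
    raise ValueError(f"unrecognized sex value: {value!r}")


@dataclass(frozen=True)
class LocusRecord:
    """Metadata for one biallelic marker (SNP or VNTR).

    ``allele_labels`` are nucleotides for SNPs (e.g. ``("A", "G")``) or
    repeat-count labels for VNTRs (e.g. ``("3R", "4R")``).
    """

    locus_id: str
    chromosome: str
    position: int
    marker_kind: str = "SNP"
    allele_labels: tuple[str, str] = ("A", "G")

    def __post_init__(self) -> None:
        chrom = str(self.chromosome)
        if chrom not in AUTOSOMES and chrom != "X":
            raise ValueError(
                f"{self.locus_id}: chromosome must be 1..22 or X, got {chrom!r}"
            )
        object.__setattr__(self, "chromosome", chrom)
        if self.marker_kind not in {"SNP", "VNTR"}:
            raise ValueError(f"{self.locus_id}: marker_kind must be SNP or VNTR")
        labels = tuple(str(a) for a in self.allele_labels)
        if len(labels) != 2 or labels[0] == labels[1]:
            raise ValueError(f"{self.locus_id}: need two distinct allele labels")
        object.__setattr__(self, "allele_labels", labels)
        if self.position < 0:
            raise ValueError(f"{self.locus_id}: negative position")

    @property
    def is_x(self) -> bool:
        return self.chromosome == "X"


@dataclass
class GenotypeMatrix:
    """Subjects x loci genotype calls with per-call quality scores.

    Sex is ``"M"``/``"F"`` per subject (``"U"`` allowed until a phenotype
    table supplies it; X-specific rules then refuse to run on unknowns).
    """

    subject_ids: list[str]
    sex: np.ndarray
    loci: list[LocusRecord]
    a1: np.ndarray
    a2: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = len(self.subject_ids), len(self.loci)
        self.sex = np.asarray([_norm_sex(s) for s in self.sex], dtype="<U1")
        self.a1 = np.asarray(self.a1, dtype=np.int8)
        self.a2 = np.asarray(self.a2, dtype=np.int8)
        if self.sex.shape != (n,):
            raise ValueError("sex length must match subject count")
        if self.a1.shape != (n, m) or self.a2.shape != (n, m):
            raise ValueError(f"call arrays must have shape ({n}, {m})")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if len({l.locus_id for l in self.loci}) != m:
            raise ValueError("duplicate locus ids")
        if self.quality is None:
            self.quality = np.ones((n, m), dtype=float)
        else:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape != (n, m):
                raise ValueError("quality array shape mismatch")
        self.validate_calls()

    # -- basic geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == "M"

    @property
    def x_mask(self) -> np.ndarray:
        """Boolean mask over loci: True where the locus is on X."""
        return np.asarray([l.is_x for l in self.loci], dtype=bool)

    def locus_index(self, locus_id: str) -> int:
        for j, l in enumerate(self.loci):
            if l.locus_id == locus_id:
                return j
        raise KeyError(locus_id)

    # -- call semantics -------------------------------------------------
    @property
    def is_missing(self) -> np.ndarray:
        return self.a1 == MISSING

    @property
    def is_hemizygous(self) -> np.ndarray:
        return self.a2 == HEMI

    def validate_calls(self) -> None:
        bad = (self.a1 == MISSING) != (self.a2 == MISSING)
        if bad.any():
            raise ValueError("half-missing call encountered")
        diploid = (self.a1 >= 0) & (self.a2 >= 0)
        het = diploid & (self.a1 != self.a2)
        male = self.is_male[:, None]
        male_het_x = het & male & self.x_mask[None, :]
        if male_het_x.any():
            i, j = np.argwhere(male_het_x)[0]
            raise ValueError(
                f"male heterozygous X call: subject {self.subject_ids[i]} "
                f"at locus {self.loci[j].locus_id}"
            )

    def allele_count_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Per subject x locus: (count of allele index 1, total alleles).

        Hemizygous calls contribute one allele, diploid calls two,
        missing calls zero.
        """
        hemi = self.is_hemizygous
        miss = self.is_missing
        c1 = np.where(miss, 0, (self.a1 == 1).astype(int))
        c1 = c1 + np.where(miss | hemi, 0, (self.a2 == 1).astype(int))
        total = np.where(miss, 0, np.where(hemi, 1, 2))
        return c1, total

    def dosage(self, allele_index: np.ndarray) -> np.ndarray:
        """Dosage (0/1/2) of the given allele index per locus; NaN missing.

        Hemizygous (male X) calls are scored 0/2, matching the convention
        that a single X allele carries a full dose.
        """
        allele_index = np.asarray(allele_index)
        d = (self.a1 == allele_index[None, :]).astype(float)
        d = d + (self.a2 == allele_index[None, :]).astype(float)
        d = np.where(self.is_hemizygous, 2.0 * (self.a1 == allele_index[None, :]), d)
        d[self.is_missing] = np.nan
        return d

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            sex=self.sex.copy(),
            loci=list(self.loci),
            a1=self.a1.copy(),
            a2=self.a2.copy(),
            quality=self.quality.copy(),
        )

    def take_subjects(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            subject_ids=[self.subject_ids[i] for i in index],
            sex=self.sex[index],
            loci=list(self.loci),
            a1=self.a1[index],
            a2=self.a2[index],
            quality=self.quality[index],
        )

    def take_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            sex=self.sex.copy(),
            loci=[self.loci[j] for j in index],
            a1=self.a1[:, index],
            a2=self.a2[:, index],
            quality=self.quality[:, index],
        )

    def with_sex_from(self, pheno: "PhenotypeTable") -> "GenotypeMatrix":
        """Fill unknown sexes by subject id from a phenotype table."""
        lookup = dict(zip(pheno.frame["subject_id"], pheno.frame["sex"]))
        sex = self.sex.copy()
        for i, sid in enumerate(self.subject_ids):
            if sex[i] == "U" and sid in lookup:
                sex[i] = lookup[sid]
        out = self.copy()
        out.sex = sex
        out.validate_calls()
        return out


REQUIRED_PHENO_COLUMNS = ("subject_id", "amygdala_volume", "sex", "icv")


@dataclass
class PhenotypeTable:
    """Validated phenotype table: volume (mm^3), sex, ICV (mm^3), optional
    Beck anxiety/depression inventory scores."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in REQUIRED_PHENO_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"phenotype table missing required column {col!r}")
        df["subject_id"] = df["subject_id"].astype(str)
        df["sex"] = [_norm_sex(s) for s in df["sex"]]
        df["amygdala_volume"] = df["amygdala_volume"].astype(float)
        df["icv"] = df["icv"].astype(float)
        for col in ("bai", "bdi"):
            if col not in df.columns:
                df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
            else:
                df[col] = pd.array(df[col], dtype="Int64")
                if (df[col].dropna() < 0).any():
                    raise ValueError(f"negative {col} score")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        if (df["amygdala_volume"] <= 0).any():
            raise ValueError("non-positive amygdala volume")
        if (df["icv"] <= df["amygdala_volume"]).any():
            bad = df.loc[df["icv"] <= df["amygdala_volume"], "subject_id"].iloc[0]
            raise ValueError(f"icv must exceed amygdala volume (subject {bad})")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    def aligned_to(self, subject_ids: Iterable[str]) -> "PhenotypeTable":
        """Reorder rows to the given subject order (all ids must be present)."""
        idx = self.frame.set_index("subject_id")
        ids = list(subject_ids)
        missing = [s for s in ids if s not in idx.index]
        if missing:
            raise KeyError(f"subjects absent from phenotype table: {missing[:5]}")
        return PhenotypeTable(idx.loc[ids].reset_index())
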