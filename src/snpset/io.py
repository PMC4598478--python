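"""Readers and writers for the genotype and phenotype formats the pipeline touches.

Three genotype dialects are supported:

* ``vcf`` -- VCF v4.x with GT calls (via :mod:`pysam`); sex is not part of
  VCF, so subjects read from it carry unknown sex until a phenotype table
  supplies it.
* ``plink_pedmap`` -- text PLINK ``.ped``/``.map`` pair; sex from column 5.
* ``tsv`` -- a plain subjects x loci matrix with calls ``"A/G"``, ``"A"``
  (hemizygous) or ``"NA"``, plus a ``*.loci.tsv`` metadata sidecar.  The
  only dialect that can carry VNTR markers.

Per-call quality scores live in an optional ``*.quality.tsv`` sidecar
(subject_id, locus_id, quality); absent sidecar means quality 1.0.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .types import HEMI, MISSING, GenotypeMatrix, LocusRecord, PhenotypeTable

GENOTYPE_FORMATS = ("vcf", "plink_pedmap", "tsv")


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def _sidecar(path: str | Path, kind: str) -> Path:
    p = Path(path)
    base = p.name
    for ext in (".vcf", ".tsv", ".ped"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return p.with_name(f"{base}.{kind}.tsv")


def _write_loci_sidecar(loci: list[LocusRecord], path: Path) -> None:
    pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chromosome": [l.chromosome for l in loci],
            "position": [l.position for l in loci],
            "marker_kind": [l.marker_kind for l in loci],
            "allele1": [l.allele_labels[0] for l in loci],
            "allele2": [l.allele_labels[1] for l in loci],
        }
    ).to_csv(path, sep="\t", index=False)


def _read_loci_sidecar(path: Path) -> list[LocusRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        LocusRecord(
            locus_id=r.locus_id,
            chromosome=r.chromosome,
            position=int(r.position),
            marker_kind=r.marker_kind,
            allele_labels=(r.allele1, r.allele2),
        )
        for r in df.itertuples()
    ]


def _write_quality_sidecar(gm: GenotypeMatrix, path: Path) -> None:
    rows = np.argwhere(gm.quality != 1.0)
    if len(rows) == 0:
        return
    pd.DataFrame(
        {
            "subject_id": [gm.subject_ids[i] for i, _ in rows],
            "locus_id": [gm.loci[j].locus_id for _, j in rows],
            "quality": [float(gm.quality[i, j]) for i, j in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def _apply_quality_sidecar(gm: GenotypeMatrix, path: Path) -> None:
    if not path.exists():
        return
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "locus_id": str})
    sidx = {s: i for i, s in enumerate(gm.subject_ids)}
    lidx = {l.locus_id: j for j, l in enumerate(gm.loci)}
    for r in df.itertuples():
        gm.quality[sidx[r.subject_id], lidx[r.locus_id]] = float(r.quality)


# ---------------------------------------------------------------------------
# genotype readers/writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    Missing-call conventions (VCF ``./.``, PLINK ``0 0``, TSV ``NA``) map to
    missing; male X calls encoded as homozygous diploid are normalized to
    single-allele once sex is known.
    """
    if format not in GENOTYPE_FORMATS:
        raise ValueError(f"unknown genotype format {format!r}")
    path = Path(path)
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "plink_pedmap":
        gm = _read_pedmap(path)
    else:
        gm = _read_tsv(path)
    _apply_quality_sidecar(gm, _sidecar(path, "quality"))
    normalize_x_hemizygotes(gm)
    return gm


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str) -> None:
    if format not in GENOTYPE_FORMATS:
        raise ValueError(f"unknown genotype format {format!r}")
    path = Path(path)
    if format != "tsv" and any(l.marker_kind == "VNTR" for l in gm.loci):
        bad = next(l.locus_id for l in gm.loci if l.marker_kind == "VNTR")
        raise ValueError(
            f"VNTR marker {bad} is only representable in the tsv dialect; "
            f"refusing {format} export"
        )
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "plink_pedmap":
        _write_pedmap(gm, path)
        _write_loci_sidecar(gm.loci, _sidecar(path, "loci"))
    else:
        _write_tsv(gm, path)
        _write_loci_sidecar(gm.loci, _sidecar(path, "loci"))
    _write_quality_sidecar(gm, _sidecar(path, "quality"))


def normalize_x_hemizygotes(gm: GenotypeMatrix) -> None:
    """Convert male homozygous-diploid X calls to the single-allele encoding.

    No-op for subjects of unknown sex.  Male heterozygous X calls are a hard
    error (raised by call validation).
    """
    x = gm.x_mask
    if not x.any():
        return
    male = gm.is_male[:, None] & x[None, :]
    diploid = (gm.a1 >= 0) & (gm.a2 >= 0)
    gm.validate_calls()
    to_fix = male & diploid
    gm.a2[to_fix] = HEMI


def _read_vcf(path: Path) -> GenotypeMatrix:
    with pysam.VariantFile(os.fspath(path)) as vf:
        subjects = list(vf.header.samples)
        loci: list[LocusRecord] = []
        rows_a1: list[np.ndarray] = []
        rows_a2: list[np.ndarray] = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.id or rec.pos}: expected exactly one ALT allele")
            loci.append(
                LocusRecord(
                    locus_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chromosome=rec.chrom.removeprefix("chr"),
                    position=rec.pos,
                    marker_kind="SNP",
                    allele_labels=(rec.ref, rec.alts[0]),
                )
            )
            a1 = np.full(len(subjects), MISSING, dtype=np.int8)
            a2 = np.full(len(subjects), MISSING, dtype=np.int8)
            for i, s in enumerate(subjects):
                gt = rec.samples[s]["GT"]
                alleles = [a for a in gt if a is not None]
                if len(alleles) == 0:
                    continue
                if len(alleles) == 1:
                    a1[i], a2[i] = alleles[0], HEMI
                else:
                    a1[i], a2[i] = alleles[0], alleles[1]
            rows_a1.append(a1)
            rows_a2.append(a2)
    return GenotypeMatrix(
        subject_ids=subjects,
        sex=np.full(len(subjects), "U"),
        loci=loci,
        a1=np.column_stack(rows_a1) if loci else np.empty((len(subjects), 0), np.int8),
        a2=np.column_stack(rows_a2) if loci else np.empty((len(subjects), 0), np.int8),
    )


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(l.chromosome for l in gm.loci):
        header.contigs.add(chrom)
    for s in gm.subject_ids:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for j, loc in enumerate(gm.loci):
            rec = vf.new_record(
                contig=loc.chromosome,
                start=loc.position - 1,
                stop=loc.position,
                alleles=loc.allele_labels,
                id=loc.locus_id,
            )
            for i, s in enumerate(gm.subject_ids):
                if gm.a1[i, j] == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                elif gm.a2[i, j] == HEMI:
                    rec.samples[s]["GT"] = (int(gm.a1[i, j]),)
                else:
                    rec.samples[s]["GT"] = (int(gm.a1[i, j]), int(gm.a2[i, j]))
            vf.write(rec)


def _read_pedmap(path: Path) -> GenotypeMatrix:
    """Read ``<prefix>.ped`` + ``<prefix>.map``; ``path`` may name either file.

    A ``<prefix>.loci.tsv`` sidecar (written by :func:`write_genotypes`)
    supplies allele labels; without it labels are the lexicographically
    sorted alleles observed per locus.
    """
    prefix = Path(os.fspath(path))
    if prefix.suffix in {".ped", ".map"}:
        prefix = prefix.with_suffix("")
    map_df = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "locus_id", "cm", "position"],
        dtype=str,
    )
    n_loci = len(map_df)
    subjects: list[str] = []
    sexes: list[str] = []
    raw_calls: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * n_loci}"
                )
            subjects.append(parts[1])
            sexes.append({"1": "M", "2": "F"}.get(parts[4], "U"))
            raw_calls.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_loci)]
            )
    sidecar = _sidecar(prefix.with_suffix(".ped"), "loci")
    if sidecar.exists():
        loci = _read_loci_sidecar(sidecar)
        if [l.locus_id for l in loci] != list(map_df["locus_id"]):
            raise ValueError("loci sidecar does not match .map file")
    else:
        loci = []
        for j, r in enumerate(map_df.itertuples()):
            seen = sorted(
                {a for row in raw_calls for a in row[j] if a != "0"}
            )
            if len(seen) == 1:
                seen.append("N")  # placeholder second allele, never observed
            if len(seen) != 2:
                raise ValueError(f"{r.locus_id}: expected <=2 alleles, saw {seen}")
            loci.append(
                LocusRecord(
                    locus_id=r.locus_id,
                    chromosome=r.chromosome,
                    position=int(r.position),
                    allele_labels=(seen[0], seen[1]),
                )
            )
    n = len(subjects)
    a1 = np.full((n, n_loci), MISSING, dtype=np.int8)
    a2 = np.full((n, n_loci), MISSING, dtype=np.int8)
    for j, loc in enumerate(loci):
        lut = {loc.allele_labels[0]: 0, loc.allele_labels[1]: 1}
        for i in range(n):
            x, y = raw_calls[i][j]
            if x == "0" or y == "0":
                continue  # "0 0" (or half-missing) -> missing call
            try:
                a1[i, j], a2[i, j] = lut[x], lut[y]
            except KeyError as exc:
                raise ValueError(
                    f"unknown allele {exc.args[0]!r} at {loc.locus_id}"
                ) from None
    return GenotypeMatrix(
        subject_ids=subjects, sex=np.asarray(sexes), loci=loci, a1=a1, a2=a2
    )


def _write_pedmap(gm: GenotypeMatrix, path: Path) -> None:
    prefix = Path(os.fspath(path))
    if prefix.suffix in {".ped", ".map"}:
        prefix = prefix.with_suffix("")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for loc in gm.loci:
            fh.write(f"{loc.chromosome}\t{loc.locus_id}\t0\t{loc.position}\n")
    sex_code = {"M": "1", "F": "2", "U": "0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(gm.subject_ids):
            fields = [sid, sid, "0", "0", sex_code[str(gm.sex[i])], "-9"]
            for j, loc in enumerate(gm.loci):
                if gm.a1[i, j] == MISSING:
                    fields += ["0", "0"]
                elif gm.a2[i, j] == HEMI:
                    al = loc.allele_labels[gm.a1[i, j]]
                    fields += [al, al]  # PLINK convention: hemizygote as homozygote
                else:
                    fields += [
                        loc.allele_labels[gm.a1[i, j]],
                        loc.allele_labels[gm.a2[i, j]],
                    ]
            fh.write(" ".join(fields) + "\n")


def _read_tsv(path: Path) -> GenotypeMatrix:
    loci = _read_loci_sidecar(_sidecar(path, "loci"))
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("subject_id", "sex"):
        if col not in df.columns:
            raise ValueError(f"genotype tsv missing column {col!r}")
    locus_ids = [l.locus_id for l in loci]
    missing_cols = [l for l in locus_ids if l not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype tsv missing locus columns {missing_cols[:5]}")
    n, m = len(df), len(loci)
    a1 = np.full((n, m), MISSING, dtype=np.int8)
    a2 = np.full((n, m), MISSING, dtype=np.int8)
    for j, loc in enumerate(loci):
        lut = {loc.allele_labels[0]: 0, loc.allele_labels[1]: 1}
        for i, cell in enumerate(df[loc.locus_id]):
            if pd.isna(cell) or cell == "NA":
                continue
            parts = str(cell).split("/")
            try:
                if len(parts) == 1:
                    a1[i, j], a2[i, j] = lut[parts[0]], HEMI
                elif len(parts) == 2:
                    a1[i, j], a2[i, j] = lut[parts[0]], lut[parts[1]]
                else:
                    raise ValueError(f"malformed call {cell!r} at {loc.locus_id}")
            except KeyError as exc:
                raise ValueError(
                    f"unknown allele {exc.args[0]!r} at {loc.locus_id}"
                ) from None
    return GenotypeMatrix(
        subject_ids=list(df["subject_id"]),
        sex=df["sex"].to_numpy(),
        loci=loci,
        a1=a1,
        a2=a2,
    )


def _write_tsv(gm: GenotypeMatrix, path: Path) -> None:
    cols: dict[str, list[str]] = {
        "subject_id": list(gm.subject_ids),
        "sex": [str(s) for s in gm.sex],
    }
    for j, loc in enumerate(gm.loci):
        col = []
        for i in range(gm.n_subjects):
            if gm.a1[i, j] == MISSING:
                col.append("NA")
            elif gm.a2[i, j] == HEMI:
                col.append(loc.allele_labels[gm.a1[i, j]])
            else:
                col.append(
                    f"{loc.allele_labels[gm.a1[i, j]]}/{loc.allele_labels[gm.a2[i, j]]}"
                )
        cols[loc.locus_id] = col
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read and validate a phenotype TSV (subject_id, amygdala_volume, sex,
    icv, optional bai/bdi)."""
    df = pd.read_csv(path, sep="\t")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def flag_unmatched_subjects(
    gm: GenotypeMatrix, pheno: PhenotypeTable
) -> dict[str, list[str]]:
    """Subjects present in only one of the two inputs (flagged, never dropped)."""
    g = set(gm.subject_ids)
    p = set(pheno.subject_ids)
    return {
        "genotypes_only": sorted(g - p),
        "phenotypes_only": sorted(p - g),
    }


def genotype_matrices_equal(x: GenotypeMatrix, y: GenotypeMatrix) -> bool:
    """Semantic equality: same subjects, sexes, loci, unordered calls, quality."""
    if x.subject_ids != y.subject_ids or not np.array_equal(x.sex, y.sex):
        return False
    if x.loci != y.loci:
        return False
    lo_x, hi_x = np.minimum(x.a1, x.a2), np.maximum(x.a1, x.a2)
    lo_y, hi_y = np.minimum(y.a1, y.a2), np.maximum(y.a1, y.a2)
    return (
        np.array_equal(lo_x, lo_y)
        and np.array_equal(hi_x, hi_y)
        and np.allclose(x.quality, y.quality)
    )
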