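"""Genotype quality control: call masking, sample missingness, genotype-group
merging, Hardy-Weinberg tests, LD pruning and relatedness screening.

The stages run in a fixed order (quality masking, then sample filtering, then
per-locus grouping) so that genotype-level and sample-level exclusions are
reported separately.  Hardy-Weinberg deviation is flagged rather than excluded
by default; LD pruning is a greedy scan in genomic order using the squared
dosage correlation; relatedness is a method-of-moments IBD estimate (PI_HAT)
from identity-by-state sharing on the pruned autosomal panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, LocusRecord, MISSING


@dataclass
class QCConfig:
    """Thresholds for every QC rule.

    All comparisons against thresholds are strict in the direction stated on
    each operation (e.g. a sample is excluded only when its missing fraction
    strictly exceeds ``sample_missing_max``).
    """

    sample_missing_max: float = 0.10
    call_quality_min: float = 0.25
    min_group_count: int = 10
    hwe_alpha: float = 0.01
    ld_r2_max: float = 0.8
    pihat_flag: float = 0.5
    hwe_policy: str = "flag_only"
    protocol_threshold: float = 0.95  # recorded in reports; not an operative gate
    min_relatedness_loci: int = 50

    def __post_init__(self) -> None:
        checks = [
            ("sample_missing_max", 0.0, 1.0),
            ("call_quality_min", 0.0, 1.0),
            ("hwe_alpha", 0.0, 1.0),
            ("ld_r2_max", 0.0, 1.0),
            ("pihat_flag", 0.0, 1.0),
            ("protocol_threshold", 0.0, 1.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_group_count < 1:
            raise ValueError("min_group_count must be >= 1")
        if self.hwe_policy not in {"flag_only", "exclude"}:
            raise ValueError("hwe_policy must be 'flag_only' or 'exclude'")


# ---------------------------------------------------------------------------
# allele frequencies and genotype classes
# ---------------------------------------------------------------------------

def minor_allele_index(gm: GenotypeMatrix) -> np.ndarray:
    """Index (0 or 1) of the minor allele per locus, from sample frequencies.

    X alleles are counted once in males.  A locus with frequency exactly 0.5
    takes the lexicographically later allele label as minor, so the choice is
    deterministic.  Monomorphic loci take the unobserved allele as minor.
    """
    c1, tot = gm.allele_count_matrix()
    n1 = c1.sum(axis=0).astype(float)
    n = tot.sum(axis=0).astype(float)
    out = np.zeros(gm.n_loci, dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(n > 0, n1 / n, np.nan)
    for j, loc in enumerate(gm.loci):
        if not np.isfinite(f1[j]) or f1[j] == 0.5:
            a, b = loc.allele_labels
            out[j] = 1 if b > a else 0
        elif f1[j] == 0.0:
            out[j] = 1
        elif f1[j] == 1.0:
            out[j] = 0
        else:
            out[j] = 1 if f1[j] < 0.5 else 0
    return out


def minor_allele_frequency(gm: GenotypeMatrix, minor: np.ndarray | None = None) -> np.ndarray:
    if minor is None:
        minor = minor_allele_index(gm)
    c1, tot = gm.allele_count_matrix()
    n1 = c1.sum(axis=0).astype(float)
    n = tot.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(n > 0, n1 / n, np.nan)
    return np.where(minor == 1, f1, 1.0 - f1)


def genotype_classes(gm: GenotypeMatrix, minor: np.ndarray | None = None) -> np.ndarray:
    """Per subject x locus genotype class: 0 major-hom, 1 het, 2 minor-hom,
    -1 missing.  Male X hemizygotes map to the matching homozygote class."""
    if minor is None:
        minor = minor_allele_index(gm)
    d = gm.dosage(minor)
    cls = np.where(np.isnan(d), -1, d).astype(int)
    return cls


# ---------------------------------------------------------------------------
# stage 1-2: masking and sample filtering
# ---------------------------------------------------------------------------

def mask_low_quality_calls(
    gm: GenotypeMatrix, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, int]:
    """Set calls with quality strictly below ``call_quality_min`` to missing.

    Returns the masked matrix and the number of newly masked calls.  A call
    with quality exactly at the threshold is retained.
    """
    cfg = cfg or QCConfig()
    out = gm.copy()
    low = (out.quality < cfg.call_quality_min) & ~out.is_missing
    out.a1[low] = MISSING
    out.a2[low] = MISSING
    return out, int(low.sum())


def filter_samples_by_missingness(
    gm: GenotypeMatrix, cfg: QCConfig | None = None
) -> tuple[GenotypeMatrix, list[tuple[str, float]]]:
    """Drop subjects whose missing-call fraction strictly exceeds the cap."""
    cfg = cfg or QCConfig()
    if gm.n_loci == 0:
        return gm.copy(), []
    frac = gm.is_missing.mean(axis=1)
    drop = frac > cfg.sample_missing_max
    excluded = [(gm.subject_ids[i], float(frac[i])) for i in np.flatnonzero(drop)]
    if drop.all():
        raise ValueError("all subjects exceed the missingness cap")
    return gm.take_subjects(np.flatnonzero(~drop)), excluded


# ---------------------------------------------------------------------------
# stage 3: genotype-group merging
# ---------------------------------------------------------------------------

CLASS_NAMES = ("major_hom", "het", "minor_hom")


@dataclass
class GenotypeGrouping:
    """Analysis groups for one locus after the small-group merging rule.

    ``membership`` maps each subject to a group index (-1 = missing call or
    excluded locus); ``merge_map`` records which original genotype class fed
    each analysis group.
    """

    locus_id: str
    labels: list[str]
    counts: list[int]
    merge_map: dict[str, str]
    membership: np.ndarray
    minor_index: int
    excluded: bool = False
    reason: str | None = None

    @property
    def n_groups(self) -> int:
        return len(self.labels)


def _class_labels(locus: LocusRecord, minor_index: int) -> list[str]:
    maj = locus.allele_labels[1 - minor_index]
    mnr = locus.allele_labels[minor_index]
    return [maj + maj, maj + mnr, mnr + mnr]


def make_grouping(
    gm: GenotypeMatrix,
    locus: int | str,
    cfg: QCConfig | None = None,
    minor: np.ndarray | None = None,
) -> GenotypeGrouping:
    """Apply the small-group rule at one locus.

    If the heterozygote or minor-homozygote class has fewer members than
    ``min_group_count``, those two classes are combined; if the combined
    group is still too small the locus is excluded.  Monomorphic loci are
    excluded outright.
    """
    cfg = cfg or QCConfig()
    j = locus if isinstance(locus, int) else gm.locus_index(locus)
    if minor is None:
        minor = minor_allele_index(gm)
    cls = genotype_classes(gm, minor)[:, j]
    loc = gm.loci[j]
    labels3 = _class_labels(loc, int(minor[j]))
    counts3 = [int((cls == c).sum()) for c in range(3)]
    membership = np.full(gm.n_subjects, -1, dtype=int)

    def excluded(reason: str) -> GenotypeGrouping:
        return GenotypeGrouping(
            locus_id=loc.locus_id,
            labels=[],
            counts=[],
            merge_map={},
            membership=membership,
            minor_index=int(minor[j]),
            excluded=True,
            reason=reason,
        )

    if sum(counts3) == 0:
        return excluded("no calls")
    if counts3[1] + counts3[2] == 0 or counts3[0] + counts3[1] == 0:
        return excluded("monomorphic")

    if counts3[1] < cfg.min_group_count or counts3[2] < cfg.min_group_count:
        combined = counts3[1] + counts3[2]
        if combined < cfg.min_group_count:
            return excluded(
                f"combined het+minor-hom group has {combined} < "
                f"{cfg.min_group_count} subjects"
            )
        if counts3[0] == 0:
            return excluded("monomorphic after merging")
        labels = [labels3[0], labels3[1] + "+" + labels3[2]]
        merge_map = {labels3[0]: labels[0], labels3[1]: labels[1], labels3[2]: labels[1]}
        counts = [counts3[0], combined]
        membership[cls == 0] = 0
        membership[(cls == 1) | (cls == 2)] = 1
    else:
        labels = [l for l, c in zip(labels3, counts3) if c > 0]
        merge_map = {l: l for l in labels}
        counts = [c for c in counts3 if c > 0]
        kept = [c for c in range(3) if counts3[c] > 0]
        for g, c in enumerate(kept):
            membership[cls == c] = g
    return GenotypeGrouping(
        locus_id=loc.locus_id,
        labels=labels,
        counts=counts,
        merge_map=merge_map,
        membership=membership,
        minor_index=int(minor[j]),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_chi_square(
    gm: GenotypeMatrix, locus: int | str, minor: np.ndarray | None = None
) -> tuple[float, float, str]:
    """Pearson chi-square (df=1) of observed vs HWE-expected genotype counts.

    X loci use female subjects only (males carry a single X, so their calls
    carry no information about departure from random mating).  Returns
    ``(chi2, p, flag)`` where flag is ``"ok"`` or ``"untestable"`` for
    monomorphic/empty loci.
    """
    j = locus if isinstance(locus, int) else gm.locus_index(locus)
    if minor is None:
        minor = minor_allele_index(gm)
    d = gm.dosage(minor)[:, j]
    use = ~np.isnan(d) & ~gm.is_hemizygous[:, j]
    if gm.loci[j].is_x:
        use &= ~gm.is_male
    d = d[use]
    n = len(d)
    if n == 0:
        return float("nan"), float("nan"), "untestable"
    obs = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], dtype=float)
    q = d.sum() / (2 * n)  # minor allele frequency among tested subjects
    if q == 0.0 or q == 1.0:
        return float("nan"), float("nan"), "untestable"
    p = 1.0 - q
    exp = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1)), "ok"


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _pairwise_r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """All-pairs squared Pearson correlation of dosage columns over complete
    pairs, computed with masked cross-products.  Degenerate pairs (fewer than
    two complete observations or zero variance) score 0."""
    U = (~np.isnan(dosage)).astype(float)
    D = np.nan_to_num(dosage, nan=0.0)
    D2 = D * D
    n = U.T @ U
    sx = D.T @ U
    sxy = D.T @ D
    sxx = D2.T @ U
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        vx = sxx - sx**2 / n
        r2 = cov**2 / (vx * vx.T)
    r2 = np.where((n >= 2) & np.isfinite(r2), r2, 0.0)
    return np.clip(r2, 0.0, 1.0)


def pairwise_r2(
    gm: GenotypeMatrix,
    locus_a: int | str,
    locus_b: int | str,
    minor: np.ndarray | None = None,
) -> float:
    """Squared correlation of minor-allele dosages between two loci (the
    composite LD estimator), over subjects called at both."""
    ja = locus_a if isinstance(locus_a, int) else gm.locus_index(locus_a)
    jb = locus_b if isinstance(locus_b, int) else gm.locus_index(locus_b)
    if minor is None:
        minor = minor_allele_index(gm)
    d = gm.dosage(minor)[:, [ja, jb]]
    return float(_pairwise_r2_matrix(d)[0, 1])


def _genomic_order(loci: Sequence[LocusRecord]) -> np.ndarray:
    def key(loc: LocusRecord):
        c = 23 if loc.chromosome == "X" else int(loc.chromosome)
        return (c, loc.position, loc.locus_id)

    return np.asarray(sorted(range(len(loci)), key=lambda j: key(loci[j])), dtype=int)


def ld_prune(
    gm: GenotypeMatrix,
    cfg: QCConfig | None = None,
    minor: np.ndarray | None = None,
    candidate_index: np.ndarray | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy LD pruning in genomic order.

    A locus is dropped iff its r^2 with an already-retained earlier locus on
    the same chromosome strictly exceeds ``ld_r2_max``; the earlier-position
    member of a high-LD pair is kept.  Returns (retained ids, dropped list
    of (locus_id, retained partner, r^2)).
    """
    cfg = cfg or QCConfig()
    if minor is None:
        minor = minor_allele_index(gm)
    idx = (
        np.arange(gm.n_loci)
        if candidate_index is None
        else np.asarray(candidate_index, dtype=int)
    )
    if len(idx) == 0:
        return [], []
    sub = [gm.loci[j] for j in idx]
    order = _genomic_order(sub)
    d = gm.dosage(minor)[:, idx]
    r2 = _pairwise_r2_matrix(d)
    retained: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for pos in order:
        partner = None
        for r in retained:
            if sub[r].chromosome != sub[pos].chromosome:
                continue
            if r2[r, pos] > cfg.ld_r2_max:
                partner = r
                break
        if partner is None:
            retained.append(pos)
        else:
            dropped.append(
                (sub[pos].locus_id, sub[partner].locus_id, float(r2[partner, pos]))
            )
    retained_ids = [sub[r].locus_id for r in sorted(retained)]
    return retained_ids, dropped


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def estimate_pi_hat(
    gm: GenotypeMatrix,
    cfg: QCConfig | None = None,
    locus_index: np.ndarray | None = None,
    minor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Method-of-moments IBD estimation from IBS sharing for every subject pair.

    Uses autosomal loci only (by default all; pass ``locus_index`` for an
    LD-pruned panel).  For each pair, observed IBS0/1/2 counts over shared
    non-missing loci are compared with their expectations under IBD states
    given sample allele frequencies; the implied P(IBD=0/1/2) are clamped to
    [0,1] and renormalized, and PI_HAT = P(IBD=1)/2 + P(IBD=2).

    Returns a data frame with one row per pair, including a ``flagged``
    column for pairs at or above ``pihat_flag``.
    """
    cfg = cfg or QCConfig()
    if minor is None:
        minor = minor_allele_index(gm)
    idx = (
        np.arange(gm.n_loci) if locus_index is None else np.asarray(locus_index, int)
    )
    idx = np.asarray([j for j in idx if not gm.loci[j].is_x], dtype=int)
    low_confidence = len(idx) < cfg.min_relatedness_loci
    if low_confidence:
        warnings.warn(
            f"only {len(idx)} autosomal loci available for relatedness "
            f"estimation (< {cfg.min_relatedness_loci}); estimates are "
            "low-confidence",
            stacklevel=2,
        )
    d = gm.dosage(minor)[:, idx]
    maf = minor_allele_frequency(gm, minor)[idx]
    ok = np.isfinite(maf) & (maf > 0) & (maf < 1)
    d, maf = d[:, ok], maf[ok]
    q, p = maf, 1.0 - maf

    G = [(d == k).astype(float) for k in (0.0, 1.0, 2.0)]
    U = G[0] + G[1] + G[2]
    ibs2 = G[0] @ G[0].T + G[1] @ G[1].T + G[2] @ G[2].T
    ibs0 = G[0] @ G[2].T + G[2] @ G[0].T
    shared = U @ U.T
    ibs1 = shared - ibs0 - ibs2

    def pair_expectation(w: np.ndarray) -> np.ndarray:
        return (U * w) @ U.T

    e0_ibd0 = pair_expectation(2 * p**2 * q**2)
    e1_ibd0 = pair_expectation(4 * p * q * (p**2 + q**2))
    e2_ibd0 = pair_expectation(p**4 + q**4 + 4 * p**2 * q**2)
    e1_ibd1 = pair_expectation(2 * p * q)
    e2_ibd1 = pair_expectation(p**2 + q**2)

    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = ibs0 / e0_ibd0
        p1 = (ibs1 - p0 * e1_ibd0) / e1_ibd1
        p2 = (ibs2 - p0 * e2_ibd0 - p1 * e2_ibd1) / shared
    probs = np.stack([p0, p1, p2])
    probs = np.clip(np.nan_to_num(probs, nan=0.0), 0.0, 1.0)
    total = probs.sum(axis=0)
    total = np.where(total > 0, total, 1.0)
    probs = probs / total
    pi_hat = probs[1] / 2 + probs[2]

    iu = np.triu_indices(gm.n_subjects, k=1)
    ids = np.asarray(gm.subject_ids)
    df = pd.DataFrame(
        {
            "subject_a": ids[iu[0]],
            "subject_b": ids[iu[1]],
            "shared_loci": shared[iu].astype(int),
            "ibs0": ibs0[iu].astype(int),
            "ibs1": ibs1[iu].astype(int),
            "ibs2": ibs2[iu].astype(int),
            "p_ibd0": probs[0][iu],
            "p_ibd1": probs[1][iu],
            "p_ibd2": probs[2][iu],
            "pi_hat": pi_hat[iu],
        }
    )
    df["flagged"] = df["pi_hat"] >= cfg.pihat_flag
    df["low_confidence"] = low_confidence
    return df


# ---------------------------------------------------------------------------
# the full QC pass
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Reconciled record of every QC decision."""

    input_subjects: int
    input_loci: int
    masked_calls: int
    masked_fraction: float
    excluded_subjects: list[tuple[str, float]]
    hwe: pd.DataFrame
    merged_loci: list[str]
    excluded_loci: list[tuple[str, str]]
    ld_dropped: list[tuple[str, str, float]]
    relatedness_flags: pd.DataFrame
    retained_subjects: int
    retained_loci: int
    candidate_loci: list[str]
    protocol_threshold: float

    def check_conservation(self) -> None:
        assert self.input_subjects == self.retained_subjects + len(
            self.excluded_subjects
        ), "subject counts do not reconcile"
        assert self.input_loci == self.retained_loci + len(self.excluded_loci) + len(
            self.ld_dropped
        ), "locus counts do not reconcile"

    def to_dict(self) -> dict:
        return {
            "input_subjects": self.input_subjects,
            "input_loci": self.input_loci,
            "masked_calls": self.masked_calls,
            "masked_fraction": self.masked_fraction,
            "excluded_subjects": [
                {"subject_id": s, "missing_fraction": f}
                for s, f in self.excluded_subjects
            ],
            "hwe_flagged": self.hwe.loc[self.hwe["flag"] == "deviating", "locus_id"]
            .tolist(),
            "merged_loci": self.merged_loci,
            "excluded_loci": [
                {"locus_id": l, "reason": r} for l, r in self.excluded_loci
            ],
            "ld_dropped": [
                {"locus_id": l, "partner": p, "r2": r} for l, p, r in self.ld_dropped
            ],
            "relatedness_flagged_pairs": self.relatedness_flags.to_dict("records"),
            "retained_subjects": self.retained_subjects,
            "retained_loci": self.retained_loci,
            "candidate_loci": self.candidate_loci,
            "protocol_threshold": self.protocol_threshold,
        }


def run_qc(
    gm: GenotypeMatrix, cfg: QCConfig | None = None, relatedness: bool = True
) -> tuple[GenotypeMatrix, list[GenotypeGrouping], QCReport]:
    """Run the full QC cascade and return the cleaned matrix, per-locus
    groupings for the retained loci, and a reconciled report.

    Stages, in order: call-quality masking; sample-missingness filter;
    per-locus grouping with the small-group merge/exclude rule; HWE flags
    (flag-only by default); greedy LD pruning of the surviving loci; and a
    PI_HAT relatedness screen on the pruned autosomal panel.
    """
    cfg = cfg or QCConfig()
    n_in, m_in = gm.n_subjects, gm.n_loci

    masked, n_masked = mask_low_quality_calls(gm, cfg)
    filtered, excluded_subjects = filter_samples_by_missingness(masked, cfg)

    minor = minor_allele_index(filtered)
    groupings = [
        make_grouping(filtered, j, cfg, minor) for j in range(filtered.n_loci)
    ]
    excluded_loci = [
        (g.locus_id, g.reason or "") for g in groupings if g.excluded
    ]
    merged_loci = [
        g.locus_id
        for g in groupings
        if not g.excluded and len(set(g.merge_map.values())) < len(g.merge_map)
    ]

    hwe_rows = []
    for j, loc in enumerate(filtered.loci):
        chi2, p, flag = hwe_chi_square(filtered, j, minor)
        if flag == "ok":
            flag = "deviating" if p < cfg.hwe_alpha else "ok"
        hwe_rows.append(
            {"locus_id": loc.locus_id, "chi2": chi2, "p": p, "flag": flag}
        )
    hwe = pd.DataFrame(hwe_rows)

    surviving = np.asarray(
        [j for j, g in enumerate(groupings) if not g.excluded], dtype=int
    )
    if cfg.hwe_policy == "exclude":
        deviating = set(hwe.loc[hwe["flag"] == "deviating", "locus_id"])
        extra = [j for j in surviving if filtered.loci[j].locus_id in deviating]
        excluded_loci += [
            (filtered.loci[j].locus_id, "Hardy-Weinberg deviation") for j in extra
        ]
        surviving = np.asarray(
            [j for j in surviving if filtered.loci[j].locus_id not in deviating],
            dtype=int,
        )

    retained_ids, ld_dropped = ld_prune(filtered, cfg, minor, surviving)
    keep = np.asarray(
        [j for j in surviving if filtered.loci[j].locus_id in set(retained_ids)],
        dtype=int,
    )
    clean = filtered.take_loci(keep)
    clean_groupings = [groupings[j] for j in keep]

    if relatedness and clean.n_loci > 0:
        rel = estimate_pi_hat(clean, cfg)
        rel_flags = rel.loc[rel["flagged"]].reset_index(drop=True)
    else:
        rel_flags = pd.DataFrame(
            columns=["subject_a", "subject_b", "pi_hat", "flagged"]
        )

    report = QCReport(
        input_subjects=n_in,
        input_loci=m_in,
        masked_calls=n_masked,
        masked_fraction=n_masked / max(n_in * m_in, 1),
        excluded_subjects=excluded_subjects,
        hwe=hwe,
        merged_loci=merged_loci,
        excluded_loci=excluded_loci,
        ld_dropped=ld_dropped,
        relatedness_flags=rel_flags,
        retained_subjects=clean.n_subjects,
        retained_loci=clean.n_loci,
        candidate_loci=[l.locus_id for l in clean.loci],
        protocol_threshold=cfg.protocol_threshold,
    )
    report.check_conservation()
    return clean, clean_groupings, report
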