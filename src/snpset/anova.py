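"""Per-locus one-way ANOVA of the residual phenotype across genotype groups.

Each locus is tested on its complete cases (subjects with a call there), so
group sizes vary across loci.  Loci passing the uncorrected p < alpha screen
feed the regression stage; family-wise error control is deferred to the
whole-procedure permutation test, so no multiplicity correction is applied
here.  Post hoc pairwise contrasts use Fisher's LSD protected by the omnibus
screen (Tukey's HSD available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .qc import GenotypeGrouping
from .types import GenotypeMatrix


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class PairContrast:
    """A significant pairwise contrast: mean(low) < mean(high)."""

    low: str
    high: str
    p: float

    def __str__(self) -> str:
        return f"{self.low} < {self.high}"


@dataclass
class AnovaResult:
    locus_id: str
    groups: list[GroupSummary]
    f: float
    df_between: int
    df_within: int
    p: float
    untestable: bool = False
    posthoc: list[PairContrast] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(g.n for g in self.groups)


def one_way_anova(residuals: np.ndarray, grouping: GenotypeGrouping) -> AnovaResult:
    """Standard one-way decomposition at one locus.

    ``residuals`` is aligned to the subject order of the genotype matrix the
    grouping was built from; subjects without a call at this locus are
    dropped for this locus only.
    """
    if grouping.excluded:
        raise ValueError(f"{grouping.locus_id} was excluded by QC")
    y = np.asarray(residuals, float)
    m = grouping.membership
    k = grouping.n_groups
    groups, values = [], []
    for g in range(k):
        yg = y[m == g]
        groups.append(
            GroupSummary(
                label=grouping.labels[g],
                mean=float(yg.mean()) if len(yg) else float("nan"),
                sd=float(yg.std(ddof=1)) if len(yg) > 1 else float("nan"),
                n=len(yg),
            )
        )
        values.append(yg)
    nonempty = [v for v in values if len(v)]
    if len(nonempty) < 2:
        return AnovaResult(grouping.locus_id, groups, float("nan"), 0, 0,
                           float("nan"), untestable=True)
    yy = np.concatenate(nonempty)
    grand = yy.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in nonempty)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in nonempty)
    df1 = len(nonempty) - 1
    df2 = len(yy) - len(nonempty)
    if df2 <= 0 or ssw == 0:
        f = float("inf") if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return AnovaResult(grouping.locus_id, groups, f, df1, max(df2, 0), p)
    f = (ssb / df1) / (ssw / df2)
    return AnovaResult(
        grouping.locus_id, groups, float(f), df1, df2, float(stats.f.sf(f, df1, df2))
    )


def anova_from_summary(
    means: np.ndarray, sds: np.ndarray, ns: np.ndarray
) -> tuple[float, int, int]:
    """Reconstruct the one-way F from per-group means, SDs and sizes.

    Algebraically identical to the raw-data ANOVA, which makes it an oracle
    for published per-group summary tables.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if len(means) < 2:
        raise ValueError("need at least two groups")
    if (ns < 2).any():
        raise ValueError("every group needs n >= 2 (SD undefined otherwise)")
    n = ns.sum()
    grand = (ns * means).sum() / n
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df1, df2 = len(means) - 1, int(n - len(means))
    if ssw == 0:
        return (float("inf") if ssb > 0 else 0.0), df1, df2
    return float((ssb / df1) / (ssw / df2)), df1, df2


def post_hoc_pairs(
    residuals: np.ndarray,
    grouping: GenotypeGrouping,
    alpha: float = 0.05,
    method: str = "lsd",
) -> list[PairContrast]:
    """All pairwise group contrasts significant at ``alpha``, with direction.

    ``lsd``: Fisher's least-significant-difference t-tests on the pooled
    within-group variance (protected: call only for loci that passed the
    omnibus screen).  ``tukey``: studentized-range HSD.
    """
    if method not in {"lsd", "tukey"}:
        raise ValueError("method must be 'lsd' or 'tukey'")
    y = np.asarray(residuals, float)
    m = grouping.membership
    values = [y[m == g] for g in range(grouping.n_groups)]
    nonempty = [(lab, v) for lab, v in zip(grouping.labels, values) if len(v) > 0]
    if len(nonempty) < 2:
        return []
    n = sum(len(v) for _, v in nonempty)
    k = len(nonempty)
    df = n - k
    if df <= 0:
        return []
    msw = sum(((v - v.mean()) ** 2).sum() for _, v in nonempty) / df
    out: list[PairContrast] = []
    for i in range(k):
        for j in range(i + 1, k):
            la, va = nonempty[i]
            lb, vb = nonempty[j]
            se = np.sqrt(msw * (1 / len(va) + 1 / len(vb)))
            if se == 0:
                continue
            diff = va.mean() - vb.mean()
            if method == "lsd":
                t = diff / se
                p = 2 * stats.t.sf(abs(t), df)
            else:
                q = abs(diff) / (se / np.sqrt(2))
                p = stats.studentized_range.sf(q, k, df)
            if p < alpha:
                low, high = (la, lb) if diff < 0 else (lb, la)
                out.append(PairContrast(low=low, high=high, p=float(p)))
    return out


def screen_loci(
    gm: GenotypeMatrix,
    groupings: list[GenotypeGrouping],
    residuals: np.ndarray,
    alpha: float = 0.05,
    posthoc_method: str = "lsd",
) -> tuple[list[str], list[AnovaResult]]:
    """ANOVA every non-excluded locus and return the ids passing p < alpha
    (strict), in genomic order, plus all results for reporting.

    Post hoc contrasts are attached only to passing loci (protected tests).
    """
    from .qc import _genomic_order

    order = _genomic_order(gm.loci)
    by_id = {g.locus_id: g for g in groupings}
    results: list[AnovaResult] = []
    passing: list[str] = []
    for j in order:
        loc = gm.loci[j]
        g = by_id.get(loc.locus_id)
        if g is None or g.excluded:
            continue
        res = one_way_anova(residuals, g)
        if not res.untestable and res.p < alpha:
            res.posthoc = post_hoc_pairs(residuals, g, alpha, posthoc_method)
            passing.append(loc.locus_id)
        results.append(res)
    return passing, results
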