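"""Additive genotype coding and forward stepwise multiple regression.

Coding maps every genotype to {1, 2, 3} on an additive scale: major
homozygote 1, heterozygote 2, minor homozygote 3.  X-linked SNPs collapse to
{1, 3} (males by their single allele; female heterozygotes join the
minor-homozygote code, reflecting X-inactivation-style dominance of the
minor allele).  An X-linked VNTR follows the MAOA convention: the 3-repeat
allele codes 1 (males by allele, females only when 3-repeat homozygous) and
everything else codes 3.  Autosomal VNTRs are coded additively like SNPs.

Stepwise selection enters the candidate with the smallest partial-F p-value
while it is below the entry threshold and (optionally) removes entered
regressors whose p rises above the removal threshold, mirroring classic
stepwise linear regression.  Candidates that are collinear with the entered
set are skipped and tagged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import GenotypeMatrix, LocusRecord


# ---------------------------------------------------------------------------
# additive coding
# ---------------------------------------------------------------------------

def _repeat_number(label: str) -> int:
    m = re.match(r"(\d+)", label)
    if not m:
        raise ValueError(f"cannot parse repeat count from VNTR allele {label!r}")
    return int(m.group(1))


def code_locus(
    locus: LocusRecord,
    a1: np.ndarray,
    a2: np.ndarray,
    is_male: np.ndarray,
    minor_index: int,
) -> tuple[np.ndarray, str]:
    """Additive 1/2/3 coding for one locus; missing calls give NaN.

    Returns the coded vector and a provenance tag naming which rule fired.
    """
    n = len(a1)
    code = np.full(n, np.nan)
    missing = a1 < 0
    hemi = a2 == -2
    diploid = ~missing & ~hemi

    if locus.marker_kind == "VNTR" and locus.is_x:
        # MAOA rule: 1 for the low-repeat (3R) allele, 3 otherwise
        reps = [_repeat_number(a) for a in locus.allele_labels]
        low = int(np.argmin(reps))
        n_low = (a1 == low).astype(int) + np.where(diploid, (a2 == low), 0)
        code[hemi] = np.where(a1[hemi] == low, 1.0, 3.0)
        code[diploid] = np.where(n_low[diploid] == 2, 1.0, 3.0)
        if (diploid & is_male).any():
            raise ValueError(
                f"{locus.locus_id}: male diploid call at an X VNTR; "
                "normalize hemizygotes first"
            )
        return code, "x_vntr_maoa"

    minor_count = (a1 == minor_index).astype(int) + np.where(
        diploid, (a2 == minor_index), 0
    )
    if locus.is_x:
        # males 1/3 by hemizygous allele; females 1 for major-hom, else 3
        code[hemi] = np.where(a1[hemi] == minor_index, 3.0, 1.0)
        code[diploid] = np.where(minor_count[diploid] == 0, 1.0, 3.0)
        return code, "x_snp"

    code[diploid] = 1.0 + minor_count[diploid]
    return code, "autosomal_additive"


@dataclass
class CodedGenotypes:
    """Per-locus additive codes for a genotype matrix (NaN = missing)."""

    locus_ids: list[str]
    codes: np.ndarray  # subjects x loci, values in {1,2,3} or NaN
    provenance: dict[str, str]

    def columns(self, locus_ids: list[str]) -> np.ndarray:
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return self.codes[:, idx]


def code_genotypes(gm: GenotypeMatrix, minor: np.ndarray) -> CodedGenotypes:
    cols, prov = [], {}
    for j, loc in enumerate(gm.loci):
        c, tag = code_locus(loc, gm.a1[:, j], gm.a2[:, j], gm.is_male, int(minor[j]))
        cols.append(c)
        prov[loc.locus_id] = tag
    codes = np.column_stack(cols) if cols else np.empty((gm.n_subjects, 0))
    return CodedGenotypes([l.locus_id for l in gm.loci], codes, prov)


# ---------------------------------------------------------------------------
# forward stepwise regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    """Result of stepwise selection: the final OLS fit plus the entry path."""

    selected: list[str]  # in entry order
    coef_b: np.ndarray
    coef_t: np.ndarray
    coef_p: np.ndarray
    intercept: float
    r_squared: float
    adj_r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    n: int
    rejected: list[tuple[str, str]] = field(default_factory=list)
    path: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def f_p(self) -> float:
        """Naive overall-F p-value of the final model (ignores selection;
        anti-conservative after screening + stepwise -- see the permutation
        test for a calibrated alternative)."""
        if self.df_model == 0:
            return 1.0
        return float(stats.f.sf(self.f_stat, self.df_model, self.df_resid))

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regressor": self.selected,
                "B": self.coef_b,
                "T": self.coef_t,
                "p": self.coef_p,
            }
        )


def _empty_model(n: int, rejected: list[tuple[str, str]]) -> StepwiseModel:
    return StepwiseModel(
        selected=[],
        coef_b=np.empty(0),
        coef_t=np.empty(0),
        coef_p=np.empty(0),
        intercept=0.0,
        r_squared=0.0,
        adj_r_squared=0.0,
        f_stat=0.0,
        df_model=0,
        df_resid=max(n - 1, 0),
        n=n,
        rejected=rejected,
    )


def forward_stepwise(
    candidates: np.ndarray,
    names: list[str],
    y: np.ndarray,
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    allow_removal: bool = True,
    collinearity_tol: float = 1e-10,
) -> StepwiseModel:
    """Stepwise linear regression of ``y`` on columns of ``candidates``.

    Subjects with a missing code at any candidate are dropped up front
    (listwise deletion over the candidate set), fixing n for the whole
    selection path so that R-squared is comparable across steps.  At each
    step the candidate with the smallest partial-F p-value enters if that p
    is strictly below ``entry_alpha``; with ``allow_removal`` an entered
    regressor is removed again when its p exceeds ``removal_alpha``.  Ties
    break by candidate (genomic) order.  A candidate whose residual variance
    given the entered set is numerically zero is tagged as collinear and
    never enters, as is a constant column.
    """
    X = np.asarray(candidates, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("candidates must be (n_subjects, n_candidates)")
    m = X.shape[1]
    if m != len(names):
        raise ValueError("names length mismatch")

    complete = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    X, y = X[complete], y[complete]
    n = len(y)
    if m == 0:
        return _empty_model(n, [])
    if n < m + 3:
        raise ValueError(f"n={n} too small for {m} candidates")

    # centered Gram system: the intercept is implicit
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    G = Xc.T @ Xc
    g = Xc.T @ yc
    syy = float(yc @ yc)
    if syy == 0:
        return _empty_model(n, [])

    def rss(sel: list[int]) -> float:
        if not sel:
            return syy
        b = np.linalg.solve(G[np.ix_(sel, sel)], g[sel])
        return max(syy - float(b @ g[sel]), 0.0)

    selected: list[int] = []
    collinear: set[int] = set()
    rejected: list[tuple[str, str]] = []
    path: list[tuple[str, str, float]] = []
    max_steps = 4 * m + 10

    for _ in range(max_steps):
        rss_cur = rss(selected)
        df_new = n - len(selected) - 2
        if df_new <= 0:
            break
        rest = np.asarray(
            [j for j in range(m) if j not in selected and j not in collinear],
            dtype=int,
        )
        if len(rest) == 0:
            break
        # one block solve gives every candidate's residual variance and
        # partial covariance with y given the entered set
        if selected:
            rhs = np.concatenate([G[np.ix_(selected, rest)], g[selected, None]], axis=1)
            W = np.linalg.solve(G[np.ix_(selected, selected)], rhs)
            Gsr = G[np.ix_(selected, rest)]
            resid_var = G[rest, rest] - np.einsum("sr,sr->r", Gsr, W[:, :-1])
            cov = g[rest] - Gsr.T @ W[:, -1]
        else:
            resid_var = G[rest, rest].copy()
            cov = g[rest].copy()
        bad = resid_var <= collinearity_tol * np.maximum(G[rest, rest], 1e-300)
        for j in rest[bad]:
            collinear.add(int(j))
            rejected.append(
                (names[j], "constant" if G[j, j] <= 0 else "collinearity")
            )
        ok = ~bad
        if not ok.any():
            continue
        rest, resid_var, cov = rest[ok], resid_var[ok], cov[ok]
        rss_new = np.maximum(rss_cur - cov**2 / resid_var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_part = (rss_cur - rss_new) / (rss_new / df_new)
        p_entry = np.where(
            rss_new > 0, special.fdtrc(1.0, float(df_new), f_part), 0.0
        )
        best = int(np.argmin(p_entry))  # ties: earliest genomic order
        best_p = float(p_entry[best])
        if best_p >= entry_alpha:
            break
        best_j = int(rest[best])
        selected.append(best_j)
        path.append((names[best_j], "enter", best_p))

        if allow_removal and len(selected) > 1:
            while len(selected) > 1:
                _, _, p_vals = _fit_subset(G, g, syy, n, selected)
                worst = int(np.argmax(p_vals))
                if p_vals[worst] > removal_alpha:
                    j_out = selected.pop(worst)
                    path.append((names[j_out], "remove", float(p_vals[worst])))
                else:
                    break

    if not selected:
        for j in range(m):
            if j not in collinear:
                rejected.append((names[j], "entry p above threshold"))
        return _empty_model(n, rejected)

    b, t_vals, p_vals = _fit_subset(G, g, syy, n, selected)
    rss_final = rss(selected)
    k = len(selected)
    r2 = 1.0 - rss_final / syy
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    f_stat = (r2 / k) / ((1.0 - r2) / (n - k - 1)) if r2 < 1.0 else float("inf")
    for j in range(m):
        if j not in selected and j not in collinear:
            rejected.append((names[j], "entry p above threshold"))
    return StepwiseModel(
        selected=[names[j] for j in selected],
        coef_b=b,
        coef_t=t_vals,
        coef_p=p_vals,
        intercept=float(ym - b @ xm[selected]),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        f_stat=float(f_stat),
        df_model=k,
        df_resid=n - k - 1,
        n=n,
        rejected=rejected,
        path=path,
    )


def _fit_subset(
    G: np.ndarray, g: np.ndarray, syy: float, n: int, sel: list[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS coefficients, t and p for the centered subset model."""
    Gs = G[np.ix_(sel, sel)]
    gs = g[sel]
    b = np.linalg.solve(Gs, gs)
    rss = max(syy - float(b @ gs), 0.0)
    df = n - len(sel) - 1
    sigma2 = rss / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(Gs)
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_vals = b / se
    p_vals = 2.0 * special.stdtr(df, -np.abs(t_vals))
    return b, t_vals, p_vals
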