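"""Selection-aware resampling inference for the stepwise model's R^2.

Stepwise selection after a per-locus screen invalidates the naive F-test of
the final model: the same data choose the regressors and judge them.  The
remedy implemented here re-runs the *entire* procedure — ANOVA screening,
additive coding, stepwise selection, R^2 — inside every permutation and
bootstrap replicate, so the empirical null and the confidence interval both
embody the selection.

``ProcedureEngine`` precomputes sparse group-membership matrices from the
(genotype-determined, hence resampling-invariant) groupings so that the
per-locus ANOVA screen is a pair of sparse matrix products batched across
all permutations at once; only the small stepwise fits run per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, special

from .model import StepwiseModel, code_genotypes, forward_stepwise
from .qc import GenotypeGrouping, _genomic_order, minor_allele_index
from .types import GenotypeMatrix


class ProcedureEngine:
    """Screen + code + stepwise as one reusable, vectorizable unit.

    Groupings (merge maps) are held fixed across replicates: they depend
    only on genotypes, which permutation never touches.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        groupings: list[GenotypeGrouping],
        screen_alpha: float = 0.05,
        entry_alpha: float = 0.05,
        removal_alpha: float = 0.10,
        allow_removal: bool = True,
    ):
        self.screen_alpha = screen_alpha
        self.entry_alpha = entry_alpha
        self.removal_alpha = removal_alpha
        self.allow_removal = allow_removal
        n = gm.n_subjects

        by_id = {g.locus_id: g for g in groupings}
        order = _genomic_order(gm.loci)
        self.active = [
            by_id[gm.loci[j].locus_id]
            for j in order
            if gm.loci[j].locus_id in by_id and not by_id[gm.loci[j].locus_id].excluded
        ]
        self.locus_ids = [g.locus_id for g in self.active]
        L = len(self.active)

        rows_m, cols_m, group_locus = [], [], []
        rows_c, cols_c = [], []
        g_row = 0
        for l, g in enumerate(self.active):
            members = g.membership
            for k in range(g.n_groups):
                idx = np.flatnonzero(members == k)
                rows_m.extend([g_row] * len(idx))
                cols_m.extend(idx.tolist())
                group_locus.append(l)
                g_row += 1
            called = np.flatnonzero(members >= 0)
            rows_c.extend([l] * len(called))
            cols_c.extend(called.tolist())
        G = g_row
        self.M = sparse.csr_matrix(
            (np.ones(len(rows_m)), (rows_m, cols_m)), shape=(G, n)
        )
        self.C = sparse.csr_matrix(
            (np.ones(len(rows_c)), (rows_c, cols_c)), shape=(L, n)
        )
        self.A = sparse.csr_matrix(
            (np.ones(G), (group_locus, np.arange(G))), shape=(L, G)
        )
        coded = code_genotypes(gm, minor_allele_index(gm))
        self.codes = coded.codes[:, [coded.locus_ids.index(l) for l in self.locus_ids]]
        self.n = n

    # -- screening ------------------------------------------------------
    def screen_batch(
        self, Y: np.ndarray, W: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized per-locus one-way ANOVA over B phenotype columns.

        ``Y`` is (n, B); optional ``W`` holds non-negative integer subject
        weights per column (bootstrap multiplicities).  Returns (p, pass)
        arrays of shape (L, B); loci untestable in a replicate never pass.
        """
        if Y.ndim == 1:
            Y = Y[:, None]
        if W is None:
            P, Q = Y, Y * Y
            grp_cnt = np.asarray(self.M.sum(axis=1))  # (G,1)
            loc_n = np.asarray(self.C.sum(axis=1))  # (L,1)
            s = self.M @ P
            grp_nonzero = grp_cnt > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(grp_nonzero, s * s / grp_cnt, 0.0)
            k_eff = (self.A @ grp_nonzero.astype(float)).astype(int)
            k_eff = np.broadcast_to(k_eff, (len(self.active), Y.shape[1]))
            loc_n = np.broadcast_to(loc_n, k_eff.shape)
        else:
            P, Q = W * Y, W * Y * Y
            grp_cnt = self.M @ W
            loc_n = self.C @ W
            s = self.M @ P
            grp_nonzero = grp_cnt > 0
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(grp_nonzero, s * s / np.where(grp_nonzero, grp_cnt, 1), 0.0)
            k_eff = self.A @ grp_nonzero.astype(float)
        loc_s = self.C @ P
        loc_q = self.C @ Q
        with np.errstate(invalid="ignore", divide="ignore"):
            ssb = self.A @ ratio - loc_s**2 / loc_n
            sst = loc_q - loc_s**2 / loc_n
        ssw = np.maximum(sst - ssb, 0.0)
        ssb = np.maximum(ssb, 0.0)
        df1 = k_eff - 1
        df2 = loc_n - k_eff
        testable = (df1 >= 1) & (df2 >= 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ssb / df1) / (ssw / df2)
        p = np.ones_like(f)
        ok = testable & (ssw > 0) & np.isfinite(f)
        p[ok] = special.fdtrc(df1[ok].astype(float), df2[ok].astype(float), f[ok])
        # zero within-group variance with real between-group spread: p -> 0
        p[testable & (ssw == 0) & (ssb > 0)] = 0.0
        passing = testable & (p < self.screen_alpha)
        return p, passing

    # -- the whole procedure on one phenotype vector ---------------------
    def run(
        self,
        y: np.ndarray,
        subject_index: np.ndarray | None = None,
        passing: np.ndarray | None = None,
        entry_alpha: float | None = None,
        allow_removal: bool | None = None,
    ) -> StepwiseModel:
        """Screen (unless a precomputed passing mask is given), then code and
        stepwise-fit.  ``subject_index`` resamples subjects (bootstrap)."""
        if passing is None:
            if subject_index is None:
                _, passing = self.screen_batch(y[:, None])
            else:
                w = np.bincount(subject_index, minlength=self.n).astype(float)
                _, passing = self.screen_batch(y[:, None], w[:, None])
            passing = passing[:, 0]
        sel = np.flatnonzero(passing)
        if subject_index is None:
            X, yy = self.codes[:, sel], y
        else:
            X, yy = self.codes[np.asarray(subject_index)][:, sel], y[subject_index]
        names = [self.locus_ids[j] for j in sel]
        return forward_stepwise(
            X,
            names,
            yy,
            entry_alpha=self.entry_alpha if entry_alpha is None else entry_alpha,
            removal_alpha=self.removal_alpha,
            allow_removal=self.allow_removal if allow_removal is None else allow_removal,
        )


def run_full_procedure(
    gm: GenotypeMatrix,
    groupings: list[GenotypeGrouping],
    residuals: np.ndarray,
    screen_alpha: float = 0.05,
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    allow_removal: bool = True,
) -> StepwiseModel:
    """One entry point for the whole procedure (screen -> code -> stepwise),
    used identically for observed, permuted and bootstrap data."""
    eng = ProcedureEngine(
        gm, groupings, screen_alpha, entry_alpha, removal_alpha, allow_removal
    )
    return eng.run(np.asarray(residuals, float))


# ---------------------------------------------------------------------------
# permutation
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Empirical null of R^2 from whole-procedure phenotype permutation."""

    n_perm: int
    observed_r2: float
    observed_adj_r2: float
    null_r2: np.ndarray
    null_adj_r2: np.ndarray
    n_degenerate: int  # replicates where no locus passed the screen
    seed: int
    tie_convention: str = "strict"

    @property
    def p_r2_strict(self) -> float:
        return float((self.null_r2 > self.observed_r2).mean())

    @property
    def p_adj_r2_strict(self) -> float:
        return float((self.null_adj_r2 > self.observed_adj_r2).mean())

    @property
    def p_r2_addone(self) -> float:
        return float(((self.null_r2 >= self.observed_r2).sum() + 1) / (self.n_perm + 1))

    @property
    def p_adj_r2_addone(self) -> float:
        return float(
            ((self.null_adj_r2 >= self.observed_adj_r2).sum() + 1) / (self.n_perm + 1)
        )

    @property
    def p_r2(self) -> float:
        return self.p_r2_strict if self.tie_convention == "strict" else self.p_r2_addone

    @property
    def p_adj_r2(self) -> float:
        return (
            self.p_adj_r2_strict
            if self.tie_convention == "strict"
            else self.p_adj_r2_addone
        )


def _spawned_rngs(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def permutation_test(
    gm: GenotypeMatrix,
    groupings: list[GenotypeGrouping],
    residuals: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    tie_convention: str = "strict",
    engine: ProcedureEngine | None = None,
    **procedure_kwargs,
) -> PermutationResult:
    """Whole-procedure permutation test of the model's variance explained.

    The residual phenotype vector is shuffled across subjects while
    genotypes stay fixed; screening and stepwise selection are redone per
    shuffle, so the null distribution of R^2 carries the full selection
    bias.  The strict convention counts null draws strictly larger than the
    observed value; the add-one convention (never exactly zero) is always
    available from the result.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tie_convention not in {"strict", "addone"}:
        raise ValueError("tie_convention must be 'strict' or 'addone'")
    y = np.asarray(residuals, float)
    eng = engine or ProcedureEngine(gm, groupings, **procedure_kwargs)
    observed = eng.run(y)

    perms = np.empty((eng.n, n_perm), dtype=int)
    for b, rng in enumerate(_spawned_rngs(seed, n_perm)):
        perms[:, b] = rng.permutation(eng.n)
    Y = y[perms]  # (n, n_perm)
    _, passing = eng.screen_batch(Y)
    null_r2 = np.zeros(n_perm)
    null_adj = np.zeros(n_perm)
    n_degen = 0
    for b in range(n_perm):
        if not passing[:, b].any():
            n_degen += 1
            continue
        m = eng.run(Y[:, b], passing=passing[:, b])
        null_r2[b] = m.r_squared
        null_adj[b] = m.adj_r_squared
    return PermutationResult(
        n_perm=n_perm,
        observed_r2=observed.r_squared,
        observed_adj_r2=observed.adj_r_squared,
        null_r2=null_r2,
        null_adj_r2=null_adj,
        n_degenerate=n_degen,
        seed=seed,
        tie_convention=tie_convention,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap CI for R^2 and adjusted R^2 (selection redone
    within each resample unless fixed_model)."""

    n_boot: int
    level: float
    r2_ci: tuple[float, float]
    adj_r2_ci: tuple[float, float]
    r2_draws: np.ndarray
    adj_r2_draws: np.ndarray
    n_degenerate: int
    seed: int
    fixed_model: bool = False


def bootstrap_ci(
    gm: GenotypeMatrix,
    groupings: list[GenotypeGrouping],
    residuals: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    fixed_model: bool = False,
    engine: ProcedureEngine | None = None,
    **procedure_kwargs,
) -> BootstrapResult:
    """Subject-level bootstrap of the whole procedure.

    Genotype rows and residuals are resampled jointly with replacement; by
    default screening and selection are redone in every resample (honest
    CI).  ``fixed_model=True`` instead refits only the observed model's
    loci, the optimistic variant."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a percentile CI")
    y = np.asarray(residuals, float)
    eng = engine or ProcedureEngine(gm, groupings, **procedure_kwargs)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2

    fixed_passing = None
    if fixed_model:
        _, obs_pass = eng.screen_batch(y[:, None])
        observed = eng.run(y, passing=obs_pass[:, 0])
        fixed_passing = np.asarray(
            [lid in set(observed.selected) for lid in eng.locus_ids]
        )

    idx_all = np.empty((n_boot, eng.n), dtype=int)
    for b, rng in enumerate(_spawned_rngs(seed, n_boot)):
        idx_all[b] = rng.integers(0, eng.n, eng.n)
    if not fixed_model:
        # batch the weighted screen: one sparse product for all resamples
        W = np.zeros((eng.n, n_boot))
        for b in range(n_boot):
            W[:, b] = np.bincount(idx_all[b], minlength=eng.n)
        Y = np.broadcast_to(y[:, None], (eng.n, n_boot))
        _, passing_all = eng.screen_batch(Y, W)

    r2 = np.zeros(n_boot)
    adj = np.zeros(n_boot)
    n_degen = 0
    for b in range(n_boot):
        idx = idx_all[b]
        if fixed_model:
            # plain OLS refit of the observed model's loci: no re-selection
            m = eng.run(
                y,
                subject_index=idx,
                passing=fixed_passing,
                entry_alpha=1.1,
                allow_removal=False,
            )
        else:
            m = eng.run(y, subject_index=idx, passing=passing_all[:, b])
        if not m.selected:
            n_degen += 1
        r2[b] = m.r_squared
        adj[b] = m.adj_r_squared
    return BootstrapResult(
        n_boot=n_boot,
        level=level,
        r2_ci=(float(np.percentile(r2, lo_q)), float(np.percentile(r2, hi_q))),
        adj_r2_ci=(float(np.percentile(adj, lo_q)), float(np.percentile(adj, hi_q))),
        r2_draws=r2,
        adj_r2_draws=adj,
        n_degenerate=n_degen,
        seed=seed,
        fixed_model=fixed_model,
    )


def null_summary(result: PermutationResult, n_bins: int = 25) -> pd.DataFrame:
    """Histogram table of the permutation null with the observed R^2 marked
    (the report's figure in tabular form)."""
    hi = max(float(result.null_r2.max(initial=0.0)), result.observed_r2, 1e-9)
    edges = np.linspace(0.0, hi * 1.0000001, n_bins + 1)
    counts, _ = np.histogram(result.null_r2, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "observed_r2": result.observed_r2,
        }
    )
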