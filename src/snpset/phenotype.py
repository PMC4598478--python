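"""Covariate screening and residualization of the volumetric phenotype.

Amygdala volume scales with head size and differs by sex, so the analysis
phenotype is the residual from an ordinary least-squares fit of volume on an
intercept, a sex indicator and intracranial volume (ICV).  State-affect
scores (Beck anxiety/depression inventories) are screened with the same
one-covariate F-test but excluded from the adjustment unless explicitly
requested.  Residual normality is summarized by bias-corrected skewness and
excess kurtosis plus a Kolmogorov-Smirnov distance whose p-value uses the
Lilliefors (estimated-parameters) null, obtained from a seeded Monte Carlo
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import PhenotypeTable


@dataclass(frozen=True)
class CovariateTest:
    """Simple-regression F-test of volume on one covariate."""

    covariate: str
    f: float
    df1: int
    df2: int
    p: float
    n: int
    untestable: bool = False


def _simple_f(y: np.ndarray, x: np.ndarray, name: str) -> CovariateTest:
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for a covariate F-test")
    if np.ptp(x) == 0:
        return CovariateTest(name, float("nan"), 1, n - 2, float("nan"), n, True)
    r = np.corrcoef(x, y)[0, 1]
    r2 = r * r
    if r2 >= 1.0 - 1e-12:  # perfect fit: F unbounded, p below machine floor
        return CovariateTest(name, float("inf"), 1, n - 2, 0.0, n)
    f = r2 * (n - 2) / (1.0 - r2)
    return CovariateTest(name, float(f), 1, n - 2, float(stats.f.sf(f, 1, n - 2)), n)


def covariate_screen(pheno: PhenotypeTable) -> dict[str, CovariateTest]:
    """One-at-a-time F-tests (df1=1, df2=n-2) of volume on sex, ICV and,
    where scored, BAI and BDI.  Each test uses that covariate's complete
    cases."""
    df = pheno.frame
    y = df["amygdala_volume"].to_numpy(float)
    out = {
        "sex": _simple_f(y, (df["sex"] == "M").to_numpy(float), "sex"),
        "icv": _simple_f(y, df["icv"].to_numpy(float), "icv"),
    }
    for col in ("bai", "bdi"):
        ok = df[col].notna().to_numpy()
        if ok.sum() >= 3:
            out[col] = _simple_f(y[ok], df.loc[ok, col].to_numpy(float), col)
    return out


@dataclass
class ResidualPhenotype:
    """Covariate-adjusted volume: the y of all downstream association tests."""

    subject_ids: list[str]
    residuals: np.ndarray
    intercept: float
    sex_coefficient: float | None
    icv_slope: float
    extra_coefficients: dict[str, float]
    skewness: float
    kurtosis_excess: float
    kurtosis_convention: str
    ks_stat: float
    ks_p: float

    def check_invariants(self, design: np.ndarray | None = None) -> None:
        scale = max(float(np.abs(self.residuals).max()), 1.0)
        assert abs(self.residuals.sum()) < 1e-8 * scale * len(self.residuals)
        if np.ptp(self.residuals) < 1e-8:
            return  # exact fit: orthogonality is vacuous at machine precision
        if design is not None:
            for col in design.T:
                if np.ptp(col) == 0:
                    continue
                r = np.corrcoef(col, self.residuals)[0, 1]
                assert abs(r) < 1e-8


def residualize_volume(
    pheno: PhenotypeTable,
    include_bai_bdi: bool = False,
    ks_monte_carlo: int = 10_000,
    ks_seed: int = 0,
) -> ResidualPhenotype:
    """OLS adjustment of volume for sex and ICV; residuals become the
    analysis phenotype.

    ``include_bai_bdi=True`` adds the affect scores as covariates for
    sensitivity analyses (rows without scores are then an error, since the
    residual must be defined for every subject).
    """
    df = pheno.frame
    y = df["amygdala_volume"].to_numpy(float)
    cols: dict[str, np.ndarray] = {}
    sex_ind = (df["sex"] == "M").to_numpy(float)
    has_sex = np.ptp(sex_ind) > 0
    if has_sex:
        cols["sex"] = sex_ind
    else:
        warnings.warn("sex has a single level; dropped from the adjustment",
                      stacklevel=2)
    icv = df["icv"].to_numpy(float)
    if np.ptp(icv) == 0:
        raise ValueError("ICV is constant; cannot residualize")
    cols["icv"] = icv
    if include_bai_bdi:
        for col in ("bai", "bdi"):
            if df[col].isna().any():
                raise ValueError(f"{col} requested as covariate but has missing rows")
            cols[col] = df[col].to_numpy(float)

    X = sm.add_constant(np.column_stack(list(cols.values())))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    fit = sm.OLS(y, X).fit()
    resid = np.asarray(fit.resid)
    names = list(cols.keys())
    params = dict(zip(names, fit.params[1:]))

    if np.ptp(resid) == 0 or len(resid) < 8:
        # degenerate (exact) fit: diagnostics undefined
        diag = (float("nan"),) * 4
    else:
        diag = normality_diagnostics(resid, n_mc=ks_monte_carlo, seed=ks_seed)
    rp = ResidualPhenotype(
        subject_ids=list(df["subject_id"]),
        residuals=resid,
        intercept=float(fit.params[0]),
        sex_coefficient=float(params["sex"]) if has_sex else None,
        icv_slope=float(params["icv"]),
        extra_coefficients={
            k: float(v) for k, v in params.items() if k not in {"sex", "icv"}
        },
        skewness=diag[0],
        kurtosis_excess=diag[1],
        kurtosis_convention="bias-corrected excess (Fisher)",
        ks_stat=diag[2],
        ks_p=diag[3],
    )
    rp.check_invariants(X[:, 1:])
    return rp


# ---------------------------------------------------------------------------
# normality diagnostics
# ---------------------------------------------------------------------------

_LILLIEFORS_TABLES: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_null_table(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Sorted Monte Carlo null distribution of the KS statistic for normal
    samples of size n with mean/SD estimated from the data (cached)."""
    key = (n, n_mc, seed)
    if key not in _LILLIEFORS_TABLES:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_mc, n))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        z.sort(axis=1)
        cdf = stats.norm.cdf(z)
        i = np.arange(1, n + 1)
        d_plus = (i / n - cdf).max(axis=1)
        d_minus = (cdf - (i - 1) / n).max(axis=1)
        _LILLIEFORS_TABLES[key] = np.sort(np.maximum(d_plus, d_minus))
    return _LILLIEFORS_TABLES[key]


def lilliefors_ks(
    x: np.ndarray, n_mc: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """KS distance to a normal with estimated mean/SD and its Lilliefors
    Monte Carlo p-value (add-one convention, so p is never exactly 0)."""
    x = np.asarray(x, float)
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    stat = float(stats.kstest(x, "norm", args=(mu, sd)).statistic)
    table = _lilliefors_null_table(len(x), n_mc, seed)
    n_ge = len(table) - np.searchsorted(table, stat, side="left")
    return stat, float((n_ge + 1) / (len(table) + 1))


def normality_diagnostics(
    residuals: np.ndarray, n_mc: int = 10_000, seed: int = 0
) -> tuple[float, float, float, float]:
    """(skewness, excess kurtosis, KS statistic, Lilliefors p).

    Skewness and kurtosis use the bias-corrected sample conventions;
    kurtosis is excess (normal = 0).
    """
    x = np.asarray(residuals, float)
    if len(x) < 8:
        raise ValueError("need at least 8 observations for diagnostics")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance residuals")
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    ks_stat, ks_p = lilliefors_ks(x, n_mc=n_mc, seed=seed)
    return skew, kurt, ks_stat, ks_p
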