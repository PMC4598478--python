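"""Report artifacts: per-locus ANOVA table, regression table, JSON summary,
permutation-null table and an optional null-histogram figure."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import AnovaResult
from .model import StepwiseModel
from .qc import QCReport
from .resample import BootstrapResult, PermutationResult, null_summary


def _posthoc_string(res: AnovaResult) -> str:
    """Compact direction string, e.g. ``"AA, AC < CC"`` when both contrasts
    share the same larger group."""
    if not res.posthoc:
        return ""
    highs = {c.high for c in res.posthoc}
    if len(highs) == 1:
        high = highs.pop()
        lows = sorted({c.low for c in res.posthoc})
        return f"{', '.join(lows)} < {high}"
    return "; ".join(str(c) for c in res.posthoc)


def anova_table(results: list[AnovaResult], passing: list[str]) -> pd.DataFrame:
    rows = []
    passed = set(passing)
    for r in results:
        row: dict = {"locus_id": r.locus_id}
        for k in range(3):
            g = r.groups[k] if k < len(r.groups) else None
            row[f"group{k + 1}"] = g.label if g else ""
            row[f"mean{k + 1}"] = g.mean if g else np.nan
            row[f"sd{k + 1}"] = g.sd if g else np.nan
            row[f"n{k + 1}"] = g.n if g else 0
        row.update(
            F=r.f,
            df_between=r.df_between,
            df_within=r.df_within,
            p=r.p,
            passed=r.locus_id in passed,
            posthoc=_posthoc_string(r),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def regression_table(model: StepwiseModel) -> pd.DataFrame:
    return model.table


def summary_dict(
    model: StepwiseModel,
    permutation: PermutationResult | None = None,
    bootstrap: BootstrapResult | None = None,
    qc_report: QCReport | None = None,
    extra: dict | None = None,
) -> dict:
    out: dict = {
        "r_squared": model.r_squared,
        "adj_r_squared": model.adj_r_squared,
        "f_stat": model.f_stat,
        "df_model": model.df_model,
        "df_resid": model.df_resid,
        "naive_model_p": model.f_p,
        "n": model.n,
        "selected": model.selected,
        "intercept": model.intercept,
        "rejected": [{"regressor": r, "reason": why} for r, why in model.rejected],
    }
    if permutation is not None:
        out["permutation"] = {
            "n_perm": permutation.n_perm,
            "p_r2_strict": permutation.p_r2_strict,
            "p_adj_r2_strict": permutation.p_adj_r2_strict,
            "p_r2_addone": permutation.p_r2_addone,
            "p_adj_r2_addone": permutation.p_adj_r2_addone,
            "tie_convention": permutation.tie_convention,
            "n_degenerate": permutation.n_degenerate,
            "seed": permutation.seed,
        }
    else:
        out["permutation"] = "not computed"
    if bootstrap is not None:
        out["bootstrap"] = {
            "n_boot": bootstrap.n_boot,
            "level": bootstrap.level,
            "r2_ci": list(bootstrap.r2_ci),
            "adj_r2_ci": list(bootstrap.adj_r2_ci),
            "n_degenerate": bootstrap.n_degenerate,
            "fixed_model": bootstrap.fixed_model,
            "seed": bootstrap.seed,
        }
    else:
        out["bootstrap"] = "not computed"
    if qc_report is not None:
        out["qc"] = qc_report.to_dict()
    if extra:
        out.update(extra)
    return out


def write_report(
    out_dir: str | Path,
    anova_results: list[AnovaResult],
    passing: list[str],
    model: StepwiseModel,
    permutation: PermutationResult | None = None,
    bootstrap: BootstrapResult | None = None,
    qc_report: QCReport | None = None,
    extra: dict | None = None,
    histogram: bool = False,
) -> dict[str, Path]:
    """Write every report artifact into ``out_dir``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    t1 = out_dir / "anova_screen.tsv"
    anova_table(anova_results, passing).to_csv(t1, sep="\t", index=False)
    paths["anova_screen"] = t1

    t2 = out_dir / "regression_model.tsv"
    regression_table(model).to_csv(t2, sep="\t", index=False)
    paths["regression_model"] = t2

    if permutation is not None:
        t3 = out_dir / "permutation_null.tsv"
        pd.DataFrame(
            {"r2": permutation.null_r2, "adj_r2": permutation.null_adj_r2}
        ).to_csv(t3, sep="\t", index=False)
        paths["permutation_null"] = t3
        t4 = out_dir / "null_histogram.tsv"
        null_summary(permutation).to_csv(t4, sep="\t", index=False)
        paths["null_histogram"] = t4
        if histogram:
            paths["null_histogram_png"] = _plot_null(permutation, out_dir)

    summary = summary_dict(model, permutation, bootstrap, qc_report, extra)
    t5 = out_dir / "summary.json"
    t5.write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    paths["summary"] = t5
    return paths


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _plot_null(permutation: PermutationResult, out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(permutation.null_r2, bins=30, density=True, histtype="step",
            linestyle="--", label="permutation null")
    ax.axvline(permutation.observed_r2, color="k", label="observed $R^2$")
    ax.set_xlabel("$R^2$")
    ax.set_ylabel("density")
    ax.legend()
    path = out_dir / "null_histogram.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
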