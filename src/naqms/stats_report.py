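"""Group-level nonparametric statistics and cohort summary tables.

Baseline differences between dysferlinopathy patients (DP) and healthy
volunteers (HV) are tested with the two-tailed Mann-Whitney U test,
correlations with Spearman's rank coefficient, and the cohort summary
mirrors the study-table layout (mean, SD, two-tailed p and the integer
percent group difference per variable).  Ties take average ranks
throughout; significance is two-tailed at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "mann_whitney",
    "spearman",
    "build_summary",
    "summary_to_markdown",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    variable: str
    mean_x: float
    sd_x: float
    n_x: int
    mean_y: float
    sd_y: float
    n_y: int
    u_statistic: float
    p_two_tailed: float
    p_exact: float | None
    p_asymptotic: float
    flagged: bool = False


@dataclass
class CorrelationResult:
    r_s: float
    p: float
    n: int
    flagged: bool = False


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney(x, y, variable: str = "") -> GroupComparison:
    """Two-tailed Mann-Whitney U comparison of two independent samples.

    The exact null distribution is used when the smaller group has <= 8
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.  Both p-values
    are reported when the exact one is computable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least three observations")

    if np.unique(np.concatenate([x, y])).size == 1:
        u = x.size * y.size / 2.0
        return GroupComparison(variable, float(x.mean()), float(x.std(ddof=1)),
                               x.size, float(y.mean()), float(y.std(ddof=1)),
                               y.size, u, 1.0, None, 1.0, flagged=True)

    ties = _has_ties(x, y)
    asym = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                              use_continuity=True)
    p_exact = None
    if not ties and max(x.size, y.size) <= 25:
        p_exact = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                           method="exact").pvalue)
    use_exact = p_exact is not None and min(x.size, y.size) <= 8
    p = p_exact if use_exact else float(asym.pvalue)
    return GroupComparison(
        variable=variable,
        mean_x=float(x.mean()), sd_x=float(x.std(ddof=1)), n_x=int(x.size),
        mean_y=float(y.mean()), sd_y=float(y.std(ddof=1)), n_y=int(y.size),
        u_statistic=float(asym.statistic), p_two_tailed=float(min(p, 1.0)),
        p_exact=p_exact, p_asymptotic=float(asym.pvalue),
    )


def spearman(x, y, alpha: float = ALPHA) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 4:
        raise ValueError("need at least four pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(r_s=np.nan, p=np.nan, n=int(x.size), flagged=True)
    res = stats.spearmanr(x, y)
    return CorrelationResult(r_s=float(res.statistic), p=float(res.pvalue),
                             n=int(x.size))


def build_summary(results: pd.DataFrame, group_col: str = "group",
                  hv_label: str = "HV", dp_label: str = "DP") -> pd.DataFrame:
    """Cohort summary table from a wide per-subject results frame.

    ``results`` has one row per subject, a group column and one numeric
    column per variable.  The output has one row per variable with group
    means/SDs, the Mann-Whitney U statistic and two-tailed p, and the
    integer percent difference 100*(mean_DP - mean_HV)/mean_HV.
    Variables missing in either group are kept with a note, never
    silently dropped.
    """
    if group_col not in results.columns:
        raise ValueError(f"missing group column {group_col!r}")
    hv = results[results[group_col] == hv_label]
    dp = results[results[group_col] == dp_label]
    if hv.empty or dp.empty:
        raise ValueError("both groups must be present")

    rows = []
    variables = [c for c in results.columns
                 if c != group_col and pd.api.types.is_numeric_dtype(results[c])]
    for var in variables:
        xv = hv[var].dropna().to_numpy()
        yv = dp[var].dropna().to_numpy()
        row = {"variable": var, "n_hv": xv.size, "n_dp": yv.size}
        if xv.size < 3 or yv.size < 3:
            row.update(mean_hv=np.nan, sd_hv=np.nan, mean_dp=np.nan, sd_dp=np.nan,
                       u_statistic=np.nan, p_two_tailed=np.nan,
                       percent_difference=np.nan, note="missing data")
            rows.append(row)
            continue
        cmp = mann_whitney(xv, yv, variable=var)
        pct = int(round(100.0 * (cmp.mean_y - cmp.mean_x) / cmp.mean_x))
        row.update(mean_hv=cmp.mean_x, sd_hv=cmp.sd_x,
                   mean_dp=cmp.mean_y, sd_dp=cmp.sd_y,
                   u_statistic=cmp.u_statistic, p_two_tailed=cmp.p_two_tailed,
                   percent_difference=pct, note="")
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def summary_to_markdown(summary: pd.DataFrame) -> str:
    """Render a build_summary frame as a small markdown table."""
    header = ("| variable | HV mean (SD) | DP mean (SD) | % diff | p (two-tailed) |",
              "|---|---|---|---|---|")
    lines = list(header)
    for var, r in summary.iterrows():
        if r.get("note"):
            lines.append(f"| {var} | - | - | - | {r['note']} |")
            continue
        lines.append(
            f"| {var} | {r['mean_hv']:.3g} ({r['sd_hv']:.2g})"
            f" | {r['mean_dp']:.3g} ({r['sd_dp']:.2g})"
            f" | {int(r['percent_difference']):+d}%"
            f" | {r['p_two_tailed']:.3g} |")
    return "\n".join(lines)
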