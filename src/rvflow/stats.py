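"""Cohort-level statistics: one-way ANOVA across severity groups and
Pearson correlation tables of flow metrics against clinical covariates.

Missing values are handled complete-case per analysis pair and the
per-analysis n is always reported.  No multiple-testing correction is
applied by default (each cell is judged at p < 0.05); a Benjamini-Hochberg
option exists for the correlation table but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult", "one_way_anova", "pearson", "correlation_table",
    "group_summary", "NAMED_SUBGROUPS",
]


@dataclass
class StatResult:
    statistic: float
    pvalue: float
    n: int
    df: tuple
    label: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.n < 3:
            raise ValueError("analysis n must be at least 3")


def one_way_anova(groups: Sequence[Sequence[float]], label: str = "anova") -> StatResult:
    """Classic one-way ANOVA F test across two or more groups.

    F = between-group mean square / within-group mean square on
    (k - 1, N - k) degrees of freedom.  The degenerate case of zero
    within-group variance everywhere with unequal means is reported as
    F = inf, p = 0 and flagged in ``note``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    k = len(arrs)
    N = sum(len(g) for g in arrs)
    df = (k - 1, N - k)
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssw == 0.0:
        if ssb == 0.0:
            return StatResult(0.0, 1.0, N, df, label, note="all values identical")
        return StatResult(float("inf"), 0.0, N, df, label,
                          note="zero within-group variance with unequal means")
    F = (ssb / df[0]) / (ssw / df[1])
    p = float(sps.f.sf(F, df[0], df[1]))
    return StatResult(float(F), p, N, df, label)


def pearson(x: Sequence[float], y: Sequence[float], label: str = "pearson") -> StatResult:
    """Pearson correlation with the two-sided t-based p-value.

    Pairs with a missing value in either variable are dropped; the
    complete-case n is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired samples of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return StatResult(float(res.statistic), float(res.pvalue), n, (n - 2,), label)


# named subgroup predicates mirroring the study's subgroup analyses
NAMED_SUBGROUPS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "tof_primary_repair": lambda df: df["group"].isin(
        ["severe_pr", "moderate_pr", "mild_pr"]) & df.get(
            "primary_repair", pd.Series(True, index=df.index)).astype(bool),
    "exercise_test": lambda df: df["group"].isin(
        ["severe_pr", "moderate_pr", "mild_pr"]) & df["vo2max"].notna(),
    "all": lambda df: pd.Series(True, index=df.index),
}


def correlation_table(
    table: pd.DataFrame,
    metrics: Sequence[str],
    covariates: Sequence[str],
    subgroup: str | Callable[[pd.DataFrame], pd.Series] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Pairwise Pearson table of flow metrics against covariates.

    Returns a long-format frame with one row per (metric, covariate) cell:
    r, p, complete-case n and a rendered ``p_display`` that shows "ns" for
    p >= 0.05.  An empty metric list yields an empty table.
    """
    for name in list(metrics) + list(covariates):
        if name not in table.columns:
            raise KeyError(f"column {name!r} not in cohort table")
    if subgroup is not None:
        pred = NAMED_SUBGROUPS[subgroup] if isinstance(subgroup, str) else subgroup
        sel = pred(table).astype(bool)
        sub = table.loc[sel]
        if len(sub) < 3:
            raise ValueError(f"subgroup leaves n={len(sub)} < 3 subjects")
    else:
        sub = table
    rows = []
    for m in metrics:
        for c in covariates:
            res = pearson(sub[m], sub[c], label=f"{m}~{c}")
            rows.append({"metric": m, "covariate": c, "r": res.statistic,
                         "p": res.pvalue, "n": res.n})
    out = pd.DataFrame(rows, columns=["metric", "covariate", "r", "p", "n"])
    if bh_correction and len(out):
        p = out["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in enumerate(order[::-1]):
            running = min(running, p[idx] * m / (m - rank))
            adj[idx] = running
        out["p_adj"] = adj
    pcol = "p_adj" if (bh_correction and len(out)) else "p"
    if len(out):
        out["p_display"] = [
            "ns" if pv >= 0.05 else (f"{pv:.3g}" if pv >= 1e-3 else "<0.001")
            for pv in out[pcol]
        ]
    else:
        out["p_display"] = pd.Series(dtype=str)
    return out


def group_summary(table: pd.DataFrame, metric: str) -> tuple[pd.DataFrame, StatResult]:
    """Per-group mean +/- SD and n for one metric, with the omnibus ANOVA.

    Pairwise claims ("highest in ...") are reported descriptively by rank
    of the group means; no post-hoc test is attached.
    """
    if metric not in table.columns:
        raise KeyError(f"unknown metric {metric!r}")
    rows = []
    samples = []
    for group, sub in table.groupby("group", sort=True):
        vals = sub[metric].dropna().to_numpy()
        if len(vals) >= 2:
            samples.append(vals)
        rows.append({"group": group, "n": len(vals),
                     "mean": float(np.mean(vals)) if len(vals) else np.nan,
                     "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan})
    summary = pd.DataFrame(rows).sort_values("mean", ascending=False).reset_index(drop=True)
    anova = one_way_anova(samples, label=f"anova:{metric}")
    return summary, anova
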