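"""Group-level inference on averaged connectivity parameters and behavior.

One-sample t tests across subjects decide which averaged coupling parameters
differ consistently from zero; the resulting p-values are corrected jointly
with the Benjamini-Hochberg step-up procedure at q = 0.05.  Behavioral
analyses follow the task conventions: trials without a response or with a
reaction time under 100 ms are discarded, condition effects are tested with
a one-way repeated-measures ANOVA (F = MS_condition / MS_condition-x-subject),
face-versus-shape performance with paired t tests, and brain-behavior
relations with Pearson correlations, again FDR-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "filter_trials",
    "one_sample_ttests",
    "fdr_bh",
    "rm_anova",
    "paired_ttest",
    "correlate_behavior",
    "behavior_summary",
]

FDR_Q = 0.05


@dataclass(frozen=True)
class TestReport:
    """Per-parameter test results with FDR-adjusted p-values."""

    table: pd.DataFrame  # columns: estimate, statistic, dof, p_raw, p_fdr, significant, degenerate

    def significant_parameters(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop unusable trials (no response, or RT < 100 ms); report the fraction."""
    required = {"responded", "rt"}
    if not required <= set(table.columns):
        raise ValueError(f"behavior table must contain columns {sorted(required)}")
    responded = table["responded"].astype(bool)
    fast = responded & (table["rt"] < 0.1)
    keep = responded & ~fast
    excluded_fraction = float((~keep).sum() / len(table)) if len(table) else 0.0
    return table[keep].copy(), excluded_fraction


def fdr_bh(p_values: np.ndarray, q: float = FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values and the rejection mask.

    Adjusted p of the j-th smallest raw p is min over k >= j of
    m * p_(k) / k, capped at 1; rejections are adjusted p < q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted, adjusted < q


def one_sample_ttests(bma_table: pd.DataFrame, q: float = FDR_Q) -> TestReport:
    """Two-sided one-sample t tests of each column against zero, FDR-corrected.

    Columns with zero variance have no defined statistic and are flagged
    ``degenerate``; they are left out of the FDR family.
    """
    if len(bma_table) < 3:
        raise ValueError("need at least 3 subjects")
    rows = {}
    for name in bma_table.columns:
        x = bma_table[name].to_numpy(dtype=float)
        degenerate = np.allclose(x.std(ddof=1), 0.0)
        if degenerate:
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = sps.ttest_1samp(x, 0.0)
        rows[name] = {
            "estimate": x.mean(),
            "statistic": t_stat,
            "dof": len(x) - 1,
            "p_raw": p,
            "degenerate": degenerate,
        }
    table = pd.DataFrame(rows).T
    table["p_fdr"] = np.nan
    table["significant"] = False
    testable = ~table["degenerate"].astype(bool)
    if testable.any():
        adj, reject = fdr_bh(table.loc[testable, "p_raw"].to_numpy(dtype=float), q)
        table.loc[testable, "p_fdr"] = adj
        table.loc[testable, "significant"] = reject
    return TestReport(table=table)


def rm_anova(values: pd.DataFrame | np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on a subjects-by-conditions table.

    F = MS_condition / MS_(condition x subject); returns (F, (df1, df2), p).
    """
    X = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("repeated-measures table must be complete")
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        return 0.0 if ss_cond == 0 else np.inf, (df1, df2), 1.0 if ss_cond == 0 else 0.0
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Standard paired t test; identical vectors return t = 0, p = 1, and a
    constant nonzero shift returns an infinite statistic (p = 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be one-dimensional and equally long")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    dof = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, dof, 1.0
        return float(np.sign(d.mean()) * np.inf), dof, 0.0
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    return t, dof, float(2 * sps.t.sf(abs(t), dof))


def correlate_behavior(
    bma_table: pd.DataFrame, behavior_summaries: pd.DataFrame, q: float = FDR_Q
) -> TestReport:
    """Pearson correlations of each parameter with each behavioral measure.

    Both tables are indexed by subject; the FDR family is the full
    parameter-by-measure grid.
    """
    common = bma_table.index.intersection(behavior_summaries.index)
    if len(common) < 3:
        raise ValueError("need at least 3 overlapping subjects")
    rows = {}
    for param in bma_table.columns:
        for measure in behavior_summaries.columns:
            x = bma_table.loc[common, param].to_numpy(dtype=float)
            y = behavior_summaries.loc[common, measure].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p, degenerate = np.nan, np.nan, True
            else:
                r, p = sps.pearsonr(x, y)
                degenerate = False
            rows[f"{param} ~ {measure}"] = {
                "estimate": r,
                "statistic": r,
                "dof": len(common) - 2,
                "p_raw": p,
                "degenerate": degenerate,
            }
    table = pd.DataFrame(rows).T
    table["p_fdr"] = np.nan
    table["significant"] = False
    testable = ~table["degenerate"].astype(bool)
    if testable.any():
        adj, reject = fdr_bh(table.loc[testable, "p_raw"].to_numpy(dtype=float), q)
        table.loc[testable, "p_fdr"] = adj
        table.loc[testable, "significant"] = reject
    return TestReport(table=table)


def behavior_summary(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-condition accuracy and mean RT from filtered trials."""
    if "subject" not in filtered.columns:
        filtered = filtered.assign(subject="sub-01")
    grouped = filtered.groupby(["subject", "condition"])
    out = grouped.agg(accuracy=("correct", "mean"), rt=("rt", "mean")).reset_index()
    return out.pivot(index="subject", columns="condition", values=["accuracy", "rt"])
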