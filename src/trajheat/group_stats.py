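"""Nonparametric group-comparison protocol for the feature table.

Per measure: group-wise descriptives (mean, sample SD), Shapiro-Wilk
normality screening within each group, a Kruskal-Wallis omnibus test
across the five groups (tie-corrected H referred to chi-square with
k-1 df), and Dunn pairwise contrasts adjusted with Benjamini-Hochberg
FDR.  WMH volumes are log(1+x)-transformed before testing; because the
Kruskal-Wallis statistic is rank-based, any strictly monotone
transform leaves H unchanged, so the transform matters only for the
descriptives and normality screening.

Observations are scan sessions by default (repeated measures per
subject); a subject-level sensitivity mode collapses each subject to
their mean first, since within-subject correlation inflates the
session-level type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from trajheat.profiles import GROUP_NAMES

__all__ = [
    "descriptives", "shapiro_wilk", "kruskal_wallis", "log1p_wmh",
    "fdr_adjust", "dunn_posthoc", "GroupStatsReport", "compute_report",
]

#: Measures analyzed by the full report; WMH is log(1+x)-transformed.
DEFAULT_MEASURES = ("csf_ml", "gm_ml", "wm_ml", "ct_mm", "wmh_ml")


def descriptives(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Per-group n, arithmetic mean and sample SD (n-1 denominator)."""
    if measure not in table.columns:
        raise KeyError(measure)
    rows = []
    for g, sub in table.groupby("group_code"):
        x = sub[measure].to_numpy(dtype=float)
        if x.size == 0:
            raise ValueError(f"empty group {g}")
        rows.append({
            "group_code": int(g),
            "group": GROUP_NAMES[int(g)],
            "n": int(x.size),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def shapiro_wilk(sample) -> float:
    """Shapiro-Wilk normality p-value (small p = non-normal)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    return float(st.shapiro(x).pvalue)


def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis test; returns (H, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical: H undefined (tie correction zero)")
    res = st.kruskal(*arrays)
    return float(res.statistic), len(arrays) - 1, float(res.pvalue)


def log1p_wmh(values):
    """Natural log(1 + x) for non-negative WMH volumes."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("WMH volumes must be non-negative")
    return np.log1p(x)


def fdr_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def dunn_posthoc(groups: dict[int, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank contrasts with BH-FDR adjustment.

    z-statistics use pooled mean ranks with the standard tie
    correction; returns one row per group pair.
    """
    codes = sorted(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in codes}
    pooled = np.concatenate([arrays[g] for g in codes])
    n = pooled.size
    ranks = st.rankdata(pooled)
    mean_rank: dict[int, float] = {}
    start = 0
    for g in codes:
        size = arrays[g].size
        mean_rank[g] = float(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))

    rows = []
    for a, b in combinations(codes, 2):
        na, nb = arrays[a].size, arrays[b].size
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * st.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p_raw"].to_numpy())
    return out


@dataclass
class GroupStatsReport:
    """Descriptives, normality screen, omnibus tests and contrasts."""

    descriptives: dict[str, pd.DataFrame]
    shapiro: pd.DataFrame  # columns: measure, group_code, p
    kruskal: pd.DataFrame  # columns: measure, H, df, p
    pairwise: dict[str, pd.DataFrame]
    unit: str = "session"


def compute_report(table: pd.DataFrame, measures=DEFAULT_MEASURES, *,
                   unit: str = "session") -> GroupStatsReport:
    """Run the full protocol on a feature table.

    ``unit='session'`` treats every scan as an observation (the
    default analysis level); ``unit='subject'`` first collapses to
    subject means as a repeated-measures sensitivity check.
    """
    if unit not in ("session", "subject"):
        raise ValueError("unit must be 'session' or 'subject'")
    df = table
    if unit == "subject":
        df = (table.groupby(["group_code", "subject_num"], as_index=False)
              [list(measures)].mean())

    desc: dict[str, pd.DataFrame] = {}
    sw_rows, kw_rows = [], []
    pairwise: dict[str, pd.DataFrame] = {}
    for measure in measures:
        work = df.copy()
        if measure == "wmh_ml":
            work[measure] = log1p_wmh(work[measure].to_numpy())
        desc[measure] = descriptives(df, measure)  # descriptives on raw scale
        groups = {int(g): sub[measure].to_numpy(dtype=float)
                  for g, sub in work.groupby("group_code")}
        for g, x in groups.items():
            try:
                p = shapiro_wilk(x)
            except ValueError:
                p = np.nan
            sw_rows.append({"measure": measure, "group_code": g, "p": p})
        h, dof, p = kruskal_wallis(*groups.values())
        kw_rows.append({"measure": measure, "H": h, "df": dof, "p": p})
        pairwise[measure] = dunn_posthoc(groups)
    return GroupStatsReport(desc, pd.DataFrame(sw_rows), pd.DataFrame(kw_rows),
                            pairwise, unit=unit)
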