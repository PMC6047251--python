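"""Repeated-measures ANOVA, Tukey post hoc tests, and Pearson correlations.

One-way within-subject ANOVA with the classical error term:
``F = MS_factor / MS_(factor x subject)`` on a balanced subject-by-level
table.  Tukey-adjusted pairwise comparisons reuse that error term through
the studentized range distribution.  An uncorrected p-value is the primary
output; a Greenhouse-Geisser-corrected p is also reported, labeled, for
readers who want a sphericity-robust version.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    p_gg: float         # Greenhouse-Geisser corrected
    eps_gg: float
    ms_error: float
    n_subjects: int
    n_levels: int


def _pivot(table: pd.DataFrame, subject: str, within: str, dv: str) -> pd.DataFrame:
    """Balanced subject x level matrix; regions sharing a level are averaged first."""
    agg = table.groupby([subject, within], observed=True)[dv].mean().reset_index()
    wide = agg.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        missing = [
            f"({s}, {l})" for s in wide.index for l in wide.columns
            if pd.isna(wide.loc[s, l])
        ]
        raise ValueError(f"unbalanced table; missing cells: {', '.join(missing)}")
    return wide


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of the levels."""
    k = wide.shape[1]
    S = np.cov(wide.T, ddof=1)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * grand**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def rm_anova(table: pd.DataFrame, within: str, dv: str = "strain",
             subject: str = "subject") -> AnovaResult:
    """One-way repeated-measures ANOVA on a long table.

    The within factor must have >= 2 levels present for every one of >= 3
    subjects (rows sharing a level within a subject are averaged first,
    e.g. the three anterior regions into one anterior value).
    """
    wide = _pivot(table, subject, within, dv)
    n, k = wide.shape
    if k < 2:
        raise ValueError("within factor needs >= 2 levels")
    if n < 3:
        raise ValueError(">= 3 subjects required")
    y = wide.to_numpy(dtype=float)
    grand = y.mean()
    ss_factor = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = ss_total - ss_factor - ss_subject
    df_num = k - 1
    df_den = (n - 1) * (k - 1)
    ms_factor = ss_factor / df_num
    ms_error = ss_error / df_den
    if ms_error <= 0:
        F = 0.0 if ms_factor <= 0 else np.inf
    else:
        F = ms_factor / ms_error
    if ss_factor <= 1e-300 * max(ss_total, 1.0):
        F = 0.0
    p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    eps = _gg_epsilon(y)
    p_gg = float(sps.f.sf(F, df_num * eps, df_den * eps)) if np.isfinite(F) else 0.0
    return AnovaResult(effect=within, F=float(F), df_num=df_num, df_den=df_den,
                       p=p, p_gg=p_gg, eps_gg=eps, ms_error=float(ms_error),
                       n_subjects=n, n_levels=k)


def tukey_posthoc(table: pd.DataFrame, within: str, dv: str = "strain",
                  subject: str = "subject") -> pd.DataFrame:
    """All pairwise level comparisons with studentized-range adjusted p.

    Uses the repeated-measures ANOVA error term (factor x subject mean
    square) rather than a pooled between-subject variance.
    """
    res = rm_anova(table, within, dv=dv, subject=subject)
    wide = _pivot(table, subject, within, dv)
    n = res.n_subjects
    k = res.n_levels
    means = wide.mean(axis=0)
    se = np.sqrt(res.ms_error / n)
    rows = []
    for a, b in combinations(wide.columns, 2):
        diff = float(means[a] - means[b])
        if se == 0:
            p_adj = 1.0 if abs(diff) == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, res.df_den))
        rows.append({"level_a": a, "level_b": b, "mean_diff": diff, "p_adj": min(1.0, p_adj)})
    return pd.DataFrame(rows)


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
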