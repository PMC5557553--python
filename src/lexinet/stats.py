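"""Statistical comparisons of end-of-phase communicative-success scores.

Replicate CS scores are compared across topologies with a one-way ANOVA
(equal variances checked by Bartlett's test; a violation is flagged but
does not block the ANOVA, which is still informative when group means are
far apart), followed by Tukey's honest-significance post-hoc test, and a
paired t-test for convergence checks between successive checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "BartlettResult",
    "TukeyPair",
    "PairedTResult",
    "one_way_anova",
    "bartlett_test",
    "tukey_hsd",
    "paired_t_test",
    "summarize",
    "score_table",
    "compare_topologies",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class BartlettResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class TukeyPair:
    group_a: int
    group_b: int
    mean_difference: float
    critical_value: float
    significant: bool


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("every group needs at least 2 values")
    return gs


def one_way_anova(groups) -> AnovaResult:
    """Standard between/within variance decomposition, F = MSB / MSW."""
    gs = _check_groups(groups)
    df1 = len(gs) - 1
    df2 = sum(len(g) for g in gs) - len(gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0:
        raise ValueError("degenerate groups: zero within-group variance")
    f = (ssb / df1) / (ssw / df2)
    return AnovaResult(F=float(f), df1=df1, df2=df2,
                       p=float(sps.f.sf(f, df1, df2)))


def bartlett_test(groups) -> BartlettResult:
    gs = _check_groups(groups)
    if any(np.var(g, ddof=1) == 0 for g in gs):
        raise ValueError("Bartlett's test requires positive group variances")
    chi2, p = sps.bartlett(*gs)
    return BartlettResult(chi2=float(chi2), df=len(gs) - 1, p=float(p))


def tukey_hsd(groups, alpha: float = 0.05) -> list[TukeyPair]:
    """All pairwise mean differences against the studentized-range
    critical value at ``alpha`` with (k, df_within) parameters."""
    gs = _check_groups(groups)
    k = len(gs)
    df_within = sum(len(g) for g in gs) - k
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    msw = ssw / df_within
    q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_within))
    out = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            diff = float(gs[i].mean() - gs[j].mean())
            # Tukey-Kramer standard error for possibly unequal group sizes
            se = np.sqrt(msw / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
            crit = q_crit * float(se)
            out.append(TukeyPair(group_a=i, group_b=j, mean_difference=diff,
                                 critical_value=crit,
                                 significant=bool(abs(diff) > crit)))
    return out


def paired_t_test(a, b) -> PairedTResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    if np.var(diffs, ddof=1) == 0:
        if np.allclose(diffs, 0):
            return PairedTResult(t=0.0, df=len(a) - 1, p=1.0)
        raise ValueError("degenerate paired t-test: constant nonzero "
                         "differences (zero variance)")
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(t=float(t), df=len(a) - 1, p=float(p))


def summarize(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation across replicates, per
    (condition, series, iteration)."""
    if frame.empty:
        raise ValueError("no trajectories to summarize")
    g = frame.groupby(["condition", "series", "iteration"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    return out


def score_table(frame: pd.DataFrame, series: str,
                iteration: int) -> pd.DataFrame:
    """End-of-phase scores: one row per (condition, replicate) at a
    checkpoint iteration."""
    sel = frame[(frame["series"] == series)
                & (frame["iteration"] == iteration)]
    if sel.empty:
        raise ValueError(f"no rows for series {series!r} at it {iteration}")
    return sel[["condition", "replicate", "value"]].reset_index(drop=True)


def compare_topologies(scores: pd.DataFrame,
                       alpha: float = 0.05) -> dict:
    """Omnibus comparison of CS scores across conditions.

    ``scores`` is a score_table frame.  Returns the ANOVA, the Bartlett
    check (flagged, never blocking) and the Tukey pairs, keyed by
    condition labels.
    """
    labels = sorted(scores["condition"].unique())
    groups = [scores.loc[scores["condition"] == c, "value"].to_numpy()
              for c in labels]
    anova = one_way_anova(groups)
    try:
        bartlett = bartlett_test(groups)
        equal_var_ok = bartlett.p >= alpha
    except ValueError:
        bartlett, equal_var_ok = None, False
    tukey = tukey_hsd(groups, alpha=alpha)
    return {
        "labels": labels,
        "anova": anova,
        "bartlett": bartlett,
        "equal_variances": equal_var_ok,
        "tukey": tukey,
    }
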