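"""Survival analysis, group comparisons, copy-number burden and cohort tables.

Kaplan-Meier estimation, the two-sided log-rank test and Cox proportional
hazards (Efron tie handling) are provided through lifelines; Fisher's exact
and Mann-Whitney U tests through scipy.  Fraction genome altered (FGA) is
the length fraction of copy-number segments that are flagged altered or have
|log2 ratio| at or above a threshold (default 0.2, the common copy-number
portal convention).  Cohort summary tables mirror the usual "n (p%)"
clinicopathologic layout, and risk-group reassignment applies the observed
upstaging of p53abn-like NSMP cases under the 2021 European risk schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimate",
    "km_at",
    "logrank_test",
    "cox_ph",
    "fisher_exact",
    "mann_whitney_u",
    "fraction_genome_altered",
    "cohort_summary",
    "RISK_GROUPS",
    "reassign_risk_group",
    "count_changes",
]

RISK_GROUPS = ("Low", "Intermediate", "High-intermediate", "High",
               "Advanced metastatic")


@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray          # distinct observed times (sorted)
    survival: np.ndarray       # S(t) at those times
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if len(s) and (np.any(s > 1 + 1e-12) or np.any(s < -1e-12)
                       or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival curve must be non-increasing in [0, 1]")


def _check_times(times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=np.float64)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    return t


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate, S(t) = prod(1 - d_i/n_i)."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    tt = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(tt).to_numpy()
    return KMCurve(times=tt, survival=surv,
                   at_risk=table["at_risk"].to_numpy(),
                   events=table["observed"].to_numpy())


def km_at(curve: KMCurve, t: float) -> float:
    """Survival probability at time t (step function, right continuous)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(times_a: Sequence[float], events_a: Sequence[int],
                 times_b: Sequence[float], events_b: Sequence[int]
                 ) -> tuple[float, float]:
    """Two-sided log-rank test; returns (chi2, p)."""
    ta, tb = _check_times(times_a), _check_times(times_b)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank statistic undefined with no events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_ph(df: pd.DataFrame, duration_col: str, event_col: str,
           covariates: Sequence[str]) -> pd.DataFrame:
    """Multivariate Cox proportional hazards via partial likelihood with
    Efron tie handling; returns hazard ratios with Wald CIs and p-values.

    Raises on constant covariates or absence of events; convergence failures
    propagate as lifelines errors.
    """
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} absent")
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    if df[event_col].sum() == 0:
        raise ValueError("no events present")
    cph = CoxPHFitter()
    cph.fit(df[[duration_col, event_col, *covariates]],
            duration_col=duration_col, event_col=event_col)
    out = cph.summary[["exp(coef)", "exp(coef) lower 95%",
                       "exp(coef) upper 95%", "p"]].copy()
    out.columns = ["hazard_ratio", "ci_lower", "ci_upper", "p"]
    return out


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; two-sided p by summing tables of
    probability <= the observed one.  Returns (sample odds ratio, p)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 nonnegative integers")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U rank test, two-sided.

    Exact null distribution when min(n, m) <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fraction_genome_altered(segments: pd.DataFrame,
                            threshold: float = 0.2) -> float:
    """Length fraction of the assayed genome in altered segments.

    A segment counts as altered when its ``altered_flag`` is set or
    |log2ratio| >= threshold.  Coordinates are half-open; overlapping
    segments on a chromosome are rejected.
    """
    if segments is None or len(segments) == 0:
        raise ValueError("empty segment table")
    seg = segments
    if np.any(seg["start"].to_numpy() >= seg["end"].to_numpy()):
        raise ValueError("segments must satisfy start < end")
    for _, chrom_df in seg.groupby("chrom"):
        s = chrom_df.sort_values("start")
        if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
            raise ValueError("overlapping segments")
    length = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    altered = (np.abs(seg["log2ratio"].to_numpy(dtype=float)) >= threshold)
    if "altered_flag" in seg.columns:
        altered |= seg["altered_flag"].to_numpy() != 0
    return float(length[altered].sum() / length.sum())


def _pct(n: int, total: int, decimals: int = 2) -> str:
    if total == 0:
        return "0 (0%)"
    q = Decimal(10) ** -decimals
    p = (Decimal(100) * Decimal(n) / Decimal(total)).quantize(q, ROUND_HALF_UP)
    return f"{n} ({p}%)"


def cohort_summary(records: pd.DataFrame, variables: Sequence[str],
                   by: str = "subtype", decimals: int = 2) -> pd.DataFrame:
    """Clinicopathologic summary: per-cell "n (p%)" with column percentages.

    Percentages are of each column's total (Unknown levels included in the
    total) and rounded half-up.  Layout mirrors the usual Table-1 style:
    a Total row, then one row per level of each variable.
    """
    if by not in records.columns:
        raise ValueError(f"grouping variable {by!r} absent")
    for v in variables:
        if v not in records.columns:
            raise ValueError(f"variable {v!r} absent")
    groups = sorted(records[by].dropna().unique().tolist())
    columns = ["Total"] + groups
    totals = {"Total": len(records),
              **{g: int((records[by] == g).sum()) for g in groups}}
    grand = totals["Total"]

    rows: list[tuple[str, str, dict]] = []
    rows.append(("Total", "", {
        "Total": str(grand),
        **{g: _pct(totals[g], grand, decimals) for g in groups},
    }))
    for v in variables:
        col = records[v].astype(object).where(records[v].notna(), "Unknown")
        for level in sorted(map(str, col.unique())):
            cells = {}
            in_level = col.astype(str) == level
            cells["Total"] = _pct(int(in_level.sum()), grand, decimals)
            for g in groups:
                n = int((in_level & (records[by] == g)).sum())
                cells[g] = _pct(n, totals[g], decimals)
            rows.append((v, level, cells))

    out = pd.DataFrame(
        [{"variable": var, "level": lev, **cells} for var, lev, cells in rows],
        columns=["variable", "level", *columns],
    )
    return out


def reassign_risk_group(current: str, refined_label: str,
                        myoinvasive: bool = True) -> tuple[str, bool]:
    """Re-risk a case as if p53abn when refined as p53abn-like NSMP.

    Low, Intermediate and High-intermediate move to High (the upstaging the
    p53abn subtype imposes under the 2021 European risk schema); High and
    Advanced metastatic are unchanged.  Tumors without myometrial invasion
    are not upstaged by p53abn status and keep their group.
    """
    if current not in RISK_GROUPS:
        raise ValueError(f"unknown risk group {current!r}")
    if refined_label != "p53abn-like NSMP":
        return current, False
    if not myoinvasive:
        return current, False
    if current in ("Low", "Intermediate", "High-intermediate"):
        return "High", True
    return current, False


def count_changes(cases: Iterable[tuple]) -> int:
    """Number of cases whose risk group changes.

    Each case is (current_risk, refined_label) or
    (current_risk, refined_label, myoinvasive)."""
    n = 0
    for case in cases:
        _, changed = reassign_risk_group(*case)
        n += changed
    return n
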