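"""Survival comparison of radscore risk groups, plus clinical group tests.

The Kaplan-Meier product-limit estimator and the two-group log-rank test
are implemented directly from their defining formulas (so tests can hold
them to exact-arithmetic oracles); `lifelines` serves as an independent
cross-check in the test suite. Clinical-table comparisons dispatch to the
conventional tests: chi-square (Fisher's exact when any expected cell is
below 5) for categorical variables, and Student's t (when both groups pass
a Shapiro normality check at alpha = 0.05) or Mann-Whitney U otherwise for
continuous ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["km_curve", "logrank_test", "compare_groups"]


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Returns one row per distinct observed time with the at-risk count,
    number of events and the survival estimate after that time.
    Right-censored observations (event = 0) leave S unchanged but reduce
    the subsequent at-risk counts.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no records")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    rows = []
    s = 1.0
    for t in uniq:
        at = times >= t
        n_at_risk = int(at.sum())
        d = int(events[times == t].sum())
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append(
            {"time": float(t), "at_risk": n_at_risk, "events": d, "survival": s}
        )
    return pd.DataFrame(rows)


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p, df = 1).

    At each distinct event time the observed group-A deaths are compared
    with their hypergeometric expectation; the statistic is
    (sum (O_A - E_A))^2 / sum V with
    V = d (n_A / n) (n_B / n) (n - d) / (n - 1).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    event_times = np.unique(
        np.concatenate([ta[ea == 1], tb[eb == 1]])
    )
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        n = na + nb
        da = int(ea[ta == t].sum())
        db = int(eb[tb == t].sum())
        d = da + db
        if n < 2 or d == 0:
            continue
        e_a = d * na / n
        o_minus_e += da - e_a
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def _categorical_test(a: pd.Series, b: pd.Series) -> tuple[str, float, float]:
    cats = sorted(set(a) | set(b))
    table = np.array(
        [[(a == c).sum() for c in cats], [(b == c).sum() for c in cats]], dtype=float
    )
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any() and table.shape == (2, 2):
        stat, p = stats.fisher_exact(table)
        return "fisher", float(stat), float(p)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(stat), float(p)


def _continuous_test(a: np.ndarray, b: np.ndarray) -> tuple[str, float, float]:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return "mannwhitney", float(len(a) * len(b) / 2.0), 1.0

    def _normal(x: np.ndarray) -> bool:
        if len(x) < 3 or np.all(x == x[0]):
            return False
        return stats.shapiro(x).pvalue > 0.05

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b)
        return "ttest", float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mannwhitney", float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str,
    kind: str = "auto",
) -> tuple[str, float, float]:
    """Two-group comparison of one clinical variable.

    Returns (test name, statistic, p). ``kind`` is 'categorical',
    'continuous' or 'auto' (inferred from the dtype).
    """
    groups = table[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"{group_col!r} must define exactly two groups")
    a = table.loc[table[group_col] == groups[0], variable].dropna()
    b = table.loc[table[group_col] == groups[1], variable].dropna()
    if a.empty or b.empty:
        raise ValueError("empty group")
    if kind == "auto":
        kind = (
            "continuous"
            if pd.api.types.is_numeric_dtype(table[variable])
            else "categorical"
        )
    if kind == "categorical":
        return _categorical_test(a, b)
    return _continuous_test(a.to_numpy(dtype=float), b.to_numpy(dtype=float))
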