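"""Cohort statistics: paired t, step-down Bonferroni (Holm), Pearson,
Dahlberg method error, and ICC reliability.

Tests are two-sided throughout. The ICC variant is ICC(3,1): two-way
mixed, single measure, consistency — the standard intra-examiner choice —
selectable via the ``variant`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    """One paired comparison in a multiple-testing family."""

    variable: str
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float
    t: float
    p_raw: float
    p_corrected: float
    significant: bool
    degenerate: bool = False


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t test; returns (t, p) with n-1 df.

    Zero variance of the differences is degenerate: returns (0.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return np.inf, 0.0
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)


def holm_correct(pvals) -> np.ndarray:
    """Step-down Bonferroni (Holm) correction.

    Sort ascending, multiply the i-th smallest by (m - i), enforce monotone
    non-decreasing corrected values, cap at 1, and return in input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def pearson(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p via the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def dahlberg_me(first, second) -> float:
    """Dahlberg method error: sqrt(sum d^2 / 2n) over repeated measurements."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape:
        raise ValueError("repeated measurements must have equal length")
    if a.size < 1:
        raise ValueError("need at least one pair")
    d = a - b
    return float(np.sqrt((d**2).sum() / (2.0 * d.size)))


def icc(session1, session2, variant: str = "icc3_1") -> float:
    """Intraclass correlation for two measurement sessions on the same objects.

    ``icc3_1``: two-way mixed effects, single measure, consistency:
    (MS_rows - MS_error) / (MS_rows + (k-1) MS_error) with k = 2.
    ``icc2_1``: two-way random, absolute agreement.
    """
    a = np.asarray(session1, dtype=float)
    b = np.asarray(session2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sessions must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 objects")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if np.isclose(ms_rows, 0.0):
        raise ValueError("zero between-object variance; ICC undefined")
    if variant == "icc3_1":
        return float((ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err))
    if variant == "icc2_1":
        denom = ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err)
        return float((ms_rows - ms_err) / denom)
    raise ValueError(f"unknown ICC variant {variant!r}")


def paired_family(
    table_t1: dict[str, np.ndarray],
    table_t2: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> list[TestResult]:
    """Paired t tests over a family of variables with Holm correction.

    ``table_t1`` / ``table_t2`` map variable name -> per-case values; keys
    must match and define the family ordering.
    """
    names = list(table_t1)
    if set(names) != set(table_t2):
        raise ValueError("T1 and T2 tables must share the same variables")
    raw = []
    stats_ = []
    for name in names:
        x, y = np.asarray(table_t1[name], float), np.asarray(table_t2[name], float)
        t, pv = paired_t(x, y)
        raw.append(pv)
        stats_.append((name, x, y, t, pv))
    corrected = holm_correct(raw)
    out = []
    for (name, x, y, t, pv), pc in zip(stats_, corrected):
        out.append(
            TestResult(
                variable=name,
                mean_t1=float(x.mean()),
                sd_t1=float(x.std(ddof=1)),
                mean_t2=float(y.mean()),
                sd_t2=float(y.std(ddof=1)),
                t=t,
                p_raw=pv,
                p_corrected=float(pc),
                significant=bool(pc < alpha),
                degenerate=bool(t == 0.0 and pv == 1.0),
            )
        )
    return out


def correlation_table(
    targets: dict[str, np.ndarray],
    predictors: dict[str, np.ndarray],
    alpha: float = 0.05,
):
    """All pairwise Pearson correlations target x predictor.

    Returns a dict ``(target, predictor) -> (r, p, significant)``; every
    cell is computed, the significance mask mirrors the publication habit
    of blanking non-significant cells.
    """
    out = {}
    for tname, tv in targets.items():
        for pname, pv in predictors.items():
            r, p = pearson(tv, pv)
            out[(tname, pname)] = (r, p, bool(p < alpha))
    return out
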