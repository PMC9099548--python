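"""Group-comparison statistics for clinico-pathological tables.

Categorical covariates are compared between the node-negative and
node-positive arms with the exact two-sided Fisher test, generalized to
r x c tables by full Freeman-Halton enumeration: the p-value is the total
probability of all tables with the observed margins whose hypergeometric
probability does not exceed that of the observed table (relative tolerance
1 + 1e-7, the de-facto reference convention).  Continuous covariates use
the Welch two-sample t test, computable directly from printed
mean/SD/n summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

ENUMERATION_LIMIT = 200
_REL_TOL = 1e-7


def _clean_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(t < 0):
        raise ValueError("contingency table entries must be non-negative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    return t


def _log_table_prob_const(rows: np.ndarray, cols: np.ndarray) -> float:
    n = rows.sum()
    return float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                 - gammaln(n + 1))


def _enum_tables(rows, cols):
    """Yield sum(gammaln(a_ij + 1)) over all tables with the given margins."""
    n_rows = len(rows)

    def fill_row(row_total, col_rem, j, acc):
        # enumerate one row's cells left to right
        if j == len(col_rem) - 1:
            if row_total <= col_rem[-1]:
                yield acc + gammaln(row_total + 1), [*col_rem[:-1],
                                                     col_rem[-1] - row_total]
            return
        remaining_capacity = sum(col_rem[j + 1:])
        lo = max(0, row_total - remaining_capacity)
        hi = min(row_total, col_rem[j])
        for a in range(lo, hi + 1):
            new_rem = list(col_rem)
            new_rem[j] -= a
            yield from fill_row(row_total - a, new_rem, j + 1, acc + gammaln(a + 1))

    def rec(i, col_rem, acc):
        if i == n_rows - 1:
            # last row forced by remaining column sums
            yield acc + gammaln(np.array(col_rem) + 1).sum()
            return
        for row_acc, new_rem in fill_row(rows[i], col_rem, 0, 0.0):
            yield from rec(i + 1, new_rem, acc + row_acc)

    yield from rec(0, list(cols), 0.0)


def fisher_exact_rxc(table) -> float:
    """Exact two-sided Fisher (Freeman-Halton) p-value for an r x c table.

    All-zero rows/columns are dropped first (provably p-invariant).  Tables
    with total n > 200 are rejected — enumeration is meant for the small
    tables of a matched clinical series.
    """
    t = _clean_table(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = int(rows.sum())
    if n > ENUMERATION_LIMIT:
        raise ValueError(
            f"table total {n} exceeds the enumeration limit "
            f"({ENUMERATION_LIMIT}); Fisher enumeration is for small tables"
        )
    const = _log_table_prob_const(rows, cols)
    logp_obs = const - float(gammaln(t + 1).sum())
    threshold = logp_obs + np.log1p(_REL_TOL)
    p = 0.0
    for cell_gammaln in _enum_tables(rows, cols):
        logp = const - float(cell_gammaln)
        if logp <= threshold:
            p += np.exp(logp)
    return min(p, 1.0)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t test from per-group summaries.

    Returns (t, Satterthwaite df, two-sided p); ``t = (mean2 - mean1) /
    sqrt(sd1^2/n1 + sd2^2/n2)``.  Identical summaries give t = 0, p = 1.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    se2 = v1 + v2
    if se2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.inf) * np.sign(mean2 - mean1), float(n1 + n2 - 2), 0.0
    t = (mean2 - mean1) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def format_p(p: float) -> str:
    """Journal-style rounding: 3 dp below 0.05, 2 dp below 0.2, else 1 dp;
    values under 0.001 print as "<0.001"."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    if p < 0.05:
        return f"{round(p, 3):g}"
    if p < 0.2:
        return f"{round(p, 2):g}"
    return f"{round(p, 1):g}"


@dataclass
class ComparisonReport:
    """Table-shaped group comparison: per-level counts and per-covariate p."""

    levels: pd.DataFrame   # covariate, level, n/pct or mean (SD) per group
    pvalues: pd.DataFrame  # covariate, test, p, p_formatted


def compare_groups(
    metadata: pd.DataFrame,
    group_col: str = "node_status",
    exclude: tuple[str, ...] = ("true_cluster",),
) -> ComparisonReport:
    """Compare every covariate between the two groups of ``group_col``.

    Categorical (non-numeric) covariates get a levels x groups contingency
    table and the exact Fisher test; numeric covariates get the Welch t
    test from per-group mean/SD/n.  Covariates with a single observed level
    are reported without a p-value.
    """
    groups = sorted(metadata[group_col].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    m1 = metadata[metadata[group_col] == g1]
    m2 = metadata[metadata[group_col] == g2]

    level_rows, p_rows = [], []
    for cov in metadata.columns:
        if cov == group_col or cov in exclude:
            continue
        series = metadata[cov]
        if pd.api.types.is_numeric_dtype(series):
            s1, s2 = m1[cov].dropna(), m2[cov].dropna()
            level_rows.append({
                "covariate": cov, "level": "",
                g1: f"{s1.mean():.1f} ({s1.std(ddof=1):.1f})",
                g2: f"{s2.mean():.1f} ({s2.std(ddof=1):.1f})",
            })
            if len(s1) >= 2 and len(s2) >= 2:
                _, _, p = welch_t_from_summary(
                    s1.mean(), s1.std(ddof=1), len(s1),
                    s2.mean(), s2.std(ddof=1), len(s2),
                )
                p_rows.append({"covariate": cov, "test": "welch_t",
                               "p": p, "p_formatted": format_p(p)})
            else:
                p_rows.append({"covariate": cov, "test": "welch_t",
                               "p": np.nan, "p_formatted": "NA"})
            continue

        levels = sorted(series.dropna().unique().tolist())
        table = np.array([
            [(m1[cov] == lv).sum(), (m2[cov] == lv).sum()] for lv in levels
        ])
        for lv, (c1, c2) in zip(levels, table):
            level_rows.append({
                "covariate": cov, "level": lv,
                g1: f"{c1} ({100 * c1 / len(m1):.1f})",
                g2: f"{c2} ({100 * c2 / len(m2):.1f})",
            })
        nonzero = table[table.sum(axis=1) > 0]
        if nonzero.shape[0] < 2:
            p_rows.append({"covariate": cov, "test": "fisher_exact",
                           "p": np.nan, "p_formatted": "NA"})
        else:
            p = fisher_exact_rxc(table)
            p_rows.append({"covariate": cov, "test": "fisher_exact",
                           "p": p, "p_formatted": format_p(p)})

    return ComparisonReport(pd.DataFrame(level_rows), pd.DataFrame(p_rows))
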