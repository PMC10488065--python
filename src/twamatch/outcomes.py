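"""Group-comparison tables and the acute-kidney-injury classifier.

Comparison tables follow the reporting conventions of perioperative
observational studies: quantitative variables are tested for normality
(Shapiro-Wilk) and summarized as mean (SD) with Student's unpaired
t-test when both groups pass, otherwise as median (IQR) with the
two-sided Mann-Whitney U-test; categorical variables are reported as
n (%) with Fisher's exact test.  Quartiles use linear interpolation
(type 7) throughout.  No multiple-testing adjustment is applied.

AKI is classified from the postoperative creatinine trajectory: a rise
of more than 0.3 mg/dL above the preoperative baseline within 48 h, or
a value at or above 1.5 times baseline within the first 7 postoperative
days (or until laboratory controls end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from twamatch.psm import smd_binary, smd_continuous

TEST_RANK_SUM = "rank-sum"
TEST_T = "t-test"
TEST_EXACT_COUNT = "exact-count"


@dataclass
class ComparisonRow:
    """One line of a group-comparison table (control column first)."""

    variable: str
    summary_a: str  # control group (e.g. non-HPI)
    summary_b: str  # treated group (e.g. HPI)
    test_used: str
    p_value: float
    smd: float  # signed, treated minus control


@dataclass
class AKIOutcome:
    patient_id: str
    baseline_creatinine: float
    max_postop_creatinine: float
    aki: bool
    criterion_met: str  # "delta48h" | "ratio7d" | "none"
    evaluable: bool = True


def choose_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
) -> str:
    """Pick the two-sample test: t-test iff Shapiro-Wilk accepts
    normality in BOTH groups at ``alpha_normality``, else rank-sum.

    Groups smaller than three force the rank-sum test (with a warning)
    since the normality test is undefined there.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(a.size, b.size) < 3:
        warnings.warn("group smaller than 3; falling back to rank-sum test")
        return TEST_RANK_SUM
    for sample in (a, b):
        if np.ptp(sample) == 0:
            return TEST_RANK_SUM  # degenerate sample: normality untestable
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.shapiro(sample).pvalue
        if not np.isfinite(p) or p < alpha_normality:
            return TEST_RANK_SUM
    return TEST_T


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value with mid-rank ties.

    Exact enumeration when the smaller group has at most 8 values and no
    ties are present; otherwise the normal approximation with continuity
    and tie correction.  Identical pooled values give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(1.0, res.pvalue))


def exact_count_test(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (hypergeometric
    tail sum over tables at most as probable as the observed one)."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    tab = tab.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        return 1.0
    return float(min(1.0, stats.fisher_exact(tab, alternative="two-sided")[1]))


def classify_aki(
    baseline: float,
    series: Sequence[tuple[float, float]],
    patient_id: str = "",
    delta_mg_dl: float = 0.3,
    ratio: float = 1.5,
    delta_window_h: float = 48.0,
    ratio_window_h: float = 168.0,
) -> AKIOutcome:
    """Classify AKI from a postoperative creatinine series.

    The absolute criterion (rise strictly greater than ``delta_mg_dl``
    within ``delta_window_h``) is checked first, then the relative
    criterion (value at or above ``ratio`` x baseline within
    ``ratio_window_h`` or until the series ends).  An empty series is
    unevaluable and reported as no AKI.
    """
    if baseline <= 0:
        raise ValueError("baseline creatinine must be positive")
    pts = [(float(h), float(v)) for h, v in series]
    if any(h < 0 for h, _ in pts):
        raise ValueError("hours must be non-negative")
    if not pts:
        return AKIOutcome(patient_id, baseline, float("nan"), False, "none", evaluable=False)
    max_post = max(v for _, v in pts)
    # tolerance keeps printed boundary values (e.g. 1.30 on baseline 1.0)
    # on the side their decimal arithmetic implies
    eps = 1e-9
    if any(h <= delta_window_h and v - baseline > delta_mg_dl + eps for h, v in pts):
        return AKIOutcome(patient_id, baseline, max_post, True, "delta48h")
    if any(h <= ratio_window_h and v >= ratio * baseline - eps for h, v in pts):
        return AKIOutcome(patient_id, baseline, max_post, True, "ratio7d")
    return AKIOutcome(patient_id, baseline, max_post, False, "none")


# ---------------------------------------------------------------------------
# table assembly


def format_count_percent(count: int, n: int) -> str:
    """Render a categorical cell as ``count (percent)`` with the percent
    computed on unrounded counts and printed to one decimal."""
    if n <= 0:
        return f"{count} (–)"
    return f"{count} ({100.0 * count / n:.1f})"


def _fmt(x: float) -> str:
    return f"{x:.3g}"


def _summary(values: np.ndarray, test_used: str) -> str:
    if test_used == TEST_T:
        return f"{_fmt(values.mean())} ({_fmt(values.std(ddof=1))})"
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7 linear interpolation
    return f"{_fmt(med)} ({_fmt(q1)}, {_fmt(q3)})"


def _is_binary_series(s: pd.Series) -> bool:
    if s.dtype == bool:
        return True
    vals = pd.unique(s.dropna())
    try:
        return len(vals) <= 2 and set(np.asarray(vals).astype(float)) <= {0.0, 1.0}
    except (TypeError, ValueError):
        return False


def build_comparison_table(
    cohort: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    group_col: str = "group",
    treated_label: str = "HPI",
    matched_ids: Optional[Sequence[str]] = None,
    alpha_normality: float = 0.05,
) -> list[ComparisonRow]:
    """One :class:`ComparisonRow` per variable (per level for
    multi-level categoricals, rendered as ``var=level``).

    ``cohort`` is indexed by patient id and carries the group column;
    ``matched_ids`` restricts the table to a matched subset.  Numeric
    variables get the normality-gated test, binary/categorical variables
    n (%) with Fisher's exact test; the SMD column uses the same pooled
    formulas as the balance diagnostics (signed treated minus control).
    """
    df = cohort.loc[list(matched_ids)] if matched_ids is not None else cohort
    is_t = df[group_col] == treated_label
    n_t, n_c = int(is_t.sum()), int((~is_t).sum())
    if variables is None:
        variables = [c for c in df.columns if c != group_col]

    rows: list[ComparisonRow] = []
    for name in variables:
        s = df[name]
        if _is_binary_series(s):
            rows.append(_binary_row(name, s.astype(float), is_t, n_t, n_c))
        elif s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            for level in sorted(s.unique(), key=str):
                rows.append(
                    _binary_row(f"{name}={level}", (s == level).astype(float), is_t, n_t, n_c)
                )
        else:
            a = s[~is_t].to_numpy(dtype=float)  # control
            b = s[is_t].to_numpy(dtype=float)  # treated
            test = choose_test(a, b, alpha_normality)
            if test == TEST_T:
                p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            else:
                p = rank_sum_test(a, b)
            if np.ptp(np.concatenate([a, b])) == 0:
                p = 1.0
            rows.append(
                ComparisonRow(
                    variable=name,
                    summary_a=_summary(a, test),
                    summary_b=_summary(b, test),
                    test_used=test,
                    p_value=p,
                    smd=smd_continuous(b, a),
                )
            )
    return rows


def _binary_row(
    name: str, ind: pd.Series, is_t: pd.Series, n_t: int, n_c: int
) -> ComparisonRow:
    k_t = int(ind[is_t].sum())
    k_c = int(ind[~is_t].sum())
    p = exact_count_test([[k_t, n_t - k_t], [k_c, n_c - k_c]])
    return ComparisonRow(
        variable=name,
        summary_a=format_count_percent(k_c, n_c),
        summary_b=format_count_percent(k_t, n_t),
        test_used=TEST_EXACT_COUNT,
        p_value=p,
        smd=smd_binary(k_t / n_t if n_t else 0.0, k_c / n_c if n_c else 0.0),
    )


def comparison_rows_to_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "summary_non_treated": r.summary_a,
                "summary_treated": r.summary_b,
                "test_used": r.test_used,
                "p_value": r.p_value,
                "smd": r.smd,
            }
            for r in rows
        ]
    )
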