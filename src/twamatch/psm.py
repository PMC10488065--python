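"""Propensity-score estimation, greedy caliper matching, balance checks.

The propensity score — the probability of receiving the treated
monitoring mode given baseline covariates — is estimated by a
maximum-likelihood logistic regression fitted with Newton/IRLS
iterations written out explicitly, so that pathological designs
(collinearity, perfect separation) surface as explicit, named errors
rather than silently diverged coefficients.

Matching is greedy 1:1 nearest-neighbor without replacement on the logit
of the propensity score, with a caliper expressed in standard deviations
of the logit score (the dominant convention in the matching literature;
a raw-probability caliper is available as an option).  Balance before
and after matching is quantified by standardized mean differences (SMD):
mean or proportion difference over the pooled standard deviation, with
|SMD| < 0.2 the usual adequacy criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from twamatch.errors import (
    MissingDataError,
    PerfectSeparationError,
    RankDeficientError,
)

#: Baseline covariates entering the propensity model and balance tables
#: (demographic, comorbidity, medication and intraoperative variables).
MATCHING_COVARIATES: tuple[str, ...] = (
    "age",
    "sex_male",
    "bsa",
    "bmi",
    "asa_class",
    "emergency",
    "chf",
    "copd",
    "diabetes",
    "hypertension",
    "ace_inhibitor",
    "beta_blocker",
    "ccb",
    "diuretic",
    "at1_antagonist",
    "preop_hb",
    "preop_creatinine",
    "surgical_approach",
    "duration_min",
    "epidural",
    "map_induction",
    "hr_induction",
    "spo2_induction",
)

_CATEGORICAL = ("asa_class", "surgical_approach")


@dataclass
class PropensityModel:
    coefficients: dict[str, float]
    fitted_scores: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float
    ids: Optional[np.ndarray] = None


@dataclass
class BalanceTable:
    """Per-covariate standardized mean differences (signed and absolute)."""

    table: pd.DataFrame  # index: covariate (or covariate=level); cols: smd, abs_smd

    @property
    def max_abs_smd(self) -> float:
        return float(self.table["abs_smd"].max())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BalanceTable(max_abs_smd={self.max_abs_smd:.3f}, n={len(self.table)})"


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]
    caliper: float
    caliper_width: float
    scale: str
    unmatched_treated: list[str]
    unmatched_control: list[str]
    balance_before: Optional[BalanceTable] = None
    balance_after: Optional[BalanceTable] = None
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list[str]:
        out: list[str] = []
        for t, c in self.pairs:
            out.extend((t, c))
        return out


def build_design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str] = MATCHING_COVARIATES
) -> pd.DataFrame:
    """Numeric design matrix for the propensity model.

    Booleans become 0/1 indicators; multi-level categoricals are expanded
    to per-level indicators with the first (reference) level dropped.
    """
    cols = []
    for name in covariates:
        if name not in cohort.columns:
            raise KeyError(f"covariate {name!r} not in cohort table")
        s = cohort[name]
        if name in _CATEGORICAL:
            levels = sorted(s.unique(), key=str)
            for level in levels[1:]:
                cols.append((s == level).astype(float).rename(f"{name}[{level}]"))
        elif s.dtype == bool:
            cols.append(s.astype(float))
        else:
            cols.append(s.astype(float))
    X = pd.concat(cols, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise MissingDataError(f"missing values in covariates: {bad}")
    return X


def _independent_columns(A: np.ndarray) -> list[int]:
    """Greedy maximal set of linearly independent columns."""
    keep: list[int] = []
    for j in range(A.shape[1]):
        trial = A[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return keep


def _separating_columns(X: np.ndarray, names: list[str], y: np.ndarray) -> list[str]:
    """Columns that individually (quasi-)separate the two groups."""
    out = []
    for j, name in enumerate(names):
        xt, xc = X[y == 1, j], X[y == 0, j]
        if np.ptp(X[:, j]) == 0:
            continue
        if xt.min() >= xc.max() or xc.min() >= xt.max():
            out.append(name)
    return out


def fit_propensity(
    covariates: pd.DataFrame | np.ndarray,
    treated: Sequence[bool],
    tolerance: float = 1e-8,
    max_iter: int = 100,
) -> PropensityModel:
    """Maximum-likelihood logistic regression via Newton/IRLS.

    ``covariates`` must be fully observed and pre-expanded to numeric
    columns (see :func:`build_design_matrix`); an intercept is added
    internally.  Convergence means the gradient max-norm is at or below
    ``tolerance``; the log-likelihood is non-decreasing across iterations
    (step-halving).  Perfect separation and rank deficiency raise
    explicit errors naming the offending columns.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        ids = np.asarray(covariates.index).astype(str)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
        ids = None
    y = np.asarray(treated, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariates and treated have different lengths")
    if np.isnan(X).any():
        bad = [names[j] for j in np.flatnonzero(np.isnan(X).any(axis=0))]
        raise MissingDataError(f"missing values in covariates: {bad}")
    if not (0 < y.sum() < len(y)):
        raise ValueError("both treated and control units are required")

    Xd = np.column_stack([np.ones(len(y)), X])
    dnames = ["intercept"] + names
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        keep = _independent_columns(Xd)
        collinear = [dnames[j] for j in range(Xd.shape[1]) if j not in keep]
        raise RankDeficientError(collinear)

    beta = np.zeros(Xd.shape[1])

    def loglik(b: np.ndarray) -> float:
        eta = Xd @ b
        # log(1 + e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll = loglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        p = expit(eta)
        grad = Xd.T @ (y - p)
        if np.max(np.abs(grad)) <= tolerance:
            converged = True
            break
        w = p * (1.0 - p)
        H = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            raise PerfectSeparationError(
                _separating_columns(X, names, y.astype(int)) or names
            )
        # step-halving keeps the log-likelihood non-decreasing
        alpha = 1.0
        slack = 1e-12 * (1.0 + abs(ll))  # float noise near the optimum
        for _ in range(30):
            candidate = beta + alpha * step
            if loglik(candidate) >= ll - slack:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        ll = loglik(beta)
        # complete separation: the likelihood approaches its supremum of 0.
        # (Quasi-separation on a rare level merely drifts one coefficient
        # outward and is fit through, as standard GLM software does.)
        if ll > -1e-6:
            sep = _separating_columns(X, names, y.astype(int))
            raise PerfectSeparationError(sep or names)
    else:
        eta = Xd @ beta
        grad = Xd.T @ (y - expit(eta))
        converged = bool(np.max(np.abs(grad)) <= tolerance)

    scores = expit(Xd @ beta)
    if np.any(scores <= 0) or np.any(scores >= 1):
        sep = _separating_columns(X, names, y.astype(int))
        raise PerfectSeparationError(sep or names)
    return PropensityModel(
        coefficients=dict(zip(dnames, beta.tolist())),
        fitted_scores=scores,
        converged=converged,
        n_iterations=it,
        log_likelihood=ll,
        ids=ids,
    )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def match_caliper(
    model: PropensityModel,
    treated: Sequence[bool],
    caliper_sd: float = 0.1,
    order_rule: str = "descending",
    scale: str = "logit_sd",
    ids: Optional[Sequence[str]] = None,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    Treated units are processed in descending propensity (ties broken by
    ascending id); each takes the not-yet-matched control nearest in
    logit-score distance, provided the distance is within the caliper
    (``caliper_sd`` x SD of the logit scores by default, or a raw
    probability distance with ``scale='probability'``).  Deterministic.
    """
    if caliper_sd <= 0:
        raise ValueError("caliper_sd must be positive")
    if order_rule not in ("descending", "ascending"):
        raise ValueError("order_rule must be 'descending' or 'ascending'")
    y = np.asarray(treated, dtype=bool)
    scores = np.asarray(model.fitted_scores, dtype=float)
    if ids is None:
        ids = model.ids if model.ids is not None else np.arange(len(y)).astype(str)
    ids = np.asarray(ids).astype(str)
    if not y.any() or y.all():
        raise ValueError("matching requires non-empty treated and control groups")

    if scale == "logit_sd":
        metric = _logit(scores)
        width = caliper_sd * float(np.std(metric, ddof=1))
    elif scale == "probability":
        metric = scores
        width = caliper_sd
    else:
        raise ValueError("scale must be 'logit_sd' or 'probability'")
    if width == 0:  # all scores identical: any pairing is within caliper
        width = np.inf

    t_idx = np.flatnonzero(y)
    c_idx = np.flatnonzero(~y)
    sign = -1.0 if order_rule == "descending" else 1.0
    t_order = t_idx[np.lexsort((ids[t_idx], sign * scores[t_idx]))]

    available = dict.fromkeys(c_idx.tolist())  # insertion-ordered set
    pairs: list[tuple[str, str]] = []
    unmatched_treated: list[str] = []
    pair_scores: dict[str, float] = {}
    for ti in t_order:
        best_j, best_d = None, np.inf
        for cj in available:
            d = abs(metric[ti] - metric[cj])
            if d < best_d - 1e-15 or (
                abs(d - best_d) <= 1e-15 and (best_j is None or ids[cj] < ids[best_j])
            ):
                best_j, best_d = cj, d
        if best_j is not None and best_d <= width:
            pairs.append((ids[ti], ids[best_j]))
            pair_scores[ids[ti]] = float(scores[ti])
            pair_scores[ids[best_j]] = float(scores[best_j])
            del available[best_j]
        else:
            unmatched_treated.append(ids[ti])
    return MatchResult(
        pairs=pairs,
        caliper=caliper_sd,
        caliper_width=float(width),
        scale=scale,
        unmatched_treated=unmatched_treated,
        unmatched_control=[ids[c] for c in available],
        scores=pair_scores,
    )


def smd_continuous(x_t: Sequence[float], x_c: Sequence[float]) -> float:
    """Standardized mean difference for a continuous covariate:
    (mean_t - mean_c) / sqrt((var_t + var_c) / 2), sample variances."""
    a = np.asarray(x_t, dtype=float)
    b = np.asarray(x_c, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    diff = a.mean() - b.mean()
    pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means; SMD is infinite")
        return float(np.copysign(np.inf, diff))
    return float(diff / np.sqrt(pooled))


def smd_binary(p_t: float, p_c: float) -> float:
    """Standardized mean difference for a binary covariate from raw
    (unrounded) proportions: (p_t - p_c) / sqrt((p_t(1-p_t) + p_c(1-p_c))/2)."""
    if not (0.0 <= p_t <= 1.0 and 0.0 <= p_c <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    diff = p_t - p_c
    pooled = (p_t * (1 - p_t) + p_c * (1 - p_c)) / 2.0
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("degenerate proportions with unequal values; SMD is infinite")
        return float(np.copysign(np.inf, diff))
    return float(diff / np.sqrt(pooled))


def _is_binary(s: pd.Series) -> bool:
    if s.dtype == bool:
        return True
    vals = pd.unique(s.dropna())
    return len(vals) <= 2 and set(np.asarray(vals).astype(float)) <= {0.0, 1.0}


def balance_table(
    covariates: pd.DataFrame,
    treated: Sequence[bool],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> BalanceTable:
    """SMD per covariate, before matching or restricted to matched ids.

    Continuous columns use the pooled-SD rule, binary columns the
    two-proportion rule; multi-level categoricals are expanded to
    per-level indicators (each reported as ``var=level``) with the
    level-maximum reported under the bare variable name.
    """
    y = pd.Series(np.asarray(treated, dtype=bool), index=covariates.index)
    if pairs is not None:
        keep = [i for pair in pairs for i in pair]
        covariates = covariates.loc[keep]
        y = y.loc[keep]
    rows: list[tuple[str, float]] = []
    for name in covariates.columns:
        s = covariates[name]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or (
            name in _CATEGORICAL and s.nunique() > 2
        ):
            level_smds = []
            for level in sorted(s.unique(), key=str):
                ind = (s == level).astype(float)
                v = smd_binary(float(ind[y].mean()), float(ind[~y].mean()))
                rows.append((f"{name}={level}", v))
                level_smds.append(v)
            worst = max(level_smds, key=abs)
            rows.append((name, worst))
        elif _is_binary(s):
            v = smd_binary(float(s[y].astype(float).mean()), float(s[~y].astype(float).mean()))
            rows.append((name, v))
        else:
            rows.append((name, smd_continuous(s[y], s[~y])))
    table = pd.DataFrame(
        {"smd": [v for _, v in rows]}, index=pd.Index([k for k, _ in rows], name="covariate")
    )
    table["abs_smd"] = table["smd"].abs()
    return BalanceTable(table=table)
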