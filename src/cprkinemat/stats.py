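"""Statistical layer: standardized multiple regression of compression depth
on the kinematic predictors, and nonparametric group comparisons.

The regression reports raw coefficients b (physical units), standardized
coefficients β = b·s_x/s_y (comparable across predictors), their standard
errors, t statistics, two-sided p-values, adjusted R² and the overall F.
Group comparisons route through a Shapiro–Wilk normality gate to Student's t
or the Mann–Whitney U test (midrank ties; exact enumeration for small
groups, normal approximation with tie correction otherwise).
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import qr as _pivoted_qr

from .config import PREDICTOR_COLUMNS
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Exact Mann–Whitney enumeration is used when both groups are this small.
EXACT_MW_MAX_N = 8


@dataclass
class RegressionResult:
    """Full output of one standardized OLS fit."""

    names: list[str]  # predictor names, excluding the intercept
    b: np.ndarray  # raw coefficients, intercept first
    se_b: np.ndarray
    beta: np.ndarray  # standardized coefficients (no intercept)
    se_beta: np.ndarray
    t: np.ndarray  # t statistics of the predictors
    p: np.ndarray  # two-sided p-values of the predictors
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    df: tuple[int, int]  # (model, residual)
    se_est: float  # residual standard error, units of y
    n: int

    def to_dict(self) -> dict:
        terms = {}
        for j, name in enumerate(self.names):
            terms[name] = {
                "b": float(self.b[j + 1]),
                "se_b": float(self.se_b[j + 1]),
                "beta": float(self.beta[j]),
                "se_beta": float(self.se_beta[j]),
                "t": float(self.t[j]),
                "p": float(self.p[j]),
            }
        return {
            "intercept": {"b": float(self.b[0]), "se_b": float(self.se_b[0])},
            "terms": terms,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "f_stat": self.f_stat,
            "f_p": self.f_p,
            "df": list(self.df),
            "se_est": self.se_est,
            "n": self.n,
        }


@dataclass
class GroupComparison:
    """Deep-vs-shallow comparison of one feature."""

    feature: str
    median_deep: float
    median_shallow: float
    n_deep: int
    n_shallow: int
    p: float
    test: str  # "t" or "mannwhitney"
    u_stat: Optional[float] = None
    t_stat: Optional[float] = None
    method: Optional[str] = None  # "exact" or "normal" for Mann–Whitney
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "median_deep": self.median_deep,
            "median_shallow": self.median_shallow,
            "n_deep": self.n_deep,
            "n_shallow": self.n_shallow,
            "p": self.p,
            "test": self.test,
            "u_stat": self.u_stat,
            "t_stat": self.t_stat,
        }


def _collinear_columns(X: np.ndarray, names: Sequence[str], rank: int) -> list[str]:
    """Name the columns a pivoted QR leaves outside the independent set."""
    _, _, piv = _pivoted_qr(X, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


def standardized_ols(predictors, depth) -> RegressionResult:
    """Ordinary least squares of depth on the predictor table, with
    standardized coefficients.

    ``predictors`` is an (n, p) DataFrame (column names kept) or array;
    ``depth`` an n-vector.  Solves the normal equations; standard errors come
    from the unscaled covariance of the estimates, σ²(XᵀX)⁻¹.
    """
    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(depth, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("depth must be an n-vector matching the predictors")
    if n < p + 3:
        raise ValidationError(f"need n >= {p + 3} rows for {p} predictors, got {n}")

    # Collinearity is judged on the z-scored design so the check is invariant
    # to the wildly different physical scales of the predictors.
    sx = X.std(axis=0, ddof=1)
    constant = [names[j] for j in range(p) if sx[j] == 0]
    if constant:
        raise ValidationError(f"rank-deficient design; collinear columns: {constant}")
    Xc = (X - X.mean(axis=0)) / sx
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        bad = _collinear_columns(Xc, names, rank)
        raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
    Xd = np.column_stack([np.ones(n), X])

    xtx = Xd.T @ Xd
    b = np.linalg.solve(xtx, Xd.T @ y)
    resid = y - Xd @ b
    df_res = n - p - 1
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    sigma2 = ssr / df_res
    cov = sigma2 * np.linalg.inv(xtx)
    se_b = np.sqrt(np.diag(cov))

    sy = y.std(ddof=1)
    beta = b[1:] * sx / sy
    se_beta = se_b[1:] * sx / sy
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_b[1:] > 0, b[1:] / se_b[1:], np.inf)
    pvals = 2.0 * sps.t.sf(np.abs(t), df_res)

    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res
    if ssr > 0:
        f_stat = ((sst - ssr) / p) / sigma2
        f_p = float(sps.f.sf(f_stat, p, df_res))
    else:
        f_stat, f_p = float("inf"), 0.0

    return RegressionResult(
        names=names,
        b=b,
        se_b=se_b,
        beta=beta,
        se_beta=se_beta,
        t=t,
        p=pvals,
        r2=float(r2),
        adj_r2=float(adj_r2),
        f_stat=float(f_stat),
        f_p=f_p,
        df=(p, df_res),
        se_est=float(math.sqrt(sigma2)),
        n=n,
    )


def _mw_u(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, method: str = "auto") -> tuple[float, float, str]:
    """Mann–Whitney U of sample ``a`` versus ``b`` with midrank ties.

    Returns (U, two-sided p, method).  The exact two-sided p enumerates every
    assignment of the pooled midranks when both groups have at most
    ``EXACT_MW_MAX_N`` observations (U is symmetric about n₁n₂/2 so the
    two-sided tail doubles cleanly even under ties); otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("mann_whitney: both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u = _mw_u(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if max(n1, n2) <= EXACT_MW_MAX_N else "normal"
    if method == "exact":
        dev = abs(u - mu)
        total = math.comb(n1 + n2, n1)
        hits = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u_perm = _mw_u(ranks[list(combo)], n1)
            if abs(u_perm - mu) >= dev - 1e-9:
                hits += 1
        return u, hits / total, "exact"

    # normal approximation with tie correction
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0, "normal"
    dev = abs(u - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(sigma2)  # continuity correction
    return u, float(2.0 * sps.norm.sf(z)), "normal"


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    alpha: float = 0.05,
    force_test: Optional[str] = None,
) -> GroupComparison:
    """Compare a feature between the deep and shallow groups.

    A Shapiro–Wilk gate (α = 0.05 on each group) routes to Student's t when
    both groups look normal, otherwise to Mann–Whitney; ``force_test``
    ("t" or "mannwhitney") overrides the gate.
    """
    if feature not in table.columns:
        raise ValidationError(f"feature {feature!r} not in table")
    deep = table.loc[table[group_col] == "deep", feature].dropna().to_numpy(float)
    shallow = (
        table.loc[table[group_col] == "shallow", feature].dropna().to_numpy(float)
    )
    if deep.size == 0 or shallow.size == 0:
        raise ValidationError("comparison needs both groups")

    test = force_test
    if test is None:
        # Shapiro–Wilk needs n >= 3 and a non-constant sample.
        gate_ok = all(g.size >= 3 and np.ptp(g) > 0 for g in (deep, shallow))
        if gate_ok and all(sps.shapiro(g).pvalue > alpha for g in (deep, shallow)):
            test = "t"
        else:
            test = "mannwhitney"

    result = GroupComparison(
        feature=feature,
        median_deep=float(np.median(deep)),
        median_shallow=float(np.median(shallow)),
        n_deep=int(deep.size),
        n_shallow=int(shallow.size),
        p=float("nan"),
        test=test,
    )
    if test == "t":
        t_stat, p = sps.ttest_ind(deep, shallow, equal_var=True)
        result.t_stat, result.p = float(t_stat), float(p)
    elif test == "mannwhitney":
        u, p, method = mann_whitney(deep, shallow)
        result.u_stat, result.p, result.method = u, p, method
    else:
        raise ValidationError(f"unknown test {force_test!r}")
    return result


def analyze_features(
    table: pd.DataFrame,
    predictors: Sequence[str] = PREDICTOR_COLUMNS,
    compare: Sequence[str] = ("pl_mm", "ea_mm2", "lkfa", "rkfa", "lefa", "refa",
                              "trunk_incl"),
) -> dict:
    """Regression of depth on the four predictors plus per-feature group
    comparisons (skipped, with a note, when a group is empty)."""
    reg = standardized_ols(table[list(predictors)], table["depth_mm"].to_numpy())
    comparisons = {}
    for feat in compare:
        if feat not in table.columns:
            continue
        try:
            comparisons[feat] = compare_groups(table, feat).to_dict()
        except ValidationError as exc:
            comparisons[feat] = {"skipped": str(exc)}
    return {"regression": reg.to_dict(), "comparisons": comparisons}
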