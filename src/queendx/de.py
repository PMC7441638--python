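"""Differential protein expression: pairwise t-tests, OLS models, BH-FDR.

The workhorse comparison is the two-sample Student's t-test with pooled
variance on log2 LFQ intensities, the convention the published degrees of
freedom imply (df = n1 + n2 - 2; e.g. df = 11 for a 7-vs-6 comparison).
Welch's unequal-variance test is available as an option.  P-values are
adjusted across the tested family by the Benjamini-Hochberg step-up
procedure; proteins with fewer than two pairwise-complete observations in
either group are reported untested and excluded from the BH family, matching
Perseus's valid-row behaviour.

Survey-style analyses with continuous and discrete covariates use ordinary
least squares (per-term t-tests plus an overall F-test) in place of
moderated statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import LfqMatrix


class TtestOutcome(NamedTuple):
    t_stat: float
    df: float
    p_value: float


#: Columns of the differential-expression result table (one row per tested
#: protein): accession, log2_fc (= mean(group A) - mean(group B) of log2
#: LFQ), t_stat, df, p_value, adj_p, n_a, n_b, direction, significant.
DE_COLUMNS = (
    "accession", "log2_fc", "t_stat", "df", "p_value", "adj_p",
    "n_a", "n_b", "direction", "significant",
)


def student_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TtestOutcome:
    """Two-sided two-sample t-test on *x* vs *y* (missing values dropped).

    With ``equal_var=True`` (default) this is Student's pooled-variance test
    with df = n_x + n_y - 2; otherwise Welch's test with Satterthwaite df.
    Fewer than two present values in either group raises.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    xa = xa[~np.isnan(xa)]
    ya = ya[~np.isnan(ya)]
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each group needs at least two present values")
    res = st.ttest_ind(xa, ya, equal_var=equal_var)
    t = float(res.statistic)
    df = float(res.df)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal: no evidence either way
        t, p = 0.0, 1.0
    return TtestOutcome(t, df, p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Adjusted values are monotone non-decreasing in the sorted p order and
    capped at 1.  Inputs outside (0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise count, mean and (ddof=1) variance of a 2-D array with NaNs."""
    present = ~np.isnan(vals)
    n = present.sum(axis=1)
    filled = np.where(present, vals, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = filled.sum(axis=1) / n
        centered = np.where(present, vals - mean[:, None], 0.0)
        var = (centered**2).sum(axis=1) / (n - 1)
    mean[n == 0] = np.nan
    var[n < 2] = np.nan
    return n, mean, var


def run_pairwise_de(
    matrix: LfqMatrix,
    group_a: str,
    group_b: str,
    fdr: float = 0.05,
    test: str = "student",
) -> pd.DataFrame:
    """Row-wise group-A-vs-group-B tests with BH correction.

    Returns one row per testable protein (>=2 present values per group),
    sorted by (adj_p, \\|t\\| descending, accession).  ``log2_fc`` is the
    group-A minus group-B mean of log2 intensities, so ``direction == 'up'``
    means higher in group A.  The number of untested proteins is recorded in
    ``result.attrs['n_untested']``.
    """
    if not matrix.log2:
        raise ValueError("run_pairwise_de expects a log2-transformed matrix")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test: {test!r}")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    known = set(matrix.group_labels())
    for g in (group_a, group_b):
        if g not in known:
            raise KeyError(f"unknown group {g!r}; known groups: {sorted(known)}")

    a_cols = matrix.samples_in_group(group_a)
    b_cols = matrix.samples_in_group(group_b)
    av = matrix.intensities[a_cols].to_numpy(dtype=float)
    bv = matrix.intensities[b_cols].to_numpy(dtype=float)

    na, ma, va = _group_stats(av)
    nb, mb, vb = _group_stats(bv)
    testable = (na >= 2) & (nb >= 2)

    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "student":
            df = na + nb - 2.0
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        else:
            term_a, term_b = va / na, vb / nb
            se = np.sqrt(term_a + term_b)
            df = (term_a + term_b) ** 2 / (
                term_a**2 / (na - 1) + term_b**2 / (nb - 1)
            )
        t = diff / se
    # degenerate rows: zero pooled variance
    zero_se = testable & ~np.isfinite(t)
    t[zero_se & (diff == 0)] = 0.0
    with np.errstate(invalid="ignore"):
        p = 2.0 * st.t.sf(np.abs(t), df)
    p[zero_se & (diff == 0)] = 1.0
    p[zero_se & (diff != 0)] = np.finfo(float).tiny
    t[zero_se & (diff != 0)] = np.sign(diff[zero_se & (diff != 0)]) * np.inf

    idx = np.flatnonzero(testable)
    out = pd.DataFrame(
        {
            "accession": np.asarray(matrix.accessions, dtype=object)[idx],
            "log2_fc": diff[idx],
            "t_stat": t[idx],
            "df": df[idx],
            "p_value": np.clip(p[idx], np.finfo(float).tiny, 1.0),
            "n_a": na[idx].astype(int),
            "n_b": nb[idx].astype(int),
        }
    )
    out["adj_p"] = benjamini_hochberg(out["p_value"]) if len(out) else []
    out["direction"] = np.where(out["log2_fc"] >= 0, "up", "down")
    out["significant"] = out["adj_p"] <= fdr
    out["_abs_t"] = out["t_stat"].abs()
    out = (
        out.sort_values(["adj_p", "_abs_t", "accession"], ascending=[True, False, True])
        .drop(columns="_abs_t")
        .reset_index(drop=True)
    )
    out = out[list(DE_COLUMNS)]
    out.attrs["n_untested"] = int((~testable).sum())
    out.attrs["fdr"] = fdr
    out.attrs["groups"] = (group_a, group_b)
    return out


@dataclass(frozen=True)
class LinearModelResult:
    """OLS fit summary for one response across samples."""

    accession: str
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    term_p_values: dict[str, float]
    f_stat: float
    residual_df: int
    p_value: float
    r_squared: float


def fit_linear_model(
    values: pd.Series | Sequence[float],
    design: pd.DataFrame,
    accession: str = "",
) -> LinearModelResult:
    """Ordinary least squares of *values* on the named *design* columns.

    An intercept is added automatically.  Reports per-term coefficients and
    t-test p-values plus the overall F-test against the intercept-only
    model.  A rank-deficient design raises, naming the collinear terms; a
    constant response yields F = 0, p = 1.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("missing response values are not allowed; drop them first")
    if design.isna().any().any():
        raise ValueError("missing covariate values are not allowed")
    X = sm.add_constant(design.astype(float), has_constant="add")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than model terms ({k})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        collinear = [
            c
            for c in design.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")

    res = sm.OLS(y, X).fit()
    ess = float(res.ess)
    tss = float(res.centered_tss)
    if tss <= 0 or ess <= 1e-12 * max(tss, 1.0):
        f_stat, f_p = 0.0, 1.0
    else:
        f_stat, f_p = float(res.fvalue), float(res.f_pvalue)
    return LinearModelResult(
        accession=accession,
        coefficients=dict(res.params),
        std_errors=dict(res.bse),
        term_p_values=dict(res.pvalues),
        f_stat=f_stat,
        residual_df=int(res.df_resid),
        p_value=f_p,
        r_squared=float(res.rsquared) if tss > 0 else 0.0,
    )
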