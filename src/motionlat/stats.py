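"""Inferential tests implemented from first principles.

Pooled-variance independent t (df = n1 + n2 - 2), paired t (df = n - 1),
uncorrected Pearson chi-square for 2x2 tables (1 df, no continuity
correction), and a univariate mixed repeated-measures ANOVA with one
between-subjects factor and up to two 2-level within-subjects factors.

The statistics are computed by hand (the formulas are the point); only the
reference distributions (t, F, chi2 tails) come from scipy.

The mixed ANOVA is computed via per-subject contrast scores: each within
effect reduces to a known contrast of a subject's cell means, regressed on
the between factor with sum-to-zero (unweighted-means) coding.  The
intercept F is the within main effect, the group-term F its interaction
with group, and the residual supplies the matching subject-within-groups
error term with df = N - g — reproducing the classical split-plot table,
including the F = t^2 identities for 2-level factors.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

P_FLOOR = 1e-300


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    tail: str = "two"
    n: tuple = ()
    degenerate: bool = False


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    error_term: str


def _t_pvalue(t: float, df: float, tail: str) -> float:
    if tail == "two":
        return float(min(1.0, 2.0 * sps.t.sf(abs(t), df)))
    if tail == "one_pos":
        return float(sps.t.sf(t, df))
    if tail == "one_neg":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"unknown tail {tail!r}")


def independent_t(x, y, tail: str = "two") -> TestResult:
    """Pooled-variance two-sample t test (x minus y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(0.0, df, 1.0, tail, (nx, ny), degenerate=True)
        t = np.inf if diff > 0 else -np.inf
        return TestResult(t, df, _t_pvalue(t, df, tail), tail, (nx, ny),
                          degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    return TestResult(float(t), df, _t_pvalue(t, df, tail), tail, (nx, ny))


def paired_t(x, y, tail: str = "two") -> TestResult:
    """t test on paired differences x - y, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, df, 1.0, tail, (n,), degenerate=True)
        t = np.inf if d.mean() > 0 else -np.inf
        return TestResult(t, df, _t_pvalue(t, df, tail), tail, (n,),
                          degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    return TestResult(float(t), df, _t_pvalue(t, df, tail), tail, (n,))


def chi_square_2x2(table) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 count table (1 df)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal")
    num = n * (obs[0, 0] * obs[1, 1] - obs[0, 1] * obs[1, 0]) ** 2
    chi2 = num / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult(float(chi2), 1, max(p, P_FLOOR), "two", (int(n),))


# ------------------------------------------------------------- correlation
def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0.0:
        raise ValueError("zero variance")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def pearson_test(x, y, tail: str = "two") -> tuple[float, float, int]:
    """Pearson r with its t-based p-value; returns (r, p, n)."""
    r = pearson(x, y)
    n = len(np.asarray(x))
    if abs(r) == 1.0:
        return r, P_FLOOR, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    return r, max(_t_pvalue(t, n - 2, tail), P_FLOOR), n


# ------------------------------------------------------------- mixed ANOVA
def _sum_coded_design(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(groups))
    g = len(levels)
    X = np.ones((len(groups), g))
    for j, lev in enumerate(levels[:-1]):
        col = np.where(groups == lev, 1.0, 0.0)
        col -= np.where(groups == levels[-1], 1.0, 0.0)
        X[:, j + 1] = col
    return X[:, :g], levels


def _ols_effect_f(y: np.ndarray, groups: np.ndarray | None
                  ) -> tuple[tuple, tuple, int]:
    """F tests from the contrast-score regression.

    Returns ((F_intercept, df1, df2), (F_group, df1g, df2), df_den) where
    F_intercept tests the (unweighted) grand mean of the scores and
    F_group tests group differences; without a between factor the group
    entry is None.
    """
    n = len(y)
    if groups is None:
        df_den = n - 1
        mean = y.mean()
        sse = ((y - mean) ** 2).sum()
        mse = sse / df_den
        f_int = mean ** 2 * n / mse if mse > 0 else (
            0.0 if mean == 0 else np.inf)
        return (float(f_int), 1, df_den), None, df_den
    X, levels = _sum_coded_design(groups)
    g = X.shape[1]
    df_den = n - g
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = (resid ** 2).sum()
    mse = sse / df_den
    xtx_inv = np.linalg.inv(X.T @ X)
    if mse > 0:
        f_int = beta[0] ** 2 / (mse * xtx_inv[0, 0])
    else:
        f_int = 0.0 if beta[0] == 0 else np.inf
    # group effect: compare against intercept-only fit
    sse_reduced = ((y - y.mean()) ** 2).sum()
    if mse > 0:
        f_grp = ((sse_reduced - sse) / (g - 1)) / mse
    else:
        f_grp = 0.0 if np.isclose(sse_reduced, sse) else np.inf
    return ((float(f_int), 1, df_den),
            (float(max(f_grp, 0.0)), g - 1, df_den), df_den)


def mixed_anova(data: pd.DataFrame, dv: str, subject: str,
                between: str | None = None,
                within: list[str] | None = None) -> list[AnovaResult]:
    """Univariate mixed repeated-measures ANOVA.

    ``data`` is long-format with one row per subject x within-cell (cell
    means).  ``within`` lists up to two factors, each with exactly two
    levels; ``between`` may have any number of groups (unequal sizes are
    pooled with unweighted-means coding).  Every subject must have every
    within cell exactly once.
    """
    within = list(within or [])
    if len(within) > 2:
        raise ValueError("at most two within-subject factors are supported")
    for w in within:
        if data[w].nunique() != 2:
            raise ValueError(
                f"within factor {w!r} must have exactly 2 levels "
                "(sphericity corrections for >2 levels are not implemented)")
    cells = within if within else []
    if cells:
        wide = data.pivot_table(index=subject, columns=cells, values=dv,
                                aggfunc="first")
        expected = int(np.prod([2] * len(cells)))
        if wide.shape[1] != expected or wide.isna().any().any():
            raise ValueError("design is not fully crossed (missing cells)")
    else:
        wide = data.set_index(subject)[[dv]]
        if wide.index.duplicated().any():
            raise ValueError("one observation per subject expected")
    groups = None
    if between is not None:
        gmap = data.groupby(subject)[between].first()
        groups = gmap.loc[wide.index].to_numpy()

    Y = wide.to_numpy(dtype=float)
    results: list[AnovaResult] = []

    def _contrast(effect_factors: list[str]) -> np.ndarray:
        # +1/-1 product coding over the named factors, averaged over others
        signs = np.ones(Y.shape[1])
        for k, w in enumerate(within):
            if w not in effect_factors:
                continue
            levels = sorted(data[w].unique())
            col_levels = [c if isinstance(c, tuple) else (c,)
                          for c in wide.columns]
            for j, cl in enumerate(col_levels):
                signs[j] *= 1.0 if cl[k] == levels[0] else -1.0
        return (Y * signs).sum(axis=1) / Y.shape[1]

    error_label = ("subjects-within-groups" if between else "subjects")

    if between is not None:
        smean = Y.mean(axis=1)
        _, grp, df_den = _ols_effect_f(smean, groups)
        f, df1, df2 = grp
        results.append(AnovaResult(between, f, df1, df2,
                                   float(sps.f.sf(f, df1, df2)), error_label))

    effect_sets = [[w] for w in within]
    if len(within) == 2:
        effect_sets.append(list(within))
    for eff in effect_sets:
        name = " x ".join(eff)
        c = _contrast(eff)
        err = f"{name} x {error_label}"
        intercept, grp, df_den = _ols_effect_f(c, groups)
        f, df1, df2 = intercept
        results.append(AnovaResult(name, f, df1, df2,
                                   float(sps.f.sf(f, df1, df2)), err))
        if grp is not None:
            fg, dfg, df2 = grp
            results.append(AnovaResult(f"{name} x {between}", fg, dfg, df2,
                                       float(sps.f.sf(fg, dfg, df2)), err))
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([{"effect": r.effect, "F": r.F, "df_num": r.df_num,
                          "df_den": r.df_den, "p": r.p,
                          "error_term": r.error_term} for r in results])
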