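"""Molecular correlates: batch z-score normalization and directional
correlation of expression / methylation features with laterality phenotypes.

Expression levels arrive in platform units with an acquisition-batch label
and are standardized within batch x feature before pooling cohorts;
methylation beta-values (in [0, 1]) are used untransformed by default.
Feature-phenotype correlations use the Pearson t test with declared tails
(directional one-tailed where the hypothesis has a direction) and are
adjusted for multiple comparisons within a declared family (default:
features sharing a phenotype, Bonferroni).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .config import AnalysisPlanRow
from .stats import P_FLOOR, pearson, pearson_test  # noqa: F401  (pearson_test re-exported)

CORRELATION_COLUMNS = ["feature", "phenotype", "n", "r", "t_stat", "p",
                       "tail", "p_adjusted", "method"]


class BatchZScorer(BaseEstimator, TransformerMixin):
    """Standardize expression values within batch x feature.

    fit computes per-(measure_type, feature, batch) sample means and SDs
    (``stats_``); transform adds a ``value_z`` column.  Methylation rows
    pass through with ``value_z = value`` (beta-values are already on a
    common scale) unless ``zscore_methylation`` is set.
    """

    def __init__(self, zscore_methylation: bool = False):
        self.zscore_methylation = zscore_methylation

    def fit(self, X: pd.DataFrame, y=None):
        expr = X[self._mask(X)]
        grp = expr.groupby(["measure_type", "feature", "batch"])["value"]
        stats = grp.agg(["mean", "std", "count"])
        bad = stats[(stats["count"] < 2) | (stats["std"].fillna(0) == 0)]
        if len(bad):
            key = bad.index[0]
            raise ValueError(
                "cannot z-score batch with <2 subjects or zero variance: "
                f"measure_type={key[0]!r} feature={key[1]!r} batch={key[2]!r}")
        self.stats_ = stats
        return self

    def _mask(self, X: pd.DataFrame) -> pd.Series:
        m = X["measure_type"] == "expression"
        if self.zscore_methylation:
            m = m | (X["measure_type"] == "methylation")
        return m

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["value_z"] = out["value"].astype(float)
        mask = self._mask(out)
        keys = list(zip(out.loc[mask, "measure_type"],
                        out.loc[mask, "feature"], out.loc[mask, "batch"]))
        mean = np.array([self.stats_.loc[k, "mean"] for k in keys])
        sd = np.array([self.stats_.loc[k, "std"] for k in keys])
        out.loc[mask, "value_z"] = (
            (out.loc[mask, "value"].to_numpy(dtype=float) - mean) / sd)
        return out


def zscore_within_batch(table: pd.DataFrame,
                        zscore_methylation: bool = False) -> pd.DataFrame:
    """Standardize within batch x feature; adds ``value_z``."""
    return BatchZScorer(zscore_methylation).fit(table).transform(table)


def logit_transform(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Optional logit transform for methylation beta-values (off by
    default in the analysis; beta is correlated directly)."""
    return logit(np.clip(np.asarray(beta, dtype=float), eps, 1 - eps))


def correlation_test(r: float, n: int, tail: str = "two") -> dict:
    """p-value for a Pearson r via the t reference distribution (df n-2).

    One-tailed p in the stated direction equals two-tailed p/2 when the
    observed sign agrees with the direction, 1 - p/2 otherwise.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return {"r": float(r), "n": n, "t_stat": np.inf * np.sign(r),
                "p": P_FLOOR, "tail": tail, "underflow": True}
    from scipy import stats as sps
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    if tail == "two":
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    elif tail == "one_pos":
        p = sps.t.sf(t, n - 2)
    elif tail == "one_neg":
        p = sps.t.cdf(t, n - 2)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return {"r": float(r), "n": n, "t_stat": float(t),
            "p": float(min(max(p, P_FLOOR), 1.0)), "tail": tail,
            "underflow": False}


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Family-wise adjustment: 'bonferroni' (min(1, m*p)) or 'holm'
    (step-down with monotonicity)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def correlate_grid(mol: pd.DataFrame, phenotypes: pd.DataFrame,
                   plan: list[AnalysisPlanRow],
                   method: str = "bonferroni",
                   family: str = "phenotype") -> pd.DataFrame:
    """One directional Pearson test per plan row, with listwise deletion
    per feature-phenotype pair and family-wise adjustment.

    ``mol`` must carry ``value_z`` (run :func:`zscore_within_batch` first);
    methylation features correlate their raw beta (= value_z passthrough).
    ``phenotypes`` is a per-subject frame with a ``subject`` column and the
    phenotype columns named in the plan (e.g. LI, S_R, S_L).
    Adjustment families default to "all features sharing a phenotype".
    """
    if "value_z" not in mol.columns:
        raise ValueError("molecular table lacks value_z; z-score it first")
    rows = []
    for item in plan:
        feat = mol[mol["feature"] == item.feature]
        if feat.empty:
            raise ValueError(f"feature {item.feature!r} absent from table")
        if item.phenotype not in phenotypes.columns:
            raise ValueError(f"phenotype {item.phenotype!r} absent")
        merged = feat.merge(
            phenotypes[["subject", item.phenotype]], on="subject",
            how="inner").dropna(subset=["value_z", item.phenotype])
        if len(merged) < 3:
            raise ValueError(
                f"insufficient subject overlap for {item.feature} x "
                f"{item.phenotype} (n={len(merged)})")
        r = pearson(merged["value_z"].to_numpy(),
                    merged[item.phenotype].to_numpy(dtype=float))
        res = correlation_test(r, len(merged), item.tail)
        rows.append({"feature": item.feature, "phenotype": item.phenotype,
                     "n": res["n"], "r": res["r"], "t_stat": res["t_stat"],
                     "p": res["p"], "tail": item.tail})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    if family == "phenotype":
        for phen, idx in out.groupby("phenotype").groups.items():
            out.loc[idx, "p_adjusted"] = adjust_pvalues(
                out.loc[idx, "p"].to_numpy(), method)
    elif family == "all":
        out["p_adjusted"] = adjust_pvalues(out["p"].to_numpy(), method)
    else:
        raise ValueError("family must be 'phenotype' or 'all'")
    out["method"] = method
    return out[CORRELATION_COLUMNS]


def split_cohort_analysis(mol: pd.DataFrame, phenotypes: pd.DataFrame,
                          feature: str, phenotype: str,
                          tail: str = "one_pos") -> pd.DataFrame:
    """Replicate the split-cohort design: analyze each acquisition batch
    separately with a directional one-tailed test, then the combined
    z-scored cohort two-tailed."""
    mol_z = zscore_within_batch(mol) if "value_z" not in mol.columns else mol
    rows = []
    for batch, sub in mol_z[mol_z.feature == feature].groupby("batch",
                                                              sort=True):
        merged = sub.merge(phenotypes[["subject", phenotype]], on="subject")
        r = pearson(merged["value_z"].to_numpy(),
                    merged[phenotype].to_numpy(dtype=float))
        res = correlation_test(r, len(merged), tail)
        rows.append({"cohort": batch, **{k: res[k]
                                         for k in ("r", "p", "n", "tail")}})
    merged = mol_z[mol_z.feature == feature].merge(
        phenotypes[["subject", phenotype]], on="subject")
    r = pearson(merged["value_z"].to_numpy(),
                merged[phenotype].to_numpy(dtype=float))
    res = correlation_test(r, len(merged), "two")
    rows.append({"cohort": "combined", **{k: res[k]
                                          for k in ("r", "p", "n", "tail")}})
    return pd.DataFrame(rows)
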