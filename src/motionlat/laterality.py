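"""Hemisphere sensitivity, the laterality index, and cohort summaries.

Definitions (microvolts; the N2 is negative-going, so *negative* values
mean the contralateral motion direction evoked the larger N2, i.e. greater
sensitivity):

    S_R = A_RH(SL) - A_RH(SR)        right-hemisphere sensitivity
    S_L = A_LH(SR) - A_LH(SL)        left-hemisphere sensitivity
    LI  = S_R - S_L                  laterality index

LI < 0: right-hemisphere specialization; LI > 0: left-hemisphere
specialization; LI = 0: equally sensitive hemispheres, not specialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import independent_t, paired_t, pearson_test

LATERALITY_COLUMNS = ["subject", "group", "handedness", "S_R_uV", "S_L_uV",
                      "LI_uV", "LI_z", "class"]


def hemisphere_sensitivity(n2: pd.DataFrame) -> pd.DataFrame:
    """Per-subject S_R and S_L from the four N2 measures.

    ``n2`` is the component table restricted to window 'N2' with rows for
    each hemisphere x condition; raises if any of the four is missing.
    """
    n2 = n2[n2["window"] == "N2"]
    wide = n2.pivot_table(index=["subject", "group", "handedness"],
                          columns=["hemisphere", "condition"],
                          values="mean_amplitude_uV")
    needed = [("RH", "M_SL"), ("RH", "M_SR"), ("LH", "M_SL"), ("LH", "M_SR")]
    missing = [c for c in needed if c not in wide.columns]
    if missing or wide[needed].isna().any().any():
        raise ValueError(f"missing N2 measures: {missing or 'NaN cells'}")
    out = wide.index.to_frame(index=False)
    out["S_R_uV"] = (wide[("RH", "M_SL")] - wide[("RH", "M_SR")]).to_numpy()
    out["S_L_uV"] = (wide[("LH", "M_SR")] - wide[("LH", "M_SL")]).to_numpy()
    return out


def sensitivity_t_tests(n2: pd.DataFrame) -> pd.DataFrame:
    """Per-hemisphere, per-group paired t of A_h(SL) vs A_h(SR)."""
    n2 = n2[n2["window"] == "N2"]
    rows = []
    for (group, hemi), sub in n2.groupby(["group", "hemisphere"], sort=True):
        wide = sub.pivot(index="subject", columns="condition",
                         values="mean_amplitude_uV").dropna()
        res = paired_t(wide["M_SL"].to_numpy(), wide["M_SR"].to_numpy())
        rows.append({"group": group, "hemisphere": hemi,
                     "t": res.statistic, "df": res.df, "p": res.p,
                     "n": len(wide)})
    return pd.DataFrame(rows)


def laterality_index(sens: pd.DataFrame, epsilon: float = 0.0,
                     z_reference: str = "combined") -> pd.DataFrame:
    """LI = S_R - S_L with specialization class and z-scored LI.

    class: RH_specialized if LI < -epsilon, LH_specialized if LI > +epsilon,
    else none.  LI_z uses the sample (n-1) SD over the combined analysis
    cohort by default (``z_reference='within_group'`` to standardize per
    group).
    """
    out = sens.copy()
    out["LI_uV"] = out["S_R_uV"] - out["S_L_uV"]
    li = out["LI_uV"].to_numpy(dtype=float)
    if not np.all(np.isfinite(li)):
        raise ValueError("non-finite sensitivities")
    out["class"] = np.where(li < -epsilon, "RH_specialized",
                            np.where(li > epsilon, "LH_specialized", "none"))
    if z_reference == "combined":
        out["LI_z"] = _zscore(li)
    elif z_reference == "within_group":
        out["LI_z"] = out.groupby("group")["LI_uV"].transform(
            lambda v: _zscore(v.to_numpy(dtype=float)))
    else:
        raise ValueError("z_reference must be 'combined' or 'within_group'")
    return out[LATERALITY_COLUMNS]


def _zscore(v: np.ndarray) -> np.ndarray:
    if len(v) < 2:
        return np.zeros_like(v)
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


class LateralityScorer(BaseEstimator, TransformerMixin):
    """transform(N2 component table) -> laterality result table."""

    def __init__(self, epsilon: float = 0.0, z_reference: str = "combined"):
        self.epsilon = epsilon
        self.z_reference = z_reference

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return laterality_index(hemisphere_sensitivity(X),
                                epsilon=self.epsilon,
                                z_reference=self.z_reference)


@dataclass
class CohortSummary:
    class_percentages: pd.DataFrame      # per group (x handedness) % by class
    interhemispheric: pd.DataFrame       # per group r(S_R, S_L), two-tailed p
    group_comparison: dict               # pooled-df t of LI between groups


def cohort_summary(results: pd.DataFrame,
                   min_per_group: int = 3) -> CohortSummary:
    """Cohort-level laterality summary.

    Per group: percent specialized by class (overall and by handedness),
    the Pearson correlation between S_R and S_L with a two-tailed p, and
    the between-group pooled-variance t test on LI.
    """
    counts = results.groupby("group").size()
    if (counts < min_per_group).any():
        raise ValueError(f"need >= {min_per_group} subjects per group")
    pct_rows = []
    for group, sub in results.groupby("group", sort=True):
        for cls in ("RH_specialized", "LH_specialized", "none"):
            pct_rows.append({"group": group, "handedness": "all",
                             "class": cls,
                             "percent": 100.0 * (sub["class"] == cls).mean(),
                             "n": len(sub)})
        for hand, hsub in sub.groupby("handedness", sort=True):
            for cls in ("RH_specialized", "LH_specialized", "none"):
                pct_rows.append({
                    "group": group, "handedness": hand, "class": cls,
                    "percent": 100.0 * (hsub["class"] == cls).mean(),
                    "n": len(hsub)})
        if not (sub.handedness == "R").any():
            warnings.warn(f"group {group} has no right-handed members; "
                          "handedness breakdown incomplete", stacklevel=2)
    inter_rows = []
    for group, sub in results.groupby("group", sort=True):
        try:
            r, p, n = pearson_test(sub["S_R_uV"].to_numpy(),
                                   sub["S_L_uV"].to_numpy(), tail="two")
        except ValueError:   # degenerate (zero-variance) sensitivities
            r, p, n = np.nan, np.nan, len(sub)
        inter_rows.append({"group": group, "r": r, "p": p, "n": n})
    groups = sorted(results["group"].unique())
    comparison = {}
    if len(groups) == 2:
        a = results.loc[results.group == groups[0], "LI_uV"].to_numpy()
        b = results.loc[results.group == groups[1], "LI_uV"].to_numpy()
        res = independent_t(b, a)   # second-listed group minus first
        comparison = {"groups": f"{groups[1]} vs {groups[0]}",
                      "t": res.statistic, "df": res.df, "p": res.p}
    return CohortSummary(pd.DataFrame(pct_rows), pd.DataFrame(inter_rows),
                         comparison)
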