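"""Group statistics: ANCOVA with age as covariate, Tukey post hoc tests on
age-adjusted values, Benjamini-Hochberg FDR control, and the
brain-cognition-CSF correlation table over the combined MCI+AD pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

COGNITION_CSF_TARGETS = ("MMSE", "MoCA", "abeta42", "abeta40", "abeta_ratio",
                         "t_tau", "p_tau")


@dataclass
class AncovaResult:
    feature: str
    f_stat: float
    p_value: float
    groups: list[str]
    posthoc: pd.DataFrame | None = field(default=None, repr=False)
    covariate_dropped: bool = False


def ancova(values: np.ndarray, groups: np.ndarray, age: np.ndarray,
           posthoc: bool = True, feature: str = "feature") -> AncovaResult:
    """Linear model ``value ~ group + age``; F test of the group term.

    Post hoc: Tukey HSD on age-adjusted values (residuals from the age-only
    fit with group structure retained), the standard ANCOVA follow-up, with
    Benjamini-Hochberg adjustment across the pairwise family.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    age = np.asarray(age, dtype=float)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2 or (counts < 3).any():
        raise ValueError("need >= 2 groups with n >= 3 each")

    dummies = np.column_stack([(groups == g).astype(float)
                               for g in levels[1:]])
    covariate_dropped = np.ptp(age) == 0
    if covariate_dropped:
        warnings.warn("age is constant; dropping the covariate")
        design = np.column_stack([np.ones(len(values)), dummies])
    else:
        design = np.column_stack([np.ones(len(values)), dummies, age])
    res = OLS(values, design).fit()
    k = dummies.shape[1]
    restriction = np.zeros((k, design.shape[1]))
    restriction[np.arange(k), 1 + np.arange(k)] = 1.0
    ftest = res.f_test(restriction)
    f_stat, p_value = float(ftest.fvalue), float(ftest.pvalue)

    posthoc_df = None
    if posthoc:
        if covariate_dropped:
            adjusted = values
        else:
            slope = np.polyfit(age, values, 1)[0]
            adjusted = values - slope * (age - age.mean())
        tk = pairwise_tukeyhsd(adjusted, groups)
        posthoc_df = pd.DataFrame(tk.summary().data[1:],
                                  columns=tk.summary().data[0])
        posthoc_df["p-adj"] = pd.to_numeric(posthoc_df["p-adj"])
        posthoc_df["p_bh"] = bh_adjust(posthoc_df["p-adj"].to_numpy())
    return AncovaResult(feature, f_stat, p_value, list(levels), posthoc_df,
                        covariate_dropped)


def ancova_table(fm_subject: pd.DataFrame, meta: pd.DataFrame,
                 features: list[str] | None = None,
                 posthoc: bool = True) -> pd.DataFrame:
    """ANCOVA per feature across all groups present in ``meta``, with a
    second BH layer across features. Returns a tidy frame with raw and
    adjusted group-term p values."""
    merged = fm_subject.merge(meta[["subject_id", "group", "age"]],
                              on="subject_id")
    if features is None:
        features = [c for c in fm_subject.columns if c != "subject_id"]
    rows = []
    for feat in features:
        ok = merged[feat].notna()
        res = ancova(merged.loc[ok, feat].to_numpy(),
                     merged.loc[ok, "group"].to_numpy(),
                     merged.loc[ok, "age"].to_numpy(),
                     posthoc=posthoc, feature=feat)
        rows.append({"feature": feat, "F": res.f_stat, "p": res.p_value,
                     "result": res})
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values
    if ((p_values < 0) | (p_values > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p_values, method="fdr_bh")[1]


def brain_cognition_csf(fm_subject: pd.DataFrame, meta: pd.DataFrame,
                        features: list[str] | None = None,
                        targets: tuple[str, ...] = COGNITION_CSF_TARGETS,
                        ) -> pd.DataFrame:
    """Pearson correlations between subject-level EEG features and
    cognition/CSF measures within the combined MCI+AD pool.

    Missing clinical values are handled pairwise-complete; cells with fewer
    than 3 complete pairs are reported as NaN. Under the default generator
    the expected sign pattern is: theta power negative with abeta42 and
    positive with p-tau; Hjorth mobility positive with MMSE/MoCA.
    """
    pool = meta[meta["group"].isin(("MCI", "AD"))]
    merged = fm_subject.merge(pool, on="subject_id")
    if features is None:
        features = [c for c in fm_subject.columns if c != "subject_id"]
    rows = []
    for feat in features:
        for target in targets:
            if target not in merged.columns:
                continue
            ok = merged[feat].notna() & merged[target].notna()
            n = int(ok.sum())
            if n < 3:
                rows.append({"feature": feat, "target": target,
                             "r": np.nan, "p": np.nan, "n": n})
                continue
            r, p = stats.pearsonr(merged.loc[ok, feat],
                                  merged.loc[ok, target])
            rows.append({"feature": feat, "target": target,
                         "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)
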