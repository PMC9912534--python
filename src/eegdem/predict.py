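"""Random-forest regression of cognitive and disease-course targets from
EEG-only, CSF/APOE-only, and hybrid feature sets.

The cross-validation scheme is repeated random subsampling: ten independent
80/20 splits of the eligible (MCI + AD) subjects, a forest fit per split,
validation predictions pooled across the ten splits, metrics computed on
the pooled (truth, prediction) pairs. A partitioned 10-fold variant is
available behind ``scheme='kfold'`` for comparison.

Two R-squared variants are reported. ``r2`` is the model-sum-of-squares
ratio MSS/TSS = sum((yhat - ybar)^2) / sum((y - ybar)^2), which is
non-negative and unbounded above; ``r2_standard`` is the usual
1 - RSS/TSS diagnostic companion. MAE applies the absolute value to each
residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, ShuffleSplit

REGRESSION_TARGETS = ("MMSE", "MoCA", "ADO", "COD")
CSF_APOE_COLUMNS = ("abeta42", "abeta40", "abeta_ratio", "t_tau", "p_tau",
                    "apoe_e4")
DEMOGRAPHIC_COLUMNS = ("sex", "age")
FEATURE_SET_NAMES = ("EEG", "CSF_APOE", "hybrid")

RF_N_TREES = 500


def feature_set_columns(name: str, eeg_columns: list[str]) -> list[str]:
    """Resolve a named feature set to concrete column selectors."""
    if name == "EEG":
        return list(eeg_columns)
    if name == "CSF_APOE":
        return list(CSF_APOE_COLUMNS)
    if name == "hybrid":
        return list(eeg_columns) + list(CSF_APOE_COLUMNS) + list(DEMOGRAPHIC_COLUMNS)
    raise ValueError(f"unknown feature set {name!r}")


def r_squared(truth: np.ndarray, predictions: np.ndarray,
              ) -> tuple[float, float]:
    """(MSS/TSS, 1 - RSS/TSS) for the same prediction vector."""
    truth = np.asarray(truth, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if len(truth) < 2:
        raise ValueError("need at least two pairs")
    ybar = truth.mean()
    tss = float(((truth - ybar) ** 2).sum())
    if tss == 0:
        raise ValueError("constant truth: TSS = 0")
    mss = float(((predictions - ybar) ** 2).sum())
    rss = float(((truth - predictions) ** 2).sum())
    return mss / tss, 1.0 - rss / tss


def mae(truth: np.ndarray, predictions: np.ndarray) -> float:
    """Mean absolute error (1/n) sum |y_i - yhat_i|."""
    truth = np.asarray(truth, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if len(truth) != len(predictions):
        raise ValueError("length mismatch")
    if len(truth) == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(truth - predictions)))


@dataclass
class RegressionEntry:
    target: str
    feature_set: str
    r2: float                      # MSS/TSS
    r2_standard: float             # 1 - RSS/TSS
    mae: float
    n: int
    truth: np.ndarray = field(repr=False, default=None)
    predictions: np.ndarray = field(repr=False, default=None)

    def to_dict(self, include_pairs: bool = True) -> dict:
        out = {"target": self.target, "feature_set": self.feature_set,
               "r2": self.r2, "r2_standard": self.r2_standard,
               "mae": self.mae, "n": self.n}
        if include_pairs:
            out["truth"] = np.asarray(self.truth).tolist()
            out["predictions"] = np.asarray(self.predictions).tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionEntry":
        return cls(d["target"], d["feature_set"], d["r2"], d["r2_standard"],
                   d["mae"], d["n"], np.asarray(d.get("truth", [])),
                   np.asarray(d.get("predictions", [])))


def _encode(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    if "sex" in out.columns:
        out["sex"] = (out["sex"] == "male").astype(float)
    return out.astype(float)


def repeated_cv_rf(data: pd.DataFrame, target: str, columns: list[str],
                   folds: int = 10, seed: int = 0, test_size: float = 0.2,
                   scheme: str = "repeated", n_trees: int = RF_N_TREES,
                   feature_set: str = "custom") -> RegressionEntry:
    """Random-forest regression with pooled validation predictions.

    ``data`` holds both the feature columns and the target for the eligible
    subjects (rows with a missing target are dropped; missing feature values
    are imputed with training-fold medians). Deterministic under ``seed``.
    """
    data = data.loc[data[target].notna()].reset_index(drop=True)
    n = len(data)
    if n < 20:
        raise ValueError(f"only {n} eligible subjects (< 20)")
    y = data[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    x = _encode(data[columns])

    if scheme == "repeated":
        splitter = ShuffleSplit(n_splits=folds, test_size=test_size,
                                random_state=seed)
    elif scheme == "kfold":
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        raise ValueError("scheme must be 'repeated' or 'kfold'")

    truths, preds = [], []
    for i, (tr, va) in enumerate(splitter.split(x)):
        x_tr, x_va = x.iloc[tr].copy(), x.iloc[va].copy()
        med = x_tr.median()
        x_tr = x_tr.fillna(med).fillna(0.0)
        x_va = x_va.fillna(med).fillna(0.0)
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   random_state=(seed * 1009 + i) % (2**31 - 1),
                                   n_jobs=1)
        rf.fit(x_tr.to_numpy(), y[tr])
        truths.append(y[va])
        preds.append(rf.predict(x_va.to_numpy()))
    truth = np.concatenate(truths)
    pred = np.concatenate(preds)
    r2, r2_std = r_squared(truth, pred)
    return RegressionEntry(target, feature_set, r2, r2_std,
                           mae(truth, pred), len(truth), truth, pred)


def assess_targets(fm_subject: pd.DataFrame, meta: pd.DataFrame,
                   eeg_columns: list[str],
                   targets: tuple[str, ...] = REGRESSION_TARGETS,
                   sets: tuple[str, ...] = FEATURE_SET_NAMES,
                   folds: int = 10, seed: int = 0,
                   scheme: str = "repeated") -> list[RegressionEntry]:
    """Run every target x feature-set combination on the MCI+AD pool."""
    pool = meta[meta["group"].isin(("MCI", "AD"))]
    merged = fm_subject.merge(pool, on="subject_id")
    out = []
    for target in targets:
        for set_name in sets:
            cols = feature_set_columns(set_name, eeg_columns)
            missing = [c for c in cols if c not in merged.columns]
            if missing:
                raise KeyError(f"columns not found: {missing}")
            entry = repeated_cv_rf(merged[cols + [target]], target, cols,
                                   folds=folds, seed=seed, scheme=scheme,
                                   feature_set=set_name)
            out.append(entry)
    return out
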