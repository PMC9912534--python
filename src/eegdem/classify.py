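"""Two-step three-level diagnosis: correlation ranking, forward selection,
LDA/SVM training, and confusion-matrix metrics.

Features are ranked by the absolute Pearson correlation between each column
and the ordinal class code (HC=1, MCI=2, AD=3); forward selection grows the
ranked prefix and scores each prefix by mean 5-fold cross-validated accuracy
inside an 80% training split. The held-out 20% is touched once, after
selection, for the reported metrics.

The default split treats epochs as samples (so one subject's epochs can land
on both sides); a subject-grouped mode is available because epoch-level
splitting leaks subject identity. Reports record which mode produced them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import (GroupShuffleSplit, StratifiedGroupKFold,
                                     StratifiedKFold, train_test_split)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

log = logging.getLogger(__name__)

LABEL_CODES = {"HC": 1, "MCI": 2, "AD": 3}
TASKS = {
    "hc-mci": ("HC", "MCI"),
    "hc-ad": ("HC", "AD"),
    "hc-mci-ad": ("HC", "MCI", "AD"),
}


def encode_labels(groups: pd.Series | np.ndarray) -> np.ndarray:
    """Ordinal class codes HC=1, MCI=2, AD=3."""
    return np.asarray([LABEL_CODES[g] for g in np.asarray(groups)])


def make_classifier(name: str):
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "svm":
        return SVC(kernel="linear")
    raise ValueError(f"unknown classifier {name!r}")


# --------------------------------------------------------------------------
# Ranking and forward selection
# --------------------------------------------------------------------------

def rank_features(fm: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Pearson r of each feature column against the ordinal label vector,
    sorted by |r| descending (stable: ties keep column order). Constant
    columns get r = 0 with a warning."""
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct labels")
    x = fm.to_numpy(dtype=float)
    y = labels - labels.mean()
    xc = x - x.mean(axis=0)
    sx = xc.std(axis=0)
    sy = y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * y[:, None]).mean(axis=0) / (sx * sy)
    constant = sx == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant feature(s); r set to 0")
        r[constant] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    ranked = pd.DataFrame({"feature": fm.columns, "r": r, "abs_r": np.abs(r)})
    return (ranked.sort_values("abs_r", ascending=False, kind="mergesort")
                  .reset_index(drop=True))


def split_and_cv(fm: pd.DataFrame, labels: np.ndarray, seed: int,
                 groups: np.ndarray | None = None, n_folds: int = 5,
                 test_size: float = 0.2):
    """Stratified 80/20 outer split plus a 5-fold inner CV iterator.

    With ``groups`` (subject ids) the split keeps every subject wholly on
    one side and the inner folds are subject-grouped as well.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 10).any():
        raise ValueError("need >= 10 samples per class for an 80/20 split")
    idx = np.arange(len(labels))
    if groups is None:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_size, stratify=labels, random_state=seed)
        cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    else:
        groups = np.asarray(groups)
        gss = GroupShuffleSplit(n_splits=1, test_size=test_size,
                                random_state=seed)
        train_idx, test_idx = next(gss.split(idx, labels, groups))
        if set(labels[train_idx]) != set(classes) or \
           set(labels[test_idx]) != set(classes):
            raise ValueError("grouped split lost a class; enlarge the cohort")
        cv = StratifiedGroupKFold(n_folds, shuffle=True, random_state=seed)
    train_counts = np.unique(labels[train_idx], return_counts=True)[1]
    if (train_counts < n_folds).any():
        raise ValueError("a class has fewer training samples than folds")
    return train_idx, test_idx, cv


def forward_select(ranked: pd.DataFrame, fm: pd.DataFrame,
                   labels: np.ndarray, classifier: str, cv,
                   groups: np.ndarray | None = None,
                   max_features: int | None = None,
                   ) -> tuple[list[str], np.ndarray]:
    """Grow the ranked prefix one feature at a time; return the prefix with
    the highest mean CV validation accuracy (first maximum on ties) and the
    full accuracy curve."""
    if ranked.empty:
        raise ValueError("ranked feature list is empty")
    n_eval = len(ranked) if max_features is None else min(max_features,
                                                          len(ranked))
    labels = np.asarray(labels)
    x_all = fm[ranked["feature"].tolist()].to_numpy(dtype=float)
    curve = np.zeros(n_eval)
    folds = list(cv.split(x_all, labels, groups))
    for k in range(1, n_eval + 1):
        x = x_all[:, :k]
        accs = []
        try:
            for tr, va in folds:
                model = make_pipeline(StandardScaler(),
                                      make_classifier(classifier))
                model.fit(x[tr], labels[tr])
                accs.append(float(np.mean(model.predict(x[va]) == labels[va])))
            curve[k - 1] = float(np.mean(accs))
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("classifier failed at step %d: %s", k, exc)
            curve[k - 1] = 0.0
    best_k = int(np.argmax(curve)) + 1
    return ranked["feature"].tolist()[:best_k], curve


# --------------------------------------------------------------------------
# Evaluation (confusion-count arithmetic)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Recall, precision, F1 and accuracy from one-vs-rest counts."""
    rc = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    pc = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    f1 = f1_from_pr(pc, rc)
    acc = (c.tp + c.tn) / c.n if c.n else 0.0
    return {"recall": rc, "precision": pc, "f1": f1, "accuracy": acc}


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def one_vs_rest_counts(y_true: np.ndarray, y_pred: np.ndarray,
                       positive) -> ConfusionCounts:
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionCounts(tp=int((t & p).sum()), tn=int((~t & ~p).sum()),
                           fp=int((~t & p).sum()), fn=int((t & ~p).sum()))


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Binary tasks: metrics of the positive (higher-code, i.e. patient)
    class. Three-class: per-class one-vs-rest recall/precision/F1 macro
    averaged; accuracy is the overall fraction correct."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    classes = np.unique(y_true)
    if len(classes) == 2:
        positive = classes.max()
        counts = one_vs_rest_counts(y_true, y_pred, positive)
        out = metrics_from_counts(counts)
        out["counts"] = counts
        out["positive_class"] = int(positive)
        return out
    per_class = {int(c): metrics_from_counts(one_vs_rest_counts(y_true, y_pred, c))
                 for c in classes}
    out = {m: float(np.mean([per_class[c][m] for c in per_class]))
           for m in ("recall", "precision", "f1")}
    out["accuracy"] = float(np.mean(y_true == y_pred))
    out["per_class"] = per_class
    return out


# --------------------------------------------------------------------------
# Whole task
# --------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    task: str
    classifier: str
    split_mode: str                 # 'epoch' or 'subject'
    selected_features: list[str]
    accuracy_curve: np.ndarray
    metrics: dict
    n_train: int
    n_test: int
    seed: int
    rank_on: str = "train"
    ranked: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        metrics = {k: v for k, v in self.metrics.items() if k != "counts"}
        if "per_class" in metrics:
            metrics["per_class"] = {str(k): v for k, v in
                                    metrics["per_class"].items()}
        if "counts" in self.metrics:
            c = self.metrics["counts"]
            metrics["counts"] = {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
        return {
            "task": self.task, "classifier": self.classifier,
            "split_mode": self.split_mode, "seed": self.seed,
            "rank_on": self.rank_on,
            "selected_features": self.selected_features,
            "accuracy_curve": self.accuracy_curve.tolist(),
            "metrics": metrics, "n_train": self.n_train,
            "n_test": self.n_test,
        }


def classify_task(fm: pd.DataFrame, groups_col: pd.Series,
                  subject_ids: pd.Series | None = None,
                  task: str = "hc-mci-ad", classifier: str = "lda",
                  seed: int = 0, split: str = "epoch",
                  max_features: int | None = None,
                  rank_on: str = "train") -> ClassificationReport:
    """End-to-end task: subset classes, split, rank, select, train, test.

    ``rank_on='train'`` (default) computes the Pearson ranking on the
    training split only; ``rank_on='all'`` mirrors the leakier variant that
    ranks on the full data before splitting.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if split not in ("epoch", "subject"):
        raise ValueError("split must be 'epoch' or 'subject'")
    keep = np.asarray([g in TASKS[task] for g in groups_col])
    missing = set(TASKS[task]) - set(np.asarray(groups_col)[keep])
    if missing:
        raise ValueError(f"task {task!r} requires groups {sorted(missing)}")
    fm = fm.loc[keep].reset_index(drop=True)
    labels = encode_labels(np.asarray(groups_col)[keep])
    groups = None
    if split == "subject":
        if subject_ids is None:
            raise ValueError("subject split requires subject ids")
        groups = np.asarray(subject_ids)[keep]

    feature_cols = [c for c in fm.columns if c not in ("subject_id", "epoch")]
    x = fm[feature_cols]
    # NaN-robust: impute column medians (sample-entropy sentinels etc.)
    x = x.fillna(x.median(numeric_only=True))

    train_idx, test_idx, cv = split_and_cv(x, labels, seed, groups)
    rank_base = x.iloc[train_idx] if rank_on == "train" else x
    rank_labels = labels[train_idx] if rank_on == "train" else labels
    ranked = rank_features(rank_base, rank_labels)

    selected, curve = forward_select(
        ranked, x.iloc[train_idx], labels[train_idx], classifier, cv,
        groups=None if groups is None else groups[train_idx],
        max_features=max_features)

    model = make_pipeline(StandardScaler(), make_classifier(classifier))
    model.fit(x.iloc[train_idx][selected], labels[train_idx])
    pred = model.predict(x.iloc[test_idx][selected])
    metrics = evaluate(labels[test_idx], pred)
    return ClassificationReport(
        task=task, classifier=classifier, split_mode=split,
        selected_features=selected, accuracy_curve=curve, metrics=metrics,
        n_train=len(train_idx), n_test=len(test_idx), seed=seed,
        rank_on=rank_on, ranked=ranked)
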