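"""Evaluation harness: subject-wise splits, stratified CV, metrics with
bootstrap confidence intervals, Wilcoxon paired tests, and the
leave-one-modality-out ablation grid."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError
from .types import CLASSES

# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------


def subject_wise_split(subject_ids: list[str], labels: list[str] | np.ndarray,
                       ratios: tuple[float, ...] = (0.7, 0.15, 0.15),
                       seed: int = 0) -> list[list[str]]:
    """Partition *subjects* (never individual samples) into len(ratios)
    groups, stratified by class; every sample of a subject follows its
    subject, preventing leakage across partitions."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigError(f"ratios must sum to 1, got {sum(ratios)}")
    subj_label: dict[str, str] = {}
    for sid, lbl in zip(subject_ids, labels):
        if subj_label.setdefault(sid, lbl) != lbl:
            raise ConfigError(f"subject {sid} has conflicting labels")
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[] for _ in ratios]
    for c_idx, cls in enumerate(sorted(set(subj_label.values()))):
        members = sorted(s for s, l in subj_label.items() if l == cls)
        members = list(rng.permutation(members))
        n = len(members)
        # largest-remainder apportionment; rotate tie-breaking across
        # classes so half-subjects alternate between partitions
        ideal = np.asarray(ratios) * n
        counts = np.floor(ideal + 1e-9).astype(int)
        tiebreak = (np.arange(len(ratios)) + c_idx) % len(ratios)
        order = np.argsort(-(ideal - counts) + 1e-12 * tiebreak)
        for j in range(n - counts.sum()):
            counts[order[j % len(order)]] += 1
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(members[start:start + c])
            start += c
    return parts


def stratified_kfold(subject_ids: list[str], labels: list[str] | np.ndarray,
                     k: int = 5, seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Subject-wise stratified k-fold: returns (train_subjects,
    test_subjects) per fold; folds are disjoint and their union is all
    subjects."""
    subj_label: dict[str, str] = {}
    for sid, lbl in zip(subject_ids, labels):
        subj_label.setdefault(sid, lbl)
    subs = sorted(subj_label)
    y = [subj_label[s] for s in subs]
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ConfigError(f"every class needs >= k={k} subjects (have {counts.to_dict()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    subs_arr = np.array(subs)
    for train_idx, test_idx in skf.split(subs_arr, y):
        out.append((subs_arr[train_idx].tolist(), subs_arr[test_idx].tolist()))
    return out


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    auc: float | None
    average_precision: float | None
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    n: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    fold_values: dict[str, list[float]] = field(default_factory=dict)

    def summary_row(self) -> dict:
        row = {"accuracy": self.accuracy, "macro_f1": self.macro_f1,
               "auc": self.auc, "ap": self.average_precision}
        for cls in CLASSES:
            row[f"{cls}_precision"] = self.precision[cls]
            row[f"{cls}_recall"] = self.recall[cls]
            row[f"{cls}_f1"] = self.f1[cls]
        return row


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_score: np.ndarray | None = None) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1, macro F1, trapezoidal AUC,
    step-interpolated average precision, and raw + row-normalized
    confusion matrices.  ``y_score`` is P(class=pd)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ConfigError("y_true and y_pred lengths differ")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros_like(cm, dtype=float),
                        where=row_sums > 0)
    auc = ap = None
    if y_score is not None and np.unique(y_true).size == 2:
        y_score = np.asarray(y_score, dtype=float)
        auc = float(roc_auc_score(y_true, y_score))
        ap = float(average_precision_score(y_true, y_score))
    return MetricsReport(
        accuracy=float((y_true == y_pred).mean()),
        precision={c: float(p) for c, p in zip(CLASSES, prec)},
        recall={c: float(r) for c, r in zip(CLASSES, rec)},
        f1={c: float(v) for c, v in zip(CLASSES, f1)},
        macro_f1=float(f1.mean()),
        auc=auc, average_precision=ap,
        confusion=cm, confusion_normalized=cm_norm, n=int(y_true.size))


def bootstrap_ci(metric_fn, y_true: np.ndarray, y_pred: np.ndarray,
                 y_score: np.ndarray | None = None, n_resamples: int = 1000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float, float]:
    """Percentile bootstrap over test-set resamples: returns
    (point estimate, lower, upper)."""
    if n_resamples < 100:
        raise ConfigError("n_resamples must be >= 100")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rng = np.random.default_rng(seed)
    n = y_true.size

    def evaluate(idx):
        if y_score is None:
            return metric_fn(y_true[idx], y_pred[idx])
        return metric_fn(y_true[idx], y_pred[idx], np.asarray(y_score)[idx])

    point = float(evaluate(np.arange(n)))
    stats = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        try:
            stats.append(float(evaluate(idx)))
        except ValueError:  # e.g. single-class resample for AUC
            continue
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return point, float(min(lo, point)), float(max(hi, point))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired fold metrics: exact
    null distribution for n <= 25 (no zero differences), normal
    approximation otherwise; all-zero differences report p = 1 with a
    warning (Pratt-style degenerate case)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ConfigError("need >= 5 paired values")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p-value undefined, reporting 1.0")
        return 0.0, 1.0
    has_zeros = np.any(d == 0)
    method = "approx" if (a.size > 25 or has_zeros) else "exact"
    res = _scipy_wilcoxon(a, b, zero_method="pratt" if has_zeros else "wilcox",
                          alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# ablation grid
# --------------------------------------------------------------------------

ABLATION_CONFIGS = (
    "handwriting", "gait", "speech",
    "handwriting+gait", "handwriting+speech", "gait+speech",
    "trimodal", "trimodal_no_xai",
)


@dataclass
class AblationGrid:
    """configuration -> MetricsReport, all on identical folds and seeds."""

    results: dict[str, MetricsReport]
    fold_seed: int
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for cfg, rep in self.results.items():
            row = rep.summary_row()
            if "accuracy" in rep.fold_values:
                fv = rep.fold_values["accuracy"]
                row["accuracy_sd"] = float(np.std(fv))
            rows[cfg] = row
        return pd.DataFrame(rows).T

    def to_markdown(self) -> str:
        df = self.to_frame()
        return df.round(3).to_markdown()


def run_ablation(evaluate_config, configs=ABLATION_CONFIGS, fold_seed: int = 0,
                 n_folds: int = 5) -> AblationGrid:
    """Evaluate every modality configuration with shared folds/seeds.

    ``evaluate_config(name)`` must return a MetricsReport computed on the
    shared fold assignments (the trimodal model object provides one).
    """
    results = {cfg: evaluate_config(cfg) for cfg in configs}
    return AblationGrid(results=results, fold_seed=fold_seed, n_folds=n_folds)
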