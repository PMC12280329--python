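"""Evaluation suite: AUROC, classification metrics with bootstrap CIs,
confusion matrices, Cohen's kappa agreement, paired reader tests and
cohort summaries.

Conventions
-----------
* Binary tasks (bladder, urethra) are scored directly; 6-class reflux
  grades are scored one-vs-rest per grade and macro-averaged over the
  grades present in the truth (absent grades are excluded with a warning).
* AUROC uses the rank (Mann–Whitney) formulation with midrank ties.
* Confidence intervals are seeded percentile bootstraps resampling at the
  subject (patient) level; resamples on which the statistic is undefined
  (e.g. a single class drawn) are redrawn and counted.
* Kappa is unweighted Cohen's kappa; a weighted variant is available behind
  a flag but is never the default.
* Percentages in cohort summaries are rounded half-up to two decimals,
  matching clinical-table style (780/1270 -> 61.42).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .utils import percent, round_half_up, substream

__all__ = [
    "roc_auc",
    "macro_ovr_auc",
    "classification_metrics",
    "bootstrap_ci",
    "confusion",
    "cohens_kappa",
    "agreement_matrix",
    "paired_reader_test",
    "cohort_summary",
    "MetricsReport",
    "task_report",
]


# --------------------------------------------------------------------------
# AUROC

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Ties in the scores are handled by midranks, so an all-tied score vector
    yields exactly 0.5.  Raises ``ValueError`` if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: only one class present")
    ranks = sps.rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _roc_auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise midrank AUROC for (R, n) score/label matrices (bootstrap
    fast path); rows with a single class return NaN."""
    ranks = sps.rankdata(scores, method="average", axis=1)
    pos = labels == 1
    n_pos = pos.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = ((ranks * pos).sum(axis=1) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    auc[(n_pos == 0) | (n_neg == 0)] = np.nan
    return auc


def macro_ovr_auc(score_matrix: np.ndarray, grades: Sequence[int]) -> float:
    """Macro one-vs-rest AUROC over the grades present in the truth.

    Each grade present in ``grades`` is scored as positive against all
    others using its score column; the per-grade AUROCs are averaged
    unweighted.  Grades absent from the truth are excluded with a warning.
    """
    scores = np.asarray(score_matrix, dtype=float)
    grades = np.asarray(grades, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != grades.shape[0]:
        raise ValueError("score_matrix must be (n_subjects, n_classes)")
    present = np.unique(grades)
    if present.size < 2:
        raise ValueError("macro AUROC needs at least 2 distinct grades")
    absent = sorted(set(range(scores.shape[1])) - set(present.tolist()))
    if absent:
        warnings.warn(f"grades absent from truth excluded from macro AUROC: {absent}",
                      stacklevel=2)
    aucs = [roc_auc(scores[:, g], (grades == g).astype(int)) for g in present]
    return float(np.mean(aucs))


# --------------------------------------------------------------------------
# thresholded classification metrics

def _binary_counts(pred: np.ndarray, truth: np.ndarray, positive: int) -> Tuple[int, int, int, int]:
    tp = int(((pred == positive) & (truth == positive)).sum())
    fn = int(((pred != positive) & (truth == positive)).sum())
    fp = int(((pred == positive) & (truth != positive)).sum())
    tn = int(((pred != positive) & (truth != positive)).sum())
    return tp, fn, fp, tn


def _safe_div(a: float, b: float) -> float:
    return float(a) / float(b) if b else float("nan")


def classification_metrics(pred: Sequence[int], truth: Sequence[int],
                           n_classes: int = 2, positive: int = 1) -> Dict[str, float]:
    """Accuracy, sensitivity, specificity and F1.

    Binary tasks use the given positive label.  For ``n_classes > 2`` each
    grade is scored one-vs-rest and the per-grade values are macro-averaged
    over grades present in the truth; per-grade values are returned under
    ``per_grade``.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length, non-empty")
    acc = float((pred == truth).mean())
    if n_classes == 2:
        tp, fn, fp, tn = _binary_counts(pred, truth, positive)
        return dict(
            accuracy=acc,
            sensitivity=_safe_div(tp, tp + fn),
            specificity=_safe_div(tn, tn + fp),
            f1=_safe_div(2 * tp, 2 * tp + fp + fn),
            n=int(pred.size),
        )
    per_grade: Dict[int, Dict[str, float]] = {}
    for g in np.unique(truth):
        tp, fn, fp, tn = _binary_counts(pred, truth, int(g))
        per_grade[int(g)] = dict(
            sensitivity=_safe_div(tp, tp + fn),
            specificity=_safe_div(tn, tn + fp),
            f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        )
    macro = {k: float(np.mean([v[k] for v in per_grade.values()]))
             for k in ("sensitivity", "specificity", "f1")}
    return dict(accuracy=acc, n=int(pred.size), per_grade=per_grade, **macro)


def confusion(pred: Sequence[int], truth: Sequence[int], k: int) -> np.ndarray:
    """k x k confusion matrix, rows = truth, columns = prediction."""
    from sklearn.metrics import confusion_matrix
    return confusion_matrix(truth, pred, labels=list(range(k)))


# --------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(statistic: Callable[[np.ndarray], float], n_subjects: int,
                 B: int = 2000, seed: int = 0, level: float = 0.95,
                 max_redraws: int = 100_000) -> Tuple[float, float, int]:
    """Seeded percentile bootstrap over subject indices.

    ``statistic`` receives an integer index array (a resample of
    ``range(n_subjects)``) and returns the statistic or raises
    ``ValueError``/returns NaN when undefined on that resample; such
    resamples are redrawn and counted.  Returns (lo, hi, n_redrawn).
    """
    full = statistic(np.arange(n_subjects))
    if not np.isfinite(full):
        raise ValueError("statistic undefined on the full sample")
    rng = substream(seed, "bootstrap")
    values = np.empty(B)
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n_subjects, size=n_subjects)
        try:
            v = statistic(idx)
        except ValueError:
            v = float("nan")
        if not np.isfinite(v):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("bootstrap: too many degenerate resamples")
            continue
        values[b] = v
        b += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi), redrawn


def bootstrap_auc_ci(scores: np.ndarray, labels: np.ndarray, B: int = 2000,
                     seed: int = 0, level: float = 0.95) -> Tuple[float, float]:
    """Vectorized percentile bootstrap CI for binary AUROC (fast path used
    by the calibration study; equivalent to :func:`bootstrap_ci` with an
    AUROC statistic, degenerate resamples redrawn)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = scores.size
    rng = substream(seed, "bootstrap")
    need = B
    out = []
    while need > 0:
        draw = rng.integers(0, n, size=(need + 16, n))
        auc = _roc_auc_rows(scores[draw], labels[draw])
        auc = auc[np.isfinite(auc)][:need]
        out.append(auc)
        need -= auc.size
    values = np.concatenate(out)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# agreement

def cohens_kappa(rater_a: Sequence[int], rater_b: Sequence[int],
                 weighted: Optional[str] = None) -> float:
    """Cohen's kappa, unweighted by default.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the raters' marginal
    products.  If both raters are constant and identical (p_e = 1) the
    agreement is perfect but chance-uncorrectable; returns 1.0 with a
    warning.  ``weighted`` may be "linear" or "quadratic".
    """
    a = np.asarray(rater_a, dtype=int)
    b = np.asarray(rater_b, dtype=int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rater vectors must be equal-length, non-empty")
    cats = np.unique(np.concatenate([a, b]))
    k = cats.size
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    table /= table.sum()
    pa = table.sum(axis=1)
    pb = table.sum(axis=0)
    if weighted is None:
        w = 1.0 - np.eye(k)
    elif weighted == "linear":
        w = np.abs(np.subtract.outer(cats, cats)).astype(float)
    elif weighted == "quadratic":
        w = np.subtract.outer(cats, cats).astype(float) ** 2
    else:
        raise ValueError(f"unknown weighting {weighted!r}")
    disagreement_o = float((w * table).sum())
    disagreement_e = float((w * np.outer(pa, pb)).sum())
    if disagreement_e == 0.0:
        warnings.warn("kappa degenerate: both raters constant and equal; "
                      "returning 1.0", stacklevel=2)
        return 1.0
    return 1.0 - disagreement_o / disagreement_e


@dataclass
class AgreementMatrix:
    readers: List[str]
    kappa: np.ndarray            # symmetric, diagonal 1

    def __post_init__(self):
        k = np.asarray(self.kappa, dtype=float)
        if k.shape != (len(self.readers), len(self.readers)):
            raise ValueError("kappa matrix shape must match reader count")
        if not np.allclose(k, k.T, atol=1e-12):
            raise ValueError("kappa matrix must be symmetric")
        self.kappa = k

    @property
    def mean_kappa(self) -> float:
        """Mean over off-diagonal reader pairs."""
        k = self.kappa
        iu = np.triu_indices(len(self.readers), 1)
        return float(k[iu].mean())


def agreement_matrix(table: pd.DataFrame, condition: str,
                     task: Optional[str] = None) -> AgreementMatrix:
    """Pairwise Cohen's kappa between all readers under one condition.

    ``table`` is long-format with columns subject_id, reader_id, condition,
    task, value (hard grades).  Subjects are aligned by id; readers must
    grade the same subjects.
    """
    sub = table[table["condition"] == condition]
    if task is not None:
        sub = sub[sub["task"] == task]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    wide = sub.pivot_table(index="subject_id", columns="reader_id",
                           values="value", aggfunc="first")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"readers with missing subjects: {missing}")
    readers = list(wide.columns)
    k = len(readers)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = cohens_kappa(wide.iloc[:, i], wide.iloc[:, j])
    return AgreementMatrix(readers=[str(r) for r in readers], kappa=mat)


def paired_reader_test(metric_a: Sequence[float], metric_b: Sequence[float]
                       ) -> Tuple[float, float]:
    """Two-sided paired t test on per-reader metric values.

    Returns (t, p).  Identical conditions give t = 0, p = 1.  A constant
    nonzero shift (zero variance of the differences) leaves the statistic
    undefined and raises ``ValueError``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired per-reader values")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        raise ValueError("degenerate pairing: constant nonzero difference, "
                         "t statistic undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


# --------------------------------------------------------------------------
# reports

@dataclass
class MetricsReport:
    task: str
    n: int
    point: Dict[str, float]
    ci: Dict[str, Tuple[float, float]]
    confusion: np.ndarray

    def __post_init__(self):
        for name, (lo, hi) in self.ci.items():
            v = self.point[name]
            if np.isfinite(v) and not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"{self.task}/{name}: point {v} outside CI ({lo},{hi})")
        if int(self.confusion.sum()) != self.n:
            raise ValueError("confusion entries must sum to n")

    def to_dict(self) -> dict:
        return dict(task=self.task, n=self.n, point=self.point,
                    ci={k: list(v) for k, v in self.ci.items()},
                    confusion=self.confusion.tolist())


def task_report(scores: np.ndarray, truth: Sequence[int], task: str,
                n_classes: int, B: int = 2000, seed: int = 0) -> MetricsReport:
    """Full per-task report: point metrics + AUROC with bootstrap 95% CIs."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pred = scores.argmax(axis=1)
    point = classification_metrics(pred, truth, n_classes=n_classes)
    point = {k: v for k, v in point.items() if k not in ("n", "per_grade")}
    if n_classes == 2:
        point["auroc"] = roc_auc(scores[:, 1], truth)
    else:
        point["auroc"] = macro_ovr_auc(scores, truth)
    ci = {}
    for name in point:
        def stat(idx, name=name):
            p, t = pred[idx], truth[idx]
            if name == "auroc":
                if n_classes == 2:
                    return roc_auc(scores[idx, 1], t)
                return macro_ovr_auc(scores[idx], t)
            m = classification_metrics(p, t, n_classes=n_classes)
            return m[name]
        lo, hi, _ = bootstrap_ci(stat, len(truth), B=B, seed=seed)
        # percentile intervals can exclude the point estimate only by
        # numerical hair; clamp so the report invariant holds
        v = point[name]
        ci[name] = (min(lo, v), max(hi, v))
    return MetricsReport(task=task, n=len(truth), point=point, ci=ci,
                         confusion=confusion(pred, truth, n_classes))


# --------------------------------------------------------------------------
# cohort summary

def cohort_summary(manifest: pd.DataFrame) -> dict:
    """Table-1-style counts and percentages for a manifest.

    Counts patients, images, sex split (with half-up two-decimal
    percentages), per-side image counts per reflux grade, and per-image
    bladder/urethra abnormal/normal counts.  Grade counts per side always
    partition the image total.
    """
    required = ["patient_id", "sex", "age_months", "lvur", "rvur",
                "bladder", "urethra"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    patients = manifest.drop_duplicates("patient_id")
    n_pat = len(patients)
    n_img = len(manifest)
    n_male = int((patients["sex"] == "M").sum())
    n_female = n_pat - n_male
    out = dict(
        patients=n_pat,
        images=n_img,
        male=(n_male, percent(n_male, n_pat)),
        female=(n_female, percent(n_female, n_pat)),
        age_mean=round_half_up(float(patients["age_months"].mean()), 2),
        age_sd=round_half_up(float(patients["age_months"].std(ddof=1)), 2)
        if n_pat > 1 else 0.0,
        grade_counts={},
        bladder={}, urethra={},
    )
    for side, col in (("left", "lvur"), ("right", "rvur")):
        counts = manifest[col].value_counts().reindex(range(6), fill_value=0)
        out["grade_counts"][side] = {g: int(counts[g]) for g in range(6)}
    for organ in ("bladder", "urethra"):
        abn = int((manifest[organ] == 1).sum())
        out[organ] = dict(abnormal=(abn, percent(abn, n_img)),
                          normal=(n_img - abn, percent(n_img - abn, n_img)))
    return out
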