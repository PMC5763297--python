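"""Cold-start cross-validation protocols and ranking metrics.

Four CV schemes mirror the four prediction scenarios:

* CV_T1 blinds random entries (lncRNA-disease pairs) of the association
  matrix; blinded entries are set to zero during training (zero encodes "no
  known association") and scored by the T1 predictor.
* CV_T2 blinds whole lncRNA rows; the model is fitted without them and the
  blinded lncRNAs are scored through the cold-start projection (T2).
* CV_T3 blinds whole disease columns analogously (T3).
* CV_T4 crosses K row-folds with K column-folds (K x K fold pairs); the
  model sees only the train-row x train-column block, test entries are the
  test-row x test-column block, and the two mixed blocks join neither side.

AUC and AUPR are computed against binary labels; for discrete/continued
matrices the binary matrix provides the labels of the same entries.  The
Correlation metric is the Pearson correlation between predicted confidence
scores and the association intensities of the scored entries.  Fold metrics
are aggregated by their mean (entry pooling available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score

from .association_builder import binarize, labels_from_binary
from .containers import LdaMatrix, SimilarityMatrix
from .graph_regression import GrufRegressor

__all__ = [
    "FoldSpec",
    "CvPlan",
    "MetricReport",
    "make_cv_plan",
    "auc",
    "aupr",
    "intensity_correlation",
    "run_cv",
]

logger = logging.getLogger(__name__)

TASKS = ("T1", "T2", "T3", "T4")


@dataclass(frozen=True)
class FoldSpec:
    """One CV round: a partition of all m x n entries into train/test/excluded."""

    train_entries: frozenset[tuple[int, int]]
    test_entries: frozenset[tuple[int, int]]
    excluded_entries: frozenset[tuple[int, int]] = frozenset()
    test_rows: tuple[int, ...] | None = None
    test_cols: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.train_entries & self.test_entries:
            raise ValueError("train and test entries overlap")
        if self.excluded_entries & (self.train_entries | self.test_entries):
            raise ValueError("excluded entries overlap train/test")


@dataclass(frozen=True)
class CvPlan:
    """A task-specific K-fold plan; T4 holds K x K row/column fold pairs."""

    task: str
    m: int
    n: int
    K: int
    seed: int
    folds: tuple[FoldSpec, ...]

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        universe = {(i, j) for i in range(self.m) for j in range(self.n)}
        for fold in self.folds:
            union = fold.train_entries | fold.test_entries | fold.excluded_entries
            if union != universe:
                raise ValueError("fold does not cover the full entry set")
        covered = [e for f in self.folds for e in f.test_entries]
        if self.task != "T4" and len(covered) != len(set(covered)):
            raise ValueError("test entries overlap across folds")
        if len(set(covered)) != self.m * self.n:
            raise ValueError("test entries do not cover all entries")


def _split(units: np.ndarray, K: int, rng: np.random.Generator) -> list[np.ndarray]:
    if K < 2 or K > len(units):
        raise ValueError(f"K={K} out of range for {len(units)} units")
    perm = rng.permutation(units)
    return np.array_split(perm, K)


def make_cv_plan(task: str, m: int, n: int, K: int, seed: int) -> CvPlan:
    """Deterministic task-specific fold construction (unit sizes differ by <= 1)."""
    task = task.upper()
    rng = np.random.default_rng(seed)
    all_entries = frozenset((i, j) for i in range(m) for j in range(n))
    folds: list[FoldSpec] = []
    if task == "T1":
        flat = _split(np.arange(m * n), K, rng)
        for chunk in flat:
            test = frozenset((int(e) // n, int(e) % n) for e in chunk)
            folds.append(FoldSpec(all_entries - test, test))
    elif task in ("T2", "T3"):
        count = m if task == "T2" else n
        for chunk in _split(np.arange(count), K, rng):
            units = tuple(int(u) for u in sorted(chunk))
            if task == "T2":
                test = frozenset((i, j) for i in units for j in range(n))
                folds.append(FoldSpec(all_entries - test, test, test_rows=units))
            else:
                test = frozenset((i, j) for j in units for i in range(m))
                folds.append(FoldSpec(all_entries - test, test, test_cols=units))
    elif task == "T4":
        row_folds = [tuple(int(u) for u in sorted(c)) for c in _split(np.arange(m), K, rng)]
        col_folds = [tuple(int(u) for u in sorted(c)) for c in _split(np.arange(n), K, rng)]
        for rows in row_folds:
            trn_r = [i for i in range(m) if i not in set(rows)]
            for cols in col_folds:
                trn_d = [j for j in range(n) if j not in set(cols)]
                test = frozenset((i, j) for i in rows for j in cols)
                train = frozenset((i, j) for i in trn_r for j in trn_d)
                folds.append(
                    FoldSpec(
                        train,
                        test,
                        all_entries - train - test,
                        test_rows=rows,
                        test_cols=cols,
                    )
                )
    else:
        raise ValueError(f"unknown task {task!r}")
    return CvPlan(task, m, n, K, seed, tuple(folds))


def _check_two_classes(labels: np.ndarray, metric: str) -> None:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(f"{metric} undefined for single-class labels {classes}")


def auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    _check_two_classes(labels, "AUC")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (no interpolation;
    equal scores form a single threshold block)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    _check_two_classes(labels, "AUPR")
    return float(average_precision_score(labels, scores))


def intensity_correlation(scores, truth, method: str = "pearson") -> float:
    """Correlation between predicted confidence scores and association intensity."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if scores.size < 3:
        raise ValueError("correlation needs at least 3 paired values")
    if np.ptp(scores) == 0 or np.ptp(truth) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        return float(stats.pearsonr(scores, truth).statistic)
    if method == "spearman":
        return float(stats.spearmanr(scores, truth).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass(frozen=True)
class MetricReport:
    """Aggregated CV metrics with per-fold detail."""

    task: str
    variant: str
    auc: float
    aupr: float
    correlation: float
    per_fold_auc: tuple[float, ...]
    per_fold_aupr: tuple[float, ...]
    per_fold_correlation: tuple[float, ...]
    n_folds: int
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "variant": self.variant,
            "auc": self.auc,
            "aupr": self.aupr,
            "correlation": self.correlation,
            "per_fold_auc": list(self.per_fold_auc),
            "per_fold_aupr": list(self.per_fold_aupr),
            "per_fold_correlation": list(self.per_fold_correlation),
            "n_folds": self.n_folds,
            "n_skipped": self.n_skipped,
        }


def _fold_scores(
    A: LdaMatrix,
    S_r: SimilarityMatrix,
    S_d: SimilarityMatrix,
    fold: FoldSpec,
    task: str,
    model: GrufRegressor,
) -> dict[tuple[int, int], float]:
    """Fit on the fold's training view and score its test entries."""
    values = A.values
    est = clone(model)
    if task == "T1":
        masked = values.copy()
        idx = tuple(np.array(sorted(fold.test_entries)).T)
        masked[idx] = 0.0
        est.fit(LdaMatrix(A.lncrna_ids, A.disease_ids, masked, A.variant), S_r, S_d)
        scores = est.predict("T1").scores
        return {e: scores[e] for e in fold.test_entries}
    if task == "T2":
        tst = list(fold.test_rows)
        trn = [i for i in range(len(A.lncrna_ids)) if i not in set(tst)]
        sub_a = LdaMatrix(
            tuple(A.lncrna_ids[i] for i in trn), A.disease_ids, values[trn], A.variant
        )
        sub_sr = S_r.subset([A.lncrna_ids[i] for i in trn])
        est.fit(sub_a, sub_sr, S_d)
        new_rows = S_r.values[np.ix_(tst, trn)]
        scores = est.predict("T2", s_new_lncrna=new_rows).scores
        row_of = {i: k for k, i in enumerate(tst)}
        return {(i, j): scores[row_of[i], j] for (i, j) in fold.test_entries}
    if task == "T3":
        tst = list(fold.test_cols)
        trn = [j for j in range(len(A.disease_ids)) if j not in set(tst)]
        sub_a = LdaMatrix(
            A.lncrna_ids, tuple(A.disease_ids[j] for j in trn), values[:, trn], A.variant
        )
        sub_sd = S_d.subset([A.disease_ids[j] for j in trn])
        est.fit(sub_a, S_r, sub_sd)
        new_cols = S_d.values[np.ix_(tst, trn)]
        scores = est.predict("T3", s_new_disease=new_cols).scores
        col_of = {j: k for k, j in enumerate(tst)}
        return {(i, j): scores[i, col_of[j]] for (i, j) in fold.test_entries}
    # T4
    tst_r, tst_d = list(fold.test_rows), list(fold.test_cols)
    trn_r = [i for i in range(len(A.lncrna_ids)) if i not in set(tst_r)]
    trn_d = [j for j in range(len(A.disease_ids)) if j not in set(tst_d)]
    sub_a = LdaMatrix(
        tuple(A.lncrna_ids[i] for i in trn_r),
        tuple(A.disease_ids[j] for j in trn_d),
        values[np.ix_(trn_r, trn_d)],
        A.variant,
    )
    est.fit(
        sub_a,
        S_r.subset([A.lncrna_ids[i] for i in trn_r]),
        S_d.subset([A.disease_ids[j] for j in trn_d]),
    )
    scores = est.predict(
        "T4",
        s_new_lncrna=S_r.values[np.ix_(tst_r, trn_r)],
        s_new_disease=S_d.values[np.ix_(tst_d, trn_d)],
    ).scores
    row_of = {i: k for k, i in enumerate(tst_r)}
    col_of = {j: k for k, j in enumerate(tst_d)}
    return {(i, j): scores[row_of[i], col_of[j]] for (i, j) in fold.test_entries}


def run_cv(
    A: LdaMatrix,
    S_r: SimilarityMatrix,
    S_d: SimilarityMatrix,
    plan: CvPlan,
    model: GrufRegressor | None = None,
    *,
    binary_labels: LdaMatrix | None = None,
    intensity: LdaMatrix | None = None,
    correlation_method: str = "pearson",
    pooled: bool = False,
) -> MetricReport:
    """Run the plan's folds and aggregate AUC / AUPR / Correlation.

    ``binary_labels`` supplies the 0/1 labels when evaluating a non-binary
    matrix; by default the binary view of ``A`` is used (for the continued
    variant an explicit matrix is required, since thresholding intensities
    is a modelling choice).  ``intensity`` is the truth for the Correlation
    metric; default is ``A`` itself.  Folds whose test entries carry a single
    label class are skipped with a warning.
    """
    if plan.m != len(A.lncrna_ids) or plan.n != len(A.disease_ids):
        raise ValueError("plan dimensions do not match the association matrix")
    model = model if model is not None else GrufRegressor()
    if binary_labels is None:
        if A.variant == "binary":
            binary_labels = A
        elif A.variant == "discrete":
            binary_labels = binarize(A)
        else:
            raise ValueError(
                "continued matrices need explicit binary_labels "
                "(thresholding intensities is left to the caller)"
            )
    label_values = labels_from_binary(A, binary_labels)
    truth = intensity.values if intensity is not None else A.values

    fold_auc, fold_aupr, fold_corr = [], [], []
    pooled_scores, pooled_labels, pooled_truth = [], [], []
    skipped = 0
    for k, fold in enumerate(plan.folds):
        scored = _fold_scores(A, S_r, S_d, fold, plan.task, model)
        entries = sorted(scored)
        s = np.array([scored[e] for e in entries])
        y = np.array([label_values[e] for e in entries])
        t = np.array([truth[e] for e in entries])
        if np.unique(y).size < 2:
            logger.warning("fold %d skipped: single-class test labels", k)
            skipped += 1
            continue
        fold_auc.append(auc(s, y))
        fold_aupr.append(aupr(s, y))
        try:
            fold_corr.append(intensity_correlation(s, t, correlation_method))
        except ValueError:
            logger.warning("fold %d: correlation undefined (constant input)", k)
            fold_corr.append(np.nan)
        pooled_scores.append(s)
        pooled_labels.append(y)
        pooled_truth.append(t)
    if not fold_auc:
        raise ValueError("every fold was skipped; no evaluable test labels")
    if pooled:
        s = np.concatenate(pooled_scores)
        y = np.concatenate(pooled_labels)
        t = np.concatenate(pooled_truth)
        agg = (auc(s, y), aupr(s, y), intensity_correlation(s, t, correlation_method))
    else:
        agg = (
            float(np.mean(fold_auc)),
            float(np.mean(fold_aupr)),
            float(np.nanmean(fold_corr)),
        )
    return MetricReport(
        task=plan.task,
        variant=A.variant,
        auc=agg[0],
        aupr=agg[1],
        correlation=agg[2],
        per_fold_auc=tuple(fold_auc),
        per_fold_aupr=tuple(fold_aupr),
        per_fold_correlation=tuple(fold_corr),
        n_folds=len(fold_auc),
        n_skipped=skipped,
    )
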