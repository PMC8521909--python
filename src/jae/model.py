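"""Logistic-regression joint health score with leave-one-subject-out CV.

The classifier is a plain logistic regression fitted by quasi-Newton
maximum likelihood (L-BFGS on the Bernoulli negative log-likelihood, with an
optional small ridge penalty on the coefficients — never the intercept — to
stabilize the fit on linearly separable data; ridge = 0 is the pure MLE).

Evaluation is leave-one-subject-out: for each fold all rows of one subject
(X_subject) are removed, the remaining matrix X' is standardized on itself,
a model is fitted, and the held-out rows are scored with X'-derived
statistics — nothing about the held-out subject ever touches training.  The
subject's joint health score is the arithmetic mean of its per-cycle JIA
probabilities; a score above the 0.5 threshold labels the subject JIA (a
tie at exactly 0.5 labels them healthy).  The majority vote over per-cycle
labels is computed alongside as a second aggregation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .features import (
    LABEL_UNKNOWN,
    FeatureMatrix,
    StandardizationStats,
    standardize_apply,
    standardize_fit,
)

__all__ = [
    "TrainedModel",
    "PredictionResult",
    "EvaluationReport",
    "FoldRecord",
    "logistic",
    "fit_logistic",
    "loso_evaluate",
    "compute_metrics",
    "score_subject",
]


def logistic(z):
    """Numerically stable sigmoid 1 / (1 + e^-z)."""
    return expit(z)


@dataclass
class TrainedModel:
    """Intercept b0, coefficients beta, and the training-fold
    standardization statistics used at fit time."""

    intercept: float
    coefficients: np.ndarray
    stats: StandardizationStats | None = None
    column_names: list[str] | None = None
    converged: bool = True

    def decision(self, values: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(values) @ self.coefficients

    def predict_proba(self, values: np.ndarray) -> np.ndarray:
        """JIA probability per row of an (already standardized) matrix."""
        return logistic(self.decision(values))


def _nll_and_grad(w, X, y, ridge):
    """Penalized Bernoulli negative log-likelihood and gradient.

    w = [b0, beta]; penalty = 0.5 * ridge * ||beta||^2 (intercept excluded).
    """
    b0, beta = w[0], w[1:]
    z = b0 + X @ beta
    # log(1 + e^z) - y*z, computed stably
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    p = expit(z)
    r = p - y
    grad = np.empty_like(w)
    grad[0] = r.sum()
    grad[1:] = X.T @ r + ridge * beta
    nll += 0.5 * ridge * float(beta @ beta)
    return nll, grad


def fit_logistic(
    X_std: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-4,
    *,
    max_iter: int = 500,
    gtol: float = 1e-6,
    stats: StandardizationStats | None = None,
) -> TrainedModel:
    """Quasi-Newton MLE for logistic regression on standardized features.

    Converged when the gradient infinity-norm drops below ``gtol`` or after
    ``max_iter`` iterations (a warning is emitted and the best iterate
    returned if the tolerance is not reached).
    """
    if isinstance(X_std, FeatureMatrix):
        values, names = X_std.values, list(X_std.column_names)
    else:
        values, names = np.asarray(X_std, dtype=float), None
    y = np.asarray(y, dtype=float).ravel()
    if values.shape[0] != y.size:
        raise ValueError("X and y disagree on row count")
    classes = np.unique(y)
    if LABEL_UNKNOWN in classes:
        raise ValueError("training labels contain unknown (-1) rows")
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError(f"training set must contain both classes, got {classes}")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")

    w0 = np.zeros(values.shape[1] + 1)
    res = minimize(
        _nll_and_grad, w0, args=(values, y, float(ridge)), jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14, "maxfun": 10 * max_iter},
    )
    grad_inf = float(np.max(np.abs(res.jac)))
    converged = grad_inf < gtol * 10 or res.success
    if not converged:
        warnings.warn(
            f"logistic MLE not fully converged (|grad|_inf={grad_inf:.2e}); "
            "returning best iterate", stacklevel=2)
    return TrainedModel(intercept=float(res.x[0]), coefficients=res.x[1:].copy(),
                        stats=stats, column_names=names, converged=converged)


# ------------------------------------------------------------------- metrics

@dataclass
class EvaluationReport:
    """Confusion counts and derived metrics at one level (cycle or subject),
    plus the ROC over probabilities."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    error_rate: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    auc: float | None = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("tp", "fp", "tn", "fn", "accuracy", "error_rate",
              "sensitivity", "specificity", "ppv", "npv")}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _safe_div(a: float, b: float) -> float:
    return a / b if b else float("nan")


def compute_metrics(pred_labels, truths, probabilities=None) -> EvaluationReport:
    """Confusion counts, sensitivity/specificity/PPV/NPV/accuracy, and —
    when probabilities are given — the ROC curve (threshold sweep) and its
    trapezoid AUC."""
    pred = np.asarray(pred_labels, dtype=int).ravel()
    truth = np.asarray(truths, dtype=int).ravel()
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.size != truth.size:
        raise ValueError("length mismatch")
    if not np.isin(truth, [0, 1]).all():
        raise ValueError("truths must be binary")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    acc = (tp + tn) / pred.size
    rep = EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, error_rate=1.0 - acc,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
    )
    if probabilities is not None and len(np.unique(truth)) == 2:
        probs = np.asarray(probabilities, dtype=float).ravel()
        fpr, tpr, _ = _sk_roc_curve(truth, probs)
        rep.roc_fpr, rep.roc_tpr = fpr, tpr
        rep.auc = float(_sk_auc(fpr, tpr))
    return rep


# ------------------------------------------------------------------ LOSO CV

@dataclass
class FoldRecord:
    """Internals of one LOSO fold, kept for leakage audits."""

    subject_id: str
    stats: StandardizationStats
    model: TrainedModel
    probabilities: np.ndarray  # held-out rows, row order of X_subject
    truth: int


@dataclass
class PredictionResult:
    """Per-cycle probabilities and per-subject joint health scores."""

    row_meta: "object"
    p_predicted: np.ndarray
    cycle_labels: np.ndarray
    subject_scores: dict[str, float]
    subject_labels_mean: dict[str, int]      # Eq.-style mean-probability rule
    subject_labels_majority: dict[str, int]  # majority of cycle labels
    subject_truth: dict[str, int]
    folds: list[FoldRecord] = field(default_factory=list)


def score_subject(probabilities: np.ndarray, threshold: float = 0.5) -> tuple[float, int]:
    """Joint health score = mean cycle probability; label JIA only when the
    score strictly exceeds the threshold (a tie is healthy)."""
    score = float(np.mean(probabilities))
    return score, int(score > threshold)


def loso_evaluate(
    X: FeatureMatrix,
    ridge: float = 1e-4,
    threshold: float = 0.5,
    *,
    keep_folds: bool = False,
) -> tuple[PredictionResult, dict[str, EvaluationReport]]:
    """Leave-one-subject-out evaluation over the baseline rows of X.

    Follow-up rows (label unknown) are excluded from every training fold and
    from evaluation.  Returns the per-row/per-subject predictions and
    reports at cycle and subject level (subject level under both
    aggregation rules).
    """
    base = X.baseline()
    labels = base.meta["label"].to_numpy()
    if np.any(labels == LABEL_UNKNOWN):
        raise ValueError("baseline rows carry unknown labels")
    subjects = base.meta["subject_id"].unique()
    subj_truth = {s: int(base.meta.loc[base.meta.subject_id == s, "label"].iloc[0])
                  for s in subjects}
    for cls in (0, 1):
        if sum(1 for s in subjects if subj_truth[s] == cls) < 2:
            raise ValueError("need >= 2 subjects per class for LOSO")

    p_all = np.full(base.n_rows, np.nan)
    folds: list[FoldRecord] = []
    for s in subjects:
        hold = (base.meta["subject_id"] == s).to_numpy()
        X_train = base.select_rows(~hold)
        y_train = X_train.meta["label"].to_numpy()
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"fold {s}: training set lost a class")
        stats = standardize_fit(X_train)
        model = fit_logistic(standardize_apply(stats, X_train), y_train,
                             ridge=ridge, stats=stats)
        X_hold = standardize_apply(stats, base.select_rows(hold))
        probs = model.predict_proba(X_hold.values)
        p_all[hold] = probs
        if keep_folds:
            folds.append(FoldRecord(subject_id=s, stats=stats, model=model,
                                    probabilities=probs, truth=subj_truth[s]))

    cycle_labels = (p_all > threshold).astype(int)
    scores, lab_mean, lab_major = {}, {}, {}
    for s in subjects:
        mask = (base.meta["subject_id"] == s).to_numpy()
        scores[s], lab_mean[s] = score_subject(p_all[mask], threshold)
        frac_jia = float(np.mean(cycle_labels[mask]))
        lab_major[s] = int(frac_jia > 0.5)  # even split -> healthy

    result = PredictionResult(
        row_meta=base.meta, p_predicted=p_all, cycle_labels=cycle_labels,
        subject_scores=scores, subject_labels_mean=lab_mean,
        subject_labels_majority=lab_major, subject_truth=subj_truth,
        folds=folds,
    )
    reports = {
        "cycle": compute_metrics(cycle_labels, labels, p_all),
        "subject_mean": compute_metrics([lab_mean[s] for s in subjects],
                                        [subj_truth[s] for s in subjects],
                                        [scores[s] for s in subjects]),
        "subject_majority": compute_metrics([lab_major[s] for s in subjects],
                                            [subj_truth[s] for s in subjects]),
    }
    return result, reports
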