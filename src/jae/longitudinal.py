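"""Longitudinal joint-health-score tracking over paired visits.

Follow-up recordings never enter any training set (their clinical label is
a spectrum of convalescence, not a binary ground truth).  Each paired
subject's baseline and follow-up rows are scored by a model trained on
baseline rows only, by default excluding the scored subject's own baseline
rows as well so no identity information leaks into its score.  The score
drop (baseline - follow-up) is tested with a one-tailed paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .features import FeatureMatrix, standardize_apply, standardize_fit
from .model import fit_logistic, score_subject

__all__ = ["PairedScores", "TTestResult", "score_pairs", "paired_one_tailed_ttest"]


@dataclass
class PairedScores:
    """Per-subject baseline/follow-up joint health scores and deltas."""

    table: pd.DataFrame  # subject_id, baseline_score, followup_score, delta

    @property
    def deltas(self) -> np.ndarray:
        return self.table["delta"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TTestResult:
    t_statistic: float
    dof: int
    p_value: float
    mean_delta: float
    sd_delta: float
    degenerate: bool = False  # zero-variance deltas with nonzero mean


def score_pairs(
    X: FeatureMatrix,
    ridge: float = 1e-4,
    threshold: float = 0.5,
    *,
    exclude: str = "subject",
) -> PairedScores:
    """Score each follow-up subject's two visits with a baseline-only model.

    exclude="subject" (default): per scored subject, train on all baseline
    rows except that subject's own.  exclude="cohort": one model trained on
    all baseline subjects that have no follow-up visit (the clinical
    protocol's reading).
    """
    if exclude not in ("subject", "cohort"):
        raise ValueError("exclude must be 'subject' or 'cohort'")
    is_follow = (X.meta["visit"] == "followup").to_numpy()
    followup_subjects = list(dict.fromkeys(X.meta.loc[is_follow, "subject_id"]))
    if not followup_subjects:
        raise ValueError("no follow-up rows in the matrix")
    base = X.baseline()
    base_subjects = set(base.meta["subject_id"])
    missing = [s for s in followup_subjects if s not in base_subjects]
    if missing:
        raise ValueError(f"follow-up subjects without baseline rows: {missing}")

    def _fit(excluded: set[str]):
        mask = ~base.meta["subject_id"].isin(excluded).to_numpy()
        X_train = base.select_rows(mask)
        stats = standardize_fit(X_train)
        model = fit_logistic(standardize_apply(stats, X_train),
                             X_train.meta["label"].to_numpy(),
                             ridge=ridge, stats=stats)
        return stats, model

    shared = _fit(set(followup_subjects)) if exclude == "cohort" else None

    rows = []
    for s in followup_subjects:
        stats, model = shared if shared is not None else _fit({s})
        out = {}
        for visit in ("baseline", "followup"):
            mask = ((X.meta["subject_id"] == s) & (X.meta["visit"] == visit)).to_numpy()
            probs = model.predict_proba(standardize_apply(stats, X.select_rows(mask)).values)
            out[visit], _ = score_subject(probs, threshold)
        rows.append((s, out["baseline"], out["followup"],
                     out["baseline"] - out["followup"]))
    table = pd.DataFrame(rows, columns=["subject_id", "baseline_score",
                                        "followup_score", "delta"])
    return PairedScores(table=table)


def paired_one_tailed_ttest(deltas: np.ndarray) -> TTestResult:
    """One-tailed paired t-test of mean(delta) > 0.

    t = mean / (sd / sqrt(n)) with the sample (n-1) SD; p is the upper-tail
    Student-t probability at n-1 degrees of freedom.  Zero-variance deltas
    with a nonzero mean give t = +/-inf with p = 0 or 1 and are flagged.
    """
    d = np.asarray(deltas, dtype=float).ravel()
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired deltas")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, dof, 0.5, mean, sd)
        t = float("inf") if mean > 0 else float("-inf")
        return TTestResult(t, dof, 0.0 if mean > 0 else 1.0, mean, sd,
                           degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = float(sp_stats.t.sf(t, dof))
    return TTestResult(float(t), dof, p, mean, sd)
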