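"""Feature importance and the feature x cycle accuracy grid.

With the matrix standardized to zero mean and unit variance, the absolute
values of the logistic-regression coefficients are directly comparable, so
a single fit on all labeled baseline rows yields an importance ranking.
The accuracy grid then measures subject-level LOSO accuracy as a joint
function of how many top-ranked features the model sees and how many
movement cycles of the held-out subject are available at test time, with
the cycle subsets averaged over up to ``perm_cap`` unique random
combinations per cell.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .features import FeatureMatrix, standardize_apply, standardize_fit
from .model import TrainedModel, fit_logistic

__all__ = ["ImportanceRanking", "HeatmapResult", "rank_features", "accuracy_heatmap"]

logger = logging.getLogger(__name__)


@dataclass
class ImportanceRanking:
    """(feature_name, |coefficient|) pairs, descending; ties keep column
    order."""

    features: list[str]
    magnitudes: np.ndarray
    model: TrainedModel | None = None

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def __len__(self) -> int:
        return len(self.features)


def _check_standardized(X: FeatureMatrix) -> None:
    means = X.values.mean(axis=0)
    var = X.values.var(axis=0)
    ok = (np.abs(means) < 1e-6) & ((np.abs(var - 1.0) < 1e-2) | (var < 1e-10))
    if not ok.all():
        bad = [X.column_names[i] for i in np.flatnonzero(~ok)][:5]
        raise ValueError(
            f"matrix does not look standardized (e.g. columns {bad}); "
            "rank_features requires zero-mean / unit-variance input")


def rank_features(X: FeatureMatrix, ridge: float = 1e-4) -> ImportanceRanking:
    """Rank columns by |beta| from one fit on all labeled baseline rows.

    ``X`` must already be standardized on those rows (follow-up rows, which
    lack a ground truth, are excluded before the call).
    """
    base = X.baseline()
    _check_standardized(base)
    y = base.meta["label"].to_numpy()
    model = fit_logistic(base, y, ridge=ridge)
    mags = np.abs(model.coefficients)
    order = np.argsort(-mags, kind="stable")  # ties -> earlier column first
    return ImportanceRanking(
        features=[base.column_names[i] for i in order],
        magnitudes=mags[order], model=model)


@dataclass
class HeatmapResult:
    """accuracy[k-1, m-1] = mean subject-level LOSO accuracy using the top-k
    features and m-cycle test subsets."""

    accuracy: np.ndarray
    n_subsets: np.ndarray
    feature_counts: np.ndarray
    cycle_counts: np.ndarray
    seed: int


def _subset_rng(seed: int, subject: str, k: int, m: int) -> np.random.Generator:
    key = int.from_bytes(
        hashlib.sha256(f"{subject}/{k}/{m}".encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def _unique_subsets(n: int, m: int, cap: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Up to ``cap`` distinct m-subsets of range(n): exhaustive when small,
    rejection-sampled otherwise."""
    total = comb(n, m)
    if total <= cap:
        return np.array(list(combinations(range(n), m)), dtype=int)
    seen: set[tuple] = set()
    out: list[tuple] = []
    while len(out) < cap:
        # batch-draw m-subsets as the smallest-key entries of random rows
        keys = rng.random((2 * (cap - len(out)), n))
        subs = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
        for row in map(tuple, subs):
            if row not in seen:
                seen.add(row)
                out.append(row)
                if len(out) == cap:
                    break
    return np.array(out, dtype=int)


def accuracy_heatmap(
    X: FeatureMatrix,
    ranking: ImportanceRanking,
    max_features: int = 20,
    perm_cap: int = 1000,
    seed: int = 0,
    *,
    ridge: float = 1e-4,
    threshold: float = 0.5,
) -> HeatmapResult:
    """LOSO subject accuracy over (top-k features) x (m test cycles).

    For each k, one LOSO pass fits fold models on the top-k columns; for
    each m, every held-out subject is scored on up to ``perm_cap`` unique
    m-subsets of its pooled rows (all channels), classified by the mean
    probability rule, and the cell holds the mean correctness over subjects
    and subsets.  Subjects with fewer than m rows contribute their full row
    set for that m.
    """
    if perm_cap < 1:
        raise ValueError("perm_cap must be >= 1")
    base = X.baseline()
    if max_features > len(base.column_names):
        raise ValueError("max_features exceeds available columns")
    subjects = base.meta["subject_id"].unique()
    truth = {s: int(base.meta.loc[base.meta.subject_id == s, "label"].iloc[0])
             for s in subjects}
    max_cycles = int(base.meta.groupby("subject_id").size().max())

    acc = np.zeros((max_features, max_cycles))
    counts = np.zeros((max_features, max_cycles), dtype=int)

    for k in range(1, max_features + 1):
        Xk = base.select_columns(ranking.top(k))
        # one LOSO pass: per-subject held-out probabilities with top-k columns
        probs: dict[str, np.ndarray] = {}
        for s in subjects:
            hold = (Xk.meta["subject_id"] == s).to_numpy()
            X_train = Xk.select_rows(~hold)
            stats = standardize_fit(X_train)
            model = fit_logistic(standardize_apply(stats, X_train),
                                 X_train.meta["label"].to_numpy(), ridge=ridge)
            X_hold = standardize_apply(stats, Xk.select_rows(hold))
            probs[s] = model.predict_proba(X_hold.values)
        for m in range(1, max_cycles + 1):
            cell_acc, cell_n = [], 0
            for s in subjects:
                p = probs[s]
                mm = min(m, len(p))
                if mm < m:
                    logger.info("subject %s has %d rows < m=%d: using full set",
                                s, len(p), m)
                rng = _subset_rng(seed, s, k, m)
                subsets = _unique_subsets(len(p), mm, perm_cap, rng)
                scores = p[subsets].mean(axis=1)
                correct = ((scores > threshold).astype(int) == truth[s])
                cell_acc.append(float(np.mean(correct)))
                cell_n += len(subsets)
            acc[k - 1, m - 1] = float(np.mean(cell_acc))
            counts[k - 1, m - 1] = cell_n
    return HeatmapResult(accuracy=acc, n_subsets=counts,
                         feature_counts=np.arange(1, max_features + 1),
                         cycle_counts=np.arange(1, max_cycles + 1), seed=seed)
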