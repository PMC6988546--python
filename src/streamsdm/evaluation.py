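"""Cross-validated discrimination metrics for presence-background models.

Presence records are randomly partitioned into k folds (sizes differing
by at most one); per fold the model is refitted on the training folds
and two metrics are computed and averaged across folds:

* AUC_test — rank-based (Mann-Whitney) discrimination of the held-out
  test presences against predictions at *all* background segments, with
  ties counted 0.5.  Invariant to any monotone transform of the
  predictions, so raw and cloglog give identical values.
* OR_mtp — the omission rate of test presences at the minimum training
  presence (MTP) threshold, i.e. the fraction of test predictions
  strictly below the lowest training-presence prediction.  The training
  set's own omission at MTP is exactly zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import maxent
from ._util import rank_auc
from .swd_io import PresenceSet, SegmentTable

__all__ = ["kfold_partition", "auc_test", "mtp_threshold", "or_mtp",
           "evaluate", "EvaluationResult"]


def kfold_partition(n_records: int, k: int, seed: int = 0) -> np.ndarray:
    """Seeded fold label (0..k-1) per record; fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_records < k:
        raise ValueError(f"cannot split {n_records} records into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    labels = np.empty(n_records, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        labels[chunk] = f
    return labels


def auc_test(test_preds, background_preds) -> float:
    """Rank-based AUC of test-presence predictions vs all background."""
    return rank_auc(np.asarray(test_preds), np.asarray(background_preds))


def mtp_threshold(training_preds) -> float:
    """Minimum training presence: the lowest prediction at a training record."""
    training_preds = np.asarray(training_preds, dtype=float)
    if training_preds.size == 0:
        raise ValueError("no training predictions")
    return float(training_preds.min())


def or_mtp(test_preds, threshold: float) -> float:
    """Fraction of test predictions strictly below the threshold
    (a record exactly at MTP is not omitted — the threshold is inclusive)."""
    test_preds = np.asarray(test_preds, dtype=float)
    if test_preds.size == 0:
        raise ValueError("no test predictions")
    return float((test_preds < threshold).mean())


@dataclass
class EvaluationResult:
    per_fold: pd.DataFrame   # fold, n_test, auc_test, mtp, or_mtp
    k: int
    seed: int
    mean_auc: float
    mean_or: float


def evaluate(segments: SegmentTable, presences: PresenceSet, beta: float = 1.0,
             classes="auto", covariates: list[str] | None = None,
             n_knots: int = 50, k: int = 5, seed: int = 0,
             tol: float = 1e-5) -> EvaluationResult:
    """k-fold cross-validation of one model specification.

    Feature classes follow the *full* presence count (so every fold uses
    the same specification); per fold the model is refitted on the
    training presences, predictions are taken over the full background,
    and AUC_test / OR_mtp are computed from the held-out fold.
    """
    ids = presences.segment_ids.drop_duplicates().to_numpy()
    n = len(ids)
    labels = kfold_partition(n, k, seed)
    if classes == "auto":
        classes = tuple(c for c in maxent.FEATURE_CLASSES
                        if n >= maxent.AUTOFEATURE_MIN_N[c])
    rows = []
    for f in range(k):
        train = ids[labels != f]
        test = ids[labels == f]
        fs = maxent.build_features(segments, train, classes=classes,
                                   covariates=covariates, n_knots=n_knots)
        try:
            m = maxent.fit(fs, train, segments, beta=beta, tol=tol)
        except (ValueError, RuntimeError) as e:
            raise RuntimeError(f"fold {f}: model fit failed ({e})") from e
        pred = maxent.predict(m, segments)
        pos = {sid: i for i, sid in enumerate(pred.segment_ids)}
        train_pred = pred.cloglog[[pos[s] for s in train]]
        test_pred = pred.cloglog[[pos[s] for s in test]]
        thr = mtp_threshold(train_pred)
        rows.append({"fold": f, "n_test": len(test),
                     "auc_test": auc_test(test_pred, pred.cloglog),
                     "mtp": thr, "or_mtp": or_mtp(test_pred, thr)})
    per_fold = pd.DataFrame(rows)
    return EvaluationResult(per_fold=per_fold, k=k, seed=seed,
                            mean_auc=float(per_fold["auc_test"].mean()),
                            mean_or=float(per_fold["or_mtp"].mean()))
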