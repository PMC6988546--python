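"""Small shared numerics."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score


def rank_auc(positive: np.ndarray, negative: np.ndarray) -> float:
    """Mann-Whitney AUC of ``positive`` scores vs ``negative`` scores.

    Ties count 0.5, matching the rank-sum definition used for
    presence-vs-background discrimination.
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    if len(positive) == 0 or len(negative) == 0:
        raise ValueError("AUC needs nonempty score sets")
    y = np.concatenate([np.ones(len(positive)), np.zeros(len(negative))])
    s = np.concatenate([positive, negative])
    if np.ptp(s) == 0:
        return 0.5
    return float(roc_auc_score(y, s))
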