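"""Cross-model comparison: binary maps, niche overlap, ensemble agreement.

Binary suitability maps threshold the cloglog output at a model's MTP
(inclusive: suitable iff cloglog >= threshold).  Niche similarity between
two models is measured on their background-normalized raw densities p
and q (each re-normalized to sum 1):

    Schoener's D = 1 - 0.5 * sum |p_i - q_i|        (total-variation complement)
    Warren's  I  = 1 - 0.5 * sum (sqrt p_i - sqrt q_i)^2   (Hellinger complement)

Both live in [0, 1] with D <= I entrywise.  The ensemble map counts, per
segment, how many of M binary maps call it suitable (0..M) — segments
with high agreement are the most robust targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import PredictionVector

__all__ = ["BinaryMap", "SimilarityMatrix", "EnsembleMap", "binary_map",
           "schoeners_d", "warrens_i", "pairwise_similarity", "ensemble"]


@dataclass
class BinaryMap:
    segment_ids: np.ndarray
    suitable: np.ndarray
    threshold: float
    label: str = ""

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())

    @property
    def fraction_suitable(self) -> float:
        return float(self.suitable.mean())


@dataclass
class SimilarityMatrix:
    labels: list[str]
    d: pd.DataFrame
    i: pd.DataFrame


@dataclass
class EnsembleMap:
    segment_ids: np.ndarray
    counts: np.ndarray
    labels: list[str]

    def histogram(self) -> pd.Series:
        """Number of segments at each agreement level 0..M."""
        m = len(self.labels)
        return pd.Series(np.bincount(self.counts, minlength=m + 1),
                         index=range(m + 1), name="n_segments")


def binary_map(pred: PredictionVector, threshold: float, label: str = "") -> BinaryMap:
    """Suitable iff cloglog >= threshold (the MTP convention)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return BinaryMap(pred.segment_ids, pred.cloglog >= threshold, threshold, label)


def _normalized_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, PredictionVector) and isinstance(q, PredictionVector):
        if len(p.segment_ids) != len(q.segment_ids) or \
                (p.segment_ids != q.segment_ids).any():
            raise ValueError("prediction vectors cover different segment universes")
        p, q = p.raw, q.raw
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("mismatched universes")
    return p / p.sum(), q / q.sum()


def schoeners_d(p, q) -> float:
    """Overlap D = 1 - TV(p, q) of two normalized suitability distributions."""
    pn, qn = _normalized_pair(p, q)
    return float(1.0 - 0.5 * np.abs(pn - qn).sum())


def warrens_i(p, q) -> float:
    """Overlap I = 1 - 0.5 * squared Hellinger distance; always >= D."""
    pn, qn = _normalized_pair(p, q)
    return float(1.0 - 0.5 * ((np.sqrt(pn) - np.sqrt(qn)) ** 2).sum())


def pairwise_similarity(preds: dict[str, PredictionVector] | list[PredictionVector]
                        ) -> SimilarityMatrix:
    """Full pairwise D and I matrices over a set of models."""
    if not isinstance(preds, dict):
        preds = {f"model_{i}": p for i, p in enumerate(preds)}
    if len(preds) < 2:
        raise ValueError("need at least 2 models to compare")
    labels = list(preds)
    d = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    i_mat = d.copy()
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            pa, pb = preds[labels[a]], preds[labels[b]]
            dv = schoeners_d(pa, pb)
            iv = warrens_i(pa, pb)
            d.iloc[a, b] = d.iloc[b, a] = dv
            i_mat.iloc[a, b] = i_mat.iloc[b, a] = iv
    return SimilarityMatrix(labels, d, i_mat)


def ensemble(maps: list[BinaryMap]) -> EnsembleMap:
    """Per-segment count of binary maps calling the segment suitable."""
    if not maps:
        raise ValueError("need at least one binary map")
    ids = maps[0].segment_ids
    for m in maps[1:]:
        if len(m.segment_ids) != len(ids) or (m.segment_ids != ids).any():
            raise ValueError("binary maps cover different segment universes")
    counts = np.sum([m.suitable.astype(int) for m in maps], axis=0)
    return EnsembleMap(ids, counts, [m.label or f"model_{i}" for i, m in enumerate(maps)])
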