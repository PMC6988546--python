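"""AICc-based complexity selection over a beta-multiplier grid.

One candidate model is fitted per regularization multiplier on the grid
(default 1.0 to 5.0 by 0.5).  For each candidate, k is the number of
nonzero coefficients read off the fitted model, the log-likelihood is
the sum over presence segments of the log of the background-normalized
raw density, and

    AICc = 2k - 2 logL + 2k(k+1) / (n - k - 1)

with n the number of (deduplicated) presence segments.  A candidate
with n - k - 1 <= 0 has more parameters than data points and its AICc
is undefined; the chosen multiplier minimizes AICc among defined rows,
ties broken toward larger (more parsimonious) multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maxent
from .swd_io import PresenceSet, SegmentTable

__all__ = ["beta_grid", "model_loglik", "aicc", "select_model", "SelectionResult"]


def beta_grid(lo: float = 1.0, hi: float = 5.0, step: float = 0.5) -> np.ndarray:
    """Inclusive arithmetic sequence of regularization multipliers."""
    if step <= 0:
        raise ValueError("step must be > 0")
    if lo > hi:
        raise ValueError("lo must be <= hi")
    n = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    return grid[grid <= hi + 1e-9]


def model_loglik(model: maxent.MaxentModel, presence_ids,
                 background: SegmentTable) -> float:
    """Presence log-likelihood under the background-normalized raw density."""
    pred = maxent.predict(model, background)
    raw = pred.raw / pred.raw.sum()
    pos = {sid: i for i, sid in enumerate(pred.segment_ids)}
    idx = np.unique([pos[s] for s in presence_ids])
    vals = raw[idx]
    if (vals <= 0).any():
        bad = pred.segment_ids[idx[vals <= 0][0]]
        raise ValueError(f"presence segment {bad!r} has zero predicted density")
    return float(np.log(vals).sum())


def aicc(k: int, logL: float, n: int) -> float | None:
    """Small-sample AIC; ``None`` when n - k - 1 <= 0 (undefined)."""
    if k < 0 or n < 1:
        raise ValueError("k must be >= 0 and n >= 1")
    if n - k - 1 <= 0:
        return None
    return 2.0 * k - 2.0 * logL + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class SelectionResult:
    """Per-beta complexity ledger plus the chosen multiplier."""

    table: pd.DataFrame        # beta, k, logL, aicc, aicc_defined, auc_test, or_mtp
    chosen_beta: float
    models: dict = field(default_factory=dict, repr=False)

    @property
    def chosen_model(self) -> maxent.MaxentModel:
        return self.models[self.chosen_beta]


def select_model(segments: SegmentTable, presences: PresenceSet,
                 grid=None, classes="auto", covariates: list[str] | None = None,
                 n_knots: int = 50, tol: float = 1e-5,
                 folds: int | None = None, seed: int = 0,
                 evaluate_all: bool = False) -> SelectionResult:
    """Fit one model per multiplier, tabulate k/logL/AICc, pick the minimum.

    With ``folds`` set, cross-validated AUC and omission metrics are
    attached to the default (first grid value) and chosen rows — or every
    row when ``evaluate_all`` — using one fold partition shared across
    the grid.
    """
    from . import evaluation  # local import to avoid a cycle

    if grid is None:
        grid = beta_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("beta grid is empty")
    ids = presences.segment_ids.drop_duplicates()
    n = len(ids)
    fs = maxent.build_features(segments, ids, classes=classes,
                               covariates=covariates, n_knots=n_knots)
    rows, models = [], {}
    for b in grid:
        m = maxent.fit(fs, ids, segments, beta=float(b), tol=tol)
        k = maxent.count_nonzero(m)
        ll = model_loglik(m, ids, segments)
        a = aicc(k, ll, n)
        models[float(b)] = m
        rows.append({"beta": float(b), "k": k, "logL": ll,
                     "aicc": np.nan if a is None else a,
                     "aicc_defined": a is not None,
                     "auc_test": np.nan, "or_mtp": np.nan})
    table = pd.DataFrame(rows)
    defined = table[table["aicc_defined"]]
    if defined.empty:
        raise ValueError(
            "AICc undefined for every multiplier (k >= n - 1 throughout); "
            "increase the presence sample or extend the beta grid")
    best = defined["aicc"].min()
    # ties toward larger beta (parsimony)
    chosen = float(defined.loc[np.isclose(defined["aicc"], best), "beta"].max())

    if folds is not None:
        want = set(table["beta"]) if evaluate_all else {float(grid[0]), chosen}
        for b in sorted(want):
            res = evaluation.evaluate(segments, presences, beta=b, classes=classes,
                                      covariates=covariates, n_knots=n_knots,
                                      k=folds, seed=seed, tol=tol)
            table.loc[table["beta"] == b, "auc_test"] = res.mean_auc
            table.loc[table["beta"] == b, "or_mtp"] = res.mean_or
    return SelectionResult(table=table, chosen_beta=chosen, models=models)
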