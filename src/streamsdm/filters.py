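"""Spatial-bias corrections for presence records.

Two thinning strategies: a classical *distance filter* retaining the
maximum number of records at least ``min_km`` apart in straight-line
aerial distance (iterative most-neighbors removal, repeated and the best
repetition kept, as in the spatial-thinning literature), and a
*riverscape filter* retaining one record per unique (HUC8 watershed,
Strahler stream order) combination — an environmental-filter analogue
that evens out coverage across watersheds and stream sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .swd_io import PresenceSet, SegmentTable

__all__ = ["FilterResult", "distance_filter", "riverscape_filter", "bias_diagnostics"]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class FilterResult:
    retained: PresenceSet
    removed: PresenceSet
    method: str
    params: dict
    seed: int | None

    def __post_init__(self) -> None:
        r = set(self.retained.data["record_id"])
        d = set(self.removed.data["record_id"])
        if r & d:
            raise ValueError("retained and removed sets overlap")


def _pairwise_km(x: np.ndarray, y: np.ndarray, latlon: bool) -> np.ndarray:
    if not latlon:
        return squareform(pdist(np.column_stack([x, y])))
    lon = np.radians(x)
    lat = np.radians(y)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _split(p: PresenceSet, keep_mask: np.ndarray, method: str, params: dict,
           seed: int | None) -> FilterResult:
    return FilterResult(
        retained=PresenceSet(p.data[keep_mask]),
        removed=PresenceSet(p.data[~keep_mask]),
        method=method, params=params, seed=seed)


def distance_filter(p: PresenceSet, min_km: float = 20.0, reps: int = 100,
                    seed: int = 0, latlon: bool = False) -> FilterResult:
    """Thin records so all retained pairs are >= ``min_km`` apart.

    Per repetition, the record with the most neighbors closer than
    ``min_km`` is removed (ties broken by seeded random choice) until no
    violating pair remains; across ``reps`` repetitions the run retaining
    the most records wins.  This maximum-retention heuristic matches the
    convention of spatial-thinning tools; the retained count can never be
    smaller than a single greedy pass since the first repetition *is* one.
    """
    if min_km <= 0:
        raise ValueError("min_km must be > 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = len(p)
    params = {"min_km": min_km, "reps": reps}
    if n == 0:
        return _split(p, np.zeros(0, dtype=bool), "distance", params, seed)
    if p.data["x"].isna().any() or p.data["y"].isna().any():
        bad = p.data.loc[p.data["x"].isna() | p.data["y"].isna(), "record_id"].tolist()
        raise ValueError(f"records missing coordinates: {bad}")
    dist = _pairwise_km(p.data["x"].to_numpy(float), p.data["y"].to_numpy(float), latlon)
    close = (dist < min_km)
    np.fill_diagonal(close, False)
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(reps):
        alive = np.ones(n, dtype=bool)
        adj = close.copy()
        counts = adj.sum(axis=1)
        while counts[alive].max(initial=0) > 0:
            worst = counts == counts[alive].max()
            worst &= alive
            cand = np.flatnonzero(worst)
            victim = int(rng.choice(cand))
            alive[victim] = False
            counts -= adj[victim]
            adj[victim, :] = False
            adj[:, victim] = False
            counts[victim] = 0
        if best is None or alive.sum() > best.sum():
            best = alive
    return _split(p, best, "distance", params, seed)


def riverscape_filter(p: PresenceSet, seed: int = 0) -> FilterResult:
    """Retain one record per unique (HUC8, stream order) combination.

    Within each combination the retained record is chosen uniformly at
    random under ``seed`` (a reproducible stand-in for the haphazard
    manual choice); the retained count always equals the number of
    distinct combinations present in the input.
    """
    df = p.data
    missing = df.loc[df["huc8"].isna() | df["stream_order"].isna(), "record_id"].tolist()
    if missing:
        raise ValueError(f"records missing huc8 or stream_order: {missing}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(df), dtype=bool)
    for _, grp in df.groupby(["huc8", "stream_order"], sort=True):
        pos = grp.index.to_numpy()
        keep[int(rng.choice(pos))] = True
    return _split(p, keep, "riverscape", {}, seed)


def bias_diagnostics(p: PresenceSet, segments: SegmentTable) -> dict:
    """Quantify presence bias relative to the background universe.

    Returns stream-order distributions (presence vs background
    proportions), the fraction of watersheds holding >= 1 record, mean
    presence vs background x-coordinate (downstream gradient), and mean
    covariate comparisons where covariates exist.
    """
    seg = segments.data
    orders = sorted(seg["stream_order"].unique())
    pres_counts = p.data["stream_order"].value_counts()
    bg_counts = seg["stream_order"].value_counts()
    table = pd.DataFrame({
        "stream_order": orders,
        "presence_prop": [pres_counts.get(o, 0) / max(len(p), 1) for o in orders],
        "background_prop": [bg_counts.get(o, 0) / len(seg) for o in orders],
    })
    out = {
        "order_distribution": table,
        "huc8_coverage": p.data["huc8"].nunique() / seg["huc8"].nunique(),
        "mean_x_presence": float(p.data["x"].mean()) if len(p) else float("nan"),
        "mean_x_background": float(seg["x"].mean()),
    }
    if segments.covariates:
        linked = seg.set_index("segment_id").loc[p.data["segment_id"]]
        out["covariate_means"] = pd.DataFrame({
            "presence_mean": linked[segments.covariates].mean(),
            "background_mean": seg[segments.covariates].mean(),
        })
    return out
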