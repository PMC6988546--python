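"""Seeded synthetic dendritic riverscapes.

Generates the three ingredients every downstream stage needs, without any
external hydrography download: (1) a rooted stream-network tree with
Strahler orders, accumulated drainage area and a HUC8-like watershed
partition; (2) environmental covariates on realistic ranges — discharge
grows downstream as a power law of drainage area (max scaled to ~1,279
m^3/s), elevation decreases monotonically along every flow path, and the
soil/geology covariates are spatially autocorrelated along the tree;
(3) a true suitability that is a rising logistic function of log
discharge, and presence records sampled from it with a tunable bias
toward large, downstream segments — emulating the access-driven sampling
bias typical of compiled occurrence datasets in large river basins.

Everything is deterministic under a fixed seed; per-stage sub-seeds are
derived from the master seed so individual stages can be regenerated
independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .swd_io import PresenceSet, SegmentTable

__all__ = [
    "RiverscapeParams",
    "generate_network",
    "assign_covariates",
    "true_suitability",
    "sample_presences",
    "generate_riverscape",
    "strahler_orders",
]

#: covariate name -> (min, max) range enforced by the generator
COVARIATE_RANGES = {
    "Q": (0.0, 1279.0),        # mean annual discharge, m^3/s
    "ELEV": (63271.0, 396264.0),   # max elevation, cm
    "SLOPE": (0.0, 1.0),       # dimensionless
    "SAND": (5.0, 83.0),       # mean % sand of soils
    "RCKDEP": (42.0, 152.0),   # mean depth to bedrock, cm
    "CAO": (0.0, 48.0),        # % lithological CaO
    "DSLINK": (1.0, 9.0),      # downstream mainstem link order
}


@dataclass(frozen=True)
class RiverscapeParams:
    """Study conditions for one synthetic riverscape.

    Attributes
    ----------
    n_segments : int
        Tree size; the modeling universe and background sample.
    branching_prob : float
        Probability a new segment starts a confluence rather than
        extending an existing channel tip; controls dendricity.
    discharge_exponent : float
        Power-law exponent of discharge vs accumulated drainage area.
    discharge_noise_sd : float
        SD of the lognormal noise multiplying the discharge power law.
    q50 : float
        Discharge (m^3/s) at which true suitability is 0.5.
    steepness : float
        Slope of the logistic in log-discharge.
    bias_strength : float
        >= 0; exponent weighting presence sampling toward high-discharge
        (downstream) segments.  0 gives suitability-proportional sampling.
    n_presences : int
    n_watersheds : int
        HUC8-like partition size.
    seed : int
    """

    n_segments: int = 2000
    branching_prob: float = 0.35
    discharge_exponent: float = 0.9
    discharge_noise_sd: float = 0.3
    q50: float = 15.0
    steepness: float = 2.0
    bias_strength: float = 3.0
    n_presences: int = 40
    n_watersheds: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 10:
            raise ValueError("n_segments must be >= 10")
        if self.n_presences < 0 or self.n_watersheds < 1:
            raise ValueError("counts must be positive")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        if self.q50 <= 0:
            raise ValueError("q50 must be > 0")


def stage_seed(seed: int, stage: str) -> int:
    """Stable sub-seed for a named generation stage (always < 2**31)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def strahler_orders(parent: np.ndarray) -> np.ndarray:
    """Strahler order per node for a rooted tree given each node's parent.

    ``parent[i]`` is the downstream node index, or -1 at the outlet.
    Standard rule: a node whose children's maximum order o is attained by
    at least two children gets o+1, otherwise o; leaves are order 1.
    """
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    root = -1
    for i, p in enumerate(parent):
        if p < 0:
            root = i
        else:
            children[p].append(i)
    order = np.zeros(n, dtype=int)
    # iterative post-order
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            if not children[node]:
                order[node] = 1
            else:
                kid_orders = [order[c] for c in children[node]]
                m = max(kid_orders)
                order[node] = m + 1 if kid_orders.count(m) >= 2 else m
        else:
            stack.append((node, True))
            for c in children[node]:
                stack.append((c, False))
    return order


def _subtree_sizes(parent: np.ndarray, topo: np.ndarray) -> np.ndarray:
    """Subtree node counts; ``topo`` is any upstream-before-downstream order
    reversed (i.e. children listed before parents)."""
    n = len(parent)
    size = np.ones(n, dtype=int)
    for i in topo:
        if parent[i] >= 0:
            size[parent[i]] += size[i]
    return size


def _partition_watersheds(parent: np.ndarray, topo: np.ndarray, k: int) -> np.ndarray:
    """Cut k-1 edges to split the tree into k connected watersheds.

    Greedy: repeatedly cut the uncut subtree whose size is closest to the
    balanced target n/k, recomputing sizes after each cut.  Membership of
    a node is the nearest cut root at or below it (the outlet component
    is watershed 0).
    """
    n = len(parent)
    cut = np.zeros(n, dtype=bool)
    eff_parent = parent.copy()
    target = n / k
    for _ in range(k - 1):
        size = _subtree_sizes(eff_parent, topo)
        # candidates: non-root, uncut-subtree roots with a live parent
        cand = [i for i in range(n) if eff_parent[i] >= 0]
        if not cand:
            break
        best = min(cand, key=lambda i: (abs(size[i] - target), i))
        cut[best] = True
        eff_parent[best] = -1
    ws = np.full(n, -1, dtype=int)
    roots = [i for i in range(n) if eff_parent[i] < 0]
    for label, r in enumerate(roots):
        ws[r] = label
    # parents-first pass: children inherit unless they are cut roots
    for i in topo[::-1]:
        p = parent[i]
        if p >= 0 and not cut[i]:
            ws[i] = ws[p]
    return ws


def generate_network(params: RiverscapeParams) -> SegmentTable:
    """Grow a dendritic tree of ``n_segments`` and return it as a SegmentTable.

    Growth starts from the outlet; each new segment either extends an
    existing channel tip upstream or joins an existing single-tributary
    segment to form a confluence (probability ``branching_prob``),
    keeping every junction binary as in real flowline networks.  Planar
    x increases toward the outlet (the basin's downstream gradient);
    edge lengths average ~5 km.
    """
    if params.n_watersheds > params.n_segments:
        raise ValueError("n_watersheds cannot exceed n_segments")
    rng = np.random.default_rng(stage_seed(params.seed, "network"))
    n = params.n_segments
    parent = np.full(n, -1, dtype=int)
    n_children = np.zeros(n, dtype=int)
    tips: list[int] = [0]        # zero-child nodes
    mid: list[int] = []          # one-child nodes (confluence candidates)
    for i in range(1, n):
        use_mid = mid and (not tips or rng.random() < params.branching_prob)
        pool = mid if use_mid else tips
        j = int(rng.integers(len(pool)))
        p = pool.pop(j)
        parent[i] = p
        n_children[p] += 1
        if n_children[p] == 1:
            mid.append(p)
        # p had 1 child and now has 2: drop silently (already popped)
        tips.append(i)

    # children-first topological order = reverse BFS from root
    order_bfs = [0]
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    head = 0
    while head < len(order_bfs):
        node = order_bfs[head]
        head += 1
        order_bfs.extend(children[node])
    topo = np.array(order_bfs[::-1], dtype=int)

    strahler = strahler_orders(parent)
    watershed = _partition_watersheds(parent, topo, params.n_watersheds)

    # planar embedding: x decreases upstream, y wanders; edge lengths are
    # sized so the basin spans several hundred km (a large-river basin at
    # reduced segment count keeps per-segment reaches long)
    x = np.zeros(n)
    y = np.zeros(n)
    for node in order_bfs[1:]:
        p = parent[node]
        x[node] = x[p] - rng.uniform(8.0, 25.0)
        y[node] = y[p] + rng.uniform(-12.0, 12.0)

    df = pd.DataFrame({
        "segment_id": [f"S{i:05d}" for i in range(n)],
        "downstream_id": [None if parent[i] < 0 else f"S{parent[i]:05d}" for i in range(n)],
        "huc8": [f"H{w:03d}" for w in watershed],
        "stream_order": strahler,
        "x": x,
        "y": y,
    })
    return SegmentTable(df, covariates=[])


def _tree_ar1(parent: np.ndarray, order_bfs: list[int], rng: np.random.Generator,
              rho: float = 0.9) -> np.ndarray:
    """Standard-normal field with AR(1) autocorrelation along the tree."""
    n = len(parent)
    z = np.zeros(n)
    z[order_bfs[0]] = rng.standard_normal()
    for node in order_bfs[1:]:
        z[node] = rho * z[parent[node]] + np.sqrt(1 - rho**2) * rng.standard_normal()
    return z


def assign_covariates(net: SegmentTable, params: RiverscapeParams) -> SegmentTable:
    """Attach the seven environmental covariates to a generated network.

    Discharge Q = c * A^exponent * lognormal noise (A = accumulated
    drainage area), rescaled so the basin maximum is ~1,279 m^3/s.
    Elevation accumulates positive increments upstream, then is mapped
    affinely onto the published cm range, preserving monotone decrease
    downstream.  SLOPE/SAND/RCKDEP/CAO are AR(1) fields along the tree
    pushed through the normal CDF onto their ranges.  DSLINK is the
    Strahler order of the next segment downstream.
    """
    rng = np.random.default_rng(stage_seed(params.seed, "covariates"))
    df = net.data.copy()
    n = len(df)
    idx = {sid: i for i, sid in enumerate(df["segment_id"])}
    parent = np.array([-1 if pd.isna(d) or d is None else idx[d]
                       for d in df["downstream_id"]])
    children: list[list[int]] = [[] for _ in range(n)]
    root = int(np.flatnonzero(parent < 0)[0])
    for i in range(n):
        if parent[i] >= 0:
            children[parent[i]].append(i)
    order_bfs = [root]
    head = 0
    while head < len(order_bfs):
        order_bfs.extend(children[order_bfs[head]])
        head += 1

    # local catchment areas (km^2), accumulated downstream
    local = rng.lognormal(mean=0.0, sigma=0.6, size=n) * 2.0
    area = local.copy()
    for i in order_bfs[::-1]:
        if parent[i] >= 0:
            area[parent[i]] += area[i]

    q = area ** params.discharge_exponent
    q *= rng.lognormal(0.0, params.discharge_noise_sd, size=n)
    qmin, qmax = COVARIATE_RANGES["Q"]
    q = q * (qmax / q.max())
    q = np.clip(q, qmin, qmax)

    # elevation: strictly increasing upstream along every path
    elev_raw = np.zeros(n)
    for node in order_bfs[1:]:
        elev_raw[node] = elev_raw[parent[node]] + rng.lognormal(0.0, 0.5) * 10.0
    emin, emax = COVARIATE_RANGES["ELEV"]
    span = elev_raw.max() - elev_raw.min()
    elev = emin + (elev_raw - elev_raw.min()) / span * (emax - emin)

    fields = {}
    for name in ("SLOPE", "SAND", "RCKDEP", "CAO"):
        lo, hi = COVARIATE_RANGES[name]
        z = _tree_ar1(parent, order_bfs, rng)
        fields[name] = lo + ndtr(z) * (hi - lo)

    dslink = np.array([df["stream_order"].iloc[parent[i]] if parent[i] >= 0
                       else df["stream_order"].iloc[i] for i in range(n)], dtype=float)

    df["Q"] = q
    df["ELEV"] = elev
    df["SLOPE"] = fields["SLOPE"]
    df["SAND"] = fields["SAND"]
    df["RCKDEP"] = fields["RCKDEP"]
    df["CAO"] = fields["CAO"]
    df["DSLINK"] = dslink
    df["drainage_area"] = area
    return SegmentTable(df, covariates=list(COVARIATE_RANGES), latlon=net.latlon)


def true_suitability(segments: SegmentTable, params: RiverscapeParams) -> np.ndarray:
    """Logistic-in-log-discharge truth: 0.5 at q50, saturating to 1 downstream."""
    q = np.maximum(segments.data["Q"].to_numpy(float), 1e-6)
    return expit(params.steepness * (np.log(q) - np.log(params.q50)))


def sample_presences(segments: SegmentTable, suitability: np.ndarray,
                     params: RiverscapeParams) -> PresenceSet:
    """Draw presence segments without replacement, biased downstream.

    Sampling weight is suitability * (q/q_max)^bias_strength, so
    ``bias_strength = 0`` reduces to suitability-proportional sampling
    and larger values congregate records along the largest rivers.
    """
    suitability = np.asarray(suitability, dtype=float)
    if suitability.min() < 0 or suitability.max() > 1:
        raise ValueError("suitability must lie in [0, 1]")
    rng = np.random.default_rng(stage_seed(params.seed, "presences"))
    q = np.maximum(segments.data["Q"].to_numpy(float), 1e-9)
    w = suitability * (q / q.max()) ** params.bias_strength
    positive = int((w > 0).sum())
    if params.n_presences == 0:
        return PresenceSet(pd.DataFrame(columns=["record_id", "segment_id"]))
    if positive < params.n_presences:
        raise ValueError(
            f"only {positive} segments have positive sampling weight; "
            f"cannot draw {params.n_presences} presences")
    pick = rng.choice(len(w), size=params.n_presences, replace=False, p=w / w.sum())
    rows = segments.data.iloc[pick]
    df = pd.DataFrame({
        "record_id": [f"P{i:04d}" for i in range(params.n_presences)],
        "segment_id": rows["segment_id"].to_numpy(),
        "huc8": rows["huc8"].to_numpy(),
        "stream_order": rows["stream_order"].to_numpy(),
        "x": rows["x"].to_numpy(),
        "y": rows["y"].to_numpy(),
        "source": "synthetic",
        "year": 2000 + (np.arange(params.n_presences) % 19),
    })
    return PresenceSet(df)


def generate_riverscape(params: RiverscapeParams) -> tuple[SegmentTable, PresenceSet, np.ndarray]:
    """Convenience: network + covariates + truth + biased presences."""
    net = generate_network(params)
    seg = assign_covariates(net, params)
    suit = true_suitability(seg, params)
    pres = sample_presences(seg, suit, params)
    return seg, pres, suit
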