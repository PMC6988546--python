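"""Samples-with-data (SWD) tables for stream-segment distribution modeling.

Non-raster Maxent workflows replace raster grids with two delimited text
tables: a *segment table* holding one row per stream segment (the modeling
universe / background sample, identified by a COMID-like id) with its
environmental covariates and network attributes, and a *presence table*
of occurrence records linked to segments by id.  This module defines both
containers, their readers/writers, presence deduplication, and the
pairwise-correlation screen used to pick a low-collinearity covariate
subset before model fitting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SegmentTable",
    "PresenceSet",
    "CorrelationReport",
    "SubsetCheck",
    "read_segments",
    "write_segments",
    "read_presences",
    "write_presences",
    "write_swd",
    "dedupe_presences",
    "link_presences",
    "correlation_screen",
    "validate_subset",
]

#: canonical non-covariate columns of a segment table
SEGMENT_COLUMNS = ["segment_id", "downstream_id", "huc8", "stream_order", "x", "y"]

#: canonical presence-record columns
PRESENCE_COLUMNS = ["record_id", "segment_id", "huc8", "stream_order", "x", "y",
                    "source", "year"]


class SWDError(ValueError):
    """Raised when an SWD table violates its contract."""


def _check_no_cycles(segment_id: pd.Series, downstream_id: pd.Series) -> None:
    """Verify the downstream links form a forest (no cycles).

    Iterative traversal with memoized colors; O(n) overall.
    """
    parent = dict(zip(segment_id, downstream_id))
    color: dict = {}  # 1 = on current path, 2 = done
    for start in parent:
        if color.get(start) == 2:
            continue
        path = []
        node = start
        while node in parent and not pd.isna(parent[node]):
            c = color.get(node)
            if c == 2:
                break
            if c == 1:
                raise SWDError(f"downstream links contain a cycle through segment {node!r}")
            color[node] = 1
            path.append(node)
            node = parent[node]
        for v in path:
            color[v] = 2


@dataclass
class SegmentTable:
    """One row per stream segment: ids, topology, watershed, coordinates, covariates.

    ``data`` holds the canonical columns (:data:`SEGMENT_COLUMNS`) plus one
    numeric column per covariate named in ``covariates``.  ``downstream_id``
    is NaN/None at the outlet.  Coordinates are planar km unless ``latlon``
    is set, in which case x=longitude and y=latitude in degrees.
    """

    data: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    latlon: bool = False

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SWDError(f"segment table missing columns: {missing}")
        dup = df["segment_id"][df["segment_id"].duplicated()]
        if len(dup):
            raise SWDError(f"duplicate segment_id: {dup.iloc[0]!r}")
        for c in self.covariates:
            if not c or not isinstance(c, str):
                raise SWDError("every covariate column must be named")
            if c not in df.columns:
                raise SWDError(f"covariate column {c!r} missing from table")
        order = df["stream_order"]
        if (order < 1).any() or not np.issubdtype(order.dtype, np.number):
            raise SWDError("stream_order must be a positive integer")
        _check_no_cycles(df["segment_id"], df["downstream_id"])
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def segment_ids(self) -> pd.Series:
        return self.data["segment_id"]

    def covariate_frame(self) -> pd.DataFrame:
        """Covariate columns only, indexed by segment_id."""
        return self.data.set_index("segment_id")[self.covariates]


@dataclass
class PresenceSet:
    """Occurrence records linked to stream segments by id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for c in ("record_id", "segment_id"):
            if c not in df.columns:
                raise SWDError(f"presence table missing column {c!r}")
        for c in PRESENCE_COLUMNS:
            if c not in df.columns:
                df = df.assign(**{c: np.nan})
        self.data = df[PRESENCE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def segment_ids(self) -> pd.Series:
        return self.data["segment_id"]


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations over the background, plus flagged pairs."""

    matrix: pd.DataFrame
    violations: list[tuple[str, str, float]]
    threshold: float


@dataclass
class SubsetCheck:
    passed: bool
    offending: list[tuple[str, str, float]]


# ---------------------------------------------------------------------------
# readers / writers


def read_segments(path, schema: dict[str, str] | None = None,
                  covariates: list[str] | None = None,
                  latlon: bool = False) -> SegmentTable:
    """Read a segment table from delimited text.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row.
    schema : dict, optional
        Maps file column names to canonical names (e.g. ``{"COMID":
        "segment_id"}``).
    covariates : list of str, optional
        Which columns are covariates; default: every column not in
        :data:`SEGMENT_COLUMNS`.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SWDError(f"segment file missing columns: {missing}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in SEGMENT_COLUMNS]
    for c in covariates:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SWDError(
                f"non-numeric covariate value {df[c].iloc[row]!r} at row {row}, column {c!r}")
        df[c] = coerced
    dup = df["segment_id"][df["segment_id"].duplicated()]
    if len(dup):
        raise SWDError(f"duplicate segment_id: {dup.iloc[0]!r}")
    return SegmentTable(df, covariates=list(covariates), latlon=latlon)


def write_segments(table: SegmentTable, path) -> None:
    cols = SEGMENT_COLUMNS + list(table.covariates)
    table.data[cols].to_csv(path, index=False)


def read_presences(path, schema: dict[str, str] | None = None,
                   segments: SegmentTable | None = None) -> PresenceSet:
    """Read presence records; optionally resolve attributes from ``segments``."""
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    p = PresenceSet(df)
    if segments is not None:
        p = link_presences(p, segments)
    return p


def write_presences(p: PresenceSet, path) -> None:
    p.data.to_csv(path, index=False)


def write_swd(segments: SegmentTable, path, presences: PresenceSet | None = None,
              species: str = "background") -> None:
    """Write a samples-with-data CSV: ``species,segment_id,<covariate...>``.

    With ``presences`` given, only their segments are written and the first
    column carries the species label; otherwise all segments are written as
    background rows.
    """
    cov = segments.covariate_frame()
    if presences is not None:
        ids = presences.segment_ids
        unresolved = ids[~ids.isin(cov.index)]
        if len(unresolved):
            raise SWDError(f"presence segment_id not in segment table: {unresolved.iloc[0]!r}")
        cov = cov.loc[ids]
    out = cov.reset_index()
    out.insert(0, "species", species)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# presence cleaning


def link_presences(p: PresenceSet, segments: SegmentTable) -> PresenceSet:
    """Fill huc8/stream_order/x/y on each record from the segment table by id."""
    ids = p.data["segment_id"]
    seg = segments.data.set_index("segment_id")
    unresolved = ids[~ids.isin(seg.index)]
    if len(unresolved):
        raise SWDError(
            f"presence segment_id does not resolve in segment table: {unresolved.iloc[0]!r}")
    joined = p.data.copy()
    for c in ("huc8", "stream_order", "x", "y"):
        joined[c] = seg.loc[ids, c].to_numpy()
    return PresenceSet(joined)


def dedupe_presences(p: PresenceSet, segments: SegmentTable | None = None) -> PresenceSet:
    """Collapse records to one per stream segment (first in file order kept).

    This mirrors Maxent's "remove duplicates" switch for SWD input: no
    segment may be represented more than once in training.
    """
    if segments is not None:
        ids = p.data["segment_id"]
        seg_ids = set(segments.data["segment_id"])
        unresolved = [i for i in ids if i not in seg_ids]
        if unresolved:
            raise SWDError(f"presence segment_id does not resolve: {unresolved[0]!r}")
    return PresenceSet(p.data.drop_duplicates(subset="segment_id", keep="first"))


# ---------------------------------------------------------------------------
# covariate screening


def correlation_screen(segments: SegmentTable, threshold: float = 0.70) -> CorrelationReport:
    """Pairwise Pearson r over all segments (the background), flag |r| > threshold.

    Multicollinear covariate pairs inflate each other's apparent importance
    in presence-background models; the conventional screen keeps a subset
    with |r| <= 0.70.
    """
    cov = segments.covariate_frame()
    if cov.shape[1] < 2:
        raise SWDError("correlation screen needs at least 2 covariates")
    if len(cov) < 3:
        raise SWDError("correlation screen needs at least 3 segments")
    sd = cov.std(ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise SWDError(f"zero-variance covariate: {dead[0]!r}")
    mat = cov.corr(method="pearson")
    np.fill_diagonal(mat.values, 1.0)
    violations = []
    names = list(mat.columns)
    for a, b in itertools.combinations(names, 2):
        r = float(mat.loc[a, b])
        if abs(r) > threshold:
            violations.append((a, b, r))
    return CorrelationReport(matrix=mat, violations=violations, threshold=threshold)


def validate_subset(report: CorrelationReport, chosen: list[str]) -> SubsetCheck:
    """Check that no pair within ``chosen`` exceeds the report's threshold."""
    known = set(report.matrix.columns)
    for c in chosen:
        if c not in known:
            raise SWDError(f"unknown covariate {c!r}")
    chosen_set = set(chosen)
    offending = [(a, b, r) for (a, b, r) in report.violations
                 if a in chosen_set and b in chosen_set]
    return SubsetCheck(passed=not offending, offending=offending)


def auto_select_covariates(report: CorrelationReport,
                           priority: list[str] | None = None) -> list[str]:
    """Greedy low-collinearity subset: walk covariates in priority order,
    keep each one whose |r| with everything already kept is within threshold."""
    names = priority if priority is not None else list(report.matrix.columns)
    kept: list[str] = []
    for c in names:
        if all(abs(report.matrix.loc[c, k]) <= report.threshold for k in kept):
            kept.append(c)
    return kept
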