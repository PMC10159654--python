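"""Reading, validation and pre-processing of longitudinal curve tables.

The raw material is a long-format table with one row per measurement:
a sample identifier, an observation time (arbitrary real units, e.g. days)
and an observed value (e.g. tumor volume in mm^3).  Optional side tables
carry per-curve annotations (categorical or numeric features keyed by id)
and a grouping map from curve id to a parent-sample id (replicate curves
sharing, say, an engrafted parental tumor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

logger = logging.getLogger("curveclust")

__all__ = [
    "CurveObservations",
    "LongitudinalDataset",
    "TimeGridSummary",
    "read_longitudinal",
    "read_annotations",
    "read_grouping",
    "write_longitudinal",
    "truncate_window",
    "summarize_grid",
]


@dataclass(frozen=True)
class CurveObservations:
    """One curve: strictly increasing times and the values observed there."""

    curve_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).reshape(-1)
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if t.size != v.size or t.size < 1:
            raise ValueError(f"curve {self.curve_id!r}: times and values must be equal length >= 1")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"curve {self.curve_id!r}: duplicate observation times")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError(f"curve {self.curve_id!r}: non-finite observation")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_obs(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class LongitudinalDataset:
    """A collection of curves plus optional annotations and replicate grouping."""

    curves: tuple[CurveObservations, ...]
    annotations: dict = field(default_factory=dict)
    grouping: dict | None = None
    time_window: tuple[float, float] | None = None

    def __post_init__(self):
        curves = tuple(self.curves)
        if not curves:
            raise EmptyInputError("dataset has no curves")
        ids = [c.curve_id for c in curves]
        if len(set(ids)) != len(ids):
            raise ValueError("curve ids are not unique")
        known = set(ids)
        for cid in self.annotations:
            if cid not in known:
                raise ValueError(f"annotation for unknown curve id {cid!r}")
        if self.grouping is not None:
            for cid in self.grouping:
                if cid not in known:
                    raise ValueError(f"grouping for unknown curve id {cid!r}")
        lo = min(c.times[0] for c in curves)
        hi = max(c.times[-1] for c in curves)
        window = (lo, hi) if self.time_window is None else tuple(map(float, self.time_window))
        if window[0] > lo or window[1] < hi:
            raise ValueError("observations fall outside the declared time window")
        object.__setattr__(self, "curves", curves)
        object.__setattr__(self, "time_window", window)

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def curve_ids(self) -> list[str]:
        return [c.curve_id for c in self.curves]

    def subset(self, ids) -> "LongitudinalDataset":
        """Dataset restricted to the given curve ids (order preserved)."""
        keep = set(ids)
        curves = tuple(c for c in self.curves if c.curve_id in keep)
        ann = {k: v for k, v in self.annotations.items() if k in keep}
        grp = None
        if self.grouping is not None:
            grp = {k: v for k, v in self.grouping.items() if k in keep}
        return LongitudinalDataset(curves, ann, grp, self.time_window)


@dataclass(frozen=True)
class TimeGridSummary:
    """Pooled view of the observation grid, used for knot placement and
    the time-density heat-map view."""

    pooled_times: np.ndarray
    counts_per_time: dict
    per_curve_counts: dict
    time_window: tuple[float, float]


def _detect_delimiter(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_longitudinal(path, delimiter: str | None = None) -> LongitudinalDataset:
    """Read a long-format curve table with header ``id,time,value``.

    The delimiter is auto-detected (tab vs comma) from the first line unless
    given.  Extra columns are ignored with a warning.  Rows with a non-finite
    time or value are dropped and counted; exact duplicate (id, time) rows are
    collapsed to one observation and conflicting repeated measurements at one
    time point are averaged, each with a logged warning.  A curve whose every
    row is invalid is dropped with a warning.
    """
    sep = delimiter or _detect_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty file") from None
    missing = {"id", "time", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    extra = [c for c in df.columns if c not in ("id", "time", "value")]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, extra)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    df = df.assign(
        id=df["id"].astype(str),
        time=pd.to_numeric(df["time"], errors="coerce"),
        value=pd.to_numeric(df["value"], errors="coerce"),
    )
    bad = ~(np.isfinite(df["time"]) & np.isfinite(df["value"]))
    if bad.any():
        logger.warning("%s: dropped %d row(s) with non-finite time/value", path, int(bad.sum()))
    all_ids = list(dict.fromkeys(df["id"]))
    df = df[~bad]

    # collapse duplicates: exact duplicates -> one row; conflicts -> average
    dup = df.duplicated(["id", "time"], keep=False)
    if dup.any():
        conflicts = df[dup].groupby(["id", "time"])["value"].nunique()
        n_conflict = int((conflicts > 1).sum())
        if n_conflict:
            logger.warning(
                "%s: %d (id, time) pair(s) with conflicting repeated values; averaged",
                path, n_conflict,
            )
        else:
            logger.warning("%s: collapsed exact duplicate (id, time) rows", path)
        df = df.groupby(["id", "time"], as_index=False, sort=False)["value"].mean()

    curves = []
    for cid in all_ids:
        sub = df[df["id"] == cid]
        if sub.empty:
            logger.warning("%s: curve %r dropped (no valid rows)", path, cid)
            continue
        curves.append(CurveObservations(cid, sub["time"].to_numpy(), sub["value"].to_numpy()))
    if not curves:
        raise EmptyInputError(f"{path}: every row was invalid")
    return LongitudinalDataset(tuple(curves))


def read_annotations(path, delimiter: str | None = None) -> dict:
    """Read an annotation table with header ``id,<feature1>,...`` into a
    mapping curve_id -> {feature: value}."""
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'id'")
    df["id"] = df["id"].astype(str)
    return {row["id"]: {c: row[c] for c in df.columns if c != "id"} for _, row in df.iterrows()}


def read_grouping(path, delimiter: str | None = None) -> dict:
    """Read a grouping table with header ``id,parent_id`` into a mapping
    curve_id -> parent_id."""
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    missing = {"id", "parent_id"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return dict(zip(df["id"].astype(str), df["parent_id"].astype(str)))


def write_longitudinal(ds: LongitudinalDataset, path, delimiter: str = ",") -> None:
    """Write a dataset back to the long-format text layout (full precision,
    so that a read round-trips bit-for-bit)."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(("id", "time", "value")) + "\n")
        for c in ds.curves:
            for t, v in zip(c.times, c.values):
                fh.write(delimiter.join((c.curve_id, format(t, ".17g"), format(v, ".17g"))) + "\n")


def truncate_window(
    ds: LongitudinalDataset, t_min: float, t_max: float, min_obs: int = 2
) -> LongitudinalDataset:
    """Restrict every curve to observations with t in [t_min, t_max].

    Curves left with fewer than ``min_obs`` points are dropped (their count is
    logged).  Raises :class:`EmptyInputError` if the window excludes all data.
    """
    if not t_min < t_max:
        raise ValueError(f"t_min={t_min} must be < t_max={t_max}")
    kept, dropped = [], 0
    for c in ds.curves:
        mask = (c.times >= t_min) & (c.times <= t_max)
        if int(mask.sum()) < min_obs:
            dropped += 1
            continue
        kept.append(CurveObservations(c.curve_id, c.times[mask], c.values[mask]))
    if dropped:
        logger.warning("truncate_window: dropped %d curve(s) with < %d in-window points",
                       dropped, min_obs)
    if not kept:
        raise EmptyInputError(f"window [{t_min}, {t_max}] leaves no curve with >= {min_obs} points")
    ids = {c.curve_id for c in kept}
    grouping = None
    if ds.grouping is not None:
        grouping = {k: v for k, v in ds.grouping.items() if k in ids}
    annotations = {k: v for k, v in ds.annotations.items() if k in ids}
    return LongitudinalDataset(tuple(kept), annotations, grouping, (float(t_min), float(t_max)))


def summarize_grid(ds: LongitudinalDataset) -> TimeGridSummary:
    """Pooled-time density: how many curves are observed at each time point,
    and how many observations each curve carries."""
    pooled = np.sort(np.concatenate([c.times for c in ds.curves]))
    counts: dict[float, int] = {}
    for c in ds.curves:
        for t in c.times:
            counts[float(t)] = counts.get(float(t), 0) + 1
    per_curve = {c.curve_id: c.n_obs for c in ds.curves}
    return TimeGridSummary(pooled, counts, per_curve, ds.time_window)
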