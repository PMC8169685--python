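"""Data model and file I/O for scotopic visual motor response (VMR) recordings.

A VMR experiment tracks one larva per well of a 96-well plate and bins its
displacement (cm) into 1-s intervals for the duration of a stimulus protocol.
The protocol in this package is a sequence of dark/light segments; the
analyzed event is the single light offset, after which the startle burst
("light-off VMR") occurs.

Time convention
---------------
``t_sec`` is the 0-based index of a 1-s bin: bin ``j`` covers the interval
``(j, j+1]`` seconds from recording start, so every recorded ``t_sec`` is
strictly less than the protocol duration.  Stimulus events fall on bin
boundaries.  Post-event offsets are 1-based and inclusive: offset ``k`` after
an event at time ``tau`` is the bin covering ``(tau+k-1, tau+k]``, i.e. bin
index ``tau + k - 1``.  The window "1 to 30 s after light offset" therefore
has exactly 30 columns.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    InsufficientSampleError,
    ProtocolError,
    TraceFormatError,
    WindowRangeError,
)

__all__ = [
    "TRACE_COLUMNS",
    "Segment",
    "StimulusProtocol",
    "SCOTOPIC_PROTOCOL",
    "PlateTrace",
    "WindowMatrix",
    "read_trace_csv",
    "write_trace_csv",
    "extract_window",
    "attenuated_intensity",
    "well_position",
    "well_name",
]

#: Column order of the trace CSV dialect.
TRACE_COLUMNS = (
    "plate",
    "batch",
    "well",
    "genotype",
    "treatment",
    "dose_uM",
    "t_sec",
    "displacement_cm",
)

WELL_ROWS = "ABCDEFGH"
WELL_COLUMNS = tuple(range(1, 13))


def well_name(row: int, col: int) -> str:
    """Return the canonical well label, e.g. ``well_name(0, 1) == "A1"``."""
    return f"{WELL_ROWS[row]}{col}"


def well_position(well: str) -> tuple[int, int]:
    """Parse a well label into 0-based row and 1-based column indices.

    Raises :class:`TraceFormatError` for labels outside A1..H12.
    """
    well = str(well).strip()
    if len(well) < 2 or well[0].upper() not in WELL_ROWS:
        raise TraceFormatError(f"malformed well label {well!r}")
    try:
        col = int(well[1:])
    except ValueError as exc:
        raise TraceFormatError(f"malformed well label {well!r}") from exc
    if col not in WELL_COLUMNS:
        raise TraceFormatError(f"well column out of range in {well!r}")
    return WELL_ROWS.index(well[0].upper()), col


@dataclass(frozen=True)
class Segment:
    """One protocol segment: a lighting condition held for a fixed duration."""

    label: str  # "dark" or "light"
    duration_s: int
    lux: float  # illuminance at plate level

    def __post_init__(self) -> None:
        if self.label not in ("dark", "light"):
            raise ProtocolError(f"segment label must be 'dark' or 'light', got {self.label!r}")
        if int(self.duration_s) != self.duration_s or self.duration_s <= 0:
            raise ProtocolError(f"segment duration must be a positive integer, got {self.duration_s!r}")
        if self.lux < 0:
            raise ProtocolError(f"illuminance must be >= 0, got {self.lux!r}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered dark/light segments with derived event times.

    The analyzed protocol has exactly one light-to-dark transition (the
    light offset that triggers the startle burst under scotopic conditions).
    """

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ProtocolError("protocol must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration_s(self) -> int:
        return int(sum(s.duration_s for s in self.segments))

    def _transitions(self, kind: str) -> list[int]:
        times, t = [], 0
        for prev, nxt in zip(self.segments, self.segments[1:]):
            t += prev.duration_s
            if kind == "light_off" and prev.label == "light" and nxt.label == "dark":
                times.append(t)
            if kind == "light_on" and prev.label == "dark" and nxt.label == "light":
                times.append(t)
        return times

    @property
    def light_on(self) -> int:
        """Time (s from start) of the first dark-to-light transition."""
        times = self._transitions("light_on")
        if not times:
            raise ProtocolError("protocol has no light-on event")
        return times[0]

    @property
    def light_off(self) -> int:
        """Time (s from start) of the unique light-to-dark transition."""
        times = self._transitions("light_off")
        if len(times) != 1:
            raise ProtocolError(
                f"protocol must contain exactly one light-off event, found {len(times)}"
            )
        return times[0]

    def event_time(self, event: str) -> int:
        if event == "light_off":
            return self.light_off
        if event == "light_on":
            return self.light_on
        raise ProtocolError(f"unknown event {event!r}")


#: 30 min dark acclimation, 60 min scotopic illumination at 0.01 lx, 5 min dark.
SCOTOPIC_PROTOCOL = StimulusProtocol(
    (
        Segment("dark", 1800, 0.0),
        Segment("light", 3600, 0.01),
        Segment("dark", 300, 0.0),
    )
)


@dataclass
class PlateTrace:
    """Per-second displacement records for every well of a recording.

    ``records`` is a long-format frame with columns :data:`TRACE_COLUMNS`.
    A larva is identified by ``(plate, well)``; all larvae share the same
    rectangular time grid and each larva belongs to exactly one batch.
    """

    protocol: StimulusProtocol
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise TraceFormatError(f"missing trace column(s): {', '.join(missing)}")
        df = df.loc[:, list(TRACE_COLUMNS)].reset_index(drop=True)
        if len(df):
            disp = df["displacement_cm"].to_numpy(float)
            if not np.isfinite(disp).all():
                row = int(np.flatnonzero(~np.isfinite(disp))[0])
                raise TraceFormatError(f"non-finite displacement at row {row}")
            if (disp < 0).any():
                row = int(np.flatnonzero(disp < 0)[0])
                raise TraceFormatError(
                    f"negative displacement {disp[row]} at row {row}"
                )
            t = df["t_sec"].to_numpy()
            if not np.issubdtype(t.dtype, np.integer):
                if not np.all(np.equal(np.mod(t, 1), 0)):
                    raise TraceFormatError("t_sec must be integer seconds")
                df["t_sec"] = t = t.astype(np.int64)
            total = self.protocol.total_duration_s
            if t.min() < 0 or t.max() >= total:
                row = int(np.flatnonzero((t < 0) | (t >= total))[0])
                raise TraceFormatError(
                    f"t_sec out of range [0, {total}) at row {row}"
                )
            self._check_grid(df)
        self.records = df

    @staticmethod
    def _check_grid(df: pd.DataFrame) -> None:
        lp = pd.factorize(df["plate"])[0].astype(np.int64)
        lw = pd.factorize(df["well"])[0].astype(np.int64)
        t = df["t_sec"].to_numpy(np.int64)
        larva = lp * (lw.max() + 1) + lw
        key = larva * (t.max() + 1) + t
        if np.unique(key).size != key.size:
            order = np.argsort(key, kind="stable")
            dup_pos = np.flatnonzero(np.diff(key[order]) == 0)[0]
            row = int(order[dup_pos + 1])
            raise TraceFormatError(
                f"duplicated (plate, well, t_sec) record at row {row}"
            )
        n_larvae = np.unique(larva).size
        n_times = np.unique(t).size
        if n_larvae * n_times != len(df):
            raise TraceFormatError(
                "ragged time grid: wells do not share the same set of seconds"
            )
        # batch must be constant per larva
        lb = pd.factorize(df["batch"])[0].astype(np.int64)
        pair = larva * (lb.max() + 1) + lb
        if np.unique(pair).size != n_larvae:
            raise TraceFormatError("a (plate, well) larva maps to multiple batches")

    @property
    def n_wells(self) -> int:
        if not len(self.records):
            return 0
        return self.records.groupby(["plate", "well"], observed=True).ngroups

    def with_displacement(self, values: np.ndarray) -> "PlateTrace":
        """Return a copy with ``displacement_cm`` replaced (same row order)."""
        df = self.records.copy()
        df["displacement_cm"] = np.asarray(values, float)
        return PlateTrace(self.protocol, df)


@dataclass(frozen=True)
class WindowMatrix:
    """Larvae-by-seconds displacement matrix aligned to a stimulus event.

    Rows are larvae (identified by ``(plate, well)``), columns are the 1-s
    bins ``event+start_offset .. event+end_offset`` inclusive, so the
    dimension is ``p = end_offset - start_offset + 1``.
    """

    values: np.ndarray
    larvae: tuple[tuple[str, str], ...]
    start_offset: int
    end_offset: int
    event: str = "light_off"
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise TraceFormatError("window matrix must be 2-dimensional")
        if values.shape[0] < 2:
            raise InsufficientSampleError(
                f"window matrix needs >= 2 larvae, got {values.shape[0]}"
            )
        p = self.end_offset - self.start_offset + 1
        if values.shape[1] != p:
            raise TraceFormatError(
                f"window declares p={p} but matrix has {values.shape[1]} columns"
            )
        if not np.isfinite(values).all():
            raise TraceFormatError("window matrix contains missing cells")
        if len(self.larvae) != values.shape[0]:
            raise TraceFormatError("larva labels do not match matrix rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _apply_filter(df: pd.DataFrame, where: Mapping | None) -> pd.DataFrame:
    if where is None:
        return df
    mask = np.ones(len(df), dtype=bool)
    for col, val in where.items():
        if col not in df.columns:
            raise TraceFormatError(f"unknown filter column {col!r}")
        if isinstance(val, (list, tuple, set, frozenset, np.ndarray, pd.Series)):
            mask &= df[col].isin(list(val)).to_numpy()
        else:
            mask &= (df[col] == val).to_numpy()
    return df.loc[mask]


def extract_window(
    trace: PlateTrace,
    where: Mapping | None = None,
    *,
    start_offset: int,
    end_offset: int,
    event: str = "light_off",
    label: str = "",
) -> WindowMatrix:
    """Extract the larvae x seconds matrix for a post-event analysis window.

    ``where`` maps record columns to a value (or collection of values) used
    to select larvae, e.g. ``{"treatment": "carvedilol"}``.  Offsets are
    1-based inclusive seconds after the event; see the module docstring.
    """
    if start_offset < 1 or end_offset < start_offset:
        raise WindowRangeError(
            f"offsets must satisfy 1 <= start <= end, got ({start_offset}, {end_offset})"
        )
    tau = trace.protocol.event_time(event)
    total = trace.protocol.total_duration_s
    if tau + end_offset > total:
        raise WindowRangeError(
            f"window end {tau + end_offset} s exceeds recording duration {total} s"
        )
    bins = np.arange(tau + start_offset - 1, tau + end_offset)
    sub = _apply_filter(trace.records, where)
    sub = sub[sub["t_sec"].isin(bins)]
    if not len(sub):
        raise InsufficientSampleError("no larvae match the window filter")
    wide = sub.pivot_table(
        index=["plate", "well"],
        columns="t_sec",
        values="displacement_cm",
        observed=True,
        sort=True,
    )
    wide = wide.reindex(columns=bins)
    if wide.shape[0] < 2:
        raise InsufficientSampleError(
            f"window needs >= 2 larvae, got {wide.shape[0]}"
        )
    if wide.isna().any().any():
        raise TraceFormatError("window has missing cells for some larvae")
    larvae = tuple((str(p), str(w)) for p, w in wide.index)
    return WindowMatrix(
        values=wide.to_numpy(float),
        larvae=larvae,
        start_offset=start_offset,
        end_offset=end_offset,
        event=event,
        label=label,
    )


def read_trace_csv(path: str | Path, protocol: StimulusProtocol) -> PlateTrace:
    """Read a trace CSV (see :data:`TRACE_COLUMNS`) into a validated trace.

    Row counts are preserved.  Malformed input raises
    :class:`~vmrscreen.exceptions.TraceFormatError` naming the offending row.
    """
    path = Path(path)
    try:
        # round_trip parsing keeps file I/O lossless for float64 values
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path} is empty: no header row") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"{path} is missing column(s): {', '.join(missing)}"
        )
    for col in ("dose_uM", "displacement_cm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise TraceFormatError(f"{path}: non-numeric {col} at data row {row}")
    return PlateTrace(protocol, df)


def write_trace_csv(trace: PlateTrace, path: str | Path) -> Path:
    """Write a trace to CSV with a stable sort order and byte-stable output.

    Rows are sorted by (plate, well row, well column, t_sec); floats are
    written with shortest round-trip representation so that
    ``read_trace_csv(write_trace_csv(t)) == t``.
    """
    path = Path(path)
    df = trace.records.copy()
    if len(df):
        codes, uniques = pd.factorize(df["well"])
        pos = np.array([well_position(str(w)) for w in uniques])
        df["_r"] = pos[codes, 0]
        df["_c"] = pos[codes, 1]
        df = df.sort_values(
            ["plate", "_r", "_c", "t_sec"], kind="mergesort"
        ).drop(columns=["_r", "_c"])
    # %.17g guarantees exact float64 round-trips through text
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
    return path


def attenuated_intensity(
    base_intensity: float, transmittance: float, n_filters: int
) -> float:
    """Intensity after stacking ``n_filters`` neutral-density filters.

    Each filter multiplies the incident intensity by its transmittance, so
    the result is ``base * transmittance ** n_filters``.  Transmittance must
    lie in (0, 1]; zero filters return the base intensity unchanged.
    """
    from .exceptions import DomainError

    if not (0 < transmittance <= 1):
        raise DomainError(
            f"transmittance must lie in (0, 1], got {transmittance!r}"
        )
    if int(n_filters) != n_filters or n_filters < 0:
        raise DomainError(f"n_filters must be a non-negative integer, got {n_filters!r}")
    if base_intensity < 0:
        raise DomainError(f"base intensity must be >= 0, got {base_intensity!r}")
    return float(base_intensity) * float(transmittance) ** int(n_filters)
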