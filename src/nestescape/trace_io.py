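"""Reading, validating, trimming and writing tri-axial accelerometer traces.

A trace is a uniformly sampled (nominally 1 Hz) tri-axial acceleration time
series in units of g, calibrated to +/-2 g.  Loggers record elapsed samples;
civil (study-site) clock time is carried as a seconds-past-midnight offset of
the trace epoch so that diel analyses can map samples onto local clock hours.

Recording gaps — timestamp deltas larger than one sample period but still an
integer multiple of it — are legal and recorded in ``meta['gaps']``; all
downstream interval logic treats in-gap time as unobserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

#: acceleration range the loggers are calibrated to, in g
RANGE_G = 2.0

#: default logger-export CSV column mapping (role -> column name)
DEFAULT_COLUMN_MAP = {"time": "datetime", "x": "x", "y": "y", "z": "z"}

_TIME_TOL = 1e-6  # seconds; tolerance on sample spacing


@dataclass
class ExclusionWindow:
    """A [start, end) interval of epoch-seconds to remove (handling, transport)."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise DataError(f"exclusion window start {self.start} must precede end {self.end}")


@dataclass
class AccelTrace:
    """A validated tri-axial acceleration time series.

    Parameters
    ----------
    animal_id : str
        Identifier of the animal / nest the logger was attached to.
    timestamps : array of float
        Seconds since the per-trace epoch; strictly increasing, each delta an
        integer multiple of ``1 / sample_rate`` (tolerance 1e-6 s).
    x, y, z : arrays of float
        Acceleration per axis in g (surge, sway, heave), within +/-2 g.
    sample_rate : float
        Samples per second (default 1 Hz).
    clock_offset_s : float
        Local clock time (seconds past midnight) at epoch t = 0.
    timezone_note : str
        Free-text note about the clock used (local study time).
    meta : dict
        Validation flags: gaps, out-of-range rows, discarded segments...
    """

    animal_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate: float = 1.0
    clock_offset_s: float = 0.0
    timezone_note: str = "local study time"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.timestamps.size

    @property
    def period(self) -> float:
        return 1.0 / self.sample_rate

    def validate(self) -> None:
        """Raise :class:`DataError` on any invariant violation."""
        n = self.timestamps.size
        if n < 1:
            raise DataError("trace must contain at least one sample")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if arr.size != n:
                raise DataError(f"axis {name} has length {arr.size}, expected {n}")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"axis {name} contains non-finite values")
            if np.any(np.abs(arr) > RANGE_G + 1e-12):
                raise DataError(f"axis {name} exceeds +/-{RANGE_G} g calibration range")
        if not np.all(np.isfinite(self.timestamps)):
            raise DataError("timestamps contain non-finite values")
        if self.sample_rate <= 0:
            raise DataError("sample_rate must be positive")
        if n > 1:
            deltas = np.diff(self.timestamps)
            if np.any(deltas <= 0):
                raise DataError("timestamps must be strictly increasing (duplicates?)")
            k = deltas / self.period
            if np.any(np.abs(k - np.round(k)) * self.period > _TIME_TOL):
                raise DataError("sample spacing is not a multiple of the sample period")

    def gap_deltas(self) -> np.ndarray:
        """Boolean mask over inter-sample deltas marking recording gaps."""
        if self.n < 2:
            return np.zeros(0, dtype=bool)
        return np.diff(self.timestamps) > self.period + _TIME_TOL

    def segments(self) -> list[tuple[int, int]]:
        """Half-open index ranges of gap-free (contiguous) recording."""
        if self.n == 0:
            return []
        breaks = np.flatnonzero(self.gap_deltas()) + 1
        bounds = np.concatenate(([0], breaks, [self.n]))
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_trace(
    path: str | Path,
    sample_rate: float = 1.0,
    column_map: dict | None = None,
    animal_id: str | None = None,
    clip_out_of_range: bool = True,
) -> AccelTrace:
    """Read a logger-export CSV into a validated :class:`AccelTrace`.

    The time column may hold either numeric epoch-seconds or datetime strings;
    in the latter case the first stamp defines the epoch and its time of day
    becomes ``clock_offset_s``.  Out-of-range samples are clipped to +/-2 g and
    their row indices recorded in ``meta['out_of_range_rows']``; recording gaps
    land in ``meta['gaps']`` as (t_before, t_after) pairs.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    cmap.update(column_map or {})
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc
    if df.empty:
        raise DataError(f"{path}: no data rows")
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; have {list(df.columns)}")

    tcol = df[cmap["time"]]
    clock_offset = 0.0
    if pd.api.types.is_numeric_dtype(tcol):
        t = tcol.to_numpy(dtype=float)
    else:
        dt = pd.to_datetime(tcol, format="mixed")
        first = dt.iloc[0]
        t = (dt - first).dt.total_seconds().to_numpy()
        clock_offset = (
            first.hour * 3600 + first.minute * 60 + first.second + first.microsecond / 1e6
        )

    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: timestamps not strictly increasing")

    axes = {}
    out_of_range: list[int] = []
    for ax in ("x", "y", "z"):
        vals = df[cmap[ax]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DataError(f"{path}: non-finite values in axis {ax}")
        bad = np.flatnonzero(np.abs(vals) > RANGE_G)
        if bad.size:
            out_of_range.extend(int(i) for i in bad)
            if clip_out_of_range:
                vals = np.clip(vals, -RANGE_G, RANGE_G)
            else:
                raise DataError(f"{path}: axis {ax} outside +/-{RANGE_G} g at rows {bad[:5]}")
        axes[ax] = vals

    period = 1.0 / sample_rate
    deltas = np.diff(t)
    gap_idx = np.flatnonzero(deltas > period + _TIME_TOL)
    gaps = [(float(t[i]), float(t[i + 1])) for i in gap_idx]

    meta = {
        "source": str(path),
        "out_of_range_rows": sorted(set(out_of_range)),
        "gaps": gaps,
    }
    return AccelTrace(
        animal_id=animal_id or path.stem,
        timestamps=t,
        x=axes["x"],
        y=axes["y"],
        z=axes["z"],
        sample_rate=sample_rate,
        clock_offset_s=clock_offset,
        meta=meta,
    )


def trim_trace(trace: AccelTrace, windows: Iterable[ExclusionWindow | tuple]) -> AccelTrace:
    """Remove samples inside any [start, end) exclusion window.

    If removal splits the trace into several index-contiguous pieces, the
    longest piece (most samples; earliest on ties) is retained and the
    discarded pieces are reported in ``meta['discarded_segments']``.
    """
    windows = [w if isinstance(w, ExclusionWindow) else ExclusionWindow(*w) for w in windows]
    if not windows:
        return trace
    t = trace.timestamps
    keep = np.ones(trace.n, dtype=bool)
    for w in windows:
        keep &= ~((t >= w.start) & (t < w.end))
    if not keep.any():
        raise DataError("exclusion windows remove the entire trace")

    idx = np.flatnonzero(keep)
    run_breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    runs = np.split(idx, run_breaks)
    best = max(runs, key=len)  # max() keeps the earliest on ties
    discarded = [
        (float(t[r[0]]), float(t[r[-1]])) for r in runs if r is not best
    ]
    meta = dict(trace.meta)
    meta["discarded_segments"] = discarded
    meta["n_excluded_samples"] = int(trace.n - len(best))
    return AccelTrace(
        animal_id=trace.animal_id,
        timestamps=t[best],
        x=trace.x[best],
        y=trace.y[best],
        z=trace.z[best],
        sample_rate=trace.sample_rate,
        clock_offset_s=trace.clock_offset_s,
        timezone_note=trace.timezone_note,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_table(rows, path: str | Path, allow_empty: bool = False) -> None:
    """Write any tabular result as a plain UTF-8 CSV with header.

    ``rows`` may be a DataFrame or a sequence of dicts/dataclasses.  Floats are
    written at full repr precision, so a write/read round trip preserves values
    far below 1e-9 relative error.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        records = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                records.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                records.append(dict(r))
        df = pd.DataFrame.from_records(records)
    if df.empty and not allow_empty:
        raise DataError("refusing to write an empty table (pass allow_empty=True)")
    df.to_csv(path, index=False, encoding="utf-8")


def write_trace(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace in the reader's default CSV dialect (round-trips).

    The time column keeps the default logger header name and holds numeric
    epoch-seconds, which :func:`read_trace` accepts without a column map.
    """
    df = pd.DataFrame(
        {
            DEFAULT_COLUMN_MAP["time"]: trace.timestamps,
            "x": trace.x,
            "y": trace.y,
            "z": trace.z,
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def read_written_trace(path: str | Path, sample_rate: float = 1.0, **kw) -> AccelTrace:
    """Read back a trace written by :func:`write_trace`."""
    return read_trace(path, sample_rate=sample_rate, **kw)
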