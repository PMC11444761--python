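"""Static/dynamic acceleration separation and VeDBA.

Static acceleration (SA) is the gravity-dominated low-frequency component,
estimated with a centred running mean (3 s at 1 Hz by default); dynamic body
acceleration (DBA) is the residual raw - SA per axis; VeDBA is the Euclidean
norm of the three DBA components, a scalar movement-intensity proxy.

Edge samples without a full smoothing window are dropped (no partial
windows), so a DbaSeries is shorter than its source trace by window - 1
samples per contiguous segment; segments shorter than the window vanish.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .trace_io import AccelTrace

_AXES = ("x", "y", "z")


@dataclass
class StaticSeries:
    """Per-axis centred running-mean (gravity) estimate aligned to trace times."""

    timestamps: np.ndarray
    sa_x: np.ndarray
    sa_y: np.ndarray
    sa_z: np.ndarray
    window_s: float


@dataclass
class DbaSeries:
    """Aligned SA, per-axis DBA and (once computed) scalar VeDBA."""

    timestamps: np.ndarray
    sa_x: np.ndarray
    sa_y: np.ndarray
    sa_z: np.ndarray
    dba_x: np.ndarray
    dba_y: np.ndarray
    dba_z: np.ndarray
    window_s: float
    sample_period: float
    vedba: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.timestamps.size


def _window_samples(window_s: float, sample_rate: float) -> int:
    w = int(round(window_s * sample_rate))
    if w < 1 or w % 2 == 0:
        raise ConfigError(
            f"smoothing window must span an odd number of samples, got {w} "
            f"({window_s} s at {sample_rate} Hz)"
        )
    return w


def static_acceleration(trace: AccelTrace, window_s: float = 3.0) -> StaticSeries:
    """Centred running mean per axis, computed within contiguous segments.

    The first and last floor(window/2) samples of each segment are dropped.
    """
    w = _window_samples(window_s, trace.sample_rate)
    h = w // 2
    kernel = np.ones(w)
    ts_parts, parts = [], {ax: [] for ax in _AXES}
    for i0, i1 in trace.segments():
        if i1 - i0 < w:
            continue
        ts_parts.append(trace.timestamps[i0 + h : i1 - h])
        for ax in _AXES:
            seg = getattr(trace, ax)[i0:i1]
            parts[ax].append(np.convolve(seg, kernel, mode="valid") / w)
    if not ts_parts:
        raise DataError(f"trace shorter than the {window_s} s smoothing window")
    return StaticSeries(
        timestamps=np.concatenate(ts_parts),
        sa_x=np.concatenate(parts["x"]),
        sa_y=np.concatenate(parts["y"]),
        sa_z=np.concatenate(parts["z"]),
        window_s=window_s,
    )


def dynamic_body_acceleration(trace: AccelTrace, sa: StaticSeries) -> DbaSeries:
    """DBA per axis: raw minus SA at every retained timestamp."""
    pos = np.searchsorted(trace.timestamps, sa.timestamps)
    if np.any(pos >= trace.n) or not np.allclose(
        trace.timestamps[np.minimum(pos, trace.n - 1)], sa.timestamps, atol=1e-9
    ):
        raise DataError("static series timestamps do not align with the trace")
    return DbaSeries(
        timestamps=sa.timestamps.copy(),
        sa_x=sa.sa_x,
        sa_y=sa.sa_y,
        sa_z=sa.sa_z,
        dba_x=trace.x[pos] - sa.sa_x,
        dba_y=trace.y[pos] - sa.sa_y,
        dba_z=trace.z[pos] - sa.sa_z,
        window_s=sa.window_s,
        sample_period=trace.period,
    )


def vedba(dba: DbaSeries) -> np.ndarray:
    """Vectorial DBA: Euclidean norm of (dba_x, dba_y, dba_z) per sample."""
    v = np.sqrt(dba.dba_x**2 + dba.dba_y**2 + dba.dba_z**2)
    dba.vedba = v
    return v


def compute_dba(trace: AccelTrace, window_s: float = 3.0) -> DbaSeries:
    """Convenience: SA -> DBA -> VeDBA in one call."""
    series = dynamic_body_acceleration(trace, static_acceleration(trace, window_s))
    vedba(series)
    return series


def mean_axis_dba(dba: DbaSeries, absolute: bool = True) -> dict:
    """Per-axis mean |DBA| (default) or signed DBA over the series.

    Signed per-axis DBA averages to ~0 by construction of the high-pass, so
    the absolute mean is the informative axis-dominance comparison.
    """
    if dba.n == 0:
        raise DataError("empty DBA series")
    out = {}
    for ax in _AXES:
        vals = getattr(dba, f"dba_{ax}")
        out[ax] = float(np.mean(np.abs(vals)) if absolute else np.mean(vals))
    return out
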