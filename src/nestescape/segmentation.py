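"""Pulse / inter-pulse-interval / bout segmentation of the VeDBA series.

A *pulse* is a single sample whose VeDBA exceeds the noise threshold
(strictly; default 0.035 g).  An *inter-pulse interval* (IPI) is the elapsed
time between consecutive pulses whenever it exceeds one sample period.  An
*activity bout* is a maximal run of pulses whose successive gaps are at most
the merge threshold (1, 5 or 10 min).  Recording gaps are unobserved time: no
IPI or bout ever spans one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body_acceleration import DbaSeries, vedba as _vedba
from .errors import DataError

_GAP_TOL = 1e-9

DEFAULT_NOISE_THRESHOLD = 0.035
DEFAULT_MERGE_THRESHOLDS = (60.0, 300.0, 600.0)
DEFAULT_SENSITIVITY_THRESHOLDS = (0.025, 0.035, 0.045, 0.055)

#: right (closed) edges of the nine IPI duration bins, seconds
IPI_BIN_UPPER = np.array([60.0, 600.0, 1800.0, 3600.0, 5400.0, 7200.0, 9000.0, 10800.0, np.inf])
IPI_BIN_LABELS = (
    "1-60 s",
    "61 s-10 min",
    "10-30 min",
    "30 min-1 h",
    "1-1.5 h",
    "1.5-2 h",
    "2-2.5 h",
    "2.5-3 h",
    "3 h+",
)


@dataclass
class PulseSeries:
    """Supra-threshold sample times inside the analysis window."""

    animal_id: str
    times: np.ndarray          # sorted pulse timestamps, seconds
    segment_ids: np.ndarray    # contiguous-recording segment index per pulse
    noise_threshold: float
    analysis_start: float
    analysis_end: float
    sample_period: float
    n_window_samples: int      # samples examined inside the window

    @property
    def n_pulses(self) -> int:
        return int(self.times.size)

    @property
    def is_empty(self) -> bool:
        return self.times.size == 0


@dataclass
class IpiRecord:
    """One inactive interval between two consecutive pulses."""

    start: float
    end: float
    duration: float


@dataclass
class Bout:
    """A maximal run of pulses with internal gaps <= merge_threshold_s."""

    start: float
    end: float
    duration: float   # end - start + one sample period
    n_pulses: int
    merge_threshold_s: float


@dataclass
class IpiHistogram:
    """IPI counts and inactive-time shares over the nine fixed duration bins."""

    labels: tuple = IPI_BIN_LABELS
    counts: np.ndarray = field(default_factory=lambda: np.zeros(9, dtype=int))
    seconds: np.ndarray = field(default_factory=lambda: np.zeros(9))
    proportions: np.ndarray = field(default_factory=lambda: np.zeros(9))
    n_ipis: int = 0
    total_ipi_s: float = 0.0


def detect_pulses(
    dba: DbaSeries,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
    analysis_start: float | None = None,
    analysis_end: float | None = None,
    animal_id: str = "",
) -> PulseSeries:
    """All samples with VeDBA strictly above threshold in [start, end).

    ``analysis_start`` is normally the head-up onset (pre-onset reorientation
    is excluded from activity analysis) and ``analysis_end`` the emergence
    time.  An empty result is legal (quiet logger) — flagged, not an error;
    a window containing no samples at all is an error.
    """
    v = dba.vedba if dba.vedba is not None else _vedba(dba)
    t = dba.timestamps
    start = float(t[0]) if analysis_start is None else float(analysis_start)
    end = float(t[-1] + dba.sample_period) if analysis_end is None else float(analysis_end)
    if not start < end:
        raise DataError("analysis_start must precede analysis_end")
    in_win = (t >= start) & (t < end)
    n_win = int(in_win.sum())
    if n_win == 0:
        raise DataError("no samples inside the analysis window")
    seg_ids = np.concatenate(
        ([0], np.cumsum(np.diff(t) > dba.sample_period + _GAP_TOL))
    )
    sel = in_win & (v > noise_threshold)
    return PulseSeries(
        animal_id=animal_id,
        times=t[sel].copy(),
        segment_ids=seg_ids[sel].astype(int),
        noise_threshold=noise_threshold,
        analysis_start=start,
        analysis_end=end,
        sample_period=dba.sample_period,
        n_window_samples=n_win,
    )


def inter_pulse_intervals(
    pulses: PulseSeries, subtract_sample_period: bool = False
) -> list[IpiRecord]:
    """IPIs: consecutive-pulse gaps greater than one sample period.

    Duration is the raw elapsed time between the two pulse timestamps by
    default; ``subtract_sample_period`` switches to the gap minus one sample
    (the time strictly between the two active seconds).  Pulse pairs
    separated by a recording gap are skipped (unobserved time).  Fewer than
    two pulses yield an empty list.
    """
    if pulses.n_pulses < 2:
        return []
    dt = np.diff(pulses.times)
    same_seg = np.diff(pulses.segment_ids) == 0
    idx = np.flatnonzero((dt > pulses.sample_period + _GAP_TOL) & same_seg)
    off = pulses.sample_period if subtract_sample_period else 0.0
    return [
        IpiRecord(float(pulses.times[i]), float(pulses.times[i + 1]), float(dt[i] - off))
        for i in idx
    ]


def bin_ipis(ipis: list[IpiRecord], total_time_s: float | None = None) -> IpiHistogram:
    """Assign each IPI to one of the nine bins (left-open, right-closed edges).

    Proportions are shares of total IPI time by default; pass ``total_time_s``
    to normalise by the whole analysis window instead.
    """
    if not ipis:
        return IpiHistogram()
    dur = np.array([r.duration for r in ipis])
    idx = np.searchsorted(IPI_BIN_UPPER, dur, side="left")
    counts = np.bincount(idx, minlength=9)
    seconds = np.bincount(idx, weights=dur, minlength=9)
    denom = float(total_time_s) if total_time_s else float(dur.sum())
    proportions = seconds / denom if denom > 0 else np.zeros(9)
    return IpiHistogram(
        counts=counts.astype(int),
        seconds=seconds,
        proportions=proportions,
        n_ipis=len(ipis),
        total_ipi_s=float(dur.sum()),
    )


def detect_bouts(pulses: PulseSeries, merge_threshold_s: float) -> list[Bout]:
    """Merge pulses into bouts whenever successive gaps are <= the threshold.

    Bout duration spans first to last pulse plus one sample period, so a
    single pulse forms a bout of one sample period.  Bouts never cross
    recording gaps.
    """
    if pulses.is_empty:
        return []
    t = pulses.times
    new_bout = np.ones(t.size, dtype=bool)
    if t.size > 1:
        gaps = np.diff(t)
        new_bout[1:] = (gaps > merge_threshold_s + _GAP_TOL) | (
            np.diff(pulses.segment_ids) != 0
        )
    starts = np.flatnonzero(new_bout)
    ends = np.append(starts[1:], t.size) - 1
    return [
        Bout(
            start=float(t[s]),
            end=float(t[e]),
            duration=float(t[e] - t[s] + pulses.sample_period),
            n_pulses=int(e - s + 1),
            merge_threshold_s=merge_threshold_s,
        )
        for s, e in zip(starts, ends)
    ]


def summarize_segments(
    ipis: list[IpiRecord],
    bouts_by_threshold: dict[float, list[Bout]],
    animal_id: str = "",
) -> pd.DataFrame:
    """Per-animal median and maximum IPI and bout durations (midpoint medians)."""
    rows = []
    if ipis:
        dur = np.array([r.duration for r in ipis])
        rows.append(
            {"animal_id": animal_id, "quantity": "ipi", "merge_threshold_s": np.nan,
             "n": dur.size, "median_s": float(np.median(dur)), "max_s": float(dur.max())}
        )
    for thr, bouts in sorted(bouts_by_threshold.items()):
        if not bouts:
            continue
        dur = np.array([b.duration for b in bouts])
        rows.append(
            {"animal_id": animal_id, "quantity": "bout", "merge_threshold_s": thr,
             "n": dur.size, "median_s": float(np.median(dur)), "max_s": float(dur.max())}
        )
    return pd.DataFrame(
        rows, columns=["animal_id", "quantity", "merge_threshold_s", "n", "median_s", "max_s"]
    )


@dataclass
class SensitivityResult:
    """Re-segmentation under alternative noise thresholds."""

    table: pd.DataFrame                  # one row per threshold
    histograms: dict                     # threshold -> IpiHistogram
    pulse_counts: dict                   # threshold -> int
    monotone: bool                       # pulse counts non-increasing in threshold


def threshold_sensitivity(
    dba: DbaSeries,
    thresholds: tuple = DEFAULT_SENSITIVITY_THRESHOLDS,
    analysis_start: float | None = None,
    analysis_end: float | None = None,
    animal_id: str = "",
) -> SensitivityResult:
    """Full pulse/IPI segmentation re-run at each candidate noise threshold."""
    thresholds = tuple(sorted(thresholds))
    if any(th <= 0 for th in thresholds):
        raise DataError("sensitivity thresholds must be positive")
    rows, hists, counts = [], {}, {}
    for th in thresholds:
        pulses = detect_pulses(dba, th, analysis_start, analysis_end, animal_id)
        ipis = inter_pulse_intervals(pulses)
        hist = bin_ipis(ipis)
        hists[th] = hist
        counts[th] = pulses.n_pulses
        row = {"animal_id": animal_id, "noise_threshold": th,
               "n_pulses": pulses.n_pulses, "n_ipis": hist.n_ipis}
        row.update({f"prop[{lab}]": p for lab, p in zip(IPI_BIN_LABELS, hist.proportions)})
        rows.append(row)
    ordered = [counts[th] for th in thresholds]
    monotone = all(a >= b for a, b in zip(ordered, ordered[1:]))
    return SensitivityResult(pd.DataFrame(rows), hists, counts, monotone)
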