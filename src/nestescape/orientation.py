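"""Body-orientation classification from gravity-dominated raw acceleration.

With the logger on the carapace, the six cardinal postures map onto signed
unit-gravity axes: head-up (x = +1 g), head-down (x = -1 g), right-side-up
(y = +1 g), right-side-down (y = -1 g), carapace-up (z = +1 g) and
carapace-down (z = -1 g).  A sample is assigned a canonical label when at
least one axis reaches |0.70| g; the signed axis with the largest magnitude
wins (exact ties break x > y > z).  Anything below threshold on every axis is
an intermediate posture.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .trace_io import AccelTrace

CANONICAL_LABELS = (
    "head_up",
    "head_down",
    "right_side_up",
    "right_side_down",
    "carapace_up",
    "carapace_down",
)
INTERMEDIATE = "intermediate"
ALL_LABELS = CANONICAL_LABELS + (INTERMEDIATE,)

#: integer code of the intermediate class in classify_codes output
INTERMEDIATE_CODE = 6

DEFAULT_THRESHOLD_G = 0.70


def classify_codes(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, threshold_g: float = DEFAULT_THRESHOLD_G
) -> np.ndarray:
    """Vectorised orientation classification; returns int8 codes 0..6.

    Codes 0..5 index :data:`CANONICAL_LABELS`; 6 is intermediate.
    """
    arr = np.stack([np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)])
    if not np.all(np.isfinite(arr)):
        raise DataError("non-finite acceleration value in orientation input")
    mag = np.abs(arr)
    axis = np.argmax(mag, axis=0)  # first max -> x > y > z tie priority
    idx = np.arange(arr.shape[1])
    winner = arr[axis, idx]
    codes = (axis * 2 + (winner < 0)).astype(np.int8)
    codes[mag[axis, idx] < threshold_g] = INTERMEDIATE_CODE
    return codes


def classify_sample(
    x: float, y: float, z: float, threshold_g: float = DEFAULT_THRESHOLD_G
) -> str:
    """Classify one (x, y, z) sample in g into a posture label."""
    code = classify_codes(np.atleast_1d(x), np.atleast_1d(y), np.atleast_1d(z), threshold_g)[0]
    return ALL_LABELS[code]


@dataclass
class OrientationSummary:
    """Per-animal orientation time budget over a recording."""

    animal_id: str
    threshold_g: float
    n_samples: int
    proportions: dict = field(default_factory=dict)  # label -> fraction, incl. intermediate

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise DataError(f"orientation proportions sum to {total}, expected 1")

    def as_row(self) -> dict:
        row = {"animal_id": self.animal_id, "threshold_g": self.threshold_g,
               "n_samples": self.n_samples}
        row.update({lab: self.proportions.get(lab, 0.0) for lab in ALL_LABELS})
        return row


def orientation_budget(
    trace: AccelTrace,
    threshold_g: float = DEFAULT_THRESHOLD_G,
    start: float | None = None,
    end: float | None = None,
) -> OrientationSummary:
    """Fraction of samples in each posture over [start, end) (whole trace default).

    By default the budget covers the entire recording phase, including the
    pre-head-up reorientation period; pass ``start``/``end`` to restrict.
    """
    t = trace.timestamps
    mask = np.ones(trace.n, dtype=bool)
    if start is not None:
        mask &= t >= start
    if end is not None:
        mask &= t < end
    n = int(mask.sum())
    if n == 0:
        raise DataError("no samples in requested window for orientation budget")
    codes = classify_codes(trace.x[mask], trace.y[mask], trace.z[mask], threshold_g)
    counts = np.bincount(codes, minlength=7)
    props = {lab: counts[i] / n for i, lab in enumerate(ALL_LABELS)}
    return OrientationSummary(trace.animal_id, threshold_g, n, props)


def orientation_budget_static(
    sa, threshold_g: float = DEFAULT_THRESHOLD_G, animal_id: str = ""
) -> OrientationSummary:
    """Orientation budget computed on smoothed (static) acceleration.

    Classification normally uses raw values; this variant accepts a
    StaticSeries from the gravity-separation stage for users who prefer to
    classify the smoothed signal.
    """
    n = sa.timestamps.size
    if n == 0:
        raise DataError("empty static series for orientation budget")
    codes = classify_codes(sa.sa_x, sa.sa_y, sa.sa_z, threshold_g)
    counts = np.bincount(codes, minlength=7)
    props = {lab: counts[i] / n for i, lab in enumerate(ALL_LABELS)}
    return OrientationSummary(animal_id, threshold_g, n, props)


def _first_run_start(mask: np.ndarray, min_len: int) -> int | None:
    """Index of the first run of ``min_len`` consecutive True values, else None."""
    if mask.size < min_len or min_len < 1:
        return None
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            return int(s)
    return None


def detect_headup_onset(
    trace: AccelTrace,
    threshold_g: float = 0.7,
    min_run_s: float = 10.0,
) -> float | None:
    """Timestamp starting the first run of x >= threshold sustained min_run_s.

    Runs are broken by any sub-threshold sample and by recording gaps.  At the
    1 Hz study rate, 10 consecutive samples satisfy "10 consecutive s".
    Returns None when no qualifying run exists.
    """
    min_len = int(round(min_run_s * trace.sample_rate))
    for i0, i1 in trace.segments():
        s = _first_run_start(trace.x[i0:i1] >= threshold_g, min_len)
        if s is not None:
            return float(trace.timestamps[i0 + s])
    return None
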