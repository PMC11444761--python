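"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive pulses, gaps, bouts and ANOVA tables with explicit
loops / closed-form sums of squares, independently of the vectorised package
implementations they are used to check.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import stats

from nestescape.trace_io import AccelTrace

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def make_trace():
    """Factory for small hand-built traces."""

    def _make(x, y=None, z=None, fs=1.0, t=None, animal_id="test", clock_offset_s=0.0):
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
        t = np.arange(x.size) / fs if t is None else np.asarray(t, dtype=float)
        return AccelTrace(animal_id, t, x, y, z, sample_rate=fs,
                          clock_offset_s=clock_offset_s)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def onset_oracle(timestamps, xvals, threshold, min_run, period):
    """First timestamp starting >= min_run consecutive x >= threshold samples.

    Single explicit pass; runs break on sub-threshold samples and on any
    timestamp gap larger than one sample period.
    """
    run = 0
    for i in range(len(xvals)):
        if i > 0 and timestamps[i] - timestamps[i - 1] > period + 1e-9:
            run = 0
        if xvals[i] >= threshold:
            run += 1
            if run == min_run:
                return timestamps[i - min_run + 1]
        else:
            run = 0
    return None


def segmentation_oracle(timestamps, vedba, threshold, merge_threshold, period):
    """Loop re-derivation of pulses, IPIs and bouts.

    Returns (pulse_times, ipi_tuples, bout_tuples) with
    ipi = (start, end, duration) and bout = (start, end, duration, n_pulses).
    """
    seg_id = [0]
    for i in range(1, len(timestamps)):
        gap = timestamps[i] - timestamps[i - 1] > period + 1e-9
        seg_id.append(seg_id[-1] + (1 if gap else 0))

    pulses = []
    for i, (t, v) in enumerate(zip(timestamps, vedba)):
        if v > threshold:
            pulses.append((t, seg_id[i]))

    ipis = []
    for (t0, s0), (t1, s1) in zip(pulses, pulses[1:]):
        if s0 == s1 and t1 - t0 > period + 1e-9:
            ipis.append((t0, t1, t1 - t0))

    bouts = []
    cur = None
    for t, s in pulses:
        if cur is None:
            cur = [t, t, s, 1]
        elif s == cur[2] and t - cur[1] <= merge_threshold + 1e-9:
            cur[1] = t
            cur[3] += 1
        else:
            bouts.append((cur[0], cur[1], cur[1] - cur[0] + period, cur[3]))
            cur = [t, t, s, 1]
    if cur is not None:
        bouts.append((cur[0], cur[1], cur[1] - cur[0] + period, cur[3]))
    return [t for t, _ in pulses], ipis, bouts


def ipi_bin_oracle(duration):
    """Bin index of one IPI duration; left-open right-closed printed edges."""
    edges = [60, 600, 1800, 3600, 5400, 7200, 9000, 10800]
    for i, e in enumerate(edges):
        if duration <= e:
            return i
    return 8


def two_way_anova_oracle(df):
    """Closed-form sequential-SS two-way ANOVA on a balanced period x block table.

    Returns dict term -> (df, sum_sq, F, p) including the residual.
    """
    y = df["mean_vedba"].to_numpy(float)
    a = df["period"].to_numpy()
    b = df["block"].to_numpy()
    alev, blev = sorted(set(a)), sorted(set(b))
    n = y.size
    grand = y.mean()
    r = n / (len(alev) * len(blev))  # replicates per cell

    ss_a = sum((y[a == ai].mean() - grand) ** 2 * (a == ai).sum() for ai in alev)
    ss_b = sum((y[b == bi].mean() - grand) ** 2 * (b == bi).sum() for bi in blev)
    ss_cells = 0.0
    ss_e = 0.0
    for ai in alev:
        for bi in blev:
            sel = (a == ai) & (b == bi)
            cm = y[sel].mean()
            ss_cells += sel.sum() * (cm - grand) ** 2
            ss_e += ((y[sel] - cm) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b

    df_a, df_b = len(alev) - 1, len(blev) - 1
    df_ab = df_a * df_b
    df_e = n - len(alev) * len(blev)
    ms_e = ss_e / df_e
    out = {}
    for term, ss, d in (("period", ss_a, df_a), ("block", ss_b, df_b),
                        ("period:block", ss_ab, df_ab)):
        F = (ss / d) / ms_e
        out[term] = (d, ss, F, stats.f.sf(F, d, df_e))
    out["residual"] = (df_e, ss_e, np.nan, np.nan)
    return out
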