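"""Diel (4-h block) activity aggregation and ANOVA.

Mean VeDBA is averaged within six fixed local-clock blocks (12-16, 16-20,
20-24, 00-04, 04-08, 08-12) for two 24-h windows per nest: the first 24 h
after head-up onset and the last 24 h before emergence.  A two-factor fixed-
effects ANOVA (period, block, interaction; sequential sums of squares, equal
to marginal SS on the balanced design) tests diel structure, followed by
one-way per-period ANOVAs across blocks.  Nest cells are treated as
independent observations; no mixed model, no multiplicity correction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import DataError

BLOCK_LABELS = ("12-16", "16-20", "20-24", "00-04", "04-08", "08-12")
PERIODS = ("first_24h", "last_24h")

_DAY_S = 86400.0


@dataclass
class DielCell:
    """Mean VeDBA of one nest in one 4-h block of one 24-h period."""

    nest_id: str
    period: str
    block: str
    mean_vedba: float
    n_samples: int


def period_windows(onset: float, emergence: float) -> tuple[tuple, tuple, bool]:
    """First/last 24-h windows and the overlap flag.

    first = [onset, onset + 24 h); last = [emergence - 24 h, emergence).
    Windows overlap when emergence - onset < 48 h; overlapping nests are
    flagged for exclusion from the cohort ANOVA.
    """
    if not emergence > onset:
        raise DataError("emergence must come after head-up onset")
    first = (onset, onset + _DAY_S)
    last = (emergence - _DAY_S, emergence)
    overlap = (emergence - onset) < 2 * _DAY_S
    return first, last, overlap


def extract_period_window(
    timestamps: np.ndarray,
    values: np.ndarray,
    onset: float,
    emergence: float,
    period: str,
    edge_slack_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a (timestamps, VeDBA) series to one of the two 24-h windows.

    ``edge_slack_s`` tolerates the samples the centred smoothing window drops
    at the ends of the recording.
    """
    first, last, _ = period_windows(onset, emergence)
    if period not in PERIODS:
        raise DataError(f"unknown period {period!r}; expected one of {PERIODS}")
    s, e = first if period == "first_24h" else last
    if timestamps[0] > s + edge_slack_s or timestamps[-1] < e - 1.0 - edge_slack_s - 1e-9:
        raise DataError(f"{period} window [{s}, {e}) extends beyond recorded data")
    mask = (timestamps >= s) & (timestamps < e)
    return timestamps[mask], values[mask]


def block_of_hour(hour: np.ndarray) -> np.ndarray:
    """Map local clock hour (0..24) to the index of its 4-h block label."""
    return ((np.asarray(hour).astype(int) // 4) + 3) % 6


def block_means(
    timestamps: np.ndarray,
    values: np.ndarray,
    clock_offset_s: float,
    nest_id: str = "",
    period: str = "",
) -> pd.DataFrame:
    """Mean VeDBA per 4-h local-clock block; split block occurrences pooled.

    Returns a DataFrame of :class:`DielCell` rows in canonical block order;
    blocks with no samples (possible after trimming) are dropped.
    """
    timestamps = np.asarray(timestamps, float)
    values = np.asarray(values, float)
    if timestamps.size == 0:
        raise DataError("empty series for block means")
    hour = ((timestamps + clock_offset_s) % _DAY_S) / 3600.0
    idx = block_of_hour(hour)
    rows = []
    for b, label in enumerate(BLOCK_LABELS):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        rows.append(
            {"nest_id": nest_id, "period": period, "block": label,
             "mean_vedba": float(values[sel].mean()), "n_samples": n}
        )
    return pd.DataFrame(rows, columns=["nest_id", "period", "block", "mean_vedba", "n_samples"])


def _as_frame(cells) -> pd.DataFrame:
    if isinstance(cells, pd.DataFrame):
        return cells
    return pd.DataFrame([c.__dict__ if isinstance(c, DielCell) else dict(c) for c in cells])


def _tidy(tab: pd.DataFrame, rename: dict) -> pd.DataFrame:
    out = tab.rename(index=rename)[["df", "sum_sq", "F", "PR(>F)"]]
    out = out.rename(columns={"PR(>F)": "p"})
    # degenerate designs: a zero-variance term is "no effect", not undefined
    resid_ms = out.loc["residual", "sum_sq"] / max(out.loc["residual", "df"], 1)
    for term in out.index:
        if term == "residual":
            continue
        if out.loc[term, "sum_sq"] <= 1e-30:
            out.loc[term, ["F", "p"]] = [0.0, 1.0]
        elif resid_ms <= 1e-30:
            out.loc[term, ["F", "p"]] = [np.inf, 0.0]
    return out


def two_factor_anova(cells) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA: mean_vedba ~ period * block.

    Sequential (type I) sums of squares, which coincide with marginal SS on
    the balanced nests x periods x blocks design.  Returns a table indexed by
    term (period, block, period:block, residual) with df, sum_sq, F and p.
    """
    df = _as_frame(cells)
    for factor, levels in (("period", PERIODS), ("block", BLOCK_LABELS)):
        present = set(df[factor])
        if len(present) < 2:
            raise DataError(f"need at least two {factor} levels, have {sorted(present)}")
    # every factor combination must be observed
    for p in sorted(set(df["period"])):
        for b in sorted(set(df["block"])):
            if not ((df["period"] == p) & (df["block"] == b)).any():
                raise DataError(f"missing cell: period={p}, block={b}")
    model = smf.ols("mean_vedba ~ C(period) * C(block)", data=df).fit()
    tab = anova_lm(model, typ=1)
    return _tidy(
        tab,
        {"C(period)": "period", "C(block)": "block",
         "C(period):C(block)": "period:block", "Residual": "residual"},
    )


def per_period_anova(cells, period: str) -> pd.DataFrame:
    """One-way ANOVA of mean VeDBA across the six blocks within one period."""
    df = _as_frame(cells)
    df = df[df["period"] == period]
    if df.empty:
        raise DataError(f"no cells for period {period!r}")
    if len(set(df["block"])) < 2:
        raise DataError("need at least two block levels")
    model = smf.ols("mean_vedba ~ C(block)", data=df).fit()
    tab = anova_lm(model, typ=1)
    return _tidy(tab, {"C(block)": "block", "Residual": "residual"})
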