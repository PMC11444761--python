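"""End-to-end orchestration: per-nest stage chain and cohort statistics.

Stage order per nest: read -> trim handling windows -> orientation budget ->
head-up onset -> SA/DBA/VeDBA -> pulse/IPI/bout segmentation (+ noise-filter
sensitivity) -> diel window extraction and block means.  The cohort step pools
diel cells from nests whose first/last 24-h windows do not overlap and fits
the two-factor and per-period ANOVAs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import body_acceleration as ba
from . import diel, orientation, segmentation as seg
from .errors import ConfigError, DataError
from .trace_io import AccelTrace, read_trace, trim_trace, write_table


@dataclass
class RunConfig:
    """All pipeline constants in one place; defaults are the study values."""

    input_paths: dict = field(default_factory=dict)       # animal_id -> CSV path
    column_map: dict | None = None
    sample_rate: float = 1.0
    exclusion_windows: dict = field(default_factory=dict)  # animal_id -> [(s, e), ...]
    emergence_time: dict = field(default_factory=dict)     # animal_id -> epoch seconds
    orientation_threshold_g: float = 0.70
    onset_min_run_s: float = 10.0
    sa_window_s: float = 3.0
    noise_threshold: float = 0.035
    merge_thresholds: tuple = seg.DEFAULT_MERGE_THRESHOLDS
    sensitivity_thresholds: tuple = seg.DEFAULT_SENSITIVITY_THRESHOLDS
    clock_offset_s: float = 0.0
    diel_noise_filtered: bool = False   # zero sub-threshold VeDBA in block means
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("orientation_threshold_g", "onset_min_run_s", "sa_window_s",
                     "noise_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class NestResult:
    """Everything the pipeline derives for one nest."""

    animal_id: str
    orientation: orientation.OrientationSummary
    onset_s: float | None
    emergence_s: float
    axis_dba: dict
    pulses: seg.PulseSeries | None
    ipis: list
    histogram: seg.IpiHistogram | None
    bouts: dict                     # merge threshold -> list[Bout]
    segment_summary: pd.DataFrame
    sensitivity: seg.SensitivityResult | None
    diel_cells: pd.DataFrame
    flags: dict


@dataclass
class CohortResult:
    nests: dict
    cells: pd.DataFrame
    anova_two_way: pd.DataFrame
    anova_first: pd.DataFrame
    anova_last: pd.DataFrame
    pooled_orientation: pd.DataFrame
    axis_dba_table: pd.DataFrame


def _load_trace(config: RunConfig, animal_id: str) -> AccelTrace:
    try:
        path = config.input_paths[animal_id]
    except KeyError as exc:
        raise ConfigError(f"no input path configured for animal {animal_id!r}") from exc
    return read_trace(path, sample_rate=config.sample_rate,
                      column_map=config.column_map, animal_id=animal_id)


def run_nest(config: RunConfig, animal_id: str, trace: AccelTrace | None = None) -> NestResult:
    """Run the full stage chain for one nest; deterministic given inputs."""
    try:
        if trace is None:
            trace = _load_trace(config, animal_id)
        windows = config.exclusion_windows.get(animal_id, [])
        if windows:
            trace = trim_trace(trace, windows)
        flags = {
            "gaps": list(trace.meta.get("gaps", [])),
            "discarded_segments": list(trace.meta.get("discarded_segments", [])),
            "out_of_range_rows": list(trace.meta.get("out_of_range_rows", [])),
        }

        budget = orientation.orientation_budget(trace, config.orientation_threshold_g)
        onset = orientation.detect_headup_onset(
            trace, config.orientation_threshold_g, config.onset_min_run_s
        )
        emergence = float(
            config.emergence_time.get(animal_id, trace.timestamps[-1] + trace.period)
        )
        dba = ba.compute_dba(trace, config.sa_window_s)
        axis_means = ba.mean_axis_dba(dba)

        pulses = None
        ipis: list = []
        hist = None
        bouts: dict = {}
        sens = None
        cells = pd.DataFrame(
            columns=["nest_id", "period", "block", "mean_vedba", "n_samples"]
        )
        if onset is None:
            flags["no_headup_onset"] = True
        else:
            pulses = seg.detect_pulses(
                dba, config.noise_threshold, onset, emergence, animal_id
            )
            flags["empty_pulses"] = pulses.is_empty
            ipis = seg.inter_pulse_intervals(pulses)
            hist = seg.bin_ipis(ipis)
            bouts = {thr: seg.detect_bouts(pulses, thr) for thr in config.merge_thresholds}
            sens = seg.threshold_sensitivity(
                dba, config.sensitivity_thresholds, onset, emergence, animal_id
            )
            _, _, overlap = diel.period_windows(onset, emergence)
            flags["diel_overlap"] = overlap
            if not overlap:  # overlapping nests are excluded from diel work
                diel_v = dba.vedba
                if config.diel_noise_filtered:
                    diel_v = np.where(diel_v > config.noise_threshold, diel_v, 0.0)
                parts = []
                for period in diel.PERIODS:
                    tw, vw = diel.extract_period_window(
                        dba.timestamps, diel_v, onset, emergence, period
                    )
                    cm = diel.block_means(tw, vw, config.clock_offset_s, animal_id, period)
                    if len(cm) < len(diel.BLOCK_LABELS):
                        flags.setdefault("missing_blocks", []).append(period)
                    parts.append(cm)
                cells = pd.concat(parts, ignore_index=True)

        result = NestResult(
            animal_id=animal_id,
            orientation=budget,
            onset_s=onset,
            emergence_s=emergence,
            axis_dba=axis_means,
            pulses=pulses,
            ipis=ipis,
            histogram=hist,
            bouts=bouts,
            segment_summary=seg.summarize_segments(ipis, bouts, animal_id),
            sensitivity=sens,
            diel_cells=cells,
            flags=flags,
        )
        if config.output_dir:
            _persist_nest(config, result)
        return result
    except Exception as exc:
        raise type(exc)(f"[nest {animal_id}] {exc}") from exc


def _persist_nest(config: RunConfig, res: NestResult) -> None:
    out = Path(config.output_dir) / res.animal_id
    out.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame([res.orientation.as_row()]), out / "orientation_budget.csv")
    write_table(
        pd.DataFrame([{"animal_id": res.animal_id, **{f"mean_abs_dba_{k}": v
                                                      for k, v in res.axis_dba.items()}}]),
        out / "axis_dba.csv",
    )
    if res.pulses is not None:
        write_table(
            pd.DataFrame({"pulse_time_s": res.pulses.times}),
            out / "pulses.csv", allow_empty=True,
        )
        write_table(res.ipis, out / "ipis.csv", allow_empty=True)
        hist = res.histogram
        write_table(
            pd.DataFrame({"bin": hist.labels, "count": hist.counts,
                          "seconds": hist.seconds, "proportion": hist.proportions}),
            out / "ipi_histogram.csv",
        )
        bout_rows = [b for bl in res.bouts.values() for b in bl]
        write_table(bout_rows, out / "bouts.csv", allow_empty=True)
        write_table(res.segment_summary, out / "segment_summary.csv", allow_empty=True)
        write_table(res.sensitivity.table, out / "sensitivity.csv")
        write_table(res.diel_cells, out / "diel_cells.csv", allow_empty=True)
    manifest = {
        "animal_id": res.animal_id,
        "config_hash": config.config_hash(),
        "onset_s": res.onset_s,
        "emergence_s": res.emergence_s,
        "flags": res.flags,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_cohort(
    config: RunConfig,
    animal_ids: list | None = None,
    traces: dict | None = None,
) -> CohortResult:
    """Per-nest runs, pooled diel cells of usable nests, and the ANOVAs."""
    if animal_ids is None:
        animal_ids = sorted(traces.keys() if traces else config.input_paths.keys())
    nests = {}
    for aid in animal_ids:
        nests[aid] = run_nest(config, aid, trace=(traces or {}).get(aid))

    usable = [
        r for r in nests.values()
        if not r.flags.get("diel_overlap", True) and not r.diel_cells.empty
    ]
    if len(usable) < 2:
        raise DataError("fewer than two nests usable for the diel ANOVA")
    cells = pd.concat([r.diel_cells for r in usable], ignore_index=True)
    two_way = diel.two_factor_anova(cells)
    first = diel.per_period_anova(cells, "first_24h")
    last = diel.per_period_anova(cells, "last_24h")

    pooled_orientation = pd.DataFrame([r.orientation.as_row() for r in nests.values()])
    axis_rows = [{"animal_id": r.animal_id, **{f"mean_abs_dba_{k}": v
                                               for k, v in r.axis_dba.items()}}
                 for r in nests.values()]
    axis_table = pd.DataFrame(axis_rows)

    result = CohortResult(nests, cells, two_way, first, last, pooled_orientation, axis_table)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(cells, out / "cohort_diel_cells.csv")
        write_table(two_way.reset_index(names="term"), out / "anova_two_way.csv")
        write_table(first.reset_index(names="term"), out / "anova_first24.csv")
        write_table(last.reset_index(names="term"), out / "anova_last24.csv")
        write_table(pooled_orientation, out / "cohort_orientation.csv")
        write_table(axis_table, out / "cohort_axis_dba.csv")
    return result


def pooled_orientation_proportions(cohort: CohortResult) -> dict:
    """Sample-weighted posture proportions across every nest of a cohort."""
    df = cohort.pooled_orientation
    weights = df["n_samples"].to_numpy(float)
    out = {}
    for lab in orientation.ALL_LABELS:
        out[lab] = float(np.average(df[lab].to_numpy(float), weights=weights))
    return out
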