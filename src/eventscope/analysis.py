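"""Post-hoc quantification of event-based runs.

Mirrors the figure-level analyses a closed-loop experiment produces: count
time series and lag-phase durations around a perfusion switch, whole-field
fluorescence summaries, and nuclear-localization time courses aggregated
across tracked cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math

import numpy as np
import pandas as pd


@dataclass
class CountSeries:
    """Cell count over time at one position, with an optional switch time."""
    times: np.ndarray
    counts: np.ndarray
    switch_time: Optional[float] = None
    source: str = "segmentation"   # or "ground_truth"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.counts = np.asarray(self.counts)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")


def count_series_from_log(log, position_id: int = 0,
                          switch_time: Optional[float] = None) -> CountSeries:
    """Build a :class:`CountSeries` from an engine EventLog.

    If ``switch_time`` is omitted, the first valve-ON event is used.
    """
    events = log.filter("analysis", position_id)
    times = [e.t_s for e in events]
    counts = [e.data["count"] for e in events]
    if switch_time is None:
        valves = [e for e in log.filter("valve") if e.data.get("state")]
        switch_time = valves[0].t_s if valves else None
    return CountSeries(np.array(times), np.array(counts), switch_time)


def lag_threshold_count(initial_count: int, factor: float = 1.3) -> int:
    """Count at which the lag phase ends: 130% of the initial size
    (counts are integers, so the threshold rounds up)."""
    return int(math.ceil(factor * initial_count))


def lag_phase_duration(series: CountSeries, factor: float = 1.3) -> Optional[float]:
    """Lag-phase duration: time from the medium switch until the population
    reaches 130% of its size at the switch.

    The end is the first sampled frame at or above the threshold (no
    interpolation between frames).  Returns None when the threshold is never
    reached.
    """
    if series.switch_time is None:
        raise ValueError("series has no switch_time")
    t0 = series.switch_time
    before = series.counts[series.times <= t0]
    if len(before) == 0:
        raise ValueError("series does not cover the switch time")
    n0 = int(before[-1])
    threshold = lag_threshold_count(n0, factor)
    after = (series.times >= t0) & (series.counts >= threshold)
    if not after.any():
        return None
    return float(series.times[after][0] - t0)


def field_fluorescence_summary(frame) -> tuple:
    """Mean and population standard deviation over all pixels of a frame."""
    px = np.asarray(frame.pixels if hasattr(frame, "pixels") else frame, float)
    return float(px.mean()), float(px.std())


def localization_timecourse(features: pd.DataFrame, cell_labels=None,
                            position_id: Optional[int] = None) -> pd.DataFrame:
    """Nuclear-localization score vs time, per cell and aggregated.

    ``features`` is the engine's feature table with an ``nls`` column.
    Returns one row per timepoint with per-cell scores (columns ``cell_<id>``),
    the across-cell ``mean`` and population ``sd``.  Cells missing from a
    frame leave a gap (NaN), never interpolated.
    """
    df = features.dropna(subset=["nls"]) if "nls" in features else features.iloc[0:0]
    if position_id is not None and len(df):
        df = df[df.position_id == position_id]
    if cell_labels is not None and len(df):
        df = df[df.label.isin(list(cell_labels))]
    if not len(df):
        return pd.DataFrame(columns=["t_s", "mean", "sd"])
    wide = df.pivot_table(index="t_s", columns="label", values="nls")
    out = pd.DataFrame({"t_s": wide.index.values})
    for label in wide.columns:
        out[f"cell_{label}"] = wide[label].values
    out["mean"] = wide.mean(axis=1).values
    out["sd"] = wide.std(axis=1, ddof=0).values
    return out


def peak_time(timecourse: pd.DataFrame, column: str = "mean") -> float:
    """Time of the maximum of an aggregated localization time course."""
    idx = int(np.nanargmax(timecourse[column].values))
    return float(timecourse["t_s"].values[idx])
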