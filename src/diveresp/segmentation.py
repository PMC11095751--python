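"""Dive segmentation of regularly sampled depth traces.

A dive is a maximal run of consecutive samples strictly deeper than a
minimum depth threshold.  The surface interval of dive *i* is the time
between the end of dive *i* and the start of dive *i+1*; the breath is
assumed to occur in that interval, so the interval is attributed to the
preceding dive.  Sample *k* of a record covers the half-open span
``[k/fs, (k+1)/fs)`` seconds relative to ``start_time``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthRecord",
    "Dive",
    "segment_dives",
    "summarize_dive",
    "zero_offset_correct",
    "match_video_labels",
]

DEFAULT_THRESHOLD = 0.5  # metres


@dataclass
class DepthRecord:
    """One whale's uniformly sampled depth trace (metres, positive down)."""

    whale_id: str
    depth: np.ndarray
    sampling_rate: float = 2.0
    start_time: float = 0.0
    sex: str = "unknown"
    age_class: str = "juvenile"
    age: Optional[float] = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if self.depth.size and not np.all(np.isfinite(self.depth)):
            raise ValueError("depth contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.depth.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.depth.size) / self.sampling_rate


@dataclass
class Dive:
    """A single dive and the surface interval that follows it."""

    whale_id: str
    index: int
    dive_start: float
    dive_end: float
    max_depth: float
    dive_duration: float
    surface_interval: float
    video_label: Optional[str] = None
    dive_type: Optional[str] = None
    duration_class: Optional[str] = None
    forage_rule: bool = False

    def __post_init__(self) -> None:
        if self.dive_duration <= 0:
            raise ValueError("dive_duration must be positive")
        if self.surface_interval < 0:
            raise ValueError("surface_interval must be non-negative")
        if not np.isclose(self.dive_end, self.dive_start + self.dive_duration):
            raise ValueError("dive_end must equal dive_start + dive_duration")

    @property
    def cycle_duration(self) -> float:
        """Dive plus its following surface interval."""
        return self.dive_duration + self.surface_interval


def summarize_dive(samples: Sequence[float], sampling_rate: float) -> tuple[float, float]:
    """Maximum depth and duration of a run of submerged samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("summarize_dive requires at least one sample")
    return float(samples.max()), samples.size / float(sampling_rate)


def _submerged_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``above`` is True."""
    if above.size == 0:
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), stops.tolist()))


def segment_dives(record: DepthRecord, threshold: float = DEFAULT_THRESHOLD) -> list[Dive]:
    """Split a depth record into complete dives with surface intervals.

    A leading surface period is discarded.  A dive truncated by the end of
    the record is dropped as incomplete; the trailing surface period is
    kept as the final dive's surface interval only when the record ends at
    the surface.

    Parameters
    ----------
    record : DepthRecord
    threshold : float
        Minimum dive depth in metres; strictly greater counts as submerged.
    """
    if record.depth.size == 0:
        raise ValueError("empty depth record")
    if threshold <= 0:
        raise ValueError("threshold must be positive")

    fs = record.sampling_rate
    above = record.depth > threshold
    runs = _submerged_runs(above)
    if not runs:
        return []
    # final run touching the record boundary is truncated -> incomplete
    if runs and runs[-1][1] == record.depth.size:
        runs = runs[:-1]

    dives: list[Dive] = []
    for i, (a, b) in enumerate(runs):
        max_depth, duration = summarize_dive(record.depth[a:b], fs)
        next_start = runs[i + 1][0] if i + 1 < len(runs) else record.depth.size
        surface_interval = (next_start - b) / fs
        start = record.start_time + a / fs
        dives.append(
            Dive(
                whale_id=record.whale_id,
                index=i,
                dive_start=start,
                dive_end=start + duration,
                max_depth=max_depth,
                dive_duration=duration,
                surface_interval=surface_interval,
            )
        )
    return dives


def zero_offset_correct(record: DepthRecord, window: float = 600.0,
                        quantile: float = 0.05) -> DepthRecord:
    """Remove slow surface drift by subtracting a rolling low quantile.

    The baseline is the per-window 5th percentile of depth (centred,
    shrinking at the edges), taken as the local surface level.  Corrected
    depths are clipped at 0 so surface samples never go negative.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = int(round(window * record.sampling_rate))
    if n_win < 2:
        raise ValueError("window shorter than 2 samples")
    s = pd.Series(record.depth)
    baseline = s.rolling(n_win, min_periods=1, center=True).quantile(quantile)
    corrected = np.clip(record.depth - baseline.to_numpy(), 0.0, None)
    return replace(record, depth=corrected)


def match_video_labels(
    dives: list[Dive],
    labeled_intervals: Sequence[tuple[float, float, str]],
) -> tuple[list[Dive], int]:
    """Attach behaviour labels observed over time intervals to dives.

    Each dive cycle ``[dive_start, dive_start + cycle)`` receives the label
    of the interval with which it overlaps most; "unidentified" labels are
    dropped (the dive stays unlabeled) and counted.

    Returns
    -------
    (dives, n_unidentified_dropped)
    """
    ivs = sorted(labeled_intervals)
    for j in range(1, len(ivs)):
        if ivs[j][0] < ivs[j - 1][1]:
            raise ValueError(f"overlapping labeled intervals: {ivs[j - 1]} and {ivs[j]}")
    n_dropped = 0
    for dive in dives:
        cycle = (dive.dive_start, dive.dive_start + dive.cycle_duration)
        best_label, best_overlap = None, 0.0
        for a, b, lab in ivs:
            overlap = min(cycle[1], b) - max(cycle[0], a)
            if overlap > best_overlap:
                best_overlap, best_label = overlap, lab
        if best_label is None:
            continue
        if best_label == "unidentified":
            n_dropped += 1
            dive.video_label = None
        else:
            dive.video_label = best_label
    return dives, n_dropped
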