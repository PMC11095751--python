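"""Grouping dive sequences into fixed-minimum-duration tracks.

A track is the shortest contiguous run of complete dive + surface-interval
cycles whose cumulative duration reaches the minimum (10 minutes by
default).  Construction is greedy left to right: a track closes at the
first dive that pushes it past the threshold.  A trailing remainder that
never reaches the threshold becomes an ineligible track — it is retained
for state decoding but excluded from respiration analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .segmentation import Dive

__all__ = ["Track", "build_tracks", "classify_duration"]

MIN_TRACK_DURATION = 600.0  # seconds
SHORT_LONG_BREAKPOINT = 60.0  # seconds


@dataclass
class Track:
    whale_id: str
    track_index: int
    dive_indices: range
    cumulative_duration: float
    eligible: bool
    behaviour: Optional[str] = None
    behaviour_source: Optional[str] = None  # video | rule | predicted

    @property
    def n_dives(self) -> int:
        return len(self.dive_indices)

    @property
    def n_surface_intervals(self) -> int:
        # one breath opportunity per member dive
        return self.n_dives


def build_tracks(dives: list[Dive], min_duration: float = MIN_TRACK_DURATION) -> list[Track]:
    """Greedily partition an ordered dive sequence into tracks.

    Raises ``ValueError`` on unordered input (dives must come from one
    whale in time order).
    """
    for prev, cur in zip(dives, dives[1:]):
        if cur.dive_start < prev.dive_end:
            raise ValueError("dives must be ordered in time")

    tracks: list[Track] = []
    start = 0
    cum = 0.0
    for i, dive in enumerate(dives):
        cum += dive.cycle_duration
        if cum >= min_duration:
            tracks.append(
                Track(
                    whale_id=dive.whale_id,
                    track_index=len(tracks),
                    dive_indices=range(start, i + 1),
                    cumulative_duration=cum,
                    eligible=True,
                )
            )
            start, cum = i + 1, 0.0
    if start < len(dives):  # trailing remainder below the threshold
        tracks.append(
            Track(
                whale_id=dives[start].whale_id,
                track_index=len(tracks),
                dive_indices=range(start, len(dives)),
                cumulative_duration=cum,
                eligible=False,
            )
        )
    return tracks


def classify_duration(dive: Dive, breakpoint: float = SHORT_LONG_BREAKPOINT) -> str:
    """"short" if the dive lasted under the breakpoint, else "long"."""
    if dive.dive_duration <= 0:
        raise ValueError("dive_duration must be positive")
    return "short" if dive.dive_duration < breakpoint else "long"
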