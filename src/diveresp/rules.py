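"""Deterministic dive-type and foraging labeling rules.

Dive types are assigned from max depth and surface-interval thresholds;
depths falling between the defined bands stay unlabeled.  Tracks holding
at least one deep dive are labelled foraging, and dives deeper than the
neighbour depth that start shortly after a deep dive ends are flagged as
foraging dives.  Video-derived track labels always outrank rule labels;
a disagreement raises instead of being silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .segmentation import Dive
from .tracks import Track

__all__ = [
    "RuleThresholds",
    "assign_dive_type",
    "propagate_foraging",
    "label_track_from_video",
    "LabelConflictError",
]

log = logging.getLogger(__name__)

BEHAVIOURS = ("resting", "travelling", "foraging")
DIVE_TYPES = ("shallow", "medium", "deep", "logging")


class LabelConflictError(ValueError):
    """A rule-derived track behaviour contradicts its video label."""


@dataclass(frozen=True)
class RuleThresholds:
    shallow_max: float = 7.5        # m, strict upper bound for shallow
    medium_min: float = 10.0        # m, inclusive
    medium_max: float = 30.0        # m, inclusive
    deep_min: float = 50.0          # m, strict lower bound for deep
    logging_si_min: float = 10.0    # s, strict; longer surface interval = logging
    forage_neighbor_depth: float = 30.0   # m, strict
    forage_neighbor_window: float = 120.0  # s after a deep dive ends, inclusive

    def __post_init__(self) -> None:
        if not (0 < self.shallow_max < self.medium_min <= self.medium_max < self.deep_min):
            raise ValueError("depth thresholds must be ordered and positive")
        if self.logging_si_min <= 0 or self.forage_neighbor_window <= 0:
            raise ValueError("time thresholds must be positive")


def assign_dive_type(dive: Dive, thresholds: RuleThresholds = RuleThresholds()) -> str:
    """Total dive-type function: logging outranks the depth bands."""
    t = thresholds
    if dive.surface_interval > t.logging_si_min:
        kind = "logging"
    elif dive.max_depth < t.shallow_max:
        kind = "shallow"
    elif t.medium_min <= dive.max_depth <= t.medium_max:
        kind = "medium"
    elif dive.max_depth > t.deep_min:
        kind = "deep"
    else:
        kind = "unlabeled"
    dive.dive_type = kind
    return kind


def propagate_foraging(
    dives: list[Dive],
    tracks: list[Track],
    thresholds: RuleThresholds = RuleThresholds(),
) -> None:
    """Spread foraging evidence from deep dives to tracks and neighbours.

    Mutates ``dives`` (``forage_rule`` flag) and ``tracks`` (behaviour =
    foraging, source = rule).  Idempotent.  Raises
    :class:`LabelConflictError` when a track already carries a different
    video behaviour.
    """
    t = thresholds
    deep_ends = [d.dive_end for d in dives if d.dive_type == "deep"]
    for dive in dives:
        if dive.dive_type == "deep":
            dive.forage_rule = True
            continue
        if dive.max_depth > t.forage_neighbor_depth:
            for end in deep_ends:
                if 0 <= dive.dive_start - end <= t.forage_neighbor_window:
                    dive.forage_rule = True
                    break
    for track in tracks:
        members = [dives[i] for i in track.dive_indices]
        if any(d.dive_type == "deep" for d in members):
            if track.behaviour_source == "video" and track.behaviour != "foraging":
                raise LabelConflictError(
                    f"track {track.whale_id}/{track.track_index}: deep-dive rule says "
                    f"foraging but video label is {track.behaviour!r}"
                )
            track.behaviour = "foraging"
            if track.behaviour_source != "video":
                track.behaviour_source = "rule"


def label_track_from_video(track: Track, member_dives: list[Dive]) -> Optional[str]:
    """Unanimous video behaviour of a track's member dives, if any.

    Logging dive labels are ignored (logging is a dive type; tracks carry
    only resting/travelling/foraging).  Mixed labels leave the track
    unlabeled and log a warning.
    """
    labels = {
        d.video_label
        for d in member_dives
        if d.video_label is not None and d.video_label != "logging"
    }
    if not labels:
        return None
    if len(labels) > 1:
        log.warning(
            "track %s/%s has conflicting video labels %s; leaving unlabeled",
            track.whale_id, track.track_index, sorted(labels),
        )
        return None
    (behaviour,) = labels
    if behaviour not in BEHAVIOURS:
        raise ValueError(f"unknown behaviour label {behaviour!r}")
    track.behaviour = behaviour
    track.behaviour_source = "video"
    return behaviour
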