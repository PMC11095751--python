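"""Synthetic depth traces with known behaviour / dive-type truth.

The generator mirrors the hierarchy the decoder assumes: a coarse
behaviour chain over tracks, a fine dive-type chain within each track,
and gamma-distributed dive observables (max depth, dive duration,
surface-interval duration) per dive type.  Each dive is rendered into a
2 Hz depth trace as a V- (or U-) shaped excursion whose samples all
exceed the segmentation threshold, separated by surface samples clipped
below it — so segmentation at the generating threshold recovers the
generated dives exactly, and every truth record aligns one-to-one with a
recovered dive.

Video-style labels are a shallow-biased subsample: each dive is labeled
with probability proportional to ``coverage * exp(-max_depth/bias_scale)``,
renormalized so the expected labeled fraction is the coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hhmm import BEHAVIOURS, DIVE_TYPES, HHMMParams
from .segmentation import DepthRecord

__all__ = [
    "WhaleSpec",
    "SimulationConfig",
    "TruthDive",
    "TruthTrack",
    "SimulatedDataset",
    "simulate_dataset",
    "render_dive",
    "sample_labels",
    "default_params",
]

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class WhaleSpec:
    whale_id: str
    sex: str = "unknown"          # male | female | unknown
    age_class: str = "juvenile"   # juvenile | adult_male
    age: float = 8.0              # years


@dataclass
class SimulationConfig:
    whales: list[WhaleSpec]
    record_duration: float               # seconds per whale
    hhmm_params: HHMMParams
    sampling_rate: float = 2.0
    track_min_duration: float = 600.0
    dive_threshold: float = 0.5
    dive_shape: str = "v"                # "v" or "u"
    depth_noise_sd: float = 0.0
    label_coverage: float = 0.0
    label_bias_scale: float = np.inf     # metres; inf = unbiased
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.whales:
            raise ValueError("need at least one whale")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.label_coverage <= 1.0:
            raise ValueError("label_coverage must be in [0, 1]")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be non-negative")
        if self.dive_shape not in ("v", "u"):
            raise ValueError("dive_shape must be 'v' or 'u'")
        self.hhmm_params.validate()


@dataclass(frozen=True)
class TruthDive:
    dive_type: str
    behaviour: str
    max_depth: float
    dive_duration: float
    surface_interval: float
    track_index: int


@dataclass(frozen=True)
class TruthTrack:
    behaviour: str
    first_dive: int
    n_dives: int
    complete: bool  # reached the minimum track duration


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    depth_records: list[DepthRecord]
    truth_dives: dict[str, list[TruthDive]]
    truth_tracks: dict[str, list[TruthTrack]]
    labels: dict[str, list[Optional[str]]]


def default_params() -> HHMMParams:
    """Study-like generative truth with a tri-modal depth structure.

    Behaviours differ only in dive-type composition: resting mixes
    shallow dives with frequent logging, travelling is almost purely
    shallow with occasional medium dives, and foraging mixes shallow,
    medium and deep dives.
    """
    def gam(mean: float, sd: float) -> tuple[float, float]:
        shape = (mean / sd) ** 2
        return shape, mean / shape

    pi_coarse = np.array([0.4, 0.4, 0.2])
    gamma_coarse = np.array([
        [0.70, 0.20, 0.10],
        [0.20, 0.70, 0.10],
        [0.15, 0.15, 0.70],
    ])
    # deep dives occur only while foraging, the premise of the deep-dive
    # labeling rule; resting is marked by frequent logging, travelling by
    # an almost purely shallow mix
    mix = np.array([
        [0.73, 0.02, 0.00, 0.25],   # resting
        [0.89, 0.10, 0.00, 0.01],   # travelling
        [0.55, 0.25, 0.15, 0.05],   # foraging
    ])
    pi_fine = mix.copy()
    gamma_fine = np.repeat(mix[:, None, :], len(DIVE_TYPES), axis=1)
    emissions = np.array([
        # (depth m), (duration s), (surface interval s) as gamma (shape, scale)
        [gam(3.0, 1.5), gam(25.0, 10.0), gam(4.5, 1.6)],    # shallow
        [gam(20.0, 4.0), gam(60.0, 15.0), gam(5.0, 1.6)],   # medium
        [gam(90.0, 20.0), gam(180.0, 40.0), gam(6.0, 1.6)],  # deep
        [gam(1.5, 0.4), gam(15.0, 5.0), gam(20.0, 5.0)],    # logging
    ])
    return HHMMParams(pi_coarse, gamma_coarse, pi_fine, gamma_fine, emissions)


def render_dive(
    max_depth: float,
    dive_duration: float,
    surface_interval: float,
    sampling_rate: float,
    noise_sd: float,
    rng: np.random.Generator,
    threshold: float = 0.5,
    shape: str = "v",
) -> np.ndarray:
    """Depth samples for one dive followed by its surface interval.

    All dive samples strictly exceed ``threshold`` and the noiseless
    maximum equals ``max_depth`` exactly; surface samples are
    ``|N(0, noise_sd)|`` clipped below the threshold so noise can never
    fabricate a dive.
    """
    if max_depth <= threshold:
        raise ValueError(f"max_depth {max_depth} must exceed threshold {threshold}")
    n_dive = int(round(dive_duration * sampling_rate))
    if n_dive < 2:
        raise ValueError("dive_duration shorter than 2 samples")
    n_surf = int(round(surface_interval * sampling_rate))

    frac = np.arange(n_dive) / (n_dive - 1)
    if shape == "v":
        profile = 1.0 - np.abs(2.0 * frac - 1.0)
    elif shape == "u":
        profile = np.clip(np.minimum(frac / 0.25, (1.0 - frac) / 0.25), 0.0, 1.0)
    else:
        raise ValueError(f"unknown dive shape {shape!r}")
    base = threshold + max(0.1, 3.0 * noise_sd)
    base = min(base, 0.5 * (threshold + max_depth))
    depth = base + (max_depth - base) * profile / profile.max()
    if noise_sd > 0:
        depth = depth + rng.normal(0.0, noise_sd, size=n_dive)
        depth = np.maximum(depth, threshold + 1e-6)
    surface = np.minimum(np.abs(rng.normal(0.0, noise_sd, size=n_surf))
                         if noise_sd > 0 else np.zeros(n_surf), threshold)
    return np.concatenate([depth, surface])


def sample_labels(
    truth_dives: Sequence[TruthDive],
    coverage: float,
    bias_scale: float,
    rng: np.random.Generator,
) -> list[Optional[str]]:
    """Shallow-biased independent labeling of dives with truth behaviours."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if not truth_dives:
        return []
    depths = np.array([d.max_depth for d in truth_dives])
    weight = np.exp(-depths / bias_scale) if np.isfinite(bias_scale) \
        else np.ones_like(depths)
    p = np.clip(coverage * weight / weight.mean(), 0.0, 1.0)
    drawn = rng.random(len(truth_dives)) < p
    return [d.behaviour if take else None for d, take in zip(truth_dives, drawn)]


def _draw_observables(params: HHMMParams, dive_type: int, cfg: SimulationConfig,
                      rng: np.random.Generator) -> tuple[float, float, float]:
    """Quantized (max_depth, duration, surface interval) with rejection of
    draws that cannot be rendered above the segmentation threshold."""
    fs = cfg.sampling_rate
    margin = cfg.dive_threshold + 0.1 + 3.0 * cfg.depth_noise_sd
    for _ in range(_MAX_REJECTIONS):
        shp = params.emissions[dive_type]
        depth = rng.gamma(shp[0, 0], shp[0, 1])
        duration = rng.gamma(shp[1, 0], shp[1, 1])
        surface = rng.gamma(shp[2, 0], shp[2, 1])
        duration = max(2, int(round(duration * fs))) / fs
        surface = max(1, int(round(surface * fs))) / fs
        if depth > margin:
            return depth, duration, surface
    raise ValueError(
        f"invalid emission parameters for dive type {params.dive_types[dive_type]}: "
        f"{_MAX_REJECTIONS} consecutive draws at or below the dive threshold")


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate every whale's depth trace, truth states and labels."""
    params = config.hhmm_params
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_total = int(round(config.record_duration * fs))
    lead_surface = int(round(2.0 * fs))  # so the first dive is complete

    records: list[DepthRecord] = []
    truth_dives: dict[str, list[TruthDive]] = {}
    truth_tracks: dict[str, list[TruthTrack]] = {}
    labels: dict[str, list[Optional[str]]] = {}

    for spec in config.whales:
        chunks: list[np.ndarray] = []
        if config.depth_noise_sd > 0:
            lead = np.minimum(np.abs(rng.normal(0, config.depth_noise_sd,
                                                lead_surface)), config.dive_threshold)
        else:
            lead = np.zeros(lead_surface)
        chunks.append(lead)
        n_used = lead_surface
        dives: list[TruthDive] = []
        tracks_out: list[TruthTrack] = []
        behaviour = int(rng.choice(params.n_behaviours, p=params.pi_coarse))
        first = True
        out_of_time = False
        while not out_of_time:
            if not first:
                behaviour = int(rng.choice(params.n_behaviours,
                                           p=params.gamma_coarse[behaviour]))
            first = False
            track_start = len(dives)
            cum = 0.0
            dtype = -1
            while cum < config.track_min_duration:
                if dtype < 0:
                    dtype = int(rng.choice(params.n_dive_types,
                                           p=params.pi_fine[behaviour]))
                else:
                    dtype = int(rng.choice(params.n_dive_types,
                                           p=params.gamma_fine[behaviour, dtype]))
                depth, duration, surface = _draw_observables(params, dtype,
                                                             config, rng)
                n_cycle = int(round((duration + surface) * fs))
                if n_used + n_cycle > n_total:
                    out_of_time = True
                    break
                chunks.append(render_dive(depth, duration, surface, fs,
                                          config.depth_noise_sd, rng,
                                          threshold=config.dive_threshold,
                                          shape=config.dive_shape))
                n_used += n_cycle
                cum += duration + surface
                dives.append(TruthDive(params.dive_types[dtype],
                                       params.behaviours[behaviour],
                                       depth, duration, surface,
                                       track_index=len(tracks_out)))
            n_in_track = len(dives) - track_start
            if n_in_track > 0:
                tracks_out.append(TruthTrack(params.behaviours[behaviour],
                                             track_start, n_in_track,
                                             complete=cum >= config.track_min_duration))
        # the record ends right after the final complete dive cycle, so the
        # last dive's recovered surface interval matches the generated one
        records.append(DepthRecord(
            whale_id=spec.whale_id,
            depth=np.concatenate(chunks),
            sampling_rate=fs,
            sex=spec.sex,
            age_class=spec.age_class,
            age=spec.age,
        ))
        truth_dives[spec.whale_id] = dives
        truth_tracks[spec.whale_id] = tracks_out
        labels[spec.whale_id] = sample_labels(dives, config.label_coverage,
                                              config.label_bias_scale, rng)
    return SimulatedDataset(config, records, truth_dives, truth_tracks, labels)
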