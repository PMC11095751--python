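"""End-to-end composition: segment -> tracks -> rules -> HHMM -> energetics."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__, io
from .energetics import (GrowthModelConfig, MassMatchError, ReferenceAnimal,
                         match_reference, predict_length, predict_mass,
                         respiration_rate, vo2)
from .hhmm import (BEHAVIOURS, DIVE_TYPES, HHMMParams, TrackObs, WhaleObs,
                   fit_em, viterbi_decode)
from .rules import (RuleThresholds, assign_dive_type, label_track_from_video,
                    propagate_foraging)
from .segmentation import DepthRecord, Dive, match_video_labels, segment_dives, \
    zero_offset_correct
from .synthetic import default_params
from .tracks import Track, build_tracks, classify_duration
from .validation import loo_crossval, error_metrics

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Structured run configuration; see ``load_config``."""

    threshold_m: float = 0.5
    zero_offset_window_s: Optional[float] = None  # None disables correction
    min_track_duration_s: float = 600.0
    short_long_breakpoint_s: float = 60.0
    rules: RuleThresholds = field(default_factory=RuleThresholds)
    tol: float = 1e-5
    max_iter: int = 200
    n_restarts: int = 2
    seed: int = 0
    logging_multiplier: float = 1.0
    run_crossval: bool = False


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    rules = RuleThresholds(**doc.pop("rules", {}))
    return PipelineConfig(rules=rules, **doc)


def process_record(record: DepthRecord, cfg: PipelineConfig,
                   label_intervals: Optional[Sequence[tuple[float, float, str]]] = None,
                   ) -> tuple[list[Dive], list[Track]]:
    """Segment one record, attach labels, build tracks and apply rules."""
    if cfg.zero_offset_window_s:
        record = zero_offset_correct(record, cfg.zero_offset_window_s)
    dives = segment_dives(record, cfg.threshold_m)
    if label_intervals:
        dives, n_dropped = match_video_labels(dives, label_intervals)
        if n_dropped:
            log.info("%s: dropped %d unidentified labels", record.whale_id, n_dropped)
    for d in dives:
        assign_dive_type(d, cfg.rules)
        d.duration_class = classify_duration(d, cfg.short_long_breakpoint_s)
    tracks = build_tracks(dives, cfg.min_track_duration_s)
    for t in tracks:
        label_track_from_video(t, [dives[i] for i in t.dive_indices])
    propagate_foraging(dives, tracks, cfg.rules)
    return dives, tracks


def to_whale_obs(record: DepthRecord, dives: list[Dive],
                 tracks: list[Track]) -> WhaleObs:
    """Convert processed dives/tracks into model-ready observations."""
    track_obs = []
    for t in tracks:
        members = [dives[i] for i in t.dive_indices]
        obs = np.array([[d.max_depth, d.dive_duration, max(d.surface_interval, 1e-3)]
                        for d in members])
        cons = np.array([DIVE_TYPES.index(d.dive_type)
                         if d.dive_type in DIVE_TYPES else -1 for d in members])
        video = BEHAVIOURS.index(t.behaviour) \
            if t.behaviour_source == "video" and t.behaviour in BEHAVIOURS else -1
        rule = BEHAVIOURS.index(t.behaviour) \
            if t.behaviour_source == "rule" and t.behaviour in BEHAVIOURS else -1
        track_obs.append(TrackObs(obs, cons, video_behaviour=video,
                                  rule_behaviour=rule))
    return WhaleObs(record.whale_id, record.age_class, track_obs)


def initial_params_from_data(whales: Sequence[WhaleObs],
                             template: Optional[HHMMParams] = None) -> HHMMParams:
    """Data-driven EM initial values.

    Emissions are moment-matched per rule-constrained dive type, falling
    back to the template for unseen types; transitions start sticky.
    """
    params = (template or default_params()).copy()
    D = params.n_dive_types
    obs = np.concatenate([t.obs for w in whales for t in w.tracks])
    cons = np.concatenate([t.dive_constraints for w in whales for t in w.tracks])
    for d in range(D):
        x = obs[cons == d]
        if x.shape[0] < 5:
            continue
        m, v = x.mean(axis=0), np.maximum(x.var(axis=0), 1e-6)
        shape = np.maximum(m ** 2 / v, 1e-2)
        params.emissions[d, :, 0] = shape
        params.emissions[d, :, 1] = m / shape
    B = params.n_behaviours
    params.pi_coarse = np.full(B, 1.0 / B)
    params.gamma_coarse = np.full((B, B), 0.15 / (B - 1)) + np.eye(B) * (0.85 - 0.15 / (B - 1))
    params.gamma_coarse /= params.gamma_coarse.sum(axis=1, keepdims=True)
    params.validate()
    return params


def run_pipeline(
    records: Sequence[DepthRecord],
    cfg: PipelineConfig,
    out_dir,
    label_intervals: Optional[dict[str, Sequence[tuple[float, float, str]]]] = None,
    references: Optional[Sequence[ReferenceAnimal]] = None,
    growth: Optional[GrowthModelConfig] = None,
    initial: Optional[HHMMParams] = None,
) -> dict[str, Path]:
    """Execute every stage and write each stage's table under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    all_dives: list[Dive] = []
    all_tracks: list[Track] = []
    whales: list[WhaleObs] = []
    per_whale: dict[str, tuple[list[Dive], list[Track]]] = {}
    for record in records:
        intervals = (label_intervals or {}).get(record.whale_id)
        dives, tracks = process_record(record, cfg, intervals)
        per_whale[record.whale_id] = (dives, tracks)
        all_dives.extend(dives)
        all_tracks.extend(tracks)
        if dives:
            whales.append(to_whale_obs(record, dives, tracks))

    outputs["dives"] = out_dir / "dives.csv"
    io.write_dive_table(all_dives, outputs["dives"])

    init = initial or initial_params_from_data(whales)
    params, trace = fit_em(init, whales, tol=cfg.tol, max_iter=cfg.max_iter,
                           n_restarts=cfg.n_restarts, seed=cfg.seed,
                           smoothing=0.5)
    outputs["params"] = out_dir / "params.yaml"
    io.save_params(params, outputs["params"])

    resp_rows, vo2_rows = [], []
    post_cols: dict = {}
    for w in whales:
        dives, tracks = per_whale[w.whale_id]
        decoded = viterbi_decode(params, w)
        for t, track in enumerate(tracks):
            if track.behaviour is None:
                track.behaviour = BEHAVIOURS[decoded.behaviours[t]]
                track.behaviour_source = "predicted"
            for b, pname in enumerate(BEHAVIOURS):
                post_cols.setdefault(f"p_{pname}", {})[
                    (w.whale_id, track.track_index)] = decoded.posteriors[t, b]
            if not track.eligible:
                continue
            members = [dives[i] for i in track.dive_indices]
            n_logging = sum(d.dive_type == "logging" for d in members)
            res = respiration_rate(track, n_logging, cfg.logging_multiplier)
            resp_rows.append(res)
            post_cols.setdefault("respiration_rate", {})[
                (w.whale_id, track.track_index)] = res.respiration_rate

    record_by_id = {r.whale_id: r for r in records}
    if references is not None and growth is not None:
        for res in resp_rows:
            rec = record_by_id[res.whale_id]
            if rec.age is None:
                continue
            length = predict_length(rec.age, rec.sex, growth)
            mass = predict_mass(length, growth)
            try:
                ref = match_reference(mass, rec.sex, rec.age_class, references)
            except MassMatchError:
                continue  # excluded, not imputed
            if res.behaviour in BEHAVIOURS:
                vo2_rows.append(vo2(res.respiration_rate, ref, res.behaviour,
                                    res.whale_id, res.track_index))

    outputs["tracks"] = out_dir / "tracks.csv"
    io.write_track_table(all_tracks, outputs["tracks"], extras=post_cols)

    import pandas as pd
    outputs["respiration"] = out_dir / "respiration.csv"
    pd.DataFrame([r.__dict__ for r in resp_rows]).to_csv(outputs["respiration"],
                                                         index=False)
    if vo2_rows:
        outputs["vo2"] = out_dir / "vo2.csv"
        pd.DataFrame([r.__dict__ for r in vo2_rows]).to_csv(outputs["vo2"],
                                                            index=False)

    if cfg.run_crossval:
        cms = loo_crossval(whales, init, tol=cfg.tol, max_iter=cfg.max_iter,
                           n_restarts=1, seed=cfg.seed)
        rows = []
        for (b, ac), cm in cms.items():
            m = error_metrics(cm).rounded()
            rows.append({"age_class": ac, "behaviour": b, "TP": cm.TP,
                         "FN": cm.FN, "FP": cm.FP, "TN": cm.TN, **m})
        outputs["crossval"] = out_dir / "crossval.csv"
        pd.DataFrame(rows).to_csv(outputs["crossval"], index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg.__dict__, default=str, sort_keys=True).encode()
        ).hexdigest(),
        "n_whales": len(records),
        "n_dives": len(all_dives),
        "n_tracks": len(all_tracks),
        "final_loglik": trace[-1],
    }
    outputs["manifest"] = out_dir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2))
    return outputs
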