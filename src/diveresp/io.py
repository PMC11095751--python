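"""CSV and YAML interchange (RFC-4180, UTF-8, '.' decimal).

Column schemas
--------------
depth table:  whale_id, time_s, depth_m
whale table:  whale_id, sex, age_class, age, sampling_rate
label table:  whale_id, start_s, end_s, behaviour
dive table:   whale_id, dive_index, dive_start_s, dive_duration_s,
              max_depth_m, surface_interval_s, video_label, dive_type,
              duration_class, forage_rule
track table:  whale_id, track_index, n_dives, cumulative_duration_s,
              eligible, behaviour, behaviour_source (+ optional extras,
              e.g. respiration_rate)

Unknown columns are preserved on read; missing required columns or
invalid values are reported with row context (schema errors raise
:class:`SchemaError`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .hhmm import HHMMParams
from .segmentation import DepthRecord, Dive
from .tracks import Track

__all__ = [
    "SchemaError",
    "write_depth_table", "read_depth_table",
    "write_dive_table", "read_dive_table", "dives_to_frame", "frame_to_dives",
    "write_track_table", "read_track_table", "tracks_to_frame",
    "save_params", "load_params",
]

DIVE_COLUMNS = ["whale_id", "dive_index", "dive_start_s", "dive_duration_s",
                "max_depth_m", "surface_interval_s", "video_label", "dive_type",
                "duration_class", "forage_rule"]
TRACK_COLUMNS = ["whale_id", "track_index", "n_dives", "cumulative_duration_s",
                 "eligible", "behaviour", "behaviour_source"]


class SchemaError(ValueError):
    """A table violates its documented schema."""


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


# -- depth ------------------------------------------------------------------

def write_depth_table(records: Sequence[DepthRecord], path) -> None:
    frames = [
        pd.DataFrame({"whale_id": r.whale_id, "time_s": r.times,
                      "depth_m": r.depth})
        for r in records
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = pd.DataFrame([
        {"whale_id": r.whale_id, "sex": r.sex, "age_class": r.age_class,
         "age": r.age, "sampling_rate": r.sampling_rate}
        for r in records
    ])
    meta.to_csv(Path(path).with_suffix(".whales.csv"), index=False)


def read_depth_table(path, whales_path=None) -> list[DepthRecord]:
    df = pd.read_csv(path)
    _require(df, ["whale_id", "time_s", "depth_m"], path)
    whales_path = whales_path or Path(path).with_suffix(".whales.csv")
    meta = pd.read_csv(whales_path).set_index("whale_id") \
        if Path(whales_path).exists() else None
    records = []
    for wid, g in df.groupby("whale_id", sort=False):
        g = g.sort_values("time_s")
        t = g["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 2.0
        kw = {}
        if meta is not None and wid in meta.index:
            row = meta.loc[wid]
            kw = {"sex": row["sex"], "age_class": row["age_class"],
                  "age": row["age"], "sampling_rate": float(row["sampling_rate"])}
        else:
            kw = {"sampling_rate": float(round(fs, 6))}
        records.append(DepthRecord(whale_id=str(wid),
                                   depth=g["depth_m"].to_numpy(),
                                   start_time=float(t[0]), **kw))
    return records


# -- dives ------------------------------------------------------------------

def dives_to_frame(dives: Sequence[Dive]) -> pd.DataFrame:
    return pd.DataFrame([
        {"whale_id": d.whale_id, "dive_index": d.index,
         "dive_start_s": d.dive_start, "dive_duration_s": d.dive_duration,
         "max_depth_m": d.max_depth, "surface_interval_s": d.surface_interval,
         "video_label": d.video_label, "dive_type": d.dive_type,
         "duration_class": d.duration_class, "forage_rule": d.forage_rule}
        for d in dives
    ], columns=DIVE_COLUMNS)


def frame_to_dives(df: pd.DataFrame) -> list[Dive]:
    dives = []
    for i, row in df.iterrows():
        dur = float(row["dive_duration_s"])
        if dur <= 0:
            raise SchemaError(f"row {i}: non-positive dive duration {dur}")
        if float(row["surface_interval_s"]) < 0:
            raise SchemaError(f"row {i}: negative surface interval")
        dives.append(Dive(
            whale_id=str(row["whale_id"]), index=int(row["dive_index"]),
            dive_start=float(row["dive_start_s"]),
            dive_end=float(row["dive_start_s"]) + dur,
            max_depth=float(row["max_depth_m"]), dive_duration=dur,
            surface_interval=float(row["surface_interval_s"]),
            video_label=None if pd.isna(row.get("video_label")) else str(row["video_label"]),
            dive_type=None if pd.isna(row.get("dive_type")) else str(row["dive_type"]),
            duration_class=None if pd.isna(row.get("duration_class")) else str(row["duration_class"]),
            forage_rule=bool(row.get("forage_rule", False)),
        ))
    return dives


def write_dive_table(dives: Sequence[Dive], path) -> None:
    dives_to_frame(dives).to_csv(path, index=False)


def read_dive_table(path) -> list[Dive]:
    df = pd.read_csv(path)
    _require(df, ["whale_id", "dive_index", "dive_start_s", "dive_duration_s",
                  "max_depth_m", "surface_interval_s"], path)
    return frame_to_dives(df)


# -- tracks -----------------------------------------------------------------

def tracks_to_frame(tracks: Sequence[Track], extras: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for t in tracks:
        row = {"whale_id": t.whale_id, "track_index": t.track_index,
               "n_dives": t.n_dives, "first_dive_index": t.dive_indices.start,
               "cumulative_duration_s": t.cumulative_duration,
               "eligible": t.eligible, "behaviour": t.behaviour,
               "behaviour_source": t.behaviour_source}
        if extras:
            for col, values in extras.items():
                row[col] = values.get((t.whale_id, t.track_index))
        rows.append(row)
    return pd.DataFrame(rows)


def write_track_table(tracks: Sequence[Track], path,
                      extras: Optional[dict] = None) -> None:
    tracks_to_frame(tracks, extras).to_csv(path, index=False)


def read_track_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRACK_COLUMNS, path)
    bad = df.index[df["cumulative_duration_s"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive cumulative duration at row {bad[0]}")
    return df


# -- parameters -------------------------------------------------------------

def save_params(params: HHMMParams, path) -> None:
    doc = {
        "behaviours": list(params.behaviours),
        "dive_types": list(params.dive_types),
        "pi_coarse": params.pi_coarse.tolist(),
        "gamma_coarse": params.gamma_coarse.tolist(),
        "pi_fine": params.pi_fine.tolist(),
        "gamma_fine": params.gamma_fine.tolist(),
        "emissions": params.emissions.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> HHMMParams:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    params = HHMMParams(
        pi_coarse=np.array(doc["pi_coarse"]),
        gamma_coarse=np.array(doc["gamma_coarse"]),
        pi_fine=np.array(doc["pi_fine"]),
        gamma_fine=np.array(doc["gamma_fine"]),
        emissions=np.array(doc["emissions"]),
        behaviours=tuple(doc["behaviours"]),
        dive_types=tuple(doc["dive_types"]),
    )
    params.validate()
    return params
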