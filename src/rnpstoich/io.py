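"""Delimited-text I/O for track sets, counts tables and configuration.

All tables are tab-separated with a header row; canonical units are um and
seconds, frame indices are 0-based.  Track tables have one row per
(track, frame): ``mt_id, track_id, channel, frame_index, time_s, position_um``.
Microtubule geometry lives in a sibling table ``mt_id, length_um``; simulated
ground truth in a JSON sidecar keyed by track id.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from ._types import DualColourCounts, MicrotubuleRef, Track, TrackSet

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_counts",
    "write_counts",
    "load_config",
]

logger = logging.getLogger("rnpstoich")

TRACK_COLUMNS = ["mt_id", "track_id", "channel", "frame_index", "time_s", "position_um"]


class SchemaError(ValueError):
    """A table violates the expected schema (message names the offending rows)."""


def _mt_table_path(track_path: Path) -> Path:
    return track_path.with_name(track_path.stem + ".microtubules.tsv")


def _truth_path(track_path: Path) -> Path:
    return track_path.with_name(track_path.stem + ".ground_truth.json")


def write_tracks(trackset: TrackSet, path: Union[str, Path]) -> None:
    """Write a TrackSet as TSV tables (tracks + microtubules [+ ground truth])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trackset.tracks:
        dt = trackset.frame_interval or (np.median(np.diff(tr.times)) if tr.n_frames > 1 else 0.5)
        frames = np.rint(tr.times / dt).astype(int)
        for f, t, x in zip(frames, tr.times, tr.positions):
            rows.append((tr.mt_id, tr.track_id, tr.channel, int(f), repr(float(t)), repr(float(x))))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, sep="\t", index=False)
    mt_df = pd.DataFrame({"mt_id": [m.mt_id for m in trackset.microtubules],
                          "length_um": [repr(float(m.length)) for m in trackset.microtubules]})
    mt_df.to_csv(_mt_table_path(path), sep="\t", index=False)
    if trackset.ground_truth is not None:
        meta = {"frame_interval": trackset.frame_interval,
                "movie_duration": trackset.movie_duration,
                "seed": trackset.seed,
                "tracks": trackset.ground_truth}
        _truth_path(path).write_text(json.dumps(meta, indent=1, default=float))


def read_tracks(path: Union[str, Path]) -> TrackSet:
    """Read a track table (and its sibling microtubule table) back losslessly.

    Raises :class:`SchemaError` for missing columns, duplicated
    (track_id, frame_index) rows, non-monotonic times within a track, or
    tracks referencing unknown microtubules; messages carry 1-based data row
    numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"mt_id": str, "track_id": str, "channel": str})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: track table has a header but no rows")
        logger.warning("read_tracks: empty table %s", path)

    dup = df.duplicated(subset=["track_id", "frame_index"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise SchemaError(f"{path}: duplicated (track_id, frame_index) at data rows {rows[:10]}")

    mt_path = _mt_table_path(path)
    if mt_path.exists():
        mt_df = pd.read_csv(mt_path, sep="\t", float_precision="round_trip", dtype={"mt_id": str})
        microtubules = [MicrotubuleRef(mt_id=r.mt_id, length=float(r.length_um))
                        for r in mt_df.itertuples()]
    else:
        # geometry table absent: infer lengths from observed positions
        microtubules = [
            MicrotubuleRef(mt_id=str(mt_id), length=float(max(g["position_um"].max(), 1.0)))
            for mt_id, g in df.groupby("mt_id", sort=True)
        ] if len(df) else []
    known = {m.mt_id for m in microtubules}

    tracks = []
    for (track_id,), g in df.groupby(["track_id"], sort=True):
        g = g.sort_values("frame_index")
        times = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = int(g.index[np.argmin(np.diff(times) > 0) + 1]) + 1
            raise SchemaError(f"{path}: non-monotonic time in track {track_id!r} near data row {bad}")
        mt_id = str(g["mt_id"].iloc[0])
        if mt_id not in known:
            raise SchemaError(f"{path}: track {track_id!r} references unknown mt_id {mt_id!r}")
        tracks.append(Track(mt_id=mt_id, track_id=str(track_id), channel=str(g["channel"].iloc[0]),
                            times=times, positions=g["position_um"].to_numpy(dtype=float)))

    ground_truth = None
    frame_interval = movie_duration = seed = None
    tp = _truth_path(path)
    if tp.exists():
        meta = json.loads(tp.read_text())
        ground_truth = meta.get("tracks")
        frame_interval = meta.get("frame_interval")
        movie_duration = meta.get("movie_duration")
        seed = meta.get("seed")
    if frame_interval is None and tracks:
        diffs = np.concatenate([np.diff(tr.times) for tr in tracks if tr.n_frames > 1] or [[0.5]])
        frame_interval = float(np.median(diffs)) if diffs.size else None
    return TrackSet(tracks=tracks, microtubules=microtubules, ground_truth=ground_truth,
                    frame_interval=frame_interval, movie_duration=movie_duration, seed=seed)


def write_counts(counts: list[DualColourCounts], path: Union[str, Path]) -> None:
    rows = [{"condition": c.condition, "n_dual": c.n_dual, "n_A_only": c.n_A_only,
             "n_B_only": c.n_B_only, "n_undetected": c.n_undetected} for c in counts]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts(path: Union[str, Path]) -> list[DualColourCounts]:
    """Read a dual-colour counts table (condition, n_dual, n_A_only, n_B_only[, n_undetected])."""
    df = pd.read_csv(path, sep="\t")
    needed = {"n_dual", "n_A_only", "n_B_only"}
    if not needed.issubset(df.columns):
        raise SchemaError(f"{path}: counts table needs columns {sorted(needed)}")
    out = []
    for r in df.itertuples():
        out.append(DualColourCounts(
            n_dual=int(r.n_dual), n_A_only=int(r.n_A_only), n_B_only=int(r.n_B_only),
            n_undetected=int(getattr(r, "n_undetected", 0) or 0),
            condition=str(getattr(r, "condition", ""))))
    return out


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON configuration document as a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}
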