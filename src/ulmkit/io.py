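"""Readers and writers for the pipeline's on-disk artifacts.

Frame stacks travel as multi-frame TIFF (frames along the first axis) plus a
JSON sidecar carrying calibration and transducer metadata; candidates, tracks
and ground-truth trajectories as CSV tables; maps as float TIFF plus sidecar,
with an optional log-compressed PNG preview.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import FrameStack
from .localize import MBCandidate
from .maps import ULMImage
from .simulate import MBTrajectory
from .tracking import Track, track_speed
from .transducer import PRESETS, TransducerSpec


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: FrameStack, path) -> Path:
    """Write a stack as multi-frame TIFF (t, z, x) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(stack.data, 2, 0).astype(np.float32), photometric='minisblack')
    meta = {
        "pixel_dz_um": stack.pixel_dz_um,
        "pixel_dx_um": stack.pixel_dx_um,
        "frame_rate_hz": stack.frame_rate_hz,
        "origin_um": list(stack.origin_um),
        "transducer": dataclasses.asdict(stack.transducer) if stack.transducer else None,
        "metadata": _jsonable(stack.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path) -> FrameStack:
    path = Path(path)
    data = np.moveaxis(tifffile.imread(path), 0, 2)
    meta = json.loads(_sidecar_path(path).read_text())
    td = meta.get("transducer")
    transducer = TransducerSpec(**td) if td else None
    return FrameStack(
        data=data,
        pixel_dz_um=meta["pixel_dz_um"],
        pixel_dx_um=meta["pixel_dx_um"],
        frame_rate_hz=meta["frame_rate_hz"],
        transducer=transducer,
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0))),
        metadata=meta.get("metadata", {}),
    )


def write_candidates_csv(candidates: Sequence[MBCandidate], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(c.frame, c.z_um, c.x_um, c.score, c.branch) for c in candidates],
        columns=["frame", "z_um", "x_um", "score", "branch"],
    )
    df.to_csv(path, index=False)
    return path


def read_candidates_csv(path) -> list[MBCandidate]:
    df = pd.read_csv(path)
    return [
        MBCandidate(frame=int(r.frame), z_um=float(r.z_um), x_um=float(r.x_um),
                    score=float(r.score), branch=str(r.branch))
        for r in df.itertuples()
    ]


def write_tracks_csv(tracks: Sequence[Track], path, frame_rate_hz: float = 1000.0) -> Path:
    path = Path(path)
    rows = []
    for t in tracks:
        speed = track_speed(t, frame_rate_hz) if len(t) >= 2 else 0.0
        for frame, z, x in t.points:
            rows.append((t.id, int(frame), z, x, t.branch, speed))
    pd.DataFrame(rows, columns=["track_id", "frame", "z_um", "x_um", "branch", "speed_um_s"]).to_csv(
        path, index=False
    )
    return path


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        pts = grp[["frame", "z_um", "x_um"]].to_numpy(dtype=float)
        tracks.append(Track(points=pts, branch=str(grp["branch"].iloc[0]), id=int(tid)))
    return tracks


def write_trajectories_csv(trajectories: Sequence[MBTrajectory], path) -> Path:
    """Ground truth: trajectory_id, frame, z_um, x_um, segment_id."""
    path = Path(path)
    rows = []
    for i, tr in enumerate(trajectories):
        for k in range(len(tr)):
            rows.append((i, int(tr.frames[k]), tr.zs_um[k], tr.xs_um[k],
                         int(tr.segment_ids[k]), tr.y_um, tr.amplitude))
    pd.DataFrame(
        rows,
        columns=["trajectory_id", "frame", "z_um", "x_um", "segment_id", "y_um", "amplitude"],
    ).to_csv(path, index=False)
    return path


def write_map(image: ULMImage, path, preview: bool = False) -> Path:
    path = Path(path)
    tifffile.imwrite(path, image.counts.astype(np.float32), photometric='minisblack')
    meta = {
        "pixel_um": image.pixel_um,
        "origin_um": list(image.origin_um),
        "kind": image.kind,
        "clipped_weight": image.clipped_weight,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    if preview:
        img = np.log1p(np.maximum(image.counts, 0.0))
        if img.max() > 0:
            img = img / img.max()
        iio.imwrite(path.with_suffix(".png"), (255 * img).astype(np.uint8))
    return path


def read_map(path) -> ULMImage:
    path = Path(path)
    counts = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    return ULMImage(counts=counts, pixel_um=meta["pixel_um"],
                    origin_um=tuple(meta["origin_um"]), kind=meta.get("kind", "density"),
                    weights=counts if meta.get("kind") == "velocity" else None,
                    clipped_weight=meta.get("clipped_weight", 0.0))


def write_spectra_csv(reports, path) -> Path:
    """Per-ensemble singular spectra, long format (ensemble, index, sigma)."""
    path = Path(path)
    rows = []
    for e, rep in enumerate(reports):
        if rep.spectrum is None:
            continue
        for i, sv in enumerate(rep.spectrum.singular_values):
            rows.append((e, i, sv))
    pd.DataFrame(rows, columns=["ensemble", "index", "singular_value"]).to_csv(path, index=False)
    return path


def write_frc_csv(curve, path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "ring_freq_per_um": curve.ring_freqs_per_um,
        "correlation": curve.correlation,
        "n_per_ring": curve.n_per_ring,
    }).to_csv(path, index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
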