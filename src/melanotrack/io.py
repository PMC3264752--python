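"""File formats: multi-page TIFF movies with JSON sidecars, CSV tables, reports.

Movies are written channel-interleaved per frame (page order: frame 0
channel 0, frame 0 channel 1, …) with a sidecar JSON carrying the physical
calibration and channel roles.  Tables (ground truth, tracks, events,
per-bin summaries) are plain CSV so externally produced tracks can enter the
pipeline at the interchange level.  All writers are deterministic: identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .core import MovieStack
from .simulate import GroundTruth

_FLOAT_FORMAT = "%.9g"


def sidecar_path(movie_path: str | Path) -> Path:
    return Path(movie_path).with_suffix(".json")


def write_movie(stack: MovieStack, movie_path: str | Path) -> None:
    """Write a movie as multi-page TIFF plus a JSON calibration sidecar."""
    movie_path = Path(movie_path)
    t, c, h, w = stack.pixels.shape
    pages = stack.pixels.reshape(t * c, h, w).astype(np.float32)
    tifffile.imwrite(movie_path, pages)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channel_roles": stack.channel_roles,
        "n_frames": t,
        "n_channels": c,
    }
    sidecar_path(movie_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_movie(movie_path: str | Path) -> MovieStack:
    """Read a TIFF movie; calibration metadata comes from the sidecar JSON."""
    movie_path = Path(movie_path)
    side = sidecar_path(movie_path)
    if not side.exists():
        raise FileNotFoundError(
            f"calibration sidecar {side} not found; pixel_size and frame_interval are required"
        )
    meta = json.loads(side.read_text())
    try:
        pages = tifffile.imread(movie_path)
    except Exception as exc:  # corrupted/truncated TIFF
        raise ValueError(f"cannot read TIFF movie {movie_path}: {exc}") from exc
    t, c = int(meta["n_frames"]), int(meta["n_channels"])
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != t * c:
        raise ValueError(
            f"TIFF {movie_path} has {pages.shape[0]} pages but sidecar declares {t}x{c}"
        )
    pixels = pages.reshape(t, c, pages.shape[1], pages.shape[2])
    return MovieStack(
        pixels=pixels,
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        channel_roles=list(meta["channel_roles"]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Deterministic CSV writer for track/event/summary tables."""
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of a configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def provenance_block(config: dict, seed: int | None) -> dict:
    return {
        "package": "melanotrack",
        "version": __version__,
        "config_sha256": config_hash(config),
        "seed": seed,
    }


def write_report(report: dict, path: str | Path) -> None:
    """Deterministic JSON report writer (sorted keys, no timestamps)."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False, default=_default) + "\n"
    )


def _jsonify(value):
    """Replace non-finite floats with None for strict-JSON reports."""
    if isinstance(value, dict):
        return {k: _jsonify(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonify(v) for v in value]
    if isinstance(value, (float, np.floating)) and not np.isfinite(value):
        return None
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, np.integer):
        return int(value)
    return value
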