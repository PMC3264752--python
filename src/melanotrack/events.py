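"""Frame-to-frame movement events: the unit of all downstream statistics.

Each consecutive pair of observations in a track yields one event carrying a
speed (Euclidean centroid displacement divided by the frame interval), a
per-channel MMFI (mean organelle-associated fluorescence; the symmetric mean
of the two bounding observations' MFI), a size (mean of the two areas) and,
when two fluorescence channels are present, optionally a channel ratio.

Events are kept as a :class:`pandas.DataFrame` with columns ``cell_id``,
``track_id``, ``frame`` (first frame of the pair), ``speed_um_s``,
``mmfi_ch1`` [, ``mmfi_ch2``, ``ratio``], ``size_um2``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import Track

logger = logging.getLogger(__name__)


def compute_events(tracks: list[Track], frame_interval: float) -> pd.DataFrame:
    """Convert tracks into movement events; a track of length L yields L−1."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    rows = []
    for track in tracks:
        obs = track.observations
        for a, b in zip(obs, obs[1:]):
            displacement = float(np.hypot(b.x - a.x, b.y - a.y))
            row = {
                "cell_id": track.cell_id,
                "track_id": track.track_id,
                "frame": a.frame_index,
                "speed_um_s": displacement / frame_interval,
            }
            for c, (fa, fb) in enumerate(zip(a.mfi, b.mfi)):
                row[f"mmfi_ch{c + 1}"] = 0.5 * (fa + fb)
            row["size_um2"] = 0.5 * (a.area + b.area)
            rows.append(row)
    columns = ["cell_id", "track_id", "frame", "speed_um_s"]
    if rows:
        n_ch = sum(1 for key in rows[0] if key.startswith("mmfi_ch"))
        columns += [f"mmfi_ch{c + 1}" for c in range(n_ch)] + ["size_um2"]
    else:
        columns += ["size_um2"]
    return pd.DataFrame(rows, columns=columns)


def compute_ratio(
    events: pd.DataFrame,
    numerator_channel: str = "mmfi_ch1",
    denominator_channel: str = "mmfi_ch2",
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Add a ``ratio`` column (numerator MMFI / denominator MMFI).

    Events whose denominator is ≤ ``epsilon`` get ``NaN`` and are thereby
    excluded from ratio analyses; the exclusion count is logged, never
    silently dropped.
    """
    for col in (numerator_channel, denominator_channel):
        if col not in events.columns:
            raise ValueError(f"channel column {col!r} missing from event table")
    out = events.copy()
    den = out[denominator_channel].to_numpy(dtype=float)
    valid = den > epsilon
    ratio = np.full(len(out), np.nan)
    ratio[valid] = out[numerator_channel].to_numpy(dtype=float)[valid] / den[valid]
    out["ratio"] = ratio
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info(
            "%d of %d events excluded from ratio analysis (denominator <= %g)",
            n_excluded,
            len(out),
            epsilon,
        )
    return out


def normalize_channel(events: pd.DataFrame, channel: str) -> pd.Series:
    """Channel values divided by the per-cell median of that channel.

    Robust, scale-free normalisation applied independently per cell, so cells
    with different expression levels become comparable.  Raises if any cell's
    median is non-positive (naming the cell).
    """
    if channel not in events.columns:
        raise ValueError(f"channel column {channel!r} missing from event table")
    values = events[channel].astype(float)
    if not np.isfinite(values).any():
        raise ValueError(f"no finite values in channel {channel!r}")
    medians = values.groupby(events["cell_id"]).transform("median")
    bad = events.loc[medians <= 0, "cell_id"].unique()
    if len(bad):
        raise ValueError(
            f"per-cell median of {channel!r} is non-positive for cell(s): {sorted(map(str, bad))}"
        )
    return values / medians
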