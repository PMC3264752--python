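"""Frame-to-frame trajectory linking by gated optimal assignment.

Detections in consecutive frames are matched one-to-one by minimising the
total squared centroid displacement over matched pairs, subject to a hard
gate: no matched pair may be farther apart than ``max_displacement``.  Among
gated matchings, larger cardinality always wins (an unmatched detection only
occurs when the gate forbids every remaining pairing), and equal-cost
matchings are tie-broken toward lexicographically smallest index pairs.
Matchings are chained into tracks with no gap closing and no merge/split
handling; tracks shorter than ``min_track_length`` frames (default 10) are
discarded with the count logged.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import ParticleObservation, Track

logger = logging.getLogger(__name__)

DEFAULT_MIN_TRACK_LENGTH = 10


def link_frame_pair(
    obs_t: list[ParticleObservation],
    obs_t1: list[ParticleObservation],
    max_displacement: float,
) -> list[tuple[int, int]]:
    """Optimal gated one-to-one matching between two frames' detections.

    Returns index pairs ``(i, j)`` meaning ``obs_t[i]`` continues as
    ``obs_t1[j]``, sorted by ``i``.  The matching minimises the summed squared
    displacement, is maximal in cardinality among gated matchings, and breaks
    exact cost ties toward lexicographically smallest pairs.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be positive")
    n, m = len(obs_t), len(obs_t1)
    if n == 0 or m == 0:
        return []
    p_t = np.array([[o.x, o.y] for o in obs_t])
    p_t1 = np.array([[o.x, o.y] for o in obs_t1])
    d2 = ((p_t[:, None, :] - p_t1[None, :, :]) ** 2).sum(axis=2)
    gate2 = max_displacement**2
    allowed = d2 <= gate2

    # Padded square formulation: real pair costs in the top-left block, one
    # private dummy per row/column at cost P.  P exceeds the largest possible
    # total pair cost, so each extra real match always lowers the optimum:
    # maximal cardinality dominates, cost decides among equal cardinalities.
    penalty = gate2 * (min(n, m) + 1) + 1.0
    big = (n + m) * (penalty + gate2) + 1.0
    # Infinitesimal lexicographic bias for exact cost ties.
    eps = gate2 * 1e-9 / (n * m + 1)
    idx_bias = eps * (np.arange(n)[:, None] * m + np.arange(m)[None, :])

    cost = np.full((n + m, n + m), big)
    cost[:n, :m] = np.where(allowed, d2 + idx_bias, big)
    cost[:n, m:] = np.where(np.eye(n, dtype=bool), penalty, big)
    cost[n:, :m] = np.where(np.eye(m, dtype=bool), penalty, big)
    cost[n:, m:] = 0.0

    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and allowed[r, c]
    ]
    pairs.sort()
    return pairs


def build_tracks(
    frames: list[list[ParticleObservation]],
    max_displacement: float,
    min_track_length: int = DEFAULT_MIN_TRACK_LENGTH,
    cell_id: str = "cell",
) -> list[Track]:
    """Chain pairwise matchings over a whole movie into tracks.

    An observation unmatched at frame t+1 starts a new track; an unmatched
    track end terminates.  Track ids are assigned in order of first
    appearance (frame, then centroid y, x).  Tracks shorter than
    ``min_track_length`` observations are discarded (count logged).
    """
    if len(frames) < 2:
        raise ValueError("tracking needs at least 2 frames of observations")

    finished: list[list[ParticleObservation]] = []
    # maps: observation index in the current frame -> growing observation list
    open_tracks: dict[int, list[ParticleObservation]] = {
        i: [obs] for i, obs in enumerate(frames[0])
    }
    for t in range(len(frames) - 1):
        pairs = link_frame_pair(frames[t], frames[t + 1], max_displacement)
        matched_t = {i for i, _ in pairs}
        matched_t1 = {j for _, j in pairs}
        next_open: dict[int, list[ParticleObservation]] = {}
        for i, j in pairs:
            seq = open_tracks[i]
            seq.append(frames[t + 1][j])
            next_open[j] = seq
        for i, seq in open_tracks.items():
            if i not in matched_t:
                finished.append(seq)
        for j, obs in enumerate(frames[t + 1]):
            if j not in matched_t1:
                next_open[j] = [obs]
        open_tracks = next_open
    finished.extend(open_tracks.values())

    kept = [seq for seq in finished if len(seq) >= min_track_length]
    n_discarded = len(finished) - len(kept)
    if n_discarded:
        logger.info(
            "discarded %d tracks shorter than %d frames (%d kept)",
            n_discarded,
            min_track_length,
            len(kept),
        )
    kept.sort(key=lambda seq: (seq[0].frame_index, seq[0].y, seq[0].x))
    return [Track(track_id=i, observations=seq, cell_id=cell_id) for i, seq in enumerate(kept)]


def track_census(tracks: list[Track]) -> dict:
    """Summary of a track set: counts, data points and length histogram."""
    lengths = [len(t) for t in tracks]
    return {
        "n_tracks": len(tracks),
        "n_frame_to_frame_points": int(sum(max(length - 1, 0) for length in lengths)),
        "length_histogram": dict(sorted(Counter(lengths).items())),
    }


def tracks_to_table(tracks: list[Track], frame_interval: float) -> pd.DataFrame:
    """One row per observation: the interchange format with the stats stage."""
    rows = []
    for track in tracks:
        for obs in track.observations:
            row = {
                "cell_id": track.cell_id,
                "track_id": track.track_id,
                "frame": obs.frame_index,
                "t_s": obs.frame_index * frame_interval,
                "x_um": obs.x,
                "y_um": obs.y,
                "area_um2": obs.area,
            }
            for c, value in enumerate(obs.mfi):
                row[f"mfi_ch{c + 1}"] = value
            rows.append(row)
    return pd.DataFrame(rows)


def table_to_tracks(table: pd.DataFrame) -> list[Track]:
    """Rebuild :class:`Track` objects from a track table (CSV round trip)."""
    mfi_cols = sorted(c for c in table.columns if c.startswith("mfi_ch"))
    tracks = []
    for (cell_id, track_id), group in table.groupby(["cell_id", "track_id"], sort=True):
        group = group.sort_values("frame")
        obs = [
            ParticleObservation(
                frame_index=int(r.frame),
                x=float(r.x_um),
                y=float(r.y_um),
                area=float(r.area_um2),
                mfi=tuple(float(getattr(r, c)) for c in mfi_cols),
            )
            for r in group.itertuples()
        ]
        tracks.append(Track(track_id=int(track_id), observations=obs, cell_id=str(cell_id)))
    return tracks
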