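"""End-to-end orchestration: movie → tracks → events → statistical report.

These functions are thin compositions of the stage modules; the CLI wraps
them, and they are equally usable from Python.  The event-table CSV is the
interchange point, so tracks produced by other software can enter at
:func:`analyze_events`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import detect, events as events_mod, stats, track as track_mod
from .core import MovieStack
from .io import _jsonify

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    intensity_threshold: float | None = None  # None -> Otsu on frame 0
    min_area: float = 0.02  # µm²
    max_area: float = 0.50  # µm²; admits pairs of touching organelles as one particle
    polarity: str = "dark"
    background_correction: bool = True


@dataclass
class TrackingParams:
    max_displacement: float = 1.2  # µm; gate ~1.5x the fastest per-frame step
    min_track_length: int = track_mod.DEFAULT_MIN_TRACK_LENGTH


@dataclass
class AnalysisParams:
    n_bins: int = 10
    variable: str = "mmfi_ch1"  # or mmfi_ch2, ratio, size_um2
    ratio_numerator: str = "mmfi_ch1"
    ratio_denominator: str = "mmfi_ch2"
    epsilon: float = 1e-9
    static_threshold: float = stats.DEFAULT_STATIC_THRESHOLD


def process_movie(
    stack: MovieStack,
    detection: DetectionParams | None = None,
    tracking: TrackingParams | None = None,
    cell_id: str = "cell",
):
    """Detect, track and extract movement events from one movie.

    Returns ``(tracks, events, census)``.
    """
    detection = detection or DetectionParams()
    tracking = tracking or TrackingParams()
    threshold = detection.intensity_threshold
    if threshold is None:
        threshold = detect.auto_threshold(stack)
        logger.info("auto (Otsu) intensity threshold: %.3f", threshold)
    frames = detect.detect_movie(
        stack,
        threshold,
        detection.min_area,
        detection.max_area,
        detection.polarity,
        detection.background_correction,
    )
    tracks = track_mod.build_tracks(
        frames, tracking.max_displacement, tracking.min_track_length, cell_id=cell_id
    )
    census = track_mod.track_census(tracks)
    logger.info(
        "cell %s: %d tracks, %d frame-to-frame data points",
        cell_id,
        census["n_tracks"],
        census["n_frame_to_frame_points"],
    )
    table = events_mod.compute_events(tracks, stack.frame_interval)
    return tracks, table, census


def analyze_events(
    event_table: pd.DataFrame,
    fixed_events: pd.DataFrame | None = None,
    params: AnalysisParams | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Run the full statistics battery over an event table (≥1 cells).

    Returns ``(report, per_cell_bin_summaries)``.  The report labels every
    quantity with its provenance: per-cell aggregates are mean±SEM of
    per-cell bin medians; hypothesis tests run on bins pooled across cells.
    """
    params = params or AnalysisParams()
    df = event_table.copy()
    if len(df) == 0:
        raise ValueError("empty event table")

    n_channels = sum(1 for c in df.columns if c.startswith("mmfi_ch"))
    if params.variable == "ratio":
        if n_channels < 2:
            raise ValueError("ratio analysis requires two fluorescence channels")
        df = events_mod.compute_ratio(
            df, params.ratio_numerator, params.ratio_denominator, params.epsilon
        )
        n_excluded = int(df["ratio"].isna().sum())
        df = df[df["ratio"].notna()]
    else:
        n_excluded = 0

    if fixed_events is not None:
        threshold = stats.calibrate_static_threshold(fixed_events)
    else:
        threshold = stats.StaticThreshold(value=params.static_threshold, source="default")

    binning = stats.bin_by_variable(df, params.variable, params.n_bins)
    summaries = stats.summarize_bins(binning, threshold)
    aggregate = stats.aggregate_cells(summaries)
    kw = stats.kruskal_wallis_dunn(stats.pooled_bins(binning))
    spearman = stats.spearman_with_ci(
        df[params.variable].to_numpy(dtype=float), df[stats.SPEED].to_numpy(dtype=float)
    )
    static = stats.classify_static(df, threshold)

    report = {
        "threshold": {
            "value_um_s": threshold.value,
            "source": threshold.source,
            "n_calibration_events": threshold.n_calibration_events,
        },
        "binning_variable": params.variable,
        "n_bins": params.n_bins,
        "n_cells": int(df["cell_id"].nunique()),
        "n_events": int(len(df)),
        "n_ratio_excluded": n_excluded,
        "percent_static_overall": {
            "value": 100.0 * float(static.mean()),
            "provenance": "pooled_events",
        },
        "speed_distribution": {
            **stats.distribution_summary(df),
            "provenance": "pooled_events",
        },
        "per_bin_aggregate": {
            "rows": aggregate.to_dict(orient="records"),
            "provenance": "mean_sem_of_per_cell_bin_medians",
        },
        "kruskal_wallis_dunn": {
            **kw.to_dict(),
            "provenance": "bins_pooled_across_cells_by_index",
        },
        "spearman_speed_vs_variable": {
            **spearman.to_dict(),
            "provenance": "pooled_events",
        },
    }
    if "size_um2" in df.columns and params.variable != "size_um2":
        report["spearman_size_vs_mmfi"] = {
            **stats.size_vs_mmfi(
                df, params.variable if params.variable.startswith("mmfi") else "mmfi_ch1"
            ).to_dict(),
            "provenance": "pooled_events",
        }
    if params.variable == "ratio":
        per_bin = {}
        for ch in (params.ratio_numerator, params.ratio_denominator):
            norm = events_mod.normalize_channel(binning.events, ch)
            grouped = norm.groupby(binning.events["bin"])
            per_bin[ch] = {
                "mean": [float(v) for v in grouped.mean()],
                "sd": [float(v) for v in grouped.std(ddof=1)],
            }
        report["normalized_channel_intensity_per_bin"] = {
            **per_bin,
            "normalization": "per-cell median",
            "provenance": "pooled_events",
        }
    return _jsonify(report), summaries
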