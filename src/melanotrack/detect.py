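"""Particle detection by intensity thresholding and size/area filtering.

Pigmented organelles absorb light, so they appear as dark objects on a bright
background in transmitted-light/phase-contrast frames.  Detection thresholds
the transmitted channel (polarity configurable), labels 8-connected
components, keeps those whose area falls inside a configured [min, max] band,
and measures each kept component's unweighted mask centroid plus its
background-corrected mean fluorescence (MFI) in every fluorescence channel.

Background is estimated per frame and channel as the median intensity outside
all thresholded foreground pixels; correction can be disabled for recordings
already selected for high organelle:cytosol signal ratio.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure

from .core import MovieStack, ParticleObservation

logger = logging.getLogger(__name__)


def foreground_mask(
    stack: MovieStack, frame_index: int, intensity_threshold: float, polarity: str = "dark"
) -> np.ndarray:
    """Boolean mask of candidate particle pixels in the transmitted channel."""
    if not (0 <= frame_index < stack.n_frames):
        raise ValueError(f"frame {frame_index} does not exist (movie has {stack.n_frames})")
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    frame = stack.pixels[frame_index, stack.transmitted_index]
    return frame < intensity_threshold if polarity == "dark" else frame > intensity_threshold


def estimate_background(
    stack: MovieStack,
    frame_index: int,
    channel: int,
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Median intensity of a fluorescence channel outside particle masks.

    With no mask (or a mask covering the whole frame, which logs a warning)
    the global frame median is returned.
    """
    if channel not in stack.fluorescence_indices:
        raise ValueError(f"channel {channel} is not a fluorescence channel")
    if not (0 <= frame_index < stack.n_frames):
        raise ValueError(f"frame {frame_index} does not exist (movie has {stack.n_frames})")
    frame = stack.pixels[frame_index, channel]
    if exclude_mask is None:
        return float(np.median(frame))
    outside = frame[~exclude_mask]
    if outside.size == 0:
        logger.warning(
            "frame %d entirely covered by particle masks; falling back to global median",
            frame_index,
        )
        return float(np.median(frame))
    return float(np.median(outside))


def detect_particles(
    stack: MovieStack,
    frame_index: int,
    intensity_threshold: float,
    min_area: float,
    max_area: float,
    polarity: str = "dark",
    background_correction: bool = True,
) -> list[ParticleObservation]:
    """Detect particles in one frame.

    Areas are in µm²; components outside ``[min_area, max_area]`` (inclusive)
    are rejected (clusters of touching organelles merge into one oversized
    component and are dropped rather than split).  Output is sorted by
    (y, x) centroid for determinism.
    """
    if min_area >= max_area:
        raise ValueError("min_area must be smaller than max_area")
    mask = foreground_mask(stack, frame_index, intensity_threshold, polarity)
    labelled = measure.label(mask, connectivity=2)
    props = measure.regionprops(labelled)

    fluo_indices = stack.fluorescence_indices
    backgrounds = {}
    if background_correction:
        for ch in fluo_indices:
            backgrounds[ch] = estimate_background(stack, frame_index, ch, exclude_mask=mask)

    px_area = stack.pixel_size**2
    observations: list[ParticleObservation] = []
    n_rejected = 0
    for prop in props:
        area_um2 = prop.area * px_area
        if not (min_area <= area_um2 <= max_area):
            n_rejected += 1
            continue
        row_c, col_c = prop.centroid  # unweighted mask centroid, px
        mfi = []
        rows, cols = prop.coords[:, 0], prop.coords[:, 1]
        for ch in fluo_indices:
            mean_val = float(stack.pixels[frame_index, ch][rows, cols].mean())
            mfi.append(mean_val - backgrounds.get(ch, 0.0))
        observations.append(
            ParticleObservation(
                frame_index=frame_index,
                x=col_c * stack.pixel_size,
                y=row_c * stack.pixel_size,
                area=area_um2,
                mfi=tuple(mfi),
            )
        )
    observations.sort(key=lambda o: (o.y, o.x))
    if not observations:
        logger.info("frame %d: zero detections", frame_index)
    if n_rejected:
        logger.info("frame %d: %d components rejected by area filter", frame_index, n_rejected)
    return observations


def detect_movie(
    stack: MovieStack,
    intensity_threshold: float,
    min_area: float,
    max_area: float,
    polarity: str = "dark",
    background_correction: bool = True,
) -> list[list[ParticleObservation]]:
    """Run :func:`detect_particles` on every frame."""
    return [
        detect_particles(
            stack, t, intensity_threshold, min_area, max_area, polarity, background_correction
        )
        for t in range(stack.n_frames)
    ]


def auto_threshold(stack: MovieStack, frame_index: int = 0) -> float:
    """Otsu threshold of the transmitted channel of one frame."""
    from skimage.filters import threshold_otsu

    frame = stack.pixels[frame_index, stack.transmitted_index]
    return float(threshold_otsu(frame))
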