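"""Core data containers shared across the pipeline.

The pipeline's stages hand each other three in-memory objects: a calibrated
multi-channel pixel stack (:class:`MovieStack`), per-frame particle detections
(:class:`ParticleObservation`) and frame-contiguous trajectories
(:class:`Track`).  Frame-to-frame movement events — the unit of all downstream
statistics — are kept as a plain :class:`pandas.DataFrame` (see
:mod:`melanotrack.events`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRANSMITTED = "transmitted"
FLUORESCENCE = "fluorescence"


@dataclass
class MovieStack:
    """A physically calibrated multi-channel time-lapse stack.

    Parameters
    ----------
    pixels
        Array of shape ``(n_frames, n_channels, rows, cols)``.
    pixel_size
        Lateral calibration in µm per pixel.
    frame_interval
        Time between consecutive frames in seconds.
    channel_roles
        One role per channel; exactly one ``"transmitted"`` entry and zero to
        two ``"fluorescence"`` entries.
    """

    pixels: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_roles: list[str] = field(default_factory=lambda: [TRANSMITTED])

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be (frames, channels, rows, cols); got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.channel_roles) != self.pixels.shape[1]:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for {self.pixels.shape[1]} channels"
            )
        n_trans = sum(r == TRANSMITTED for r in self.channel_roles)
        n_fluo = sum(r == FLUORESCENCE for r in self.channel_roles)
        if n_trans != 1:
            raise ValueError("channel_roles must contain exactly one 'transmitted' entry")
        if n_fluo > 2:
            raise ValueError("at most two fluorescence channels are supported")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def transmitted_index(self) -> int:
        return self.channel_roles.index(TRANSMITTED)

    @property
    def fluorescence_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == FLUORESCENCE]


@dataclass
class ParticleObservation:
    """One detected particle in one frame.

    Centroid coordinates are in µm with ``x`` along columns, ``y`` along rows
    and the origin at the centre of the top-left pixel.  ``mfi`` holds one
    background-corrected mean fluorescence value per fluorescence channel, in
    acquisition order; values may be ≤ 0 after background correction.
    """

    frame_index: int
    x: float
    y: float
    area: float  # µm²
    mfi: tuple[float, ...] = ()

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class Track:
    """An ordered, frame-contiguous sequence of observations of one particle."""

    track_id: int
    observations: list[ParticleObservation]
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        frames = [o.frame_index for o in self.observations]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError(f"track {self.track_id} has a frame gap: {frames}")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_links(self) -> int:
        """Number of frame-to-frame movement events this track yields."""
        return max(len(self.observations) - 1, 0)
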