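"""Core in-memory containers shared across the pipeline.

The pipeline moves data through four container types: a movie stack
(raw fluorescence, frames-first), labeled 2-D maps (regions of activity
or cells), trace tables (regions x frames at successive processing
stages) and a small metadata record describing the acquisition and the
pharmacology epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

TraceStage = Literal["raw", "filtered", "corrected", "dff"]
MapKind = Literal["ROA", "cell"]


@dataclass
class MovieStack:
    """Single-channel time-lapse recording.

    Parameters
    ----------
    frames : ndarray, shape (t, y, x)
        Fluorescence intensities in arbitrary units.
    frame_rate : float
        Acquisition rate in Hz. Time of frame ``i`` is ``i / frame_rate``
        seconds.
    spatial_resolution : float
        Pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    frame_rate: float
    spatial_resolution: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"movie must be (t, y, x); got shape {self.frames.shape}"
            )
        if min(self.frames.shape) < 1:
            raise ValueError("movie must have at least one frame and one pixel")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive (Hz)")
        if self.spatial_resolution <= 0:
            raise ValueError("spatial_resolution must be positive (um/pixel)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie intensities must be finite")
        if np.any(self.frames < 0):
            raise ValueError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def canvas(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times(self) -> np.ndarray:
        """Frame times in seconds, 0-based."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class LabeledMap:
    """2-D integer region map: 0 is background, regions are 1..region_count."""

    labels: np.ndarray
    region_count: int
    kind: MapKind = "ROA"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.min() < 0 or self.labels.max() > self.region_count:
            raise ValueError("labels must lie in {0..region_count}")
        present = np.unique(self.labels)
        expected = np.arange(1, self.region_count + 1)
        if not np.all(np.isin(expected, present)):
            raise ValueError("every label 1..region_count must occupy >= 1 pixel")

    @property
    def canvas(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_counts(self) -> np.ndarray:
        """Pixels per region, index 0 -> region 1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.region_count + 1)
        return counts[1:]


@dataclass
class TraceTable:
    """Regions x frames matrix of mean fluorescence at one processing stage."""

    values: np.ndarray
    stage: TraceStage
    frame_rate: float
    region_ids: Sequence[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace values must be regions x frames")
        if min(self.values.shape) < 1:
            raise ValueError("need at least one region and one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive (Hz)")
        if self.region_ids is None:
            self.region_ids = list(range(1, self.values.shape[0] + 1))
        self.region_ids = [int(r) for r in self.region_ids]
        if len(self.region_ids) != self.values.shape[0]:
            raise ValueError("region_ids length must match the region axis")
        if any(b <= a for a, b in zip(self.region_ids, self.region_ids[1:])):
            raise ValueError("region_ids must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def with_values(self, values: np.ndarray, stage: TraceStage) -> "TraceTable":
        """Same regions/rate, new values at a new stage."""
        return TraceTable(values, stage, self.frame_rate, list(self.region_ids))


@dataclass
class RunMetadata:
    """Acquisition and analysis parameters recorded alongside outputs."""

    frame_rate: float
    spatial_resolution: float
    drug_frame: Optional[int] = None
    signal_threshold: float = 3.0
    output_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive (Hz)")
        if self.spatial_resolution <= 0:
            raise ValueError("spatial_resolution must be positive (um/pixel)")
        if self.signal_threshold <= 0:
            raise ValueError("signal_threshold must be positive (multiples of SD)")

    def validate_drug_frame(self, frame_count: int) -> None:
        if self.drug_frame is not None and not (0 <= self.drug_frame < frame_count):
            raise ValueError(
                f"drug_frame {self.drug_frame} outside [0, {frame_count})"
            )
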