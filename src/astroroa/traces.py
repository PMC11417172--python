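"""Per-region mean-fluorescence time-series extraction.

Mirrors the ImageJ multi-measure semantics: for every frame, each
region's value is the arithmetic mean of the raw movie over the region's
full footprint — even where the instantaneous activity covers only part
of it.
"""

from __future__ import annotations

import numpy as np

from .containers import LabeledMap, MovieStack, TraceTable


def extract_traces(movie: MovieStack, region_map: LabeledMap) -> TraceTable:
    """Mean fluorescence of every labeled region in every frame.

    Regions appear in label order; time is the column axis.
    """
    if region_map.canvas != movie.canvas:
        raise ValueError(
            f"canvas mismatch: movie is {movie.canvas}, map is "
            f"{region_map.canvas}; restore the detection output to the full "
            "recording canvas before overlaying the map"
        )
    n = region_map.region_count
    labels = region_map.labels.ravel()
    counts = np.bincount(labels, minlength=n + 1)[1:].astype(float)
    flat = movie.frames.reshape(movie.n_frames, -1)
    sums = np.empty((n, movie.n_frames), dtype=float)
    for t in range(movie.n_frames):
        sums[:, t] = np.bincount(labels, weights=flat[t], minlength=n + 1)[1:]
    values = sums / counts[:, None]
    return TraceTable(values, stage="raw", frame_rate=movie.frame_rate)


def region_areas(region_map: LabeledMap, spatial_resolution: float) -> np.ndarray:
    """Region areas in um^2 (pixel count x pixel size squared)."""
    if spatial_resolution <= 0:
        raise ValueError("spatial_resolution must be positive")
    return region_map.pixel_counts() * spatial_resolution**2
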