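"""Frame-by-frame detection of supra-threshold active pixel patches.

This is the activity-detection front end of the pipeline: per pixel, a
temporal baseline and noise estimate are computed over the whole
recording; each frame is spatially smoothed and thresholded at
``baseline + intensity_scaling * SD``; supra-threshold pixels are grouped
into 8-connected per-frame patches, small patches are discarded, and the
surviving patches can be filtered by physical area before the region-of-
activity map is projected from them.

Patches are strictly per-frame 2-D components: no spatio-temporal linking
or propagation model is applied, in keeping with the micro-domain view of
astrocyte calcium activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
from scipy import ndimage

from .containers import MovieStack
from .io import STRUCTURE_8

#: 1.4826 scales the median absolute deviation to the SD of a Gaussian.
MAD_TO_SD = 1.4826


@dataclass
class DetectionParams:
    """User-facing active-pixel detection parameters.

    intensity_scaling
        Detection threshold in multiples of the per-pixel noise SD
        (default 2.5).
    smoothing_sigma
        Gaussian spatial smoothing sigma in pixels applied to each frame
        before thresholding (default 0.5).
    min_size
        Minimum patch size in pixels; smaller 8-connected components are
        discarded (default 10).
    border_exclude
        Pixels within this distance of any canvas edge are never active
        (default 0; use 2-5 after motion correction to suppress edge
        artifacts).
    area_min, area_max
        Physical patch-area window in um^2 applied by
        :func:`filter_patches`; ``area_min`` defaults to ``min_size``
        converted at the recording's pixel size, ``area_max`` to 40 um^2.
    sd_method
        'mad' (robust, default) or 'std' for the per-pixel noise estimate.
    """

    intensity_scaling: float = 2.5
    smoothing_sigma: float = 0.5
    min_size: int = 10
    border_exclude: int = 0
    area_min: Optional[float] = None
    area_max: float = 40.0
    sd_method: Literal["mad", "std"] = "mad"

    def __post_init__(self) -> None:
        if self.intensity_scaling <= 0:
            raise ValueError("intensity_scaling must be positive")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1 pixel")
        if self.border_exclude < 0:
            raise ValueError("border_exclude must be >= 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")

    def resolved_area_min(self, spatial_resolution: float) -> float:
        if self.area_min is not None:
            return self.area_min
        return self.min_size * spatial_resolution**2


@dataclass
class ActivePatch:
    """One 8-connected set of active pixels in a single frame."""

    frame: int
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)
    area_um2: float = 0.0

    @property
    def n_pixels(self) -> int:
        return len(self.rows)

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def pixel_noise_stats(
    movie: MovieStack, sd_method: str = "mad"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel temporal baseline (median) and noise SD.

    The robust default estimates SD as ``1.4826 x MAD`` over time so that
    sparse transients do not inflate the noise floor.  Statistics are
    computed on the unsmoothed series.
    """
    baseline = np.median(movie.frames, axis=0)
    if sd_method == "mad":
        sd = MAD_TO_SD * np.median(np.abs(movie.frames - baseline), axis=0)
    elif sd_method == "std":
        sd = movie.frames.std(axis=0, ddof=1) if movie.n_frames > 1 else np.zeros_like(baseline)
    else:
        raise ValueError("sd_method must be 'mad' or 'std'")
    return baseline.astype(float), sd.astype(float)


def active_pixel_mask(movie: MovieStack, params: DetectionParams) -> np.ndarray:
    """Boolean (t, y, x) mask of supra-threshold pixels (before size filter)."""
    baseline, sd = pixel_noise_stats(movie, params.sd_method)
    if not np.any(sd > 0):
        raise ValueError(
            "no temporal variance: every pixel is constant over time; "
            "cannot estimate a noise threshold"
        )
    threshold = baseline + params.intensity_scaling * sd
    active = np.empty(movie.frames.shape, dtype=bool)
    for t in range(movie.n_frames):
        frame = movie.frames[t].astype(float)
        if params.smoothing_sigma > 0:
            frame = ndimage.gaussian_filter(
                frame, params.smoothing_sigma, mode="reflect"
            )
        active[t] = frame > threshold
    b = params.border_exclude
    if b > 0:
        ny, nx = movie.canvas
        if b >= min(ny, nx) / 2:
            raise ValueError("border_exclude leaves no interior canvas")
        active[:, :b, :] = False
        active[:, ny - b:, :] = False
        active[:, :, :b] = False
        active[:, :, nx - b:] = False
    return active


def detect_active_patches(
    movie: MovieStack, params: DetectionParams | None = None
) -> list[ActivePatch]:
    """Detect per-frame active pixel patches of at least ``min_size`` pixels."""
    params = params or DetectionParams()
    active = active_pixel_mask(movie, params)
    px_area = movie.spatial_resolution**2
    patches: list[ActivePatch] = []
    for t in range(movie.n_frames):
        labels, n = ndimage.label(active[t], structure=STRUCTURE_8)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        # ndimage.label numbers components in raster order of first pixel
        for lab in range(1, n + 1):
            if counts[lab] < params.min_size:
                continue
            rows, cols = np.nonzero(labels == lab)
            patches.append(
                ActivePatch(
                    frame=t,
                    rows=rows,
                    cols=cols,
                    area_um2=float(counts[lab] * px_area),
                )
            )
    return patches


def filter_patches(
    patches: Iterable[ActivePatch], area_min: float, area_max: float
) -> list[ActivePatch]:
    """Keep patches whose physical area lies in [area_min, area_max] um^2."""
    if area_min < 0 or area_max <= 0:
        raise ValueError("area bounds must be positive")
    return [p for p in patches if area_min <= p.area_um2 <= area_max]


def activity_stack(
    patches: Iterable[ActivePatch],
    n_frames: int,
    canvas: tuple[int, int],
    border_exclude: int = 0,
) -> np.ndarray:
    """Binary uint8 (t, y, x) stack of patch pixels.

    With ``border_exclude > 0`` the stack is cropped to the interior
    canvas (the convention of detectors that drop an edge margin: a
    512x512 recording with a 2-pixel margin yields a 508x508 stack);
    :func:`restore_canvas` re-centers it on the full canvas.
    """
    ny, nx = canvas
    stack = np.zeros((n_frames, ny, nx), dtype=np.uint8)
    for p in patches:
        stack[p.frame, p.rows, p.cols] = 255
    b = border_exclude
    if b > 0:
        stack = stack[:, b:ny - b, b:nx - b]
    return stack


def restore_canvas(cropped: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Center a cropped 2-D image or 3-D stack on a zero canvas.

    When the size difference is odd, the extra row/column of margin goes
    to the trailing side (e.g. 507 -> 512 pads 2 leading, 3 trailing).
    """
    cropped = np.asarray(cropped)
    if cropped.ndim not in (2, 3):
        raise ValueError("expected a 2-D image or (t, y, x) stack")
    ty, tx = target_shape
    cy, cx = cropped.shape[-2:]
    if cy > ty or cx > tx:
        raise ValueError(
            f"cropped shape ({cy}, {cx}) exceeds target ({ty}, {tx})"
        )
    lead_y, lead_x = (ty - cy) // 2, (tx - cx) // 2
    pad = [(lead_y, ty - cy - lead_y), (lead_x, tx - cx - lead_x)]
    if cropped.ndim == 3:
        pad = [(0, 0)] + pad
    return np.pad(cropped, pad)
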