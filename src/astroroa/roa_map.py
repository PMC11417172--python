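"""Region-of-activity (ROA) map construction.

A ROA is the aggregate spatial footprint of all active pixel patches
t-projected over the recording: the union of the (already area-filtered)
patch pixels, with interior holes filled, split into 8-connected
components.  Two patches that never coexist in time but touch spatially
(even diagonally) therefore belong to the same ROA, while any two
distinct ROAs are spatially disconnected and treated as independent
analysis units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .active_pixels import ActivePatch
from .containers import LabeledMap
from .io import label_components


@dataclass
class ROAMap:
    """Labeled ROA map plus per-ROA sizes."""

    labeled: LabeledMap
    pixel_counts: np.ndarray  # per ROA, index 0 -> ROA 1
    sizes_um2: np.ndarray
    spatial_resolution: float

    @property
    def region_count(self) -> int:
        return self.labeled.region_count


def build_roa_map(
    patches: Sequence[ActivePatch],
    canvas: tuple[int, int],
    spatial_resolution: float,
    frame_range: Optional[tuple[int, int]] = None,
) -> ROAMap:
    """T-project patches into a labeled ROA map.

    ``frame_range`` (start, stop), when given, restricts the projection to
    patches whose frame lies in ``[start, stop)`` — useful to build the
    map from a stable sub-epoch of a long recording.  ROAs of any size
    are kept; size selection belongs to the patch area filter upstream.
    """
    if frame_range is not None:
        lo, hi = frame_range
        patches = [p for p in patches if lo <= p.frame < hi]
    if len(patches) == 0:
        raise ValueError(
            "no activity detected: no active pixel patches to project; "
            "check detection parameters (intensity_scaling, min_size, "
            "area filter) or the selected frame_range"
        )
    binary = np.zeros(canvas, dtype=bool)
    for p in patches:
        binary[p.rows, p.cols] = True
    # replicate the "include holes" behavior: fill background components
    # not connected to the canvas border
    binary = ndimage.binary_fill_holes(binary)
    labels, n = label_components(binary)
    labeled = LabeledMap(labels, region_count=n, kind="ROA")
    counts = labeled.pixel_counts()
    return ROAMap(
        labeled=labeled,
        pixel_counts=counts,
        sizes_um2=counts * spatial_resolution**2,
        spatial_resolution=spatial_resolution,
    )


def roa_mask(roa: ROAMap) -> np.ndarray:
    """Binary mask (uint8, foreground 255) of the union of all ROAs."""
    if roa.region_count == 0:
        raise ValueError("empty ROA map")
    return np.where(roa.labeled.labels > 0, 255, 0).astype(np.uint8)
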