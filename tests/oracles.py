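"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (python loops, BFS flood fill,
linear scans) and shares no code with the package under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_label(foreground: np.ndarray) -> tuple[np.ndarray, int]:
    """8-connected component labeling by BFS, raster order of first pixel."""
    fg = np.asarray(foreground).astype(bool)
    labels = np.zeros(fg.shape, dtype=int)
    current = 0
    ny, nx = fg.shape
    for y in range(ny):
        for x in range(nx):
            if fg[y, x] and labels[y, x] == 0:
                current += 1
                queue = deque([(y, x)])
                labels[y, x] = current
                while queue:
                    cy, cx = queue.popleft()
                    for dy, dx in NEIGHBORS_8:
                        py, px = cy + dy, cx + dx
                        if 0 <= py < ny and 0 <= px < nx and fg[py, px] and labels[py, px] == 0:
                            labels[py, px] = current
                            queue.append((py, px))
    return labels, current


def is_8_connected(pixels: set[tuple[int, int]]) -> bool:
    """True iff the pixel set forms one 8-connected component."""
    if not pixels:
        return False
    start = next(iter(pixels))
    seen = {start}
    queue = deque([start])
    while queue:
        cy, cx = queue.popleft()
        for dy, dx in NEIGHBORS_8:
            p = (cy + dy, cx + dx)
            if p in pixels and p not in seen:
                seen.add(p)
                queue.append(p)
    return seen == pixels


def scan_signals(dff, threshold: float):
    """Linear-scan oracle for signal bounds on one dF/F0 trace.

    Walks the trace sample by sample, tracking the most recent
    at-or-below-zero sample; whenever a supra-threshold sample is seen,
    the enclosing excursion is delimited by that sample and the next
    at-or-below-zero sample.  Returns (complete, truncated) lists of
    (start, peak, end) with None for a missing bound.
    """
    dff = list(map(float, dff))
    n = len(dff)
    complete, truncated = [], []
    i = 0
    last_below = None
    while i < n:
        if dff[i] <= 0.0:
            last_below = i
            i += 1
            continue
        if dff[i] > threshold:
            start = last_below
            j = i
            while j + 1 < n and dff[j + 1] > 0.0:
                j += 1
            end = j + 1 if j + 1 < n else None
            lo = 0 if start is None else start
            hi = n - 1 if end is None else end
            peak = lo
            for k in range(lo, hi + 1):
                if dff[k] > dff[peak]:
                    peak = k
            rec = (start, peak, end)
            if start is not None and end is not None:
                complete.append(rec)
            else:
                truncated.append(rec)
            i = hi if end is not None else n
            last_below = end
        else:
            i += 1
    return complete, truncated


def trace_mean_loop(frames: np.ndarray, labels: np.ndarray, region: int) -> np.ndarray:
    """Per-frame mean of one region via an explicit per-pixel loop."""
    coords = [
        (y, x)
        for y in range(labels.shape[0])
        for x in range(labels.shape[1])
        if labels[y, x] == region
    ]
    out = np.empty(frames.shape[0])
    for t in range(frames.shape[0]):
        total = 0.0
        for y, x in coords:
            total += frames[t, y, x]
        out[t] = total / len(coords)
    return out
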