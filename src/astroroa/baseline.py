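"""Trace preprocessing, iterative baseline (F0) estimation and signal detection.

The baseline of each fluorescence trace is found by iterating a
three-step process: (1) compute an interim F0 as the mean of the
currently signal-free samples, (2) identify segments exceeding
``F0 + k x SD``, each extended outward to the nearest F0 crossings,
(3) remove those segments and recompute.  The first iteration uses the
whole trace; the loop stops at the allowed iteration count or when the
relative change in F0 falls below 1e-6.  The converged F0 is then used
to express the trace as dF/F0 and to delimit signals: a signal is a
maximal excursion bounded by the nearest F0-crossing samples flanking
one or more threshold crossings.  Excursions missing an initiation or
termination crossing (they run into a recording edge) are *truncated*
and excluded unless explicitly included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .containers import TraceTable

logger = logging.getLogger(__name__)

#: Relative |dF0|/F0 below which the iteration is considered converged.
CONVERGENCE_RTOL = 1e-6

#: Relative floor applied to a zero noise SD so thresholds stay positive.
SD_FLOOR_REL = 1e-12


@dataclass
class FilterParams:
    """Zero-phase Butterworth low-pass settings (order 4, cutoff 0.4 Hz)."""

    order: int = 4
    cutoff: float = 0.4

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive (Hz)")


@dataclass
class Signal:
    """One detected signal on a single trace (frame indices, 0-based).

    ``start``/``end`` are the F0-crossing samples bounding the excursion;
    for truncated signals the missing bound is clamped to the recording
    edge and the corresponding ``has_*`` flag is False.
    """

    start: int
    peak: int
    end: int
    has_start: bool = True
    has_end: bool = True

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_end


@dataclass
class BaselineResult:
    """Converged baseline and detected signals for every trace."""

    F0: np.ndarray                  # per trace, raw fluorescence units
    noise_SD: np.ndarray            # per trace, raw units (signal-free samples)
    threshold_k: float              # user threshold, multiples of SD
    thresholds_dff: np.ndarray      # per trace, k*SD/F0 in dF/F0 units
    n_iterations: int               # allowed iteration count
    converged_at: np.ndarray        # per trace first iteration meeting rtol (0 = not reached)
    f0_history: list[np.ndarray]    # per trace, F0 value at each executed iteration
    dff: TraceTable
    signals: list[list[Signal]]     # per trace, complete signals in time order
    truncated: list[list[Signal]]   # per trace, truncated signals in time order
    include_incomplete: bool = False

    def signals_for_analysis(self) -> list[list[Signal]]:
        """Complete signals, plus truncated ones when they were included."""
        if not self.include_incomplete:
            return self.signals
        merged = []
        for comp, trunc in zip(self.signals, self.truncated):
            merged.append(sorted(comp + trunc, key=lambda s: (s.start, s.peak)))
        return merged


def lowpass_filter(traces: TraceTable, params: FilterParams | None = None) -> TraceTable:
    """Zero-phase (forward-backward) Butterworth low-pass, per trace.

    DC gain is exactly 1, so flat traces pass unchanged.  If the cutoff is
    at or above the Nyquist frequency the traces are returned unchanged
    with a warning.
    """
    params = params or FilterParams()
    nyquist = traces.frame_rate / 2.0
    if params.cutoff >= nyquist:
        warnings.warn(
            f"cutoff {params.cutoff} Hz >= Nyquist {nyquist} Hz; "
            "traces passed through unfiltered",
            stacklevel=2,
        )
        return traces.with_values(traces.values.copy(), "filtered")
    sos = sps.butter(params.order, params.cutoff, fs=traces.frame_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, traces.values, axis=1)
    return traces.with_values(filtered, "filtered")


def correct_shift(
    traces: TraceTable, correction_factor: float = 0.5
) -> tuple[TraceTable, np.ndarray]:
    """Partially remove a linear trend from every trace.

    Fits an ordinary least-squares slope against the frame index and
    subtracts ``correction_factor`` (0..1) of the centered trend, leaving
    each trace's mean untouched.  The returned slopes (units/frame) are
    the drift diagnostic: a slope distribution not centered on zero flags
    photobleaching or focal drift.
    """
    if not 0 <= correction_factor <= 1:
        raise ValueError("correction_factor must be in [0, 1]")
    n = traces.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames to fit a trend")
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    slopes = traces.values @ tc / (tc @ tc)
    corrected = traces.values - correction_factor * np.outer(slopes, tc)
    return traces.with_values(corrected, "corrected"), slopes


def _crossing_bounds(
    trace: np.ndarray, level: float, run_start: int, run_stop: int
) -> tuple[Optional[int], Optional[int]]:
    """Nearest at-or-below-``level`` samples flanking ``[run_start, run_stop]``."""
    start: Optional[int] = None
    for i in range(run_start - 1, -1, -1):
        if trace[i] <= level:
            start = i
            break
    end: Optional[int] = None
    n = len(trace)
    for i in range(run_stop + 1, n):
        if trace[i] <= level:
            end = i
            break
    return start, end


def _supra_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def detect_signals(
    dff: np.ndarray, threshold: float, baseline_level: float = 0.0
) -> tuple[list[Signal], list[Signal]]:
    """Delimit signals on one dF/F0 trace.

    A signal spans from the last baseline crossing before its first
    threshold crossing to the first baseline crossing after its last
    threshold crossing; its peak is the argmax of dF/F0 within the span
    (earliest frame on ties).  Threshold excursions separated by a dip
    that never reaches baseline share their crossings and merge into one
    signal.  Returns (complete, truncated) signal lists in time order.
    """
    dff = np.asarray(dff, dtype=float)
    n = len(dff)
    complete: list[Signal] = []
    truncated: list[Signal] = []
    seen: set[tuple[Optional[int], Optional[int]]] = set()
    for run_start, run_stop in _supra_runs(dff > threshold):
        start, end = _crossing_bounds(dff, baseline_level, run_start, run_stop)
        key = (start, end)
        if key in seen:
            continue  # same excursion as a previous run (no crossing between)
        seen.add(key)
        lo = 0 if start is None else start
        hi = n - 1 if end is None else end
        peak = lo + int(np.argmax(dff[lo:hi + 1]))
        sig = Signal(
            start=lo,
            peak=peak,
            end=hi,
            has_start=start is not None,
            has_end=end is not None,
        )
        (complete if sig.complete else truncated).append(sig)
    return complete, truncated


def _signal_sample_mask(trace: np.ndarray, f0: float, sd: float, k: float) -> np.ndarray:
    """Samples belonging to supra-threshold segments, extended to F0 crossings.

    Only samples strictly inside the crossing bounds are marked (the
    crossing samples themselves sit at or below F0 and stay in the
    baseline pool), so removal can never raise the interim F0.
    """
    mask = np.zeros(len(trace), dtype=bool)
    thr = f0 + k * sd
    for run_start, run_stop in _supra_runs(trace > thr):
        start, end = _crossing_bounds(trace, f0, run_start, run_stop)
        lo = 0 if start is None else start + 1
        hi = len(trace) if end is None else end
        mask[lo:hi] = True
    return mask


def iterative_baseline(
    traces: TraceTable,
    threshold_k: float = 3.0,
    n_iterations: int = 5,
    baseline_start: int = 0,
    baseline_end: int = -1,
    include_incomplete: bool = False,
) -> BaselineResult:
    """Iteratively determine F0, convert to dF/F0 and detect signals.

    Parameters
    ----------
    traces : TraceTable
        Raw, filtered or drift-corrected fluorescence traces.
    threshold_k : float
        Signal detection threshold in multiples of the baseline noise SD
        above F0; 2-3 SD is the usual working range.
    n_iterations : int
        Maximum number of baseline iterations (convergence is typically
        reached well within 5).
    baseline_start, baseline_end : int
        Frame window over which F0 and SD are computed; ``baseline_end``
        of -1 means the end of the trace.  Signal segments are still
        identified on the whole trace.
    include_incomplete : bool
        When True, truncated signals (missing an initiation or
        termination F0 crossing) are carried along for partial feature
        extraction instead of being dropped.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    n_frames = traces.n_frames
    stop = n_frames if baseline_end == -1 else baseline_end
    if not (0 <= baseline_start < stop <= n_frames):
        raise ValueError(
            f"baseline window [{baseline_start}, {stop}) outside trace of "
            f"{n_frames} frames"
        )
    window = slice(baseline_start, stop)

    n_traces = traces.n_regions
    F0 = np.empty(n_traces)
    SD = np.empty(n_traces)
    converged_at = np.zeros(n_traces, dtype=int)
    histories: list[np.ndarray] = []
    dff_values = np.empty_like(traces.values)
    all_signals: list[list[Signal]] = []
    all_truncated: list[list[Signal]] = []

    for r in range(n_traces):
        trace = traces.values[r]
        signal_mask = np.zeros(n_frames, dtype=bool)
        f0_prev = np.nan
        f0 = trace[window].mean()
        sd = trace[window].std(ddof=1) if stop - baseline_start > 1 else 0.0
        history = []
        for it in range(1, n_iterations + 1):
            free = ~signal_mask[window]
            win = trace[window][free]
            if win.size == 0:
                # every window sample classified as signal; keep previous F0
                logger.warning(
                    "trace %s: baseline window fully occupied by signal; "
                    "keeping previous F0", traces.region_ids[r],
                )
                break
            f0 = win.mean()
            sd = win.std(ddof=1) if win.size > 1 else 0.0
            history.append(f0)
            if it > 1 and abs(f0 - f0_prev) < CONVERGENCE_RTOL * abs(f0_prev):
                converged_at[r] = it
                break
            f0_prev = f0
            signal_mask = _signal_sample_mask(trace, f0, sd, threshold_k)
        histories.append(np.asarray(history))
        if f0 <= 0:
            raise ValueError(
                f"trace {traces.region_ids[r]}: non-positive baseline F0 "
                f"({f0:.3g}); dF/F0 is undefined"
            )
        if sd <= 0:
            warnings.warn(
                f"trace {traces.region_ids[r]} has no baseline variance; "
                "noise SD floored, no signals detectable at any threshold",
                stacklevel=2,
            )
        sd = max(sd, SD_FLOOR_REL * abs(f0))
        F0[r] = f0
        SD[r] = sd
        dff_values[r] = (trace - f0) / f0
        tau = threshold_k * sd / f0
        comp, trunc = detect_signals(dff_values[r], tau)
        all_signals.append(comp)
        all_truncated.append(trunc)

    dff = traces.with_values(dff_values, "dff")
    return BaselineResult(
        F0=F0,
        noise_SD=SD,
        threshold_k=threshold_k,
        thresholds_dff=threshold_k * SD / F0,
        n_iterations=n_iterations,
        converged_at=converged_at,
        f0_history=histories,
        dff=dff,
        signals=all_signals,
        truncated=all_truncated,
        include_incomplete=include_incomplete,
    )
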