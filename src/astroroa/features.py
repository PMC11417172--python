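"""Per-signal feature extraction and ROA/cell-level summaries.

Each detected signal gets one feature row (onset/peak/termination frames
and times, Simpson AUC, amplitude, SNR, 10-90% rise and 90-10% decay
times, half-width, duration, inter-event interval, pharmacology epoch).
Signals are then aggregated per region of activity and per cell, and
each ROA is classified by its activity relative to the drug application
frame: active in both epochs ("stable"), only after ("on"), only before
("off"), or never ("inactive").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .baseline import BaselineResult, Signal
from .containers import LabeledMap, TraceTable
from .roa_map import ROAMap

logger = logging.getLogger(__name__)

#: Per-signal feature columns, in output order.
FEATURE_COLUMNS = [
    "ROA_ID",
    "signal_start_frame",
    "signal_start_time",
    "signal_end_frame",
    "signal_end_time",
    "peak_frame",
    "peak_time",
    "AUC",
    "amplitude",
    "signal_to_noise",
    "rise_time",
    "decay_time",
    "half_width",
    "duration",
    "inter_event_interval",
    "epoch",
]

#: Feature columns averaged in the per-ROA and per-cell summaries.
MEAN_FEATURES = [
    "amplitude",
    "AUC",
    "signal_to_noise",
    "rise_time",
    "decay_time",
    "half_width",
    "duration",
    "inter_event_interval",
]

ROA_TYPES = ("stable", "on", "off", "inactive")


@dataclass
class EpochSpec:
    """Baseline/drug epoch split of a recording.

    The baseline epoch is frames ``[0, drug_frame)`` and the drug epoch
    ``[drug_frame, frame_count)``; without a drug frame the whole
    recording is one unnamed epoch.
    """

    frame_count: int
    frame_rate: float
    drug_frame: Optional[int] = None

    def __post_init__(self) -> None:
        if self.drug_frame is not None and not (0 <= self.drug_frame < self.frame_count):
            raise ValueError(
                f"drug_frame {self.drug_frame} outside [0, {self.frame_count})"
            )

    def epochs(self) -> list[tuple[object, int, int]]:
        if self.drug_frame is None:
            return [(pd.NA, 0, self.frame_count)]
        return [
            ("baseline", 0, self.drug_frame),
            ("drug", self.drug_frame, self.frame_count),
        ]

    def epoch_of(self, peak_frame: int) -> object:
        """Epoch label for a signal peaking at ``peak_frame``.

        A peak strictly before the drug frame is "baseline"; a peak at the
        drug frame already belongs to the drug epoch.
        """
        if self.drug_frame is None:
            return pd.NA
        return "baseline" if peak_frame < self.drug_frame else "drug"

    def duration_min(self, epoch: object) -> float:
        for name, start, stop in self.epochs():
            if epoch is name or epoch == name:
                return (stop - start) / self.frame_rate / 60.0
        raise ValueError(f"unknown epoch {epoch!r}")


def composite_simpson(y: np.ndarray, dx: float) -> float:
    """Composite Simpson quadrature with a trapezoid tail on odd intervals.

    For an even number of intervals this is plain composite Simpson; for
    an odd number, Simpson is applied to the leading even block and the
    final interval is closed with a trapezoid.
    """
    y = np.asarray(y, dtype=float)
    m = len(y) - 1  # number of intervals
    if m < 1:
        return 0.0
    if m == 1:
        return float(dx * (y[0] + y[1]) / 2.0)
    if m % 2 == 1:
        head = composite_simpson(y[:-1], dx)
        return float(head + dx * (y[-2] + y[-1]) / 2.0)
    s = y[0] + y[-1] + 4.0 * y[1:-1:2].sum() + 2.0 * y[2:-1:2].sum()
    return float(dx / 3.0 * s)


def _cross_before(
    y: np.ndarray, peak: int, lo: int, level: float, dt: float
) -> float:
    """Time of the level crossing nearest the peak on the rise limb.

    Scans backward from the peak for the first sample strictly below
    ``level`` and linearly interpolates the crossing between that sample
    and its successor.  NaN if the limb never drops below the level
    within ``[lo, peak]`` (truncated rise).
    """
    for i in range(peak, lo - 1, -1):
        if y[i] < level:
            if i == peak:
                return float("nan")
            frac = (level - y[i]) / (y[i + 1] - y[i])
            return (i + frac) * dt
    return float("nan")


def _cross_after(
    y: np.ndarray, peak: int, hi: int, level: float, dt: float
) -> float:
    """Time of the level crossing nearest the peak on the decay limb."""
    for i in range(peak, hi + 1):
        if y[i] < level:
            if i == peak:
                return float("nan")
            frac = (y[i - 1] - level) / (y[i - 1] - y[i])
            return (i - 1 + frac) * dt
    return float("nan")


def _signal_free_max(dff: np.ndarray, spans: Sequence[Signal]) -> float:
    """Peak dF/F0 of the baseline (signal-free) portion of one trace."""
    mask = np.ones(len(dff), dtype=bool)
    for s in spans:
        mask[s.start:s.end + 1] = False
    free = dff[mask]
    if free.size == 0:
        return float("nan")
    return float(free.max())


def analyze_signal(
    dff: TraceTable,
    signals: Sequence[Sequence[Signal]],
    truncated: Optional[Sequence[Sequence[Signal]]] = None,
    drug_frame: Optional[int] = None,
    include_incomplete: bool = False,
) -> pd.DataFrame:
    """Extract one feature row per detected signal.

    ``signals``/``truncated`` are per-trace signal lists as produced by
    the baseline stage; truncated signals contribute rows (with only the
    features their partial bounds support: amplitude, peak and, when the
    rise limb is intact, rise time) only when ``include_incomplete``.
    They are always excluded from the signal-free noise estimate.

    The signal-to-noise ratio is the signal's peak amplitude divided by
    the peak dF/F0 amplitude of the trace's signal-free samples.
    """
    truncated = truncated if truncated is not None else [[] for _ in signals]
    epochs = EpochSpec(dff.n_frames, dff.frame_rate, drug_frame)
    dt = 1.0 / dff.frame_rate
    rows: list[dict] = []
    for r, roa_id in enumerate(dff.region_ids):
        y = dff.values[r]
        comp = list(signals[r])
        trunc = list(truncated[r])
        noise_peak = _signal_free_max(y, comp + trunc)
        prev_end_time: Optional[float] = None
        for s in sorted(comp, key=lambda s: s.start):
            amp = float(y[s.peak])
            t10 = _cross_before(y, s.peak, s.start, 0.1 * amp, dt)
            t90 = _cross_before(y, s.peak, s.start, 0.9 * amp, dt)
            d90 = _cross_after(y, s.peak, s.end, 0.9 * amp, dt)
            d10 = _cross_after(y, s.peak, s.end, 0.1 * amp, dt)
            h_up = _cross_before(y, s.peak, s.start, 0.5 * amp, dt)
            h_down = _cross_after(y, s.peak, s.end, 0.5 * amp, dt)
            start_time = s.start * dt
            end_time = s.end * dt
            if noise_peak > 0:
                snr = amp / noise_peak
            else:
                snr = float("inf")
            rows.append(
                {
                    "ROA_ID": roa_id,
                    "signal_start_frame": s.start,
                    "signal_start_time": start_time,
                    "signal_end_frame": s.end,
                    "signal_end_time": end_time,
                    "peak_frame": s.peak,
                    "peak_time": s.peak * dt,
                    "AUC": composite_simpson(y[s.start:s.end + 1], dt),
                    "amplitude": amp,
                    "signal_to_noise": snr,
                    "rise_time": t90 - t10,
                    "decay_time": d10 - d90,
                    "half_width": h_down - h_up,
                    "duration": end_time - start_time,
                    "inter_event_interval": (
                        np.nan if prev_end_time is None else start_time - prev_end_time
                    ),
                    "epoch": epochs.epoch_of(s.peak),
                }
            )
            prev_end_time = end_time
        if include_incomplete:
            for s in sorted(trunc, key=lambda s: s.start):
                amp = float(y[s.peak])
                rise = np.nan
                if s.has_start:
                    t10 = _cross_before(y, s.peak, s.start, 0.1 * amp, dt)
                    t90 = _cross_before(y, s.peak, s.start, 0.9 * amp, dt)
                    rise = t90 - t10
                rows.append(
                    {
                        "ROA_ID": roa_id,
                        "signal_start_frame": np.nan,
                        "signal_start_time": np.nan,
                        "signal_end_frame": np.nan,
                        "signal_end_time": np.nan,
                        "peak_frame": s.peak,
                        "peak_time": s.peak * dt,
                        "AUC": np.nan,
                        "amplitude": amp,
                        "signal_to_noise": np.nan,
                        "rise_time": rise,
                        "decay_time": np.nan,
                        "half_width": np.nan,
                        "duration": np.nan,
                        "inter_event_interval": np.nan,
                        "epoch": epochs.epoch_of(s.peak),
                    }
                )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return df


def analyze_result(
    result: BaselineResult, drug_frame: Optional[int] = None
) -> pd.DataFrame:
    """Feature table straight from a :class:`BaselineResult`."""
    return analyze_signal(
        result.dff,
        result.signals,
        result.truncated,
        drug_frame=drug_frame,
        include_incomplete=result.include_incomplete,
    )


def roa_info_table(roa: ROAMap) -> pd.DataFrame:
    """ROA_ID / size_um2 table for a ROA map (no cell assignment)."""
    return pd.DataFrame(
        {
            "ROA_ID": np.arange(1, roa.region_count + 1),
            "size_um2": roa.sizes_um2,
        }
    )


def align_roa_cell(
    roa_map: LabeledMap,
    cell_map: LabeledMap,
    spatial_resolution: float,
) -> pd.DataFrame:
    """Assign every ROA to the cell it maximally overlaps.

    ROAs overlapping no cell go to cell 0 (unassigned); overlap ties are
    broken toward the smaller cell ID with a warning.  Also reports each
    ROA's size in um^2.
    """
    if roa_map.canvas != cell_map.canvas:
        raise ValueError(
            f"canvas mismatch: ROA map {roa_map.canvas} vs cell map "
            f"{cell_map.canvas}"
        )
    n_roa = roa_map.region_count
    n_cell = cell_map.region_count
    roa_px = roa_map.labels.ravel()
    cell_px = cell_map.labels.ravel()
    sel = roa_px > 0
    key = roa_px[sel].astype(np.int64) * (n_cell + 1) + cell_px[sel]
    overlap = np.bincount(key, minlength=(n_roa + 1) * (n_cell + 1))
    overlap = overlap.reshape(n_roa + 1, n_cell + 1)[1:, :]  # rows: ROA 1..n
    cell_part = overlap[:, 1:]  # drop background column
    best = cell_part.argmax(axis=1)  # first max -> smallest cell ID on tie
    cell_ids = np.where(cell_part.max(axis=1) > 0, best + 1, 0)
    for r in range(n_roa):
        winners = np.flatnonzero(cell_part[r] == cell_part[r].max())
        if cell_part[r].max() > 0 and len(winners) > 1:
            logger.warning(
                "ROA %d overlaps cells %s equally; assigned to cell %d",
                r + 1, (winners + 1).tolist(), cell_ids[r],
            )
    counts = roa_map.pixel_counts()
    return pd.DataFrame(
        {
            "ROA_ID": np.arange(1, n_roa + 1),
            "cell_ID": cell_ids,
            "size_um2": counts * spatial_resolution**2,
        }
    )


def roa_analysis(
    features: pd.DataFrame,
    roa_info: pd.DataFrame,
    epochs: EpochSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(ROA, epoch) summary and ROA-type census.

    Every ROA in ``roa_info`` contributes one row per epoch, including
    ROAs with no detected signal.  Feature means are unweighted across a
    ROA's signals in the epoch.  Returns ``(ROA_based, ROA_summary)``;
    without a drug frame the ROA type and epoch are NA and the census is
    empty.
    """
    has_cells = "cell_ID" in roa_info.columns
    rows = []
    type_by_roa: dict[int, object] = {}
    for _, info in roa_info.iterrows():
        roa_id = int(info["ROA_ID"])
        sigs = features[features["ROA_ID"] == roa_id]
        if epochs.drug_frame is not None:
            n_base = int((sigs["epoch"] == "baseline").sum())
            n_drug = int((sigs["epoch"] == "drug").sum())
            if n_base and n_drug:
                roa_type: object = "stable"
            elif n_base:
                roa_type = "off"
            elif n_drug:
                roa_type = "on"
            else:
                roa_type = "inactive"
        else:
            roa_type = pd.NA
        type_by_roa[roa_id] = roa_type
        for name, start, stop in epochs.epochs():
            if epochs.drug_frame is None:
                in_epoch = sigs
            else:
                in_epoch = sigs[sigs["epoch"] == name]
            row = {
                "ROA_ID": roa_id,
                "size_um2": info["size_um2"],
                "ROA_type": roa_type,
                "epoch": name,
                "signal_count": len(in_epoch),
                "frequency_permin": len(in_epoch) / epochs.duration_min(name),
            }
            if has_cells:
                row["cell_ID"] = int(info["cell_ID"])
            for feat in MEAN_FEATURES:
                vals = in_epoch[feat].astype(float)
                row[f"mean_{feat}"] = vals.mean() if vals.notna().any() else np.nan
            rows.append(row)
    cols = ["ROA_ID"] + (["cell_ID"] if has_cells else []) + [
        "size_um2", "ROA_type", "epoch", "signal_count", "frequency_permin",
    ] + [f"mean_{f}" for f in MEAN_FEATURES]
    roa_based = pd.DataFrame(rows, columns=cols)
    if epochs.drug_frame is not None:
        census = pd.DataFrame(
            {
                "ROA_type": list(ROA_TYPES),
                "count": [
                    sum(1 for t in type_by_roa.values() if t == k) for k in ROA_TYPES
                ],
            }
        )
    else:
        census = pd.DataFrame({"ROA_type": [], "count": []})
    return roa_based, census


def cell_analysis(roa_based: pd.DataFrame) -> pd.DataFrame:
    """Per-(cell, epoch) summary across a cell's ROAs.

    Signal counts are summed; feature means are unweighted means of the
    ROAs' per-epoch means.  Cell 0 collects the unassigned ROAs and is
    reported like any other row; it is not a real cell.
    """
    if "cell_ID" not in roa_based.columns:
        raise ValueError("cell_analysis requires a cell-assigned ROA table")
    rows = []
    for (cell, epoch), grp in roa_based.groupby(
        ["cell_ID", "epoch"], dropna=False, sort=True
    ):
        row = {
            "cell_ID": int(cell),
            "epoch": epoch,
            "ROA_count": grp["ROA_ID"].nunique(),
            "signal_count": int(grp["signal_count"].sum()),
        }
        for k in ROA_TYPES:
            row[f"n_{k}"] = int((grp["ROA_type"] == k).sum())
        for feat in MEAN_FEATURES:
            vals = grp[f"mean_{feat}"].astype(float)
            row[f"mean_{feat}"] = vals.mean() if vals.notna().any() else np.nan
        rows.append(row)
    cols = ["cell_ID", "epoch", "ROA_count", "signal_count"] + [
        f"n_{k}" for k in ROA_TYPES
    ] + [f"mean_{f}" for f in MEAN_FEATURES]
    return pd.DataFrame(rows, columns=cols)
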