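"""End-to-end drivers for the three analysis modes.

Modes
-----
``roa``
    Region-of-activity analysis: movie (or precomputed ROA mask +
    time-series CSV) -> dF/F0, per-signal features, per-ROA summary and
    ROA-type census.
``cell_assigned``
    Same, plus assignment of every ROA to the cell it overlaps (from a
    binary cell mask) and a per-cell roll-up of the ROA summaries.
``cell``
    Whole-cell analysis: the cell mask regions themselves are the
    analysis units (no ROA map); the summary table is per cell.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .active_pixels import DetectionParams, detect_active_patches, filter_patches
from .baseline import BaselineResult, FilterParams, correct_shift, iterative_baseline, lowpass_filter
from .containers import LabeledMap, MovieStack, RunMetadata, TraceTable
from .features import (
    EpochSpec,
    align_roa_cell,
    analyze_signal,
    cell_analysis,
    roa_analysis,
    roa_info_table,
)
from .roa_map import ROAMap, build_roa_map, roa_mask
from .traces import extract_traces, region_areas

logger = logging.getLogger(__name__)

MODES = ("roa", "cell", "cell_assigned")


@dataclass
class PipelineConfig:
    """Everything the non-interactive pipeline needs to know."""

    frame_rate: float = 1.0
    spatial_resolution: float = 1.0
    drug_frame: Optional[int] = None
    # detection (movie entry point)
    detection: DetectionParams = field(default_factory=DetectionParams)
    frame_range: Optional[tuple[int, int]] = None
    # preprocessing
    use_filtered: bool = True
    filter_params: FilterParams = field(default_factory=FilterParams)
    detrend: bool = False
    correction_factor: float = 0.5
    # baseline / detection
    signal_threshold: float = 3.0
    iterations: int = 5
    baseline_start: int = 0
    baseline_end: int = -1
    include_incomplete: bool = False
    # output
    save_as: str = "csv"


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run."""

    mode: str
    metadata: RunMetadata
    raw_traces: TraceTable
    baseline: BaselineResult
    signal_features: pd.DataFrame
    region_summary: pd.DataFrame       # per (region, epoch)
    roa_summary: Optional[pd.DataFrame]  # ROA-type census (ROA modes w/ drug)
    cell_assigned: Optional[pd.DataFrame]
    roa_map: Optional[ROAMap]
    region_map: LabeledMap
    slopes: Optional[np.ndarray]
    written: list[str] = field(default_factory=list)


def movie_to_roa_map(movie: MovieStack, config: PipelineConfig) -> ROAMap:
    """Detect active patches, area-filter them and project the ROA map."""
    params = config.detection
    patches = detect_active_patches(movie, params)
    area_min = params.resolved_area_min(movie.spatial_resolution)
    kept = filter_patches(patches, area_min, params.area_max)
    logger.info(
        "detected %d patches, %d within area window [%.3g, %.3g] um^2",
        len(patches), len(kept), area_min, params.area_max,
    )
    return build_roa_map(
        kept, movie.canvas, movie.spatial_resolution, frame_range=config.frame_range
    )


def process_traces(
    raw: TraceTable, config: PipelineConfig
) -> tuple[BaselineResult, Optional[np.ndarray]]:
    """Filter, optionally detrend, then run the iterative baseline."""
    working = lowpass_filter(raw, config.filter_params) if config.use_filtered else raw
    slopes = None
    if config.detrend:
        working, slopes = correct_shift(working, config.correction_factor)
    result = iterative_baseline(
        working,
        threshold_k=config.signal_threshold,
        n_iterations=config.iterations,
        baseline_start=config.baseline_start,
        baseline_end=config.baseline_end,
        include_incomplete=config.include_incomplete,
    )
    return result, slopes


def inspect_trace(result: BaselineResult, region_ids: list[int]) -> pd.DataFrame:
    """Long-form table of dF/F0 with baseline and threshold overlays.

    One row per (region, frame) with the dF/F0 value, the baseline level
    (0 in dF/F0 units) and the region's detection threshold — the data
    behind a diagnostic trace plot for e.g. unexpectedly inactive regions.
    """
    frames = np.arange(result.dff.n_frames)
    parts = []
    for rid in region_ids:
        try:
            r = result.dff.region_ids.index(rid)
        except ValueError:
            raise KeyError(f"region {rid} not in this result") from None
        parts.append(
            pd.DataFrame(
                {
                    "region_id": rid,
                    "frame": frames,
                    "time_s": frames / result.dff.frame_rate,
                    "dff": result.dff.values[r],
                    "baseline": 0.0,
                    "threshold": result.thresholds_dff[r],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def _check_counts(traces: TraceTable, region_map: LabeledMap, what: str) -> None:
    if traces.n_regions != region_map.region_count:
        raise ValueError(
            f"count mismatch: time series has {traces.n_regions} columns but "
            f"the {what} mask yields {region_map.region_count} regions; "
            "regions that touch (even diagonally) merge under 8-connected "
            "labeling — re-draw the mask with at least one pixel of "
            "separation or regenerate the time series"
        )


def run_pipeline(
    mode: str,
    out_dir: str | os.PathLike,
    config: PipelineConfig,
    movie: Optional[MovieStack] = None,
    movie_path: Optional[str] = None,
    timeseries_path: Optional[str] = None,
    roa_mask_path: Optional[str] = None,
    cell_mask_path: Optional[str] = None,
    write: bool = True,
) -> PipelineResult:
    """Run one analysis mode end to end and (optionally) write outputs.

    Entry points, in order of precedence: an in-memory movie, a movie
    TIFF path, or a precomputed time-series CSV plus mask(s).  When both
    a movie and a time-series CSV are given the CSV wins for traces and
    the movie is only used for map building.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    os.makedirs(out_dir, exist_ok=True)

    if movie is None and movie_path is not None:
        movie = io.read_movie(movie_path, config.frame_rate, config.spatial_resolution)

    meta = RunMetadata(
        frame_rate=config.frame_rate,
        spatial_resolution=config.spatial_resolution,
        drug_frame=config.drug_frame,
        signal_threshold=config.signal_threshold,
        output_path=str(out_dir),
    )

    roa: Optional[ROAMap] = None
    cell_map: Optional[LabeledMap] = None

    if mode == "cell":
        if cell_mask_path is None:
            raise ValueError("cell mode requires a cell mask")
        region_map = io.read_mask(cell_mask_path, "cell")
        logger.info("cell mask: %d cells", region_map.region_count)
        info = pd.DataFrame(
            {
                "ROA_ID": np.arange(1, region_map.region_count + 1),
                "size_um2": region_areas(region_map, config.spatial_resolution),
            }
        )
    else:
        if roa_mask_path is not None:
            region_map = io.read_mask(roa_mask_path, "ROA")
        elif movie is not None:
            roa = movie_to_roa_map(movie, config)
            region_map = roa.labeled
            if write:
                io.write_mask(os.path.join(out_dir, "ROA_mask.tif"), roa_mask(roa))
        else:
            raise ValueError(f"{mode} mode requires a movie or a ROA mask")
        logger.info("ROA map: %d ROAs", region_map.region_count)
        if roa is not None:
            info = roa_info_table(roa)
        else:
            info = pd.DataFrame(
                {
                    "ROA_ID": np.arange(1, region_map.region_count + 1),
                    "size_um2": region_areas(region_map, config.spatial_resolution),
                }
            )
        if mode == "cell_assigned":
            if cell_mask_path is None:
                raise ValueError("cell_assigned mode requires a cell mask")
            cell_map = io.read_mask(cell_mask_path, "cell")
            logger.info("cell mask: %d cells", cell_map.region_count)
            info = align_roa_cell(region_map, cell_map, config.spatial_resolution)

    if timeseries_path is not None:
        raw = io.read_imagej_timeseries(timeseries_path, config.frame_rate)
        _check_counts(raw, region_map, "cell" if mode == "cell" else "ROA")
    elif movie is not None:
        raw = extract_traces(movie, region_map)
    else:
        raise ValueError("need a movie or a time-series CSV for traces")

    meta.validate_drug_frame(raw.n_frames)
    result, slopes = process_traces(raw, config)
    epochs = EpochSpec(raw.n_frames, config.frame_rate, config.drug_frame)
    features = analyze_signal(
        result.dff,
        result.signals,
        result.truncated,
        drug_frame=config.drug_frame,
        include_incomplete=config.include_incomplete,
    )
    features = info.merge(features, on="ROA_ID", how="right")
    region_summary, census = roa_analysis(features, info, epochs)

    cell_table = None
    tables: dict[str, pd.DataFrame] = {
        "dff_traces": io.traces_to_frame(result.dff),
        "signal_features": features,
    }
    if mode == "cell":
        tables["cell_based"] = region_summary.rename(columns={"ROA_ID": "cell_ID"})
    else:
        tables["ROA_based"] = region_summary
        if config.drug_frame is not None:
            tables["ROA_summary"] = census
        if mode == "cell_assigned":
            cell_table = cell_analysis(region_summary)
            tables["cell_assigned"] = cell_table

    written: list[str] = []
    if write:
        written = io.write_outputs(tables, meta, out_dir, save_as=config.save_as)

    return PipelineResult(
        mode=mode,
        metadata=meta,
        raw_traces=raw,
        baseline=result,
        signal_features=features,
        region_summary=region_summary,
        roa_summary=census if mode != "cell" else None,
        cell_assigned=cell_table,
        roa_map=roa,
        region_map=region_map,
        slopes=slopes,
        written=written,
    )
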