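"""Readers and writers for every on-disk artifact the pipeline touches.

Movies and masks travel as plain multi-page grayscale TIFF; time series
travel as the ImageJ multi-measure CSV dialect (one row per frame, one
mean-intensity column per region, optional leading 1-based slice index);
analysis results leave as fixed-name CSV files or one Excel workbook.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .containers import LabeledMap, MapKind, MovieStack, RunMetadata, TraceTable

logger = logging.getLogger(__name__)

#: 8-connectivity structuring element used for all region labeling
#: (matches the ImageJ Analyze Particles default).
STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: Fixed output file stems, in write order.
OUTPUT_TABLES = (
    "metadata",
    "dff_traces",
    "signal_features",
    "ROA_based",
    "cell_assigned",
    "cell_based",
    "ROA_summary",
)


def label_components(foreground: np.ndarray) -> tuple[np.ndarray, int]:
    """Label 8-connected foreground components in raster-scan order.

    Components are numbered 1..N by the raster position (row-major) of
    each component's first pixel, which makes labeling deterministic and
    independent of the underlying labeling library's internals.
    """
    labels, n = ndimage.label(foreground, structure=STRUCTURE_8)
    if n == 0:
        return labels, 0
    # ndimage.label already assigns labels in first-encounter raster order,
    # but we relabel explicitly so the ordering is a documented contract.
    first_pixel = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    # reversed so earlier raster positions overwrite later ones
    first_pixel[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first_pixel[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[labels], n


def read_movie(
    path: str | os.PathLike,
    frame_rate: float,
    spatial_resolution: float,
) -> MovieStack:
    """Read a single-channel multi-page TIFF movie.

    Acquisition metadata (frame rate, pixel size) is supplied by the
    caller's configuration rather than guessed from TIFF tags, which are
    unreliable across acquisition software.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        if "S" in axes or "C" in axes:
            raise ValueError(
                "single-channel required: this TIFF has color/sample channels; "
                "split channels before analysis"
            )
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in TIFF: {sorted(shapes)}")
        frames = series.asarray()
    if frames.ndim == 2:
        frames = frames[np.newaxis, ...]
    if frames.ndim != 3:
        raise ValueError(
            "single-channel required: expected grayscale pages, got array of "
            f"shape {frames.shape}"
        )
    return MovieStack(frames, frame_rate=frame_rate, spatial_resolution=spatial_resolution)


def write_movie(path: str | os.PathLike, frames: np.ndarray) -> None:
    """Write a (t, y, x) stack as a multi-page TIFF."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (t, y, x) stack")
    tifffile.imwrite(path, frames)


def read_mask(path: str | os.PathLike, kind: MapKind = "ROA") -> LabeledMap:
    """Read an 8-bit binary mask TIFF and label its 8-connected regions.

    Foreground is pixel value 255, background 0.  Other nonzero values are
    tolerated as foreground with a warning (8-bit mask variants exist).
    """
    pixels = tifffile.imread(path)
    if pixels.ndim == 3 and pixels.shape[0] == 1:
        pixels = pixels[0]
    if pixels.ndim != 2:
        raise ValueError(f"mask must be a single 2-D page; got shape {pixels.shape}")
    values = np.unique(pixels)
    if not np.all(np.isin(values, (0, 255))):
        logger.warning(
            "mask %s contains values other than {0, 255}; "
            "treating all nonzero pixels as foreground", path,
        )
    foreground = pixels > 0
    labels, n = label_components(foreground)
    if n == 0:
        raise ValueError(f"no regions found in mask {path}")
    return LabeledMap(labels, region_count=n, kind=kind)


def write_mask(path: str | os.PathLike, mask: np.ndarray | LabeledMap) -> None:
    """Write a binary mask TIFF (foreground 255, background 0)."""
    if isinstance(mask, LabeledMap):
        mask = mask.labels > 0
    out = np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8)
    tifffile.imwrite(path, out)


def _looks_like_slice_index(col: pd.Series) -> bool:
    """True iff a column is the ImageJ 1-based slice counter 1, 2, ..., n."""
    vals = pd.to_numeric(col, errors="coerce")
    if vals.isna().any():
        return False
    arr = vals.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        return False
    return bool(np.array_equal(arr, np.arange(1, len(arr) + 1)))


def read_imagej_timeseries(
    path: str | os.PathLike, frame_rate: float = 1.0
) -> TraceTable:
    """Read an ImageJ multi-measure CSV into a raw TraceTable.

    One row per frame, one mean-intensity column per region.  A leading
    column is treated as the slice index and dropped iff it is exactly the
    monotone integer sequence 1..n; otherwise it counts as a region.
    Internally frames are 0-based.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged rows in {path}: {exc}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError(f"empty time-series file {path}")
    if df.shape[1] >= 2 and _looks_like_slice_index(df.iloc[:, 0]):
        df = df.iloc[:, 1:]
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise ValueError(
                f"ragged or missing cell in {path} at row {row + 2}, column {j + 1}"
            )
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"non-numeric cell in {path} at row {row + 2}, column {j + 1} "
                f"({df[col][row]!r})"
            )
        df[col] = numeric
    values = df.to_numpy(dtype=float).T  # regions x frames
    return TraceTable(values, stage="raw", frame_rate=frame_rate)


def write_imagej_timeseries(path: str | os.PathLike, traces: TraceTable) -> None:
    """Write a TraceTable in the ImageJ multi-measure dialect.

    Emits a leading 1-based slice-index column and one ``Mean<i>`` column
    per region, so the file round-trips through :func:`read_imagej_timeseries`.
    """
    df = pd.DataFrame(
        {"": np.arange(1, traces.n_frames + 1)}
        | {f"Mean{r}": traces.values[i] for i, r in enumerate(traces.region_ids)}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def traces_to_frame(traces: TraceTable) -> pd.DataFrame:
    """Regions-as-rows DataFrame view of a TraceTable (region_id index)."""
    return pd.DataFrame(
        traces.values,
        index=pd.Index(traces.region_ids, name="region_id"),
        columns=[str(t) for t in range(traces.n_frames)],
    )


def frame_to_traces(
    df: pd.DataFrame, stage: str, frame_rate: float
) -> TraceTable:
    """Inverse of :func:`traces_to_frame`."""
    return TraceTable(
        df.to_numpy(dtype=float),
        stage=stage,  # type: ignore[arg-type]
        frame_rate=frame_rate,
        region_ids=[int(i) for i in df.index],
    )


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    metadata: RunMetadata,
    out_dir: str | os.PathLike,
    save_as: str = "csv",
) -> list[str]:
    """Write the analysis result tables with fixed names.

    ``tables`` maps output names (any of :data:`OUTPUT_TABLES` except
    ``metadata``) to DataFrames.  Missing optional tables are skipped,
    never emitted empty.  Returns the written file paths.
    """
    if save_as not in ("csv", "excel"):
        raise ValueError("save_as must be 'csv' or 'excel'")
    unknown = set(tables) - set(OUTPUT_TABLES)
    if unknown:
        raise ValueError(f"unknown output tables: {sorted(unknown)}")
    os.makedirs(out_dir, exist_ok=True)
    meta_df = pd.DataFrame(
        {
            "frame_rate": [metadata.frame_rate],
            "spatial_resolution": [metadata.spatial_resolution],
            "drug_frame": [metadata.drug_frame],
            "drug_time": [
                None
                if metadata.drug_frame is None
                else metadata.drug_frame / metadata.frame_rate
            ],
            "signal_threshold": [metadata.signal_threshold],
        }
    )
    ordered = {"metadata": meta_df}
    for name in OUTPUT_TABLES[1:]:
        if name in tables and tables[name] is not None:
            ordered[name] = tables[name]

    written: list[str] = []
    if save_as == "csv":
        for name, df in ordered.items():
            path = os.path.join(out_dir, f"{name}.csv")
            index = name == "dff_traces"
            df.to_csv(path, index=index, float_format="%.17g")
            written.append(path)
    else:
        path = os.path.join(out_dir, "results.xlsx")
        with pd.ExcelWriter(path) as writer:
            for name, df in ordered.items():
                # Excel sheet names are capped at 31 characters
                df.to_excel(writer, sheet_name=name[:31], index=name == "dff_traces")
        written.append(path)
    return written


def read_dff_traces(path: str | os.PathLike, frame_rate: float) -> TraceTable:
    """Read back a ``dff_traces.csv`` written by :func:`write_outputs`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return frame_to_traces(df, stage="dff", frame_rate=frame_rate)
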