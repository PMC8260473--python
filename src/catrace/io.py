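"""On-disk contracts: image stacks in, trace tables in/out, parameter tables out.

Multi-frame grayscale TIFF is the baseline stack format; common video
containers (.avi/.mov/.mp4/.m4v) are decoded through imageio behind the same
reader interface.  Pre-extracted traces arrive as delimited tables (CSV/TSV
or spreadsheet), one column per cell.  Parameter output is written both as
plain CSV and as a spreadsheet with one sheet per output class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, List, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .extraction import FluorescenceTrace
    from .transients import TransientParameters
    from .irregularity import IrregularityReport

VIDEO_SUFFIXES = {".avi", ".mov", ".mp4", ".m4v", ".mkv"}
TIFF_SUFFIXES = {".tif", ".tiff"}
TABLE_SUFFIXES = {".csv", ".tsv", ".txt", ".xlsx", ".xls"}


class FormatError(ValueError):
    """Raised when an input file cannot be decoded as expected."""


@dataclass
class ImageStack:
    """Ordered grayscale frames plus acquisition metadata.

    Frame index is 0-based; the time of frame ``i`` is ``i / fps`` seconds.
    """

    frames: np.ndarray
    fps: float
    pixel_depth: int = 16
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (frame, row, col); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("an image stack needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class TraceTable:
    """A collection of same-length, same-rate fluorescence traces."""

    traces: List["FluorescenceTrace"]
    fps: float
    pacing_hz: float

    def __post_init__(self) -> None:
        if self.traces:
            n = len(self.traces[0].values)
            for t in self.traces:
                if len(t.values) != n:
                    raise ValueError("all traces must have the same length")
                if t.fps != self.fps:
                    raise ValueError("all traces must share the table fps")

    def __len__(self) -> int:
        return len(self.traces)


def _grayscale(frames: np.ndarray, channel_index: Optional[int] = None) -> np.ndarray:
    """Collapse a possible channel axis.

    Multi-channel frames use the single channel of maximum mean intensity
    (calcium indicators are single-channel) unless an index is configured.
    """
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4:
        # channel axis is the trailing one (imageio convention)
        if channel_index is None:
            channel_index = int(np.argmax(frames.mean(axis=(0, 1, 2))))
        return frames[..., channel_index]
    raise FormatError(f"cannot interpret frame array of shape {frames.shape}")


def read_image_stack(
    path: str | Path, fps: float, channel_index: Optional[int] = None
) -> ImageStack:
    """Read a multi-frame TIFF stack or a video file as an ImageStack.

    Intensities are preserved at their stored dtype (widened to float only
    downstream, never truncated).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix in TIFF_SUFFIXES:
            import tifffile

            frames = tifffile.imread(path)
        elif suffix in VIDEO_SUFFIXES:
            import imageio.v3 as iio

            frames = np.asarray(iio.imread(path))
        else:
            raise FormatError(f"unsupported stack format: {path.suffix!r}")
    except FormatError:
        raise
    except Exception as exc:  # undecodable / truncated file
        raise FormatError(f"could not decode {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError(f"{path} holds a single frame, not a stack")
    frames = _grayscale(frames, channel_index)
    depth = frames.dtype.itemsize * 8 if frames.dtype.kind in "ui" else 32
    return ImageStack(frames=frames, fps=fps, pixel_depth=depth, source_path=str(path))


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-frame TIFF (lossless at the stored depth)."""
    import tifffile

    tifffile.imwrite(Path(path), stack.frames)


def read_trace_table(path: str | Path, fps: float, pacing_hz: float) -> TraceTable:
    """Read pre-extracted traces from a delimited table or spreadsheet.

    Expects one numeric column per cell (wide format); a leading ``frame`` or
    ``time_ms`` column is ignored.  Column order is preserved.
    """
    from .extraction import FluorescenceTrace

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    elif suffix == ".tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    drop = [c for c in df.columns if str(c).lower() in {"frame", "time_ms", "time"}]
    df = df.drop(columns=drop)
    traces = []
    for i, col in enumerate(df.columns):
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() & series.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"non-numeric value in column {col!r} at row {row}: {series[row]!r}"
            )
        if numeric.isna().all() or len(numeric.dropna()) == 0:
            raise ValueError(f"column {col!r} is empty")
        traces.append(
            FluorescenceTrace(values=numeric.dropna().to_numpy(float), fps=fps, cell_id=i)
        )
    if not traces:
        raise ValueError(f"no trace columns found in {path}")
    return TraceTable(traces=traces, fps=fps, pacing_hz=pacing_hz)


def write_trace_table(traces: Sequence["FluorescenceTrace"], path: str | Path) -> None:
    """Export traces as CSV: frame, time_ms, one column per cell."""
    if not traces:
        raise ValueError("no traces to write")
    n = len(traces[0].values)
    data = {"frame": np.arange(n), "time_ms": traces[0].times_ms}
    for t in traces:
        data[f"cell_{t.cell_id}"] = t.values
    pd.DataFrame(data).to_csv(Path(path), index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# parameter tables

PARAMETER_COLUMNS = [
    "cell_id",
    "beat_index",
    "f0",
    "fmax",
    "magnitude",
    "fmax_over_f0",
    "redefined_baseline",
    "t_on",
    "t10_on",
    "t50_on",
    "t90_on",
    "t_off",
    "t10_off",
    "t50_off",
    "t90_off",
    "cd",
    "tau",
    "fit_a",
    "fit_b",
    "fit_c",
    "fit_gof",
    "snr",
    "beat_to_beat_ms",
    "n_intervals",
    "n_beats",
    "flags",
]


def parameters_frame(records: Sequence["TransientParameters"]) -> pd.DataFrame:
    """Flatten parameter records into the fixed, documented column set."""
    rows = []
    for rec in records:
        d = rec.to_dict()
        rows.append({c: d.get(c) for c in PARAMETER_COLUMNS})
    return pd.DataFrame(rows, columns=PARAMETER_COLUMNS)


def write_parameters(
    records: Sequence["TransientParameters"],
    path: str | Path,
    per_beat: Optional[Sequence["TransientParameters"]] = None,
    irregularity: Optional[Sequence["IrregularityReport"]] = None,
) -> None:
    """Write per-cell parameter records to CSV or a spreadsheet.

    Spreadsheet output uses one sheet per output class (mean-transient
    parameters, per-beat parameters, irregularity report).  Per-beat output
    includes, for each cell, one row per beat plus an ``sd`` row with the
    across-beat SD of every parameter as a quality-control metric.
    """
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    mean_df = parameters_frame(records)
    beat_df = _per_beat_frame(per_beat) if per_beat else None
    irr_df = _irregularity_frame(irregularity) if irregularity else None
    if path.suffix.lower() in {".xlsx", ".xls"}:
        with pd.ExcelWriter(path) as xl:
            mean_df.to_excel(xl, sheet_name="mean_transient", index=False)
            if beat_df is not None:
                beat_df.to_excel(xl, sheet_name="per_beat", index=False)
            if irr_df is not None:
                irr_df.to_excel(xl, sheet_name="irregularity", index=False)
    else:
        mean_df.to_csv(path, index=False, float_format="%.10g")
        if beat_df is not None:
            beat_df.to_csv(path.with_suffix(".per_beat.csv"), index=False,
                           float_format="%.10g")
        if irr_df is not None:
            irr_df.to_csv(path.with_suffix(".irregularity.csv"), index=False,
                          float_format="%.10g")


def _per_beat_frame(per_beat: Sequence["TransientParameters"]) -> pd.DataFrame:
    df = parameters_frame(per_beat)
    numeric = [c for c in df.columns if c not in ("cell_id", "beat_index", "flags")]
    sd_rows = []
    for cell_id, group in df.groupby("cell_id"):
        if len(group) < 2:
            continue
        sd = group[numeric].std(ddof=1)
        row = {"cell_id": cell_id, "beat_index": "sd", "flags": ""}
        row.update(sd.to_dict())
        sd_rows.append(row)
    if sd_rows:
        df = pd.concat([df, pd.DataFrame(sd_rows)], ignore_index=True)
    return df


def _irregularity_frame(reports: Sequence["IrregularityReport"]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        if rep.events:
            for ev in rep.events:
                rows.append(
                    {
                        "cell_id": ev.cell_id,
                        "beat_index": ev.beat_index,
                        "class": ev.event_class,
                        "n_total_beats": rep.n_total_beats,
                        "n_irregular": rep.n_irregular,
                        "n_excluded": rep.n_excluded,
                        "beat_to_beat_ms": rep.beat_to_beat_ms,
                        "n_intervals": rep.n_intervals,
                        "adheres_to_pacing": rep.adheres_to_pacing,
                    }
                )
        else:
            rows.append(
                {
                    "cell_id": rep.cell_id,
                    "beat_index": None,
                    "class": "none",
                    "n_total_beats": rep.n_total_beats,
                    "n_irregular": rep.n_irregular,
                    "n_excluded": rep.n_excluded,
                    "beat_to_beat_ms": rep.beat_to_beat_ms,
                    "n_intervals": rep.n_intervals,
                    "adheres_to_pacing": rep.adheres_to_pacing,
                }
            )
    return pd.DataFrame(rows)


def read_parameters(path: str | Path) -> pd.DataFrame:
    """Read back a written parameter table (CSV or spreadsheet)."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, sheet_name="mean_transient")
    return pd.read_csv(path)
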