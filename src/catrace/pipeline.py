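"""Directory-level orchestration: files in, parameter tables and reports out.

Every input file is processed independently; a failure on one file (or one
cell) yields a flagged entry in the run manifest, never an aborted run.
A Nyquist-based temporal-resolution advisory is logged for each acquisition
rate: sampling at ``fps`` gives an interval of ``1000/fps`` ms and a
theoretical resolution of ``2.3 x 1000/fps`` ms (resolution equals 1/2.3 of
the sampling frequency); rates below 25 FPS draw a low-rate warning because
cardiomyocyte calcium kinetics are too fast to capture reliably there.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from . import __version__
from .config import AnalysisConfig
from .io import (TABLE_SUFFIXES, TIFF_SUFFIXES, VIDEO_SUFFIXES,
                 read_image_stack, read_trace_table, write_parameters)

logger = logging.getLogger("catrace")

MIN_RECOMMENDED_FPS = 25.0
NYQUIST_FACTOR = 2.3


def temporal_resolution_advisory(fps: float) -> Tuple[float, float]:
    """Sampling interval and theoretical temporal resolution, both in ms.

    At 25 FPS the interval is 40 ms and the resolution 92 ms; timing
    parameters shorter than the resolution are interpolation-limited.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    interval_ms = 1000.0 / fps
    resolution_ms = NYQUIST_FACTOR * interval_ms
    if fps < MIN_RECOMMENDED_FPS:
        logger.warning(
            "acquisition rate %.3g FPS is below the recommended minimum of "
            "%.0f FPS; timing parameters will be unreliable",
            fps, MIN_RECOMMENDED_FPS,
        )
    logger.info("QC advisory: sampling interval %.4g ms, temporal resolution "
                "%.4g ms", interval_ms, resolution_ms)
    return interval_ms, resolution_ms


@dataclass
class FileEntry:
    path: str
    status: str  # "processed" | "skipped" | "failed"
    n_cells: int = 0
    n_flagged: int = 0
    error: str = ""


@dataclass
class RunManifest:
    """Accounting for a directory run: every input file is either processed,
    skipped with a reason, or failed with its error."""

    input_dir: str
    config: dict
    files: List[FileEntry] = field(default_factory=list)
    software_version: str = __version__
    seed: int = 0

    @property
    def n_processed(self) -> int:
        return sum(1 for f in self.files if f.status == "processed")

    @property
    def n_failed(self) -> int:
        return sum(1 for f in self.files if f.status == "failed")

    @property
    def n_good_cells(self) -> int:
        return sum(f.n_cells - f.n_flagged for f in self.files)

    def to_json(self, path: str | Path) -> None:
        d = {
            "input_dir": self.input_dir,
            "config": self.config,
            "software_version": self.software_version,
            "seed": self.seed,
            "files": [asdict(f) for f in self.files],
        }
        Path(path).write_text(json.dumps(d, indent=2))


def run_directory(
    directory: str | Path,
    config: Optional[AnalysisConfig] = None,
    fps: float = 100.0,
    output_dir: Optional[str | Path] = None,
    mode: str = "multi",
) -> RunManifest:
    """Analyze every readable stack/video/table in a directory.

    Writes one parameter CSV per input file into ``output_dir`` (defaults to
    ``<directory>/catrace_output``) plus a JSON run manifest.
    """
    directory = Path(directory)
    config = config or AnalysisConfig()
    inputs = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (TIFF_SUFFIXES | VIDEO_SUFFIXES | TABLE_SUFFIXES)
    )
    if not inputs:
        raise ValueError(f"no readable input files in {directory}")
    output_dir = Path(output_dir) if output_dir else directory / "catrace_output"
    output_dir.mkdir(parents=True, exist_ok=True)
    temporal_resolution_advisory(fps)

    manifest = RunManifest(input_dir=str(directory), config=config.to_dict(),
                           seed=config.random_seed)
    for path in inputs:
        try:
            records, reports = _process_file(path, config, fps, mode)
            out_path = output_dir / (path.stem + "_parameters.csv")
            if records:
                write_parameters(records, out_path, irregularity=reports)
            n_flagged = sum(1 for r in records if r.is_flagged)
            manifest.files.append(FileEntry(path=str(path), status="processed",
                                            n_cells=len(records),
                                            n_flagged=n_flagged))
        except Exception as exc:
            logger.error("failed on %s: %s", path, exc)
            manifest.files.append(FileEntry(path=str(path), status="failed",
                                            error=str(exc)))
    manifest.to_json(output_dir / "run_manifest.json")
    return manifest


def _process_file(path: Path, config: AnalysisConfig, fps: float, mode: str):
    from .extraction import extract_trace, subtract_background
    from .segmentation import average_frame, segment_cells
    from .transients import analyze_cell

    records, reports = [], []
    if path.suffix.lower() in TABLE_SUFFIXES:
        table = read_trace_table(path, fps=fps, pacing_hz=config.pacing_hz)
        traces = table.traces
    else:
        stack = read_image_stack(path, fps=fps,
                                 channel_index=config.channel_index)
        mask = segment_cells(average_frame(stack), mode=mode,
                             params=config.segmentation)
        traces = []
        for cid in mask.accepted_ids:
            trace = extract_trace(stack, mask, cid)
            try:
                trace = subtract_background(trace, stack, mask)
            except ValueError:
                trace.flags.append("background_subtraction_failed")
            traces.append(trace)
    for trace in traces:
        res = analyze_cell(trace, config)
        records.append(res.params)
        reports.append(res.irregularity)
    return records, reports
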