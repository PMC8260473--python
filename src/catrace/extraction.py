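"""Per-cell fluorescence traces: extraction from masked stacks, background
subtraction and the signal-to-noise quality metric.

The raw trace of cell *n* is the sum of all pixel intensities inside its
fixed mask region at every frame.  The signal-to-noise ratio (SNR) used for
quality control is the mean of the above-baseline signal (baseline
subtracted) divided by the standard deviation of the values below the
baseline; traces below an SNR of 15 are flagged as potentially unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .io import ImageStack
from .segmentation import CellMask


@dataclass
class FluorescenceTrace:
    """One cell's fluorescence intensity per frame."""

    values: np.ndarray
    fps: float
    cell_id: int = 0
    background_subtracted: bool = False
    detrended: bool = False
    snr: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_ms(self) -> np.ndarray:
        """Time of frame i is i/fps seconds, reported in milliseconds."""
        return np.arange(len(self.values)) * (1000.0 / self.fps)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fps

    def with_values(self, values: np.ndarray, **changes) -> "FluorescenceTrace":
        out = replace(self, **changes)
        out.values = np.asarray(values, dtype=float)
        out.flags = list(self.flags)
        return out


def extract_trace(stack: ImageStack, mask: CellMask, cell_id: int) -> FluorescenceTrace:
    """Sum of pixel intensities within an accepted cell region, per frame."""
    props = mask.get(cell_id)
    if props is None:
        raise ValueError(f"cell {cell_id} not present in mask")
    if not props.accepted:
        raise ValueError(
            f"cell {cell_id} was rejected ({props.rejection_reason}); "
            "no trace extracted"
        )
    region = mask.label_image == cell_id
    values = stack.frames[:, region].sum(axis=1).astype(float)
    return FluorescenceTrace(values=values, fps=stack.fps, cell_id=cell_id)


def subtract_background(
    trace: FluorescenceTrace, stack: ImageStack, mask: CellMask
) -> FluorescenceTrace:
    """Remove the per-frame background estimate from a summed-intensity trace.

    The background region is every pixel outside all detected cell regions
    (accepted or rejected), eroded by 3 px to avoid halo contamination.  Its
    per-frame mean, scaled by the cell's pixel area, is subtracted.
    """
    from scipy import ndimage

    bg_region = mask.label_image == 0
    bg_region = ndimage.binary_erosion(bg_region, iterations=3)
    if not bg_region.any():
        raise ValueError("mask covers the entire frame; no background region")
    props = mask.get(trace.cell_id)
    area = props.area_px if props is not None else int((mask.label_image == trace.cell_id).sum())
    bg_mean = stack.frames[:, bg_region].mean(axis=1).astype(float)
    corrected = trace.values - bg_mean * area
    return trace.with_values(corrected, background_subtracted=True)


def signal_to_noise(trace: FluorescenceTrace, baseline: float) -> float:
    """SNR = mean(above-baseline signal − baseline) / SD(below-baseline values).

    Returns ``math.inf`` (and flags the trace) when no values fall below the
    baseline or their SD is zero — a noiseless trace has unbounded SNR.
    """
    v = trace.values
    above = v[v > baseline]
    below = v[v < baseline]
    if above.size == 0:
        trace.flags.append("snr_no_signal")
        return 0.0
    if below.size == 0:
        trace.flags.append("snr_noiseless")
        return math.inf
    sd = float(np.std(below))
    if sd == 0.0:
        trace.flags.append("snr_noiseless")
        return math.inf
    return float(np.mean(above - baseline) / sd)
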