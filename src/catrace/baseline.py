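"""Photobleach / baseline-drift correction.

Fluorescence baseline drift — from photobleaching, dye loss or cell damage —
is modeled by a second-degree polynomial in time, which captures both linear
and exponential (to second order) trends.  The polynomial is fitted to
baseline-phase samples only (the lowest quartile of each pacing cycle), so
transient peaks do not bias the trend, and the fitted trend minus its first
value is subtracted from the trace.  Anchoring at the first frame keeps the
absolute intensity scale interpretable; any constant offset cancels in ratio
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .config import AnalysisConfig, PhotobleachMode
from .extraction import FluorescenceTrace


@dataclass
class DriftModel:
    """Degree-2 polynomial baseline trend c2·t² + c1·t + c0 (t in seconds)."""

    coefficients: Tuple[float, float, float]
    applied: bool = False
    pre_correction_slope_fraction: float = 0.0

    def trend(self, times_s: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, times_s)


def fit_drift(trace: FluorescenceTrace, pacing_hz: float) -> DriftModel:
    """Fit the baseline trend of a paced trace.

    Within each pacing-cycle window the lowest-quartile samples are taken as
    baseline-phase points; a degree-2 polynomial over time is fitted to them.
    The diagnostic ``pre_correction_slope_fraction`` is the fitted trend's
    total change over the trace divided by its initial value.
    """
    n = len(trace.values)
    cycle_frames = max(1, round(trace.fps / pacing_hz))
    if n < 2 * cycle_frames:
        raise ValueError("trace must span at least 2 full pacing cycles")
    times_s = np.arange(n) / trace.fps
    # cycle windows are aligned to the trace end so every window covers the
    # same beat phase; a partial leading window (pre-stimulus head) would
    # otherwise contribute baseline samples at a different level and fake a
    # trend on drift-free traces
    t_sel, v_sel = [], []
    for start in range(n - cycle_frames, -1, -cycle_frames):
        window = trace.values[start : start + cycle_frames]
        q = np.quantile(window, 0.25)
        idx = np.nonzero(window <= q)[0] + start
        t_sel.append(times_s[idx])
        v_sel.append(trace.values[idx])
    t_sel = np.concatenate(t_sel)
    v_sel = np.concatenate(v_sel)
    if t_sel.size < 3:
        raise ValueError("fewer than 3 baseline samples; cannot fit drift")
    coeffs = np.polyfit(t_sel, v_sel, deg=2)
    trend = np.polyval(coeffs, times_s)
    t0 = trend[0] if trend[0] != 0 else 1.0
    slope_fraction = float((trend[-1] - trend[0]) / t0)
    return DriftModel(
        coefficients=tuple(float(c) for c in coeffs),
        pre_correction_slope_fraction=slope_fraction,
    )


def detrend(trace: FluorescenceTrace, model: DriftModel) -> FluorescenceTrace:
    """Subtract the fitted trend (anchored at the first frame) from the trace."""
    times_s = np.arange(len(trace.values)) / trace.fps
    trend = model.trend(times_s)
    corrected = trace.values - (trend - trend[0])
    model.applied = True
    return trace.with_values(corrected, detrended=True)


def correct_photobleach(
    trace: FluorescenceTrace, config: AnalysisConfig
) -> Tuple[FluorescenceTrace, DriftModel | None]:
    """Apply the configured photobleach policy.

    ``off`` passes the trace through bit-identically; ``force`` always
    detrends; ``auto`` detrends only when the fitted trend changes by more
    than the auto threshold (default 3%) of the initial baseline.
    """
    mode = config.photobleach_correct
    if mode == PhotobleachMode.OFF:
        return trace, None
    model = fit_drift(trace, config.pacing_hz)
    if mode == PhotobleachMode.AUTO and (
        abs(model.pre_correction_slope_fraction) <= config.drift_auto_threshold
    ):
        return trace, model
    return detrend(trace, model), model
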