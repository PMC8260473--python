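"""Ratiometric (Fura-2 style) calibration: excitation-ratio traces to
absolute calcium concentration.

Two calibration modes are supported.  Parametric mode uses the standard
ratiometric conversion

    [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R)

with Kd the indicator dissociation constant (nM), Rmin/Rmax the ratios at
zero and saturating calcium, and beta the free/bound fluorescence ratio of
the denominator channel.  Empirical mode builds a strictly monotone
interpolated map from user-supplied (known-calcium, ratio) points.
Conversion is monotone in R in both modes; concentration traces then flow
through the same temporal analysis pipeline as fluorescence traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .extraction import FluorescenceTrace


@dataclass
class ParametricCalibration:
    kd: float  # nM
    rmin: float
    rmax: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.rmin < self.rmax):
            raise ValueError("rmin must be < rmax")
        if self.kd <= 0 or self.beta <= 0:
            raise ValueError("kd and beta must be positive")

    def ratio_from_calcium(self, ca_nm: np.ndarray) -> np.ndarray:
        """Forward conversion [Ca] -> R (used for synthetic data and checks)."""
        ca_nm = np.asarray(ca_nm, dtype=float)
        kb = self.kd * self.beta
        return (ca_nm * self.rmax + kb * self.rmin) / (ca_nm + kb)

    def calcium_from_ratio(self, ratio: np.ndarray) -> np.ndarray:
        ratio = np.asarray(ratio, dtype=float)
        return self.kd * self.beta * (ratio - self.rmin) / (self.rmax - ratio)


@dataclass
class CalibrationCurve:
    """Either a parametric conversion or a monotone empirical map."""

    mode: str  # "parametric" | "empirical"
    parametric: Optional[ParametricCalibration] = None
    points: Optional[List[Tuple[float, float]]] = None  # (calcium_nM, ratio)
    valid_range: Tuple[float, float] = (0.0, math.inf)  # in nM
    _interp: object = field(default=None, repr=False)

    @classmethod
    def from_parameters(cls, kd: float, rmin: float, rmax: float,
                        beta: float = 1.0) -> "CalibrationCurve":
        p = ParametricCalibration(kd=kd, rmin=rmin, rmax=rmax, beta=beta)
        return cls(mode="parametric", parametric=p)

    @property
    def ratio_range(self) -> Tuple[float, float]:
        if self.mode == "parametric":
            return (self.parametric.rmin, self.parametric.rmax)
        ratios = [r for _, r in self.points]
        return (min(ratios), max(ratios))


def build_calibration(points: Sequence[Tuple[float, float]]) -> CalibrationCurve:
    """Build an empirical calibration from (calcium_nM, ratio) points.

    Requires at least 3 points, strictly monotone in ratio; the fitted map
    is a monotone piecewise-cubic (PCHIP) interpolant.  Conversions outside
    the calibrated range are flagged by :func:`ratio_to_calcium`.
    """
    from scipy.interpolate import PchipInterpolator

    pts = sorted((float(ca), float(r)) for ca, r in points)
    if len(pts) < 3:
        raise ValueError("calibration needs at least 3 points")
    cas = np.array([p[0] for p in pts])
    ratios = np.array([p[1] for p in pts])
    d = np.diff(ratios)
    if np.any(d <= 0):
        raise ValueError("calibration points must be strictly monotone in ratio")
    interp = PchipInterpolator(ratios, cas)  # monotone-preserving
    return CalibrationCurve(
        mode="empirical",
        points=pts,
        valid_range=(float(cas.min()), float(cas.max())),
        _interp=interp,
    )


def ratio_to_calcium(
    ratio_trace: np.ndarray,
    curve: CalibrationCurve,
    smoothing_window: int = 3,
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Convert a ratio trace to calcium concentration (nM).

    Returns ``(ca_raw, ca_smoothed, flags)``.  In parametric mode ratios at
    or above Rmax are clipped just below it and flagged; in empirical mode
    ratios outside the calibrated range are flagged (the monotone map
    extrapolates).  The smoothed companion is a centered moving average
    (window 3 samples by default); the raw trace is always retained.
    """
    ratio = np.asarray(ratio_trace, dtype=float)
    flags: List[str] = []
    if curve.mode == "parametric":
        p = curve.parametric
        if np.any(ratio >= p.rmax):
            flags.append("ratio_clipped_at_rmax")
            eps = 1e-9 * (p.rmax - p.rmin)
            ratio = np.minimum(ratio, p.rmax - eps)
        if np.any(ratio < p.rmin):
            flags.append("ratio_below_rmin")
        ca = p.calcium_from_ratio(ratio)
    elif curve.mode == "empirical":
        lo, hi = curve.ratio_range
        if np.any((ratio < lo) | (ratio > hi)):
            flags.append("ratio_outside_calibrated_range")
        ca = np.asarray(curve._interp(ratio), dtype=float)
    else:
        raise ValueError(f"unknown calibration mode {curve.mode!r}")
    window = max(1, int(smoothing_window))
    kernel = np.ones(window) / window
    ca_smooth = np.convolve(ca, kernel, mode="same")
    return ca, ca_smooth, flags


def ratio_trace_from_channels(
    numerator: np.ndarray, denominator: np.ndarray
) -> np.ndarray:
    """Per-frame excitation ratio of a dual-channel acquisition.

    Scaling both channels by a common factor leaves the ratio unchanged.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("channel traces must have the same length")
    if np.any(den == 0):
        raise ValueError("denominator channel contains zeros")
    return num / den


def concentration_parameters(
    ca_trace: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    fps: float = 100.0,
    cell_id: int = 0,
):
    """Run the temporal analysis pipeline on a calcium-concentration trace.

    Returns a :class:`~catrace.transients.TransientResults` whose parameter
    record is in concentration units: ``f0`` is the baseline [Ca2+] (nM),
    ``fmax`` the peak [Ca2+] (nM) and ``magnitude`` the amplitude (nM).
    """
    from .transients import CalciumTransientModel

    config = config or AnalysisConfig()
    trace = FluorescenceTrace(values=np.asarray(ca_trace, dtype=float),
                              fps=fps, cell_id=cell_id)
    return CalciumTransientModel(trace, config=config).fit()


def read_calibration_points(path) -> List[Tuple[float, float]]:
    """Read a calibration-points CSV with columns calcium_nM, ratio."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    ca_col = cols.get("calcium_nm") or list(df.columns)[0]
    r_col = cols.get("ratio") or list(df.columns)[1]
    return list(zip(df[ca_col].astype(float), df[r_col].astype(float)))
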