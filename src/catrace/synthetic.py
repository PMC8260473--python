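"""Synthetic data with full ground truth for end-to-end testing.

The generator emulates paced cardiomyocyte calcium imaging with a
phenomenological transient waveform: each beat contributes

    g(t) = (1 - exp(-t / tau_on)) * exp(-t / tau_off),   t >= 0

normalized to unit peak, so a trace is
``baseline + magnitude * sum_k g(t - onset_k) / g_peak``.  The product of an
activation and a relaxation exponential reproduces the shape features the
analysis measures (fast sigmoidal upstroke, exponential decay with time
constant ~tau_off) without simulating membrane currents.  On top of the
clean waveform the generator can add white Gaussian noise scaled either to
the SD of the final 300 ms of the clean trace or to a target SNR, linear or
exponential baseline drift, EAD/DAD-like Gaussian bumps at controlled
phases, multi-cell image stacks (rod-shaped beating cells plus rounded
static dead cells), and dual-channel ratiometric pairs.

Ground-truth kinetic parameters are computed by brute-force dense-grid
evaluation of the continuous waveform (1000x oversampled), deliberately
sharing no interpolation code with the analysis modules, so they serve as an
independent oracle.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .extraction import FluorescenceTrace
from .io import ImageStack

DEFAULT_OVERSAMPLE = 1000


@dataclass
class WaveformSpec:
    """Conditions of one synthetic paced trace.

    Defaults describe a typical 1 Hz field-paced cardiomyocyte imaged at
    100 FPS: baseline 100 AU, transient magnitude 100 AU (Fmax/F0 ~ 2),
    activation time constant 15 ms (time to peak ~50 ms) and decay time
    constant 300 ms, with the first upstroke 100 ms into the recording.
    """

    pacing_hz: float = 1.0
    n_beats: int = 5
    fps: float = 100.0
    baseline: float = 100.0
    magnitude: float = 100.0
    tau_on: float = 15.0  # ms
    tau_off: float = 300.0  # ms
    latency_ms: float = 100.0
    seed: int = 0
    # virtual pre-recording beats so the trace starts at the steady-state
    # diastolic level rather than a cold-start pristine baseline; continuous
    # pacing reaches steady state long before a recording begins
    n_warmup_beats: int = 20

    def __post_init__(self) -> None:
        for name in ("pacing_hz", "n_beats", "fps", "baseline", "magnitude",
                     "tau_on", "tau_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.pacing_hz

    @property
    def duration_ms(self) -> float:
        return self.latency_ms + self.n_beats * self.cycle_ms

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_ms / 1000.0 * self.fps))

    @property
    def peak_delay_ms(self) -> float:
        """Closed-form time from beat onset to the waveform peak."""
        return self.tau_on * math.log(1.0 + self.tau_off / self.tau_on)

    @property
    def onset_times_ms(self) -> np.ndarray:
        return self.latency_ms + np.arange(self.n_beats) * self.cycle_ms

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "WaveformSpec":
        import yaml
        from pathlib import Path

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class DriftTruth:
    kind: str  # "linear" | "exponential"
    fraction: float
    baseline: float


@dataclass
class GroundTruth:
    """Everything a test needs to judge the analysis of a synthetic trace."""

    spec: WaveformSpec
    onset_times_ms: np.ndarray
    peak_times_ms: np.ndarray
    tau: float  # ms; the decay time constant of the waveform
    f0: float
    fmax: float
    fmax_over_f0: float
    t_on: float
    t10_on: float
    t50_on: float
    t90_on: float
    t_off: float
    t10_off: float
    t50_off: float
    t90_off: float
    cd: float
    tau_fit: float = math.nan  # ms; exponential best fit to the continuous decay
    injected_events: List[Tuple[int, str, float, float]] = field(default_factory=list)
    injected_drift: Optional[DriftTruth] = None
    target_snr: Optional[float] = None
    noise_sd: float = 0.0


def waveform_value(spec: WaveformSpec, t_ms: np.ndarray) -> np.ndarray:
    """The continuous noiseless waveform at times ``t_ms`` (milliseconds)."""
    t_ms = np.asarray(t_ms, dtype=float)
    g_peak = _unit_g(spec, spec.peak_delay_ms)
    out = np.full(t_ms.shape, spec.baseline, dtype=float)
    warmup = spec.latency_ms - np.arange(1, spec.n_warmup_beats + 1) * spec.cycle_ms
    for onset in np.concatenate([warmup, spec.onset_times_ms]):
        dt = t_ms - onset
        mask = dt > 0
        out[mask] += spec.magnitude * _unit_g(spec, dt[mask]) / g_peak
    return out


def _unit_g(spec: WaveformSpec, dt_ms) -> np.ndarray:
    dt_ms = np.asarray(dt_ms, dtype=float)
    return (1.0 - np.exp(-dt_ms / spec.tau_on)) * np.exp(-dt_ms / spec.tau_off)


# ---------------------------------------------------------------------------
# dense-grid oracle


_truth_cache: Dict[tuple, Dict[str, float]] = {}


def _dense_truth(spec: WaveformSpec,
                 onset_offset_fraction: float = 0.10,
                 baseline_window_fraction: float = 0.20,
                 baseline_redefine_fraction: float = 0.03) -> Dict[str, float]:
    """Brute-force kinetic parameters from the continuous waveform.

    Emulates the analysis definitions (segment window, tail-window baseline,
    redefined baseline, threshold crossings) on a dense time grid — an
    independent implementation used only as a test oracle.  Results are
    cached per waveform shape (the seed does not affect the clean waveform).
    """
    key = (spec.pacing_hz, spec.n_beats, spec.fps, spec.baseline,
           spec.magnitude, spec.tau_on, spec.tau_off, spec.latency_ms,
           spec.n_warmup_beats, onset_offset_fraction,
           baseline_window_fraction, baseline_redefine_fraction)
    if key in _truth_cache:
        return _truth_cache[key]
    cycle = spec.cycle_ms
    offset = onset_offset_fraction * cycle
    dt = cycle / (DEFAULT_OVERSAMPLE * max(1, round(spec.fps / spec.pacing_hz)))
    rel = np.arange(0.0, cycle, dt)
    acc = np.zeros_like(rel)
    for onset in spec.onset_times_ms:
        acc += waveform_value(spec, onset - offset + rel)
    seg = acc / spec.n_beats

    tail_n = max(1, int(round(baseline_window_fraction * cycle / dt)))
    f0 = float(seg[-tail_n:].mean())
    i_peak = int(np.argmax(seg))
    fmax = float(seg[i_peak])
    magnitude = fmax - f0
    redefined = f0 + baseline_redefine_fraction * magnitude
    m2 = fmax - redefined

    def cross_up(level: float, until: int) -> float:
        for i in range(until):
            if seg[i] < level <= seg[i + 1]:
                frac = (level - seg[i]) / (seg[i + 1] - seg[i])
                return (i + frac) * dt
        return 0.0 if seg[0] >= level else math.nan

    def cross_down(level: float, start: int) -> float:
        sub = seg[start:]
        hits = np.nonzero((sub[:-1] > level) & (sub[1:] <= level))[0]
        if hits.size == 0:
            return math.nan
        i = int(hits[0])
        frac = (sub[i] - level) / (sub[i] - sub[i + 1])
        return (i + frac) * dt

    t0 = cross_up(redefined, i_peak)
    peak_ms = i_peak * dt
    out = {
        "f0": f0,
        "fmax": fmax,
        "fmax_over_f0": fmax / f0,
        "t_on": peak_ms - t0,
        "t10_on": cross_up(redefined + 0.1 * m2, i_peak) - t0,
        "t50_on": cross_up(redefined + 0.5 * m2, i_peak) - t0,
        "t90_on": cross_up(redefined + 0.9 * m2, i_peak) - t0,
        "t10_off": cross_down(redefined + 0.9 * m2, i_peak),
        "t50_off": cross_down(redefined + 0.5 * m2, i_peak),
        "t90_off": cross_down(redefined + 0.1 * m2, i_peak),
        "t_off": cross_down(redefined, i_peak),
    }
    out["cd"] = out["t_on"] + out["t_off"]

    # measurement-level tau: the best-fit exponential to the continuous
    # decaying arm.  The product waveform's decay is only asymptotically
    # exponential (the activation term perturbs it near the peak), so the
    # oracle for a decay-arm fit is this fitted constant, which converges to
    # tau_off as tau_on -> 0.
    from scipy.optimize import curve_fit

    step = max(1, (seg.size - i_peak) // 4000)  # fit grid still ~0.25 ms dense
    t_dec = (np.arange(seg.size - i_peak) * dt)[::step]
    decay = seg[i_peak::step]
    try:
        popt, _ = curve_fit(
            lambda t, a, tau, c: a * np.exp(-t / tau) + c,
            t_dec, decay, p0=(m2, spec.tau_off, redefined), maxfev=10000,
        )
        out["tau_fit"] = float(popt[1])
    except (RuntimeError, ValueError):
        out["tau_fit"] = math.nan
    _truth_cache[key] = out
    return out


def make_transient_trace(spec: WaveformSpec) -> Tuple[FluorescenceTrace, GroundTruth]:
    """Sample a clean periodic paced trace and its dense-grid ground truth."""
    t_ms = np.arange(spec.n_frames) * 1000.0 / spec.fps
    values = waveform_value(spec, t_ms)
    trace = FluorescenceTrace(values=values, fps=spec.fps)
    d = _dense_truth(spec)
    truth = GroundTruth(
        spec=spec,
        onset_times_ms=spec.onset_times_ms.copy(),
        peak_times_ms=spec.onset_times_ms + spec.peak_delay_ms,
        tau=spec.tau_off,
        tau_fit=d["tau_fit"],
        f0=d["f0"], fmax=d["fmax"], fmax_over_f0=d["fmax_over_f0"],
        t_on=d["t_on"], t10_on=d["t10_on"], t50_on=d["t50_on"],
        t90_on=d["t90_on"], t_off=d["t_off"], t10_off=d["t10_off"],
        t50_off=d["t50_off"], t90_off=d["t90_off"], cd=d["cd"],
    )
    return trace, truth


# ---------------------------------------------------------------------------
# noise, drift, irregular events


def add_noise(
    trace: FluorescenceTrace,
    noise_sd_multiple: Optional[float] = None,
    target_snr: Optional[float] = None,
    seed: int = 0,
    truth: Optional[GroundTruth] = None,
) -> FluorescenceTrace:
    """Add white Gaussian noise to a clean trace.

    In multiple mode the noise SD is ``multiple x SD of the final 300 ms`` of
    the clean trace.  In SNR mode the SD is solved so the noisy trace hits
    the target under the pipeline's SNR definition (mean above-baseline
    signal over SD of below-baseline values).
    """
    if (noise_sd_multiple is None) == (target_snr is None):
        raise ValueError("specify exactly one of noise_sd_multiple / target_snr")
    v = trace.values
    rng = np.random.default_rng(seed)
    if noise_sd_multiple is not None:
        if noise_sd_multiple < 0:
            raise ValueError("noise multiple must be >= 0")
        if noise_sd_multiple == 0:
            return trace.with_values(v.copy())
        tail_n = max(2, int(round(0.300 * trace.fps)))
        if tail_n > len(v):
            raise ValueError("trace shorter than the 300 ms noise-reference tail")
        sd = noise_sd_multiple * float(np.std(v[-tail_n:]))
    else:
        f0 = truth.f0 if truth is not None else float(np.quantile(v, 0.25))
        above = v[v > f0]
        below = v[v < f0]
        signal = float(np.mean(above - f0)) if above.size else 0.0
        below_var = float(np.var(below)) if below.size else 0.0
        sd = math.sqrt(max((signal / target_snr) ** 2 - below_var, 1e-12))
        # the below-baseline population is re-selected on the noisy trace
        # (truncation shrinks its SD), so refine sd by fixed-point iteration
        # against the actual SNR definition; e is drawn once -> deterministic
        e = rng.standard_normal(v.shape)

        def measured(s: float) -> float:
            w = v + s * e
            ab, be = w[w > f0], w[w < f0]
            if not (ab.size and be.size and np.std(be) > 0):
                return math.inf
            return float(np.mean(ab - f0) / np.std(be))

        for _ in range(8):
            m = measured(sd)
            if not math.isfinite(m) or abs(m - target_snr) < 0.01 * target_snr:
                break
            sd = min(max(sd * m / target_snr, 1e-12), 10.0 * sd + 1e-9)
        out = trace.with_values(v + sd * e)
        if truth is not None:
            truth.noise_sd = sd
            truth.target_snr = target_snr
        return out
    out = trace.with_values(v + rng.normal(0.0, sd, size=v.shape))
    if truth is not None:
        truth.noise_sd = sd
        truth.target_snr = target_snr
    return out


def add_drift(
    trace: FluorescenceTrace,
    kind: str = "linear",
    fraction: float = 0.1,
    baseline: Optional[float] = None,
    truth: Optional[GroundTruth] = None,
) -> Tuple[FluorescenceTrace, DriftTruth]:
    """Scale the baseline component by a decay reaching ``1 - fraction`` at
    the trace end (transient amplitude is untouched, matching a subtractive
    correction model)."""
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("drift fraction must lie in [0, 0.5]")
    v = trace.values
    if baseline is None:
        baseline = truth.spec.baseline if truth is not None else float(np.min(v))
    n = len(v)
    x = np.arange(n) / max(1, n - 1)
    if kind == "linear":
        decay = 1.0 - fraction * x
    elif kind == "exponential":
        if fraction == 0.0:
            decay = np.ones(n)
        else:
            lam = -math.log(1.0 - fraction)
            decay = np.exp(-lam * x)
    else:
        raise ValueError(f"unknown drift kind {kind!r}")
    drift_truth = DriftTruth(kind=kind, fraction=fraction, baseline=baseline)
    out = trace.with_values(v + baseline * (decay - 1.0))
    if truth is not None:
        truth.injected_drift = drift_truth
    return out, drift_truth


def inject_irregularity(
    trace: FluorescenceTrace,
    events: Sequence[Tuple[int, str, float, float]],
    truth: GroundTruth,
    width_ms: float = 25.0,
) -> Tuple[FluorescenceTrace, GroundTruth]:
    """Add EAD/DAD-like Gaussian bumps at controlled phases.

    Each event is ``(beat, class, phase, amplitude)``: the bump is centered
    ``phase`` cycle-fractions after the beat's upstroke, with amplitude a
    fraction of the transient magnitude.  EAD phases must fall during the
    decay limb (before the waveform returns to the redefined baseline); DAD
    phases after the return but before the next onset.  A phase/class
    mismatch is an input error.
    """
    spec = truth.spec
    cycle = spec.cycle_ms
    v = trace.values.copy()
    t_ms = np.arange(len(v)) * 1000.0 / trace.fps
    decay_end = spec.peak_delay_ms + truth.t_off  # onset-relative, ms
    new_truth = replace(truth)
    new_truth.injected_events = list(truth.injected_events)
    for beat, cls, phase, amplitude in events:
        if not 0 <= beat < spec.n_beats:
            raise ValueError(f"beat {beat} outside 0..{spec.n_beats - 1}")
        center_rel = phase * cycle
        if cls == "EAD":
            if not (spec.peak_delay_ms < center_rel < decay_end):
                raise ValueError(
                    f"EAD phase {phase} is not on the decay limb "
                    f"(expected within ({spec.peak_delay_ms / cycle:.2f}, "
                    f"{decay_end / cycle:.2f}))"
                )
        elif cls == "DAD":
            if not (decay_end < center_rel < cycle):
                raise ValueError(
                    f"DAD phase {phase} is not post-decay "
                    f"(expected within ({decay_end / cycle:.2f}, 1))"
                )
        else:
            raise ValueError(f"unknown event class {cls!r}")
        center = truth.onset_times_ms[beat] + center_rel
        v += amplitude * spec.magnitude * np.exp(
            -0.5 * ((t_ms - center) / width_ms) ** 2
        )
        new_truth.injected_events.append((beat, cls, phase, amplitude))
    return trace.with_values(v), new_truth


# ---------------------------------------------------------------------------
# frequency-scaled families


def frequency_scaled_spec(pacing_hz: float, base: Optional[WaveformSpec] = None,
                          seed: int = 0) -> WaveformSpec:
    """A pacing-rate-dependent spec mirroring physiological rate adaptation.

    Higher pacing produces smaller, faster transients: magnitude scales as
    ``pacing^-0.3`` and the decay constant as ``pacing^-0.4`` relative to
    the 1 Hz defaults, so recovered CD, T_off, tau and Fmax/F0 decrease
    monotonically from 0.5 to 2 Hz.
    """
    base = base or WaveformSpec()
    s = 1.0 / pacing_hz
    return replace(
        base,
        pacing_hz=pacing_hz,
        magnitude=base.magnitude * s**0.3,
        tau_off=base.tau_off * s**0.4,
        tau_on=base.tau_on * s**0.15,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class CellSpec:
    center: Tuple[float, float]
    axes: Tuple[float, float]  # semi-axes in px (major, minor)
    angle_deg: float
    waveform: Optional[WaveformSpec] = None  # None -> static (dead) cell
    intensity: float = 1.0  # static intensity scale for dead cells


@dataclass
class FieldSpec:
    shape: Tuple[int, int] = (192, 192)
    background: float = 20.0
    noise_sd: float = 2.0
    n_frames: int = 50
    fps: float = 25.0


@dataclass
class StackTruth:
    label_image: np.ndarray  # live cells 1..n, 0 background
    dead_label_image: np.ndarray
    cells: List[CellSpec]
    overlap_warning: bool = False


def _ellipse_weight(shape, center, axes, angle_deg) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    th = math.radians(angle_deg)
    u = dx * math.cos(th) + dy * math.sin(th)
    w = -dx * math.sin(th) + dy * math.cos(th)
    rho = np.sqrt((u / axes[0]) ** 2 + (w / axes[1]) ** 2)
    # ~1 px anti-aliased rim
    edge = 1.0 / max(1.0, min(axes))
    return np.clip((1.0 - rho) / edge, 0.0, 1.0)


def make_image_stack(
    cells: Sequence[CellSpec],
    field_spec: Optional[FieldSpec] = None,
    seed: int = 0,
    max_overlap_fraction: float = 0.10,
) -> Tuple[ImageStack, StackTruth]:
    """Render a multi-cell field: beating rod-shaped cells whose interior
    follows their waveform, static rounded dead cells, constant background
    and per-pixel shot-like noise."""
    fs = field_spec or FieldSpec()
    rng = np.random.default_rng(seed)
    labels = np.zeros(fs.shape, dtype=int)
    dead_labels = np.zeros(fs.shape, dtype=int)
    weights = []
    overlap = False
    live_idx = dead_idx = 0
    for cell in cells:
        if not (0 <= cell.center[0] < fs.shape[0] and 0 <= cell.center[1] < fs.shape[1]):
            raise ValueError(f"cell center {cell.center} outside field {fs.shape}")
        w = _ellipse_weight(fs.shape, cell.center, cell.axes, cell.angle_deg)
        footprint = w > 0.5
        if cell.waveform is not None:
            live_idx += 1
            taken = labels > 0
            if (footprint & taken).sum() > max_overlap_fraction * footprint.sum():
                overlap = True
            labels[footprint] = live_idx
        else:
            dead_idx += 1
            dead_labels[footprint] = dead_idx
        weights.append(w)

    t_ms = np.arange(fs.n_frames) * 1000.0 / fs.fps
    frames = np.full((fs.n_frames, *fs.shape), fs.background, dtype=float)
    for cell, w in zip(cells, weights):
        if cell.waveform is not None:
            series = waveform_value(cell.waveform, t_ms)
        else:
            series = np.full(fs.n_frames, cell.intensity * 100.0)
        frames += w[None, :, :] * series[:, None, None]
    if fs.noise_sd > 0:
        frames += rng.normal(0.0, fs.noise_sd, size=frames.shape) * np.sqrt(
            np.maximum(frames, 1.0) / max(fs.background, 1.0)
        )
    frames = np.clip(frames, 0, 65535).astype(np.uint16)
    stack = ImageStack(frames=frames, fps=fs.fps, pixel_depth=16)
    truth = StackTruth(label_image=labels, dead_label_image=dead_labels,
                       cells=list(cells), overlap_warning=overlap)
    return stack, truth


def random_field(
    n_live: int,
    n_dead: int,
    seed: int = 0,
    field_spec: Optional[FieldSpec] = None,
    waveform: Optional[WaveformSpec] = None,
    live_axes: Tuple[float, float] = (24.0, 6.0),
    dead_radius: float = 10.0,
    min_separation: float = 40.0,
) -> List[CellSpec]:
    """Place rod-shaped live cells and rounded dead cells with limited
    footprint overlap (rejection sampling on center separation)."""
    fs = field_spec or FieldSpec()
    wf = waveform or WaveformSpec(fps=fs.fps, n_beats=3,
                                  latency_ms=100.0)
    rng = np.random.default_rng(seed)
    centers: List[Tuple[float, float]] = []
    margin = live_axes[0] + 2
    cells: List[CellSpec] = []
    kinds = ["live"] * n_live + ["dead"] * n_dead
    for kind in kinds:
        for _ in range(500):
            c = (rng.uniform(margin, fs.shape[0] - margin),
                 rng.uniform(margin, fs.shape[1] - margin))
            if all(math.hypot(c[0] - p[0], c[1] - p[1]) >= min_separation
                   for p in centers):
                centers.append(c)
                break
        else:
            raise ValueError("could not place cells without excessive overlap")
        if kind == "live":
            jitter = replace(wf, latency_ms=wf.latency_ms + rng.uniform(0, 40),
                             magnitude=wf.magnitude * rng.uniform(0.8, 1.2))
            cells.append(CellSpec(center=c, axes=live_axes,
                                  angle_deg=rng.uniform(0, 180), waveform=jitter))
        else:
            cells.append(CellSpec(center=c, axes=(dead_radius, dead_radius),
                                  angle_deg=0.0, waveform=None,
                                  intensity=rng.uniform(0.5, 1.0)))
    return cells


# ---------------------------------------------------------------------------
# ratiometric pairs


def make_ratiometric_pair(
    ca_waveform_nm: np.ndarray,
    curve,
    seed: int = 0,
    gains: Tuple[float, float] = (1.0, 1.0),
    base_intensity: float = 1000.0,
    noise_sd: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Forward-convert a calcium waveform (nM) to a dual-channel pair whose
    per-frame ratio maps back to the waveform through the calibration."""
    ca = np.asarray(ca_waveform_nm, dtype=float)
    if curve.mode == "parametric":
        p = curve.parametric
        if np.any(ca < 0):
            raise ValueError("calcium concentrations must be non-negative")
        ratio = p.ratio_from_calcium(ca)
    else:
        lo, hi = curve.valid_range
        if np.any((ca < lo) | (ca > hi)):
            raise ValueError("calcium outside the calibrated range")
        from scipy.interpolate import PchipInterpolator

        cas = np.array([p_[0] for p_ in curve.points])
        ratios = np.array([p_[1] for p_ in curve.points])
        ratio = PchipInterpolator(cas, ratios)(ca)
    rng = np.random.default_rng(seed)
    # a common optical gain multiplies both channels and cancels in the ratio;
    # unequal channel gains rescale the ratio and must match the calibration
    den = np.full(ca.shape, base_intensity * gains[1])
    num = ratio * base_intensity * gains[0]
    if noise_sd > 0:
        num = num + rng.normal(0.0, noise_sd, size=ca.shape)
        den = den + rng.normal(0.0, noise_sd, size=ca.shape)
    return num, den
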