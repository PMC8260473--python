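"""Irregular-beat detection and classification.

Traces that do not adhere to the stated pacing frequency (more transients
detected than pacing justifies) are reported as non-adherent.  Within each
beat, secondary positive deflections passing a dual prominence criterion —
at least 10% of the recalculated transient magnitude and at least 3x the
below-baseline noise SD — are classified by phase: during the decay limb,
before the trace has returned to the redefined baseline, they are
early-afterdepolarization-like (EAD); after the return to baseline but
before the next onset they are delayed-afterdepolarization-like (DAD).
Contaminated beats are excluded in full and the regular subset re-analyzed;
detection requires a high signal-to-noise ratio and is skipped (with a
quality flag) on traces below the SNR warning threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .extraction import FluorescenceTrace


@dataclass
class AberrationEvent:
    cell_id: int
    beat_index: int
    event_class: str  # "EAD" | "DAD" | "non_adherent"
    frame_index: int = -1  # index within the parent trace


@dataclass
class IrregularityReport:
    """Per-cell counts and classifications of irregular beats."""

    cell_id: int = 0
    n_total_beats: int = 0
    n_irregular: int = 0
    n_excluded: int = 0
    events: List[AberrationEvent] = field(default_factory=list)
    beat_to_beat_ms: float = math.nan
    n_intervals: int = 0
    adheres_to_pacing: bool = True
    flags: List[str] = field(default_factory=list)


def check_pacing_adherence(peaks, config: AnalysisConfig, duration_s: float) -> bool:
    """A trace adheres to pacing when the number of detected onsets does not
    exceed what the pacing frequency justifies (tolerance one extra beat)."""
    n = peaks.n_onsets
    if n == 0:
        return False
    return n <= math.ceil(config.pacing_hz * duration_s) + 1


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")[: len(values)]


def _mean_template(segments: Sequence, exclude=frozenset()) -> np.ndarray:
    used = [s for s in segments if s.beat_index not in exclude] or list(segments)
    length = min(len(s.values) for s in used)
    return np.stack([s.values[:length] for s in used]).mean(axis=0)


def _detect_pass(
    segments: Sequence,
    template: np.ndarray,
    params_context,
    config: AnalysisConfig,
    cell_id: int,
) -> List[AberrationEvent]:
    redefined = params_context.redefined_baseline
    m2 = params_context.fmax - redefined
    peak_rel = int(np.argmax(template))
    post = template[peak_rel:]
    returned = np.nonzero(post <= redefined)[0]
    return_rel = peak_rel + int(returned[0]) if returned.size else len(template)
    n_t = len(template)

    events: List[AberrationEvent] = []
    for seg in segments:
        v = np.asarray(seg.values, dtype=float)
        # residual against the periodically extended mean transient cancels
        # the beat shape, so bump amplitude is slope-free
        resid = v - template[np.arange(len(v)) % n_t]
        resid = _smooth(resid, config.smoothing_window)
        mad = float(np.median(np.abs(resid - np.median(resid))))
        noise_sd = 1.4826 * mad
        threshold = max(
            config.aberration_magnitude_fraction * m2,
            config.aberration_noise_multiple * noise_sd,
        )
        cand, _ = sps.find_peaks(resid, prominence=threshold)
        for idx in cand:
            # the upstroke region carries segmentation-jitter spikes, not
            # afterdepolarization-like deflections
            if peak_rel - 5 <= idx <= peak_rel + 2:
                continue
            if idx < peak_rel:
                if seg.beat_index == 0:
                    continue  # pre-stimulus head of the first beat
                events.append(AberrationEvent(cell_id, seg.beat_index - 1,
                                              "DAD", seg.start_frame + idx))
                continue
            cls = "EAD" if idx <= return_rel else "DAD"
            events.append(AberrationEvent(cell_id, seg.beat_index, cls,
                                          seg.start_frame + idx))
    return events


def detect_aberrations(
    segments: Sequence,
    params_context,
    config: AnalysisConfig,
    snr: float = math.inf,
    cell_id: int = 0,
) -> List[AberrationEvent]:
    """Find and classify EAD/DAD-like secondary deflections in each beat.

    Each beat is compared against the mean transient of the trace; positive
    residual deflections passing the dual criterion (>= 10% of the
    recalculated magnitude and >= 3x the residual noise SD) are events.
    Events on the decay limb before the mean transient has returned to the
    redefined baseline are EAD-like; later ones (through the diastolic
    interval, including the next segment's pre-upstroke head) are DAD-like.
    A second pass with the template rebuilt from uncontaminated beats
    confirms the events.  ``params_context`` supplies the magnitude and
    redefined baseline from a preliminary whole-trace analysis.  Detection
    is skipped (with a quality flag) when the trace SNR is below the
    warning threshold.
    """
    if math.isfinite(snr) and snr < config.snr_warn_threshold:
        params_context.flags.append("aberration_detection_skipped_low_snr")
        return []
    m2 = params_context.fmax - params_context.redefined_baseline
    if not (math.isfinite(m2) and m2 > 0):
        return []
    template = _mean_template(segments)
    events = _detect_pass(segments, template, params_context, config, cell_id)
    if events:
        contaminated = {e.beat_index for e in events}
        template = _mean_template(segments, exclude=contaminated)
        events = _detect_pass(segments, template, params_context, config,
                              cell_id)
    return events


def analyze_regular_subset(
    trace: FluorescenceTrace,
    events: Sequence[AberrationEvent],
    config: Optional[AnalysisConfig] = None,
) -> Tuple["TransientParameters", IrregularityReport]:
    """Compute parameters on the regular beats only, excluding every beat
    that contains an aberration, and report all counts and classifications.

    With no regular beat remaining the parameters are flagged missing and
    only the report is meaningful.
    """
    from .transients import (TransientParameters, average_transient,
                             compute_parameters, detect_onsets, fit_tau,
                             segment_transients)
    from .extraction import signal_to_noise

    config = config or AnalysisConfig()
    peaks = detect_onsets(trace, config)
    report = IrregularityReport(cell_id=trace.cell_id, events=list(events))
    if peaks.n_onsets == 0:
        report.adheres_to_pacing = False
        report.flags.append("empty_trace")
        rec = TransientParameters(cell_id=trace.cell_id)
        rec.flags.append("no_onsets")
        return rec, report
    segments = segment_transients(trace, peaks, config)
    onsets = np.sort(peaks.peak_indices)
    intervals = np.diff(onsets) * 1000.0 / trace.fps
    report.n_total_beats = len(segments)
    report.beat_to_beat_ms = float(np.mean(intervals)) if intervals.size else math.nan
    report.n_intervals = int(intervals.size)
    report.adheres_to_pacing = check_pacing_adherence(peaks, config,
                                                      trace.duration_s)
    excluded = {ev.beat_index for ev in events}
    report.n_irregular = len(excluded & {s.beat_index for s in segments})
    regular = [s for s in segments if s.beat_index not in excluded]
    report.n_excluded = len(segments) - len(regular)
    if not regular:
        rec = TransientParameters(cell_id=trace.cell_id)
        rec.flags.append("no_regular_beats")
        return rec, report
    avg = average_transient(regular, trace.fps)
    rec = compute_parameters(avg, config, trace.fps, cell_id=trace.cell_id)
    if not rec.is_flagged or "multi_crossing" in rec.flags:
        fit_tau(avg, rec, trace.fps)
    if math.isfinite(rec.f0):
        rec.snr = signal_to_noise(trace, rec.f0)
    rec.beat_to_beat_ms = report.beat_to_beat_ms
    rec.n_intervals = report.n_intervals
    rec.n_beats = avg.n_beats
    return rec, report
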