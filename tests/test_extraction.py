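import math

import numpy as np
import pytest

import catrace as ct
from catrace.segmentation import CellMask, CellProps
from catrace.synthetic import CellSpec, FieldSpec


def _tiny_mask():
    label = np.zeros((4, 4), dtype=int)
    label[1, 1:4] = 1
    props = [CellProps(label=1, area_px=3, eccentricity=0.9,
                       bbox=(1, 1, 2, 4), accepted=True)]
    return CellMask(label_image=label, per_cell_props=props)


class TestExtractTrace:
    def test_hand_sum(self):
        frames = np.zeros((2, 4, 4))
        frames[0, 1, 1:4] = [1, 2, 3]
        frames[1, 1, 1:4] = [2, 2, 2]
        stack = ct.ImageStack(frames=frames, fps=25.0)
        trace = ct.extract_trace(stack, _tiny_mask(), 1)
        np.testing.assert_allclose(trace.values, [6.0, 6.0])

    def test_all_zero_frames(self):
        stack = ct.ImageStack(frames=np.zeros((3, 4, 4)), fps=25.0)
        trace = ct.extract_trace(stack, _tiny_mask(), 1)
        np.testing.assert_allclose(trace.values, 0.0)

    def test_rejected_cell_is_input_error(self):
        mask = _tiny_mask()
        mask.per_cell_props[0].accepted = False
        mask.per_cell_props[0].rejection_reason = "non_elongated"
        stack = ct.ImageStack(frames=np.zeros((3, 4, 4)), fps=25.0)
        with pytest.raises(ValueError, match="rejected"):
            ct.extract_trace(stack, mask, 1)
        with pytest.raises(ValueError, match="not present"):
            ct.extract_trace(stack, mask, 9)

    def test_linearity_under_intensity_scaling(self):
        rng = np.random.default_rng(0)
        frames = rng.random((6, 4, 4))
        stack = ct.ImageStack(frames=frames, fps=25.0)
        scaled = ct.ImageStack(frames=3.5 * frames, fps=25.0)
        t1 = ct.extract_trace(stack, _tiny_mask(), 1)
        t2 = ct.extract_trace(scaled, _tiny_mask(), 1)
        np.testing.assert_allclose(t2.values, 3.5 * t1.values)

    def test_trace_maxima_match_generator_peaks(self):
        fs = FieldSpec(shape=(64, 64), noise_sd=0.0, n_frames=75, fps=25.0)
        wf = ct.WaveformSpec(fps=25.0, n_beats=2, latency_ms=200.0)
        cell = CellSpec(center=(32, 32), axes=(20, 6), angle_deg=0, waveform=wf)
        stack, truth = ct.make_image_stack([cell], fs, seed=0)
        mask = ct.segment_cells(ct.average_frame(stack), "multi")
        trace = ct.extract_trace(stack, mask, mask.accepted_ids[0])
        peak_frames = np.round(
            (wf.onset_times_ms + wf.peak_delay_ms) * fs.fps / 1000.0)
        for pf in peak_frames:
            lo, hi = int(pf) - 2, int(pf) + 3
            local = lo + np.argmax(trace.values[lo:hi])
            assert abs(local - pf) <= 1


class TestBackgroundSubtraction:
    def _stack_pair(self, bg=5.0):
        fs = FieldSpec(shape=(64, 64), noise_sd=0.0, n_frames=30, fps=25.0,
                       background=0.0)
        wf = ct.WaveformSpec(fps=25.0, n_beats=1, latency_ms=100.0)
        cell = CellSpec(center=(32, 32), axes=(20, 6), angle_deg=0, waveform=wf)
        stack0, _ = ct.make_image_stack([cell], fs, seed=0)
        lifted = ct.ImageStack(frames=stack0.frames.astype(float) + bg,
                               fps=fs.fps)
        return stack0, lifted

    def test_uniform_background_removed(self):
        stack0, lifted = self._stack_pair(bg=5.0)
        mask = ct.segment_cells(ct.average_frame(lifted), "multi")
        cid = mask.accepted_ids[0]
        plain = ct.extract_trace(stack0, mask, cid)
        corrected = ct.subtract_background(
            ct.extract_trace(lifted, mask, cid), lifted, mask)
        assert corrected.background_subtracted
        np.testing.assert_allclose(corrected.values, plain.values,
                                   rtol=1e-6, atol=1e-6)

    def test_zero_background_is_identity(self):
        stack0, _ = self._stack_pair()
        mask = ct.segment_cells(ct.average_frame(stack0), "multi")
        cid = mask.accepted_ids[0]
        plain = ct.extract_trace(stack0, mask, cid)
        corrected = ct.subtract_background(plain, stack0, mask)
        np.testing.assert_allclose(corrected.values, plain.values, atol=1e-9)

    def test_commutes_with_extraction(self):
        stack0, lifted = self._stack_pair(bg=7.0)
        mask = ct.segment_cells(ct.average_frame(lifted), "multi")
        cid = mask.accepted_ids[0]
        # subtract constant image from frames, then extract
        pre = ct.ImageStack(frames=lifted.frames.astype(float) - 7.0,
                            fps=lifted.fps)
        route_a = ct.extract_trace(pre, mask, cid)
        # extract, then subtract estimated background
        route_b = ct.subtract_background(
            ct.extract_trace(lifted, mask, cid), lifted, mask)
        np.testing.assert_allclose(route_a.values, route_b.values,
                                   rtol=1e-6, atol=1e-6)

    def test_full_frame_mask_is_error(self, clean_trace):
        trace, _ = clean_trace
        label = np.ones((4, 4), dtype=int)
        mask = CellMask(label_image=label, per_cell_props=[
            CellProps(label=1, area_px=16, eccentricity=0.9,
                      bbox=(0, 0, 4, 4), accepted=True)])
        stack = ct.ImageStack(frames=np.zeros((3, 4, 4)), fps=25.0)
        with pytest.raises(ValueError, match="background"):
            ct.subtract_background(trace, stack, mask)


class TestSignalToNoise:
    def test_direct_formula(self):
        values = np.array([10.0] * 5 + [-1.0, -5.0, -1.0, -5.0])
        trace = ct.FluorescenceTrace(values=values, fps=25.0)
        assert ct.signal_to_noise(trace, 0.0) == pytest.approx(5.0)

    def test_noiseless_flat_baseline_gives_infinity(self):
        values = np.array([0.0] * 10 + [5.0, 10.0, 5.0] + [0.0] * 10)
        trace = ct.FluorescenceTrace(values=values, fps=25.0)
        snr = ct.signal_to_noise(trace, 1.0)
        assert math.isinf(snr)
        assert "snr_noiseless" in trace.flags

    def test_generator_hits_target_snr(self):
        trace, truth = ct.make_transient_trace(ct.WaveformSpec(seed=4))
        noisy = ct.add_noise(trace, target_snr=20.0, seed=4, truth=truth)
        res = ct.analyze_cell(noisy, ct.AnalysisConfig())
        assert res.params.snr == pytest.approx(20.0, rel=0.25)
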