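import numpy as np
import pytest

import catrace as ct
from catrace.synthetic import CellSpec, FieldSpec


def _field(seed=0, n_live=5, n_dead=3):
    fs = FieldSpec()
    cells = ct.random_field(n_live, n_dead, seed=seed, field_spec=fs)
    stack, truth = ct.make_image_stack(cells, fs, seed=seed)
    return stack, truth


class TestAverageFrame:
    def test_identical_frames_identity(self):
        frame = np.arange(16, dtype=float).reshape(4, 4)
        stack = ct.ImageStack(frames=np.stack([frame] * 3), fps=25.0)
        np.testing.assert_allclose(ct.average_frame(stack), frame)

    def test_two_frame_mean(self):
        stack = ct.ImageStack(
            frames=np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)]), fps=25.0
        )
        np.testing.assert_allclose(ct.average_frame(stack), np.ones((4, 4)))

    def test_cell_footprint_brighter_than_background(self):
        stack, truth = _field(seed=3)
        mean = ct.average_frame(stack)
        inside = mean[truth.label_image > 0].mean()
        outside = mean[(truth.label_image == 0) & (truth.dead_label_image == 0)].mean()
        assert inside > 2 * outside


class TestSegmentCells:
    def test_single_ellipse_found_with_good_overlap(self):
        fs = FieldSpec(shape=(96, 96))
        cell = CellSpec(center=(48, 48), axes=(24, 6), angle_deg=30,
                        waveform=ct.WaveformSpec(fps=fs.fps, n_beats=2))
        stack, truth = ct.make_image_stack([cell], fs, seed=0)
        mask = ct.segment_cells(ct.average_frame(stack), "multi")
        assert len(mask.accepted_ids) == 1
        found = mask.label_image == mask.accepted_ids[0]
        true = truth.label_image == 1
        jaccard = (found & true).sum() / (found | true).sum()
        assert jaccard >= 0.8

    def test_rods_accepted_circles_rejected(self):
        stack, truth = _field(seed=1)
        mask = ct.segment_cells(ct.average_frame(stack), "multi")
        assert len(mask.accepted_ids) == 5
        # every accepted region overlaps a true live cell, none a dead cell
        for label in mask.accepted_ids:
            region = mask.label_image == label
            assert truth.label_image[region].max() > 0
            live_frac = (truth.label_image[region] > 0).mean()
            dead_frac = (truth.dead_label_image[region] > 0).mean()
            assert live_frac > dead_frac

    def test_constant_image_gives_empty_diagnostic(self):
        mask = ct.segment_cells(np.full((32, 32), 7.0), "multi")
        assert mask.is_empty
        assert "constant" in mask.diagnostic

    def test_single_mode_largest_component(self):
        fs = FieldSpec(shape=(96, 96))
        cell = CellSpec(center=(40, 48), axes=(30, 12), angle_deg=0,
                        waveform=ct.WaveformSpec(fps=fs.fps, n_beats=2))
        stack, truth = ct.make_image_stack([cell], fs, seed=0)
        mask = ct.segment_cells(ct.average_frame(stack), "single")
        assert mask.accepted_ids == [1]
        found = mask.label_image == 1
        true = truth.label_image == 1
        assert (found & true).sum() / (found | true).sum() >= 0.7


class TestReviewMask:
    def _mask(self):
        stack, _ = _field(seed=2)
        return ct.segment_cells(ct.average_frame(stack), "multi")

    def test_empty_exclusion_is_identity(self):
        mask = self._mask()
        out = ct.review_mask(mask, [])
        assert out.accepted_ids == mask.accepted_ids
        np.testing.assert_array_equal(out.label_image, mask.label_image)

    def test_exclusion_marks_user_reason_and_keeps_labels(self):
        mask = self._mask()
        victim = mask.accepted_ids[1]
        out = ct.review_mask(mask, [victim])
        assert victim not in out.accepted_ids
        assert out.get(victim).rejection_reason == "user"
        assert len(out.accepted_ids) == len(mask.accepted_ids) - 1
        # identity map preserved for the others
        assert out.accepted_ids == [l for l in mask.accepted_ids if l != victim]

    def test_exclude_all_gives_empty_accepted_set(self):
        mask = self._mask()
        out = ct.review_mask(mask, [p.label for p in mask.per_cell_props])
        assert out.accepted_ids == []

    def test_unknown_label_rejected(self):
        mask = self._mask()
        with pytest.raises(ValueError, match="unknown"):
            ct.review_mask(mask, [999])


def test_label_image_export_round_trip(tmp_path):
    import tifffile

    stack, _ = _field(seed=4)
    mask = ct.segment_cells(ct.average_frame(stack), "multi")
    from catrace.segmentation import export_label_image

    export_label_image(mask, tmp_path / "labels.tif")
    back = tifffile.imread(tmp_path / "labels.tif")
    np.testing.assert_array_equal(back, mask.label_image.astype(np.uint16))


def test_overlap_monotonicity_of_false_positives():
    """Tighter cell packing never decreases merged/false-positive regions."""
    fps_counts = []
    for sep in (60.0, 40.0, 26.0):
        fs = FieldSpec(shape=(224, 224))
        cells = ct.random_field(6, 0, seed=7, field_spec=fs, min_separation=sep)
        stack, truth = ct.make_image_stack(cells, fs, seed=7)
        mask = ct.segment_cells(ct.average_frame(stack), "multi")
        # a false positive here: an accepted region spanning >1 true cell
        n_fp = 0
        for label in mask.accepted_ids:
            covered = set(np.unique(truth.label_image[mask.label_image == label]))
            covered.discard(0)
            if len(covered) > 1:
                n_fp += 1
        fps_counts.append(n_fp)
    assert fps_counts == sorted(fps_counts)
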