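"""Analysis configuration shared by every pipeline stage.

The defaults encode the pipeline's core conventions: the transient onset
offset is 10% of the pacing cycle length (100 ms at 1 Hz), the resting
baseline is averaged over the final 20% of the cycle (200 ms at 1 Hz),
onset candidates must reach 50% of the maximum difference-array peak
prominence, and the working baseline is redefined upward by 3% of the
transient magnitude so that interpolated timing parameters are robust to
end-of-trace baseline sag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml


class PhotobleachMode(str, Enum):
    """Whether baseline-drift correction is skipped, automatic, or forced."""

    OFF = "off"
    AUTO = "auto"
    FORCE = "force"


@dataclass
class SegmentationSettings:
    """Tunables for multi-cell mask construction.

    Difference-of-Gaussians sigmas bracket the cell-boundary scale;
    the elongation filter rejects rounded (dead) cells.
    """

    dog_sigma_small: float = 2.0
    dog_sigma_large: float = 20.0
    clahe_clip_limit: float = 0.01
    clahe_tiles: int = 8
    morph_radius: int = 3
    min_eccentricity: float = 0.75
    min_area_px: int = 200
    merge_area_factor: float = 3.0


@dataclass
class AnalysisConfig:
    """Per-run analysis parameters.

    All fractions are of the pacing cycle length and must lie in (0, 1).
    """

    pacing_hz: float = 1.0
    onset_offset_fraction: float = 0.10
    baseline_window_fraction: float = 0.20
    baseline_redefine_fraction: float = 0.03
    prominence_fraction: float = 0.50
    photobleach_correct: PhotobleachMode = PhotobleachMode.AUTO
    per_beat_output: bool = False
    ratiometric: bool = False
    downsample_target_fps: float = 100.0
    snr_warn_threshold: float = 15.0
    random_seed: int = 0
    # irregular-beat detection thresholds (fractions of recalculated magnitude
    # and multiples of the below-baseline noise SD)
    aberration_magnitude_fraction: float = 0.10
    aberration_noise_multiple: float = 3.0
    # auto photobleach correction triggers above this |trend change|/baseline
    drift_auto_threshold: float = 0.03
    smoothing_window: int = 3
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    channel_index: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.photobleach_correct, str):
            self.photobleach_correct = PhotobleachMode(self.photobleach_correct)
        for name in (
            "onset_offset_fraction",
            "baseline_window_fraction",
            "baseline_redefine_fraction",
            "prominence_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.pacing_hz <= 0:
            raise ValueError(f"pacing_hz must be positive, got {self.pacing_hz}")

    # -- derived anchors -------------------------------------------------
    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.pacing_hz

    @property
    def onset_offset_ms(self) -> float:
        """Offset subtracted from each detected onset (10% of the cycle)."""
        return self.onset_offset_fraction * self.cycle_length_ms

    @property
    def baseline_window_ms(self) -> float:
        """Tail window used to estimate the baseline (20% of the cycle)."""
        return self.baseline_window_fraction * self.cycle_length_ms

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["photobleach_correct"] = self.photobleach_correct.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        seg = d.pop("segmentation", None)
        cfg = cls(**d)
        if seg is not None:
            cfg.segmentation = SegmentationSettings(**seg)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
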