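"""Cell-mask construction from the time-averaged frame.

The mask is computed once from the pixelwise mean over all frames and then
applied unchanged to every frame.  For multi-cell (low magnification) fields
the mean image is contrast-enhanced with a difference-of-Gaussians filter
followed by contrast-limited adaptive histogram equalization, binarized,
cleaned by erosion-dilation, and labeled; rounded (dead) cells are rejected
by an elongation filter, since viable cardiomyocytes are rod-shaped.  For
single-cell (high magnification) fields the whole-cell footprint is the
largest thresholded component, with no elongation filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
from skimage import exposure, filters, measure, morphology

from .config import SegmentationSettings
from .io import ImageStack


@dataclass
class CellProps:
    label: int
    area_px: int
    eccentricity: float
    bbox: tuple
    accepted: bool
    rejection_reason: str = ""


@dataclass
class CellMask:
    """Labeled per-cell pixel regions (0 = background, k = cell k)."""

    label_image: np.ndarray
    per_cell_props: List[CellProps] = field(default_factory=list)
    diagnostic: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.per_cell_props)

    @property
    def accepted_ids(self) -> List[int]:
        return [p.label for p in self.per_cell_props if p.accepted]

    def get(self, label: int) -> Optional[CellProps]:
        for p in self.per_cell_props:
            if p.label == label:
                return p
        return None

    @property
    def is_empty(self) -> bool:
        return not self.accepted_ids


def average_frame(stack: ImageStack) -> np.ndarray:
    """Pixelwise mean over all frames (floating point)."""
    return stack.frames.mean(axis=0, dtype=float)


def _label_regions(binary: np.ndarray) -> np.ndarray:
    return measure.label(binary, connectivity=2)


def segment_cells(
    mean_image: np.ndarray,
    mode: str = "multi",
    params: Optional[SegmentationSettings] = None,
) -> CellMask:
    """Build a CellMask from the time-averaged frame.

    In ``multi`` mode, regions failing the elongation filter
    (eccentricity below the threshold) are kept in the label image but
    marked rejected as non-elongated; undersized regions and area outliers
    (possible merged/overlapping cells) are rejected likewise.  An image on
    which no region survives yields an empty mask with a diagnostic, never
    an exception.
    """
    params = params or SegmentationSettings()
    mean_image = np.asarray(mean_image, dtype=float)
    if not np.all(np.isfinite(mean_image)):
        raise ValueError("mean image contains non-finite values")
    if mean_image.max() == mean_image.min():
        return CellMask(
            label_image=np.zeros(mean_image.shape, dtype=int),
            diagnostic="constant image: no cells detected",
        )

    if mode == "single":
        binary = _threshold(mean_image)
        labels = _label_regions(binary)
        if labels.max() == 0:
            return CellMask(
                label_image=labels, diagnostic="no region above threshold"
            )
        regions = measure.regionprops(labels)
        largest = max(regions, key=lambda r: r.area)
        out = np.where(labels == largest.label, 1, 0)
        props = [
            CellProps(
                label=1,
                area_px=int(largest.area),
                eccentricity=float(largest.eccentricity),
                bbox=tuple(largest.bbox),
                accepted=True,
            )
        ]
        return CellMask(label_image=out, per_cell_props=props)

    if mode != "multi":
        raise ValueError(f"unknown segmentation mode {mode!r}")

    enhanced = filters.difference_of_gaussians(
        mean_image, params.dog_sigma_small, params.dog_sigma_large
    )
    rescaled = exposure.rescale_intensity(enhanced, out_range=(0.0, 1.0))
    tile = max(8, min(rescaled.shape) // params.clahe_tiles)
    equalized = exposure.equalize_adapthist(
        rescaled, kernel_size=tile, clip_limit=params.clahe_clip_limit
    )
    binary = _threshold(equalized)
    selem = morphology.disk(params.morph_radius)
    binary = morphology.dilation(morphology.erosion(binary, selem), selem)
    labels = _label_regions(binary)
    if labels.max() == 0:
        return CellMask(label_image=labels, diagnostic="no region survived filtering")

    regions = measure.regionprops(labels)
    # a region must also stand out from the background in the raw mean image;
    # equalization can promote pure-noise texture on empty fields
    bg_pixels = mean_image[labels == 0]
    bg_mean, bg_sd = float(bg_pixels.mean()), float(bg_pixels.std())
    areas = []
    props: List[CellProps] = []
    for r in regions:
        accepted = True
        reason = ""
        region_mean = float(mean_image[labels == r.label].mean())
        if r.area < params.min_area_px:
            accepted, reason = False, "too_small"
        elif r.eccentricity < params.min_eccentricity:
            accepted, reason = False, "non_elongated"
        elif region_mean < bg_mean + 2.0 * bg_sd:
            accepted, reason = False, "low_contrast"
        props.append(
            CellProps(
                label=int(r.label),
                area_px=int(r.area),
                eccentricity=float(r.eccentricity),
                bbox=tuple(r.bbox),
                accepted=accepted,
                rejection_reason=reason,
            )
        )
        if accepted:
            areas.append(r.area)
    # overlapping/touching cells are not split; flag area outliers instead
    if areas:
        median_area = float(np.median(areas))
        for p in props:
            if p.accepted and p.area_px > params.merge_area_factor * median_area:
                p.accepted = False
                p.rejection_reason = "possible_merge"
    mask = CellMask(label_image=labels, per_cell_props=props)
    if mask.is_empty:
        mask.diagnostic = "no region survived filtering"
    return mask


def _threshold(image: np.ndarray) -> np.ndarray:
    return image > filters.threshold_otsu(image)


def review_mask(mask: CellMask, exclusions: Sequence[int]) -> CellMask:
    """Apply user-review exclusions, marking labels rejected with reason 'user'.

    The identity map for remaining cells is preserved (no relabeling).
    """
    known = {p.label for p in mask.per_cell_props}
    unknown = [x for x in exclusions if x not in known]
    if unknown:
        raise ValueError(f"unknown cell labels in exclusion list: {unknown}")
    new_props = []
    for p in mask.per_cell_props:
        if p.label in exclusions:
            new_props.append(replace(p, accepted=False, rejection_reason="user"))
        else:
            new_props.append(replace(p))
    return CellMask(
        label_image=mask.label_image.copy(),
        per_cell_props=new_props,
        diagnostic=mask.diagnostic,
    )


def export_label_image(mask: CellMask, path) -> None:
    """Write the label image as a TIFF for external review tools."""
    import tifffile

    tifffile.imwrite(path, mask.label_image.astype(np.uint16))


def export_mask_overlay(
    mask: CellMask, mean_image: np.ndarray, path
) -> None:
    """Write a PNG of the mean image with accepted/rejected outlines for review."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(mean_image, cmap="gray")
    for p in mask.per_cell_props:
        contours = measure.find_contours(mask.label_image == p.label, 0.5)
        color = "lime" if p.accepted else "red"
        for c in contours:
            ax.plot(c[:, 1], c[:, 0], color=color, lw=1)
        r0, c0 = p.bbox[0], p.bbox[1]
        ax.text(c0, r0, str(p.label), color=color, fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
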