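"""Vessel binarization: thresholding with tubularity-based specificity.

Vessels are segmented as white pixels, background as black.  The default
chain thresholds the *preprocessed intensity* raster — a global Otsu
threshold for the high-contrast OCTA frames, a local mean threshold for
the lower-contrast ICGA frames (which also adapts to the smooth
fluorescence gradient) — then applies morphological closing, small-object
removal, and finally a tubularity gate: connected components that contain
no multiscale Hessian vesselness seed are discarded as non-vascular.

Thresholding the vesselness response itself was rejected for density
work: ridge filters are centreline-peaked, so any threshold on them
systematically under-recovers vessel width (Dice against ground truth
saturates near 0.85 on dense plexuses).  The Hessian response is instead
used where it is reliable — deciding *whether* a structure is a vessel —
while the intensity threshold decides *how wide* it is.

Conventions: threshold ties go to foreground; connectivity is 8-connected
everywhere so thin diagonal vessels stay connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import sato, threshold_local, threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, remove_small_objects

from .errors import ValidationError
from .io_formats import ImageFrame

OTSU_GLOBAL = "otsu_global"
LOCAL_MEAN = "local_mean"


@dataclass
class SegmentationParams:
    scales: tuple[float, ...] = (1.0, 1.5, 2.5)
    threshold_method: str = OTSU_GLOBAL
    local_window: int = 31
    local_offset: float = 0.0
    min_object_area: int = 20
    closing_radius: int = 1
    vesselness_gate: bool = True

    def validate(self) -> None:
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValidationError("vesselness scales must be positive")
        if list(self.scales) != sorted(self.scales):
            raise ValidationError("vesselness scales must be ascending")
        if self.threshold_method not in (OTSU_GLOBAL, LOCAL_MEAN):
            raise ValidationError(
                f"unknown threshold method {self.threshold_method!r}"
            )
        if self.local_window < 3 or self.local_window % 2 == 0:
            raise ValidationError("local window must be odd and >= 3")
        if self.min_object_area < 0 or self.closing_radius < 0:
            raise ValidationError("min_object_area and closing_radius must be >= 0")


OCTA_SEGMENTATION = SegmentationParams(threshold_method=OTSU_GLOBAL)
ICGA_SEGMENTATION = SegmentationParams(
    threshold_method=LOCAL_MEAN, local_window=31, local_offset=-0.04
)
DEFAULT_SEGMENTATION = {"OCTA": OCTA_SEGMENTATION, "ICGA": ICGA_SEGMENTATION}


@dataclass
class BinaryVesselMask:
    """Boolean vessel map together with the ROI it is valid on."""

    mask: np.ndarray
    roi: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.mask.shape != self.roi.shape:
            raise ValidationError("mask and roi shapes differ")
        if not self.roi.any():
            raise ValidationError("ROI is empty")
        if (self.mask & ~self.roi).any():
            raise ValidationError("mask extends outside its ROI")


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components with pixel count < min_area."""
    if min_area <= 1 or not mask.any():
        return mask
    return remove_small_objects(mask, max_size=min_area - 1, connectivity=2)


def enhance_vessels(
    image: ImageFrame | np.ndarray, scales: Sequence[float] = (1.0, 1.5, 2.5)
) -> np.ndarray:
    """Multiscale tubularity response, min-max normalized to [0, 1].

    Per scale a Hessian-eigenvalue line filter responds to bright
    curvilinear structures; the pixelwise maximum over scales is taken.
    A structureless (flat) image maps to an all-zero response.
    """
    if not scales or any(s <= 0 for s in scales):
        raise ValidationError("scales must be positive")
    arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image, float)
    response = sato(arr, sigmas=tuple(scales), black_ridges=False, mode="reflect")
    hi = response.max()
    if hi <= 0:
        return np.zeros_like(response)
    return response / hi


def binarize(
    vesselness: np.ndarray,
    roi: np.ndarray,
    params: SegmentationParams | None = None,
    provenance: dict | None = None,
) -> BinaryVesselMask:
    """Threshold a [0, 1] raster (vesselness or intensity) within the ROI.

    The threshold is computed from ROI pixels only; ties go to the
    foreground.  Closing bridges 1-px gaps, then components smaller than
    ``min_object_area`` are dropped (8-connectivity).
    """
    params = params or SegmentationParams()
    params.validate()
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValidationError("empty ROI")
    v = np.asarray(vesselness, dtype=np.float64)
    if v.shape != roi.shape:
        raise ValidationError("vesselness and roi shapes differ")
    values = v[roi]
    if params.threshold_method == OTSU_GLOBAL:
        if np.ptp(values) == 0:
            mask = np.zeros_like(roi)  # structureless: nothing to segment
        else:
            t = threshold_otsu(values)
            mask = (v >= t) & roi
    else:
        t_map = threshold_local(
            v, block_size=params.local_window, method="mean", offset=params.local_offset
        )
        mask = (v >= t_map) & roi
    if params.closing_radius > 0 and mask.any():
        mask = closing(mask, disk(params.closing_radius)) & roi
    mask = _drop_small(mask, params.min_object_area)
    return BinaryVesselMask(
        mask=mask,
        roi=roi,
        provenance=dict(provenance or {}, params=params),
    )


def clean_mask(mask: BinaryVesselMask, min_area: int) -> BinaryVesselMask:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    if min_area < 0:
        raise ValidationError("min_area must be >= 0")
    return BinaryVesselMask(
        mask=_drop_small(mask.mask.copy(), min_area),
        roi=mask.roi,
        provenance=dict(mask.provenance, min_area=min_area),
    )


def _gate_by_vesselness(
    mask: np.ndarray, image_pixels: np.ndarray, roi: np.ndarray,
    scales: Sequence[float],
) -> np.ndarray:
    """Keep only mask components containing a tubularity seed.

    Seeds are the Otsu-thresholded top of the multiscale vesselness
    response; isolated bright blobs without curvilinear structure carry
    no seed and are discarded.
    """
    if not mask.any():
        return mask
    response = enhance_vessels(image_pixels, scales)
    values = response[roi]
    if np.ptp(values) == 0:
        return mask
    seeds = (response >= threshold_otsu(values)) & roi
    labels = label(mask, connectivity=2)
    keep = np.unique(labels[seeds & mask])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def segment_frame(
    image: ImageFrame,
    roi: np.ndarray,
    params: SegmentationParams | None = None,
) -> BinaryVesselMask:
    """Segment one preprocessed frame with modality defaults.

    Intensity thresholding (global Otsu for OCTA, local mean for ICGA)
    followed by the vesselness component gate when enabled.
    """
    if params is None:
        params = DEFAULT_SEGMENTATION.get(image.modality, SegmentationParams())
    result = binarize(
        image.pixels,
        roi,
        params,
        provenance={
            "animal_id": image.animal_id,
            "modality": image.modality,
            "week": image.week,
            "replicate": image.replicate,
        },
    )
    if params.vesselness_gate:
        gated = _gate_by_vesselness(result.mask, image.pixels, result.roi, params.scales)
        result = BinaryVesselMask(mask=gated, roi=result.roi, provenance=result.provenance)
    return result
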