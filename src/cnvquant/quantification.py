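"""Vessel density, vessel growth density and repeatability error.

Vessel density (%) is the fraction of region-of-interest pixels
classified as vessel, times 100 — exact integer pixel counts, no
physical units.  Vessel growth density (%) between two consecutive
follow-ups is the difference of the two binarized images' densities on
their *common overlay region*: the later mask is warped into the earlier
visit's frame (nearest-neighbour, masks stay boolean) and the comparison
is restricted to pixels valid in both.  Positive values are growth,
negative regression.

The pixelwise counterpart of the scalar is the :class:`ChangeMap`
partition of the common region into grown / regressed / persistent /
empty, used for diagnostic overlays.

Repeatability error is the signed density difference between two
same-session scans of the same region; its smallness relative to
between-visit change is what validates the growth statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .registration import RegistrationResult, warp
from .segmentation import BinaryVesselMask

# ChangeMap label values
EMPTY, GROWN, REGRESSED, PERSISTENT = 0, 1, 2, 3
OUTSIDE = 255  # pixels outside the common ROI


@dataclass(frozen=True)
class DensityMeasurement:
    vessel_density_pct: float
    n_vessel_px: int
    n_roi_px: int
    source: dict | None = None


@dataclass(frozen=True)
class GrowthMeasurement:
    growth_density_pct: float
    interval: tuple[int, int]
    common_roi_px: int
    grown_px: int
    regressed_px: int
    persistent_px: int


@dataclass
class ChangeMap:
    """Label raster over the common ROI: grown/regressed/persistent/empty."""

    labels: np.ndarray  # uint8, OUTSIDE beyond the common ROI

    def to_rgb(self) -> np.ndarray:
        """Colour rendering: grown=green, regressed=red, persistent=white."""
        h, w = self.labels.shape
        rgb = np.zeros((h, w, 3), dtype=np.float64)
        rgb[self.labels == GROWN] = (0.0, 0.8, 0.0)
        rgb[self.labels == REGRESSED] = (0.9, 0.0, 0.0)
        rgb[self.labels == PERSISTENT] = (1.0, 1.0, 1.0)
        return rgb


def vessel_density(
    mask: BinaryVesselMask | np.ndarray,
    roi: np.ndarray | None = None,
    source: dict | None = None,
) -> DensityMeasurement:
    """Exact pixel-count vessel density on the (non-empty) ROI."""
    if isinstance(mask, BinaryVesselMask):
        m = mask.mask
        r = mask.roi if roi is None else np.asarray(roi, dtype=bool)
    else:
        m = np.asarray(mask, dtype=bool)
        if roi is None:
            raise ValidationError("an ROI is required for a bare mask")
        r = np.asarray(roi, dtype=bool)
    if m.shape != r.shape:
        raise ValidationError("mask and ROI shapes differ")
    n_roi = int(r.sum())
    if n_roi == 0:
        raise ValidationError("empty ROI")
    n_vessel = int((m & r).sum())
    return DensityMeasurement(
        vessel_density_pct=100.0 * n_vessel / n_roi,
        n_vessel_px=n_vessel,
        n_roi_px=n_roi,
        source=source,
    )


def growth_density(
    mask_a: BinaryVesselMask,
    mask_b: BinaryVesselMask,
    reg: RegistrationResult | None = None,
) -> tuple[GrowthMeasurement, ChangeMap]:
    """Vessel growth density from visit a (earlier) to visit b (later).

    ``mask_b`` is warped into ``mask_a``'s frame by ``reg`` (nearest
    neighbour) and all counts are restricted to the common region:
    ``reg.common_mask`` intersected with both ROIs.  ``reg=None`` means
    the masks are already in one frame (same-session replicates).

    The scalar satisfies, exactly,
    ``growth = density(b | common) - density(a | common)``.
    """
    a = mask_a.mask
    roi_a = mask_a.roi
    if reg is None:
        b = mask_b.mask
        common = roi_a & mask_b.roi
    else:
        b, valid = warp(mask_b.mask, reg.transform, order=0)
        roi_b_w, _ = warp(mask_b.roi, reg.transform, order=0)
        common = reg.common_mask & valid & roi_a & roi_b_w
    if a.shape != b.shape:
        raise ValidationError("mask shapes differ")
    n_common = int(common.sum())
    if n_common == 0:
        raise ValidationError("empty common ROI: registration overlap is void")
    grown = b & ~a & common
    regressed = a & ~b & common
    persistent = a & b & common
    n_grown = int(grown.sum())
    n_regressed = int(regressed.sum())
    week_a = (mask_a.provenance or {}).get("week", 0)
    week_b = (mask_b.provenance or {}).get("week", week_a + 1)
    measurement = GrowthMeasurement(
        growth_density_pct=100.0 * (n_grown - n_regressed) / n_common,
        interval=(week_a, week_b),
        common_roi_px=n_common,
        grown_px=n_grown,
        regressed_px=n_regressed,
        persistent_px=int(persistent.sum()),
    )
    labels = np.full(a.shape, OUTSIDE, dtype=np.uint8)
    labels[common] = EMPTY
    labels[grown] = GROWN
    labels[regressed] = REGRESSED
    labels[persistent] = PERSISTENT
    return measurement, ChangeMap(labels=labels)


def repeatability_error(
    mask_r1: BinaryVesselMask,
    mask_r2: BinaryVesselMask,
    roi: np.ndarray | None = None,
) -> float:
    """Signed density difference (%) between two same-session replicates.

    Replicates image the same region in one sitting, so no registration
    is applied; the ROIs must agree.
    """
    r = mask_r1.roi if roi is None else np.asarray(roi, dtype=bool)
    if not np.array_equal(r, mask_r2.roi if roi is None else r):
        raise ValidationError("replicate ROIs differ")
    if mask_r1.mask.shape != mask_r2.mask.shape:
        raise ValidationError("replicate shapes differ")
    d1 = vessel_density(mask_r1, r)
    d2 = vessel_density(mask_r2, r)
    return d2.vessel_density_pct - d1.vessel_density_pct
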