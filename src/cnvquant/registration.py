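"""Rigid registration of follow-up angiograms and the common overlay region.

Between imaging sessions the eye is repositioned approximately rigidly at
this field size, so the transform family is translation + rotation about
the image centre (scale fixed at 1: same device, same optics).  The
estimate is two-stage and derivative-free:

1. a coarse rotation grid (0.5 deg steps within the search bound), each
   candidate's translation resolved by subpixel phase correlation;
2. golden-section refinement of the rotation around the best grid node,
   re-estimating the translation at every evaluation.

The objective throughout is the normalized cross-correlation (NCC) of the
two images on their valid overlap.  All downstream density comparisons
are restricted to the resulting common overlay mask.

Registration always runs on preprocessed *intensity* images, never on
binary masks, so that binarization error cannot propagate into alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import DegenerateImageError, RegistrationFailure
from .io_formats import ImageFrame

DEFAULT_SCORE_FLOOR = 0.2
DEFAULT_MAX_ROTATION_DEG = 10.0
COARSE_ROTATION_STEP_DEG = 0.5
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the image centre followed by a translation.

    Maps a point ``p = (x, y)`` in the moving frame to the fixed frame:
    ``p' = R(theta) @ (p - c) + c + (dx, dy)`` where ``c`` is the centre
    of the canvas the transform is applied on.  ``x`` is the column
    coordinate, ``y`` the row coordinate; the rotation angle is measured
    counter-clockwise in that axis convention.
    """

    dx: float = 0.0
    dy: float = 0.0
    rotation_deg: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.rotation_deg == 0.0

    def _rot(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Transform an (N, 2) array of (x, y) points on a canvas of ``shape``."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        centre = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])
        out = (pts - centre) @ self._rot().T + centre + np.array([self.dx, self.dy])
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        t_other = np.array([other.dx, other.dy])
        t = self._rot() @ t_other + np.array([self.dx, self.dy])
        return RigidTransform(
            dx=float(t[0]),
            dy=float(t[1]),
            rotation_deg=self.rotation_deg + other.rotation_deg,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = RigidTransform(rotation_deg=-self.rotation_deg)._rot()
        t = -(rot_inv @ np.array([self.dx, self.dy]))
        return RigidTransform(
            dx=float(t[0]), dy=float(t[1]), rotation_deg=-self.rotation_deg
        )

    def to_dict(self) -> dict:
        return {"dx": self.dx, "dy": self.dy, "rotation_deg": self.rotation_deg}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            dx=float(d["dx"]), dy=float(d["dy"]), rotation_deg=float(d["rotation_deg"])
        )


@dataclass
class RegistrationResult:
    """Estimated moving-to-fixed transform plus the common overlay region."""

    transform: RigidTransform
    common_mask: np.ndarray  # boolean, on the fixed canvas
    score: float  # NCC on the common region, in [-1, 1]


def _source_coords(
    transform: RigidTransform, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """For each output pixel, the (row, col) source location in the moving image."""
    h, w = shape
    inv = transform.inverse()
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    src = inv.apply(pts, shape)
    return src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)  # rows, cols


def warp(
    image: ImageFrame | np.ndarray, transform: RigidTransform, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an image under a rigid transform (moving -> fixed frame).

    Bilinear interpolation by default (``order=0`` gives nearest-neighbour,
    used for binary masks).  Returns ``(warped, valid)`` where ``valid``
    marks output pixels whose source location lies inside the moving
    canvas; invalid pixels are 0 and must be excluded via the mask, never
    interpreted as intensity.
    """
    arr = image.pixels if isinstance(image, ImageFrame) else np.asarray(image)
    arr_f = arr.astype(np.float64)
    h, w = arr.shape
    rows, cols = _source_coords(transform, (h, w))
    valid = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    warped = ndimage.map_coordinates(
        arr_f, [rows, cols], order=order, mode="constant", cval=0.0, prefilter=False
    )
    warped[~valid] = 0.0
    if arr.dtype == bool:
        return warped > 0.5, valid
    return warped, valid


def warp_frame(image: ImageFrame, transform: RigidTransform) -> tuple[ImageFrame, np.ndarray]:
    """``warp`` preserving frame metadata; intensities clipped to [0, 1]."""
    warped, valid = warp(image, transform)
    return image.with_pixels(np.clip(warped, 0.0, 1.0)), valid


def masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Normalized cross-correlation of two images on a boolean region."""
    av = a[mask]
    bv = b[mask]
    if av.size < 16:
        return -1.0
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = math.sqrt(float(av @ av) * float(bv @ bv))
    if denom == 0.0:
        return 0.0
    return float(av @ bv) / denom


def _translation_for_rotation(
    fixed: np.ndarray,
    moving: np.ndarray,
    rotation_deg: float,
    upsample_factor: int,
) -> tuple[RigidTransform, float]:
    """Best translation (by phase correlation) for a fixed candidate rotation."""
    rot = RigidTransform(rotation_deg=rotation_deg)
    rotated, valid = warp(moving, rot)
    shift, _, _ = phase_cross_correlation(
        fixed, rotated, upsample_factor=upsample_factor, normalization=None
    )
    cand = RigidTransform(dx=float(shift[1]), dy=float(shift[0]), rotation_deg=rotation_deg)
    warped, valid_full = warp(moving, cand)
    score = masked_ncc(fixed, warped, valid_full)
    return cand, score


def register_pair(
    moving: ImageFrame | np.ndarray,
    fixed: ImageFrame | np.ndarray,
    max_rotation_deg: float = DEFAULT_MAX_ROTATION_DEG,
    score_floor: float = DEFAULT_SCORE_FLOOR,
    coarse_step_deg: float = COARSE_ROTATION_STEP_DEG,
    rotation_tol_deg: float = 0.02,
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Raises :class:`DegenerateImageError` on flat input and
    :class:`RegistrationFailure` (carrying the best score) when the final
    NCC is below ``score_floor``.
    """
    fix = (fixed.pixels if isinstance(fixed, ImageFrame) else np.asarray(fixed)).astype(
        np.float64
    )
    mov = (moving.pixels if isinstance(moving, ImageFrame) else np.asarray(moving)).astype(
        np.float64
    )
    if fix.shape != mov.shape:
        raise ValueError(f"canvas mismatch: fixed {fix.shape} vs moving {mov.shape}")
    if fix.std() == 0.0 or mov.std() == 0.0:
        raise DegenerateImageError("flat image cannot be registered")

    # stage 1: coarse rotation grid, translation by phase correlation
    n_steps = int(round(max_rotation_deg / coarse_step_deg))
    grid = np.arange(-n_steps, n_steps + 1) * coarse_step_deg
    best: RigidTransform | None = None
    best_score = -2.0
    for theta in grid:
        cand, score = _translation_for_rotation(fix, mov, float(theta), upsample_factor=10)
        if score > best_score:
            best, best_score = cand, score

    # stage 2: golden-section refinement of rotation around the best node
    lo = best.rotation_deg - coarse_step_deg
    hi = best.rotation_deg + coarse_step_deg
    cache: dict[float, tuple[RigidTransform, float]] = {
        best.rotation_deg: (best, best_score)
    }

    def evaluate(theta: float) -> tuple[RigidTransform, float]:
        theta = round(theta, 6)
        if theta not in cache:
            cache[theta] = _translation_for_rotation(fix, mov, theta, upsample_factor=50)
        return cache[theta]

    a, b = lo, hi
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    _, f1 = evaluate(x1)
    _, f2 = evaluate(x2)
    while (b - a) > rotation_tol_deg:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            _, f2 = evaluate(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            _, f1 = evaluate(x1)
    for theta, (cand, score) in cache.items():
        if score > best_score:
            best, best_score = cand, score

    # refine the winning translation once more at high precision
    best, best_score = _translation_for_rotation(
        fix, mov, best.rotation_deg, upsample_factor=100
    )
    _, valid = warp(mov, best)
    if best_score < score_floor:
        raise RegistrationFailure(best_score, score_floor)
    return RegistrationResult(transform=best, common_mask=valid, score=best_score)


def overlay_composite(
    fixed: ImageFrame | np.ndarray, moving_warped: ImageFrame | np.ndarray
) -> np.ndarray:
    """Magenta/green checking composite of a registered pair.

    The fixed image drives the red and blue channels (magenta), the warped
    moving image the green channel, so agreement renders grayscale/white
    and disagreement magenta or green.
    """
    f = fixed.pixels if isinstance(fixed, ImageFrame) else np.asarray(fixed, dtype=float)
    m = (
        moving_warped.pixels
        if isinstance(moving_warped, ImageFrame)
        else np.asarray(moving_warped, dtype=float)
    )
    if f.shape != m.shape:
        raise ValueError("composite requires same-shape images")
    rgb = np.stack([f, m, f], axis=-1)
    return np.clip(rgb, 0.0, 1.0)
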