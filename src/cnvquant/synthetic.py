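"""Ground-truthed simulator of longitudinal corneal-vascularization studies.

The simulator emulates the suture-induced rabbit model: vessels sprout
from a limbal arc and advance centripetally toward four concentric
"suture row" attractor arcs (row 4 innermost, near the central cornea).
Growth is a biased branching random walk — not a physiological
angiogenesis model — chosen because the analysis pipeline only needs
plausible vessel geometry with controllable density and direction.

A simulated study mirrors the anti-VEGF treatment design: vessels grow
over weeks 1-2 (pre-treatment), then per-arm schedules apply from week 3:

* saline controls keep growing;
* an aflibercept-like arm regresses and stays regressed (distal-first
  pruning at weeks 3 and 4);
* a ranibizumab-like arm regresses at week 3 and rebounds at week 4
  (stronger rebound for the single sub-conjunctival injection, partial
  for topical instillation).

Each visit is rendered in two modalities from the *same* vasculature:
an OCTA-like image (speckle, bright horizontal motion-artefact lines)
and an ICGA-like image (wider PSF, smooth background fluorescence
gradient, lower contrast).  Each visit is rendered twice per modality
with independent noise (same-session replicates for repeatability), and
a known random rigid transform is applied between consecutive visits
and recorded so registration accuracy can be scored against truth.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import SimulationError, ValidationError
from .io_formats import (
    ImageFrame,
    ManifestRecord,
    StudyManifest,
    write_image,
)
from .registration import RigidTransform

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NoiseParams:
    """Rendering parameters for one modality."""

    vessel_level: float
    background_level: float
    speckle_sigma: float  # multiplicative log-normal sigma (unit mean)
    psf_sigma: float  # gaussian point-spread blur, px
    additive_sigma: float  # additive gaussian noise
    gradient_amplitude: float  # smooth background fluorescence gradient
    motion_line_rate: float  # expected number of bright artefact rows
    motion_line_strength: float

    def validate(self) -> None:
        for name in ("speckle_sigma", "psf_sigma", "additive_sigma",
                     "gradient_amplitude", "motion_line_rate",
                     "motion_line_strength"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.background_level <= self.vessel_level <= 1):
            raise ValidationError(
                "need 0 <= background_level <= vessel_level <= 1"
            )


OCTA_NOISE = NoiseParams(
    vessel_level=0.82,
    background_level=0.12,
    speckle_sigma=0.35,
    psf_sigma=0.5,
    additive_sigma=0.02,
    gradient_amplitude=0.0,
    motion_line_rate=4.0,
    motion_line_strength=0.5,
)

ICGA_NOISE = NoiseParams(
    vessel_level=0.62,
    background_level=0.22,
    speckle_sigma=0.12,
    psf_sigma=1.0,
    additive_sigma=0.03,
    gradient_amplitude=0.22,
    motion_line_rate=0.0,
    motion_line_strength=0.0,
)

NOISELESS = NoiseParams(
    vessel_level=1.0,
    background_level=0.0,
    speckle_sigma=0.0,
    psf_sigma=0.0,
    additive_sigma=0.0,
    gradient_amplitude=0.0,
    motion_line_rate=0.0,
    motion_line_strength=0.0,
)

# action kinds allowed in the per-arm weekly schedule
PRUNE, REGROW, GROW = "prune", "regrow", "grow"


@dataclass
class SimulationConfig:
    """All knobs of the simulated study; defaults emulate the rabbit design."""

    canvas: tuple[int, int] = (256, 256)
    # limbal arc on which vascular roots sit (full circle by default)
    limbal_radius_frac: float = 0.46  # of min(canvas)
    limbal_span_deg: tuple[float, float] = (0.0, 360.0)
    # concentric suture-row attractor arcs; innermost = row 4
    suture_row_fracs: tuple[float, ...] = (0.78, 0.62, 0.46, 0.30)
    n_roots: int = 20
    step_len: float = 4.0
    branch_prob: float = 0.09
    branch_angle: float = 0.6  # radians offset of the second child
    direction_noise_sd: float = 0.28  # radians
    root_radius: float = 2.2  # px, half-width of a root vessel
    taper_per_step: float = 0.995
    branch_taper: float = 0.88
    # thinnest capillaries are kept comparable to the device resolution
    # (PSF ~1 px): sub-resolution vessels would be unquantifiable by any
    # intensity-based pipeline
    min_radius: float = 1.3
    max_steps: int = 400
    # which suture row growth targets per pre-treatment week
    growth_target_row: dict[int, int] = field(default_factory=lambda: {1: 2, 2: 4})
    # weekly action per (arm, route): prune fraction, regrow target row,
    # or continued growth with extra roots
    regression_schedule: dict[tuple[str, str], dict[int, tuple[str, float]]] = field(
        default_factory=lambda: {
            ("saline", "subconjunctival"): {3: (GROW, 5), 4: (GROW, 5)},
            ("saline", "topical"): {3: (GROW, 5), 4: (GROW, 5)},
            ("aflibercept", "subconjunctival"): {3: (PRUNE, 0.48), 4: (PRUNE, 0.18)},
            ("aflibercept", "topical"): {3: (PRUNE, 0.62), 4: (PRUNE, 0.45)},
            ("ranibizumab", "subconjunctival"): {3: (PRUNE, 0.55), 4: (REGROW, 4)},
            ("ranibizumab", "topical"): {3: (PRUNE, 0.68), 4: (REGROW, 3)},
        }
    )
    # study design
    weeks: int = 4
    replicates: int = 2
    animals_per_drug_arm: int = 3
    animals_per_control_arm: int = 2
    modalities: tuple[str, ...] = ("OCTA", "ICGA")
    noise: dict[str, NoiseParams] = field(
        default_factory=lambda: {"OCTA": OCTA_NOISE, "ICGA": ICGA_NOISE}
    )
    # inter-visit rigid repositioning ranges
    max_shift_frac: float = 0.10  # of canvas side, per axis
    max_rotation_deg: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.branch_prob < 1 or self.branch_prob in (0.0, 1.0)):
            raise ValidationError("branch_prob must lie in [0, 1]")
        if self.n_roots < 1 or self.step_len <= 0 or self.root_radius <= 0:
            raise ValidationError("n_roots, step_len, root_radius must be positive")
        if not all(0 < f < 1 for f in self.suture_row_fracs):
            raise ValidationError("suture row fractions must lie in (0, 1)")
        if list(self.suture_row_fracs) != sorted(self.suture_row_fracs, reverse=True):
            raise ValidationError("suture rows must be ordered outermost to innermost")
        for (arm, route), weeks in self.regression_schedule.items():
            for wk, (kind, value) in weeks.items():
                if kind == PRUNE and not 0 <= value <= 1:
                    raise ValidationError(
                        f"prune fraction {value} for ({arm}, {route}, week {wk}) "
                        "outside [0, 1]"
                    )
                if kind not in (PRUNE, REGROW, GROW):
                    raise ValidationError(f"unknown schedule action {kind!r}")
        for params in self.noise.values():
            params.validate()
        if not 0 <= self.max_shift_frac <= 0.5:
            raise ValidationError("max_shift_frac outside [0, 0.5]")

    # geometry helpers -----------------------------------------------------
    @property
    def centre(self) -> tuple[float, float]:
        h, w = self.canvas
        return ((w - 1) / 2.0, (h - 1) / 2.0)  # (x, y)

    @property
    def limbal_radius(self) -> float:
        return self.limbal_radius_frac * min(self.canvas)

    def row_radius(self, row: int) -> float:
        return self.suture_row_fracs[row - 1] * self.limbal_radius

    def roi_mask(self) -> np.ndarray:
        """Analysis region: the corneal disk inside the limbal arc."""
        h, w = self.canvas
        cx, cy = self.centre
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.limbal_radius ** 2

    def scaled(
        self, animals_per_drug_arm: int, animals_per_control_arm: int
    ) -> "SimulationConfig":
        """A copy with a reduced number of animals per arm (same conditions)."""
        return replace(
            self,
            animals_per_drug_arm=animals_per_drug_arm,
            animals_per_control_arm=animals_per_control_arm,
        )


# ---------------------------------------------------------------------------
# vessel trees


@dataclass(frozen=True)
class Segment:
    start: tuple[float, float]  # (x, y)
    end: tuple[float, float]
    radius: float
    birth_step: int
    parent: int  # index into the segment list, -1 for roots


@dataclass
class VesselTree:
    """A corneal vascular tree as a list of connected line segments."""

    segments: list[Segment]
    arc_centre: tuple[float, float]
    arc_radius: float
    arc_span_deg: tuple[float, float]
    canvas: tuple[int, int]

    def validate(self) -> None:
        h, w = self.canvas
        for i, seg in enumerate(self.segments):
            if seg.radius <= 0:
                raise ValidationError(f"segment {i} has non-positive radius")
            if seg.parent >= 0:
                parent = self.segments[seg.parent]
                if not np.allclose(seg.start, parent.end):
                    raise ValidationError(
                        f"segment {i} does not start at its parent's end"
                    )
                if seg.radius > parent.radius + 1e-9:
                    raise ValidationError(f"segment {i} thicker than its parent")
                if seg.birth_step <= parent.birth_step:
                    raise ValidationError(
                        f"segment {i} born no later than its parent"
                    )
            for (x, y) in (seg.start, seg.end):
                if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                    raise ValidationError(f"segment {i} endpoint outside canvas")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def max_birth_step(self) -> int:
        return max((s.birth_step for s in self.segments), default=-1)

    def leaves(self) -> list[int]:
        """Indices of segments without children (active growth fronts)."""
        has_child = np.zeros(len(self.segments), dtype=bool)
        for seg in self.segments:
            if seg.parent >= 0:
                has_child[seg.parent] = True
        return [i for i in range(len(self.segments)) if not has_child[i]]

    def transformed(self, transform: RigidTransform) -> "VesselTree":
        """Apply a rigid transform to every endpoint (pose change).

        Posed trees may extend beyond the canvas; rasterization clips
        them, emulating the field-of-view crop of a repositioned eye.
        """
        pts = np.array(
            [[*s.start, *s.end] for s in self.segments], dtype=np.float64
        ).reshape(-1, 2) if self.segments else np.zeros((0, 2))
        if len(pts):
            pts = transform.apply(pts, self.canvas)
        segs = []
        for i, seg in enumerate(self.segments):
            start = tuple(pts[2 * i])
            end = tuple(pts[2 * i + 1])
            segs.append(replace(seg, start=start, end=end))
        centre = transform.apply(np.array([self.arc_centre]), self.canvas)[0]
        return VesselTree(
            segments=segs,
            arc_centre=(float(centre[0]), float(centre[1])),
            arc_radius=self.arc_radius,
            arc_span_deg=(
                self.arc_span_deg[0] + transform.rotation_deg,
                self.arc_span_deg[1] + transform.rotation_deg,
            ),
            canvas=self.canvas,
        )


def _clamp(p: np.ndarray, canvas: tuple[int, int], margin: float) -> np.ndarray:
    h, w = canvas
    return np.array(
        [min(max(p[0], margin), w - 1 - margin), min(max(p[1], margin), h - 1 - margin)]
    )


def _advance(
    tree: VesselTree,
    config: SimulationConfig,
    target_row: int,
    rng: np.random.Generator,
) -> None:
    """Grow all current leaves inward until they reach ``target_row``.

    Mutates ``tree`` in place.  Raises :class:`SimulationError` if the
    step budget is exhausted before any tip reaches the target row.
    """
    centre = np.array(config.centre)
    target_r = config.row_radius(target_row)
    margin = config.root_radius + 1.0

    tips: list[dict] = []
    for idx in tree.leaves():
        seg = tree.segments[idx]
        pos = np.array(seg.end)
        if np.linalg.norm(pos - centre) <= target_r:
            continue  # already past the target row
        d = np.array(seg.end) - np.array(seg.start)
        n = np.linalg.norm(d)
        direction = d / n if n > 0 else (centre - pos) / np.linalg.norm(centre - pos)
        tips.append({"index": idx, "pos": pos, "dir": direction, "radius": seg.radius})

    birth = tree.max_birth_step + 1
    any_reached = not tips
    for _ in range(config.max_steps):
        if not tips:
            break
        new_tips: list[dict] = []
        for tip in tips:
            pos = tip["pos"]
            inward = centre - pos
            dist = np.linalg.norm(inward)
            if dist <= target_r:
                any_reached = True
                continue
            inward = inward / dist
            # persistence keeps paths smooth; bias keeps them centripetal
            direction = 0.5 * tip["dir"] + 0.5 * inward
            direction = direction / np.linalg.norm(direction)
            theta = rng.normal(0.0, config.direction_noise_sd)
            c, s = math.cos(theta), math.sin(theta)
            direction = np.array(
                [c * direction[0] - s * direction[1], s * direction[0] + c * direction[1]]
            )
            end = _clamp(pos + config.step_len * direction, config.canvas, margin)
            radius = max(config.min_radius, tip["radius"] * config.taper_per_step)
            tree.segments.append(
                Segment(
                    start=(float(pos[0]), float(pos[1])),
                    end=(float(end[0]), float(end[1])),
                    radius=radius,
                    birth_step=birth,
                    parent=tip["index"],
                )
            )
            child_index = len(tree.segments) - 1
            new_tips.append(
                {"index": child_index, "pos": end, "dir": direction, "radius": radius}
            )
            if rng.random() < config.branch_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                phi = sign * config.branch_angle
                c2, s2 = math.cos(phi), math.sin(phi)
                bdir = np.array(
                    [
                        c2 * direction[0] - s2 * direction[1],
                        s2 * direction[0] + c2 * direction[1],
                    ]
                )
                bend = _clamp(pos + config.step_len * bdir, config.canvas, margin)
                bradius = max(config.min_radius, tip["radius"] * config.branch_taper)
                tree.segments.append(
                    Segment(
                        start=(float(pos[0]), float(pos[1])),
                        end=(float(bend[0]), float(bend[1])),
                        radius=bradius,
                        birth_step=birth,
                        parent=tip["index"],
                    )
                )
                new_tips.append(
                    {
                        "index": len(tree.segments) - 1,
                        "pos": bend,
                        "dir": bdir,
                        "radius": bradius,
                    }
                )
        tips = new_tips
        birth += 1
    if tips and not any_reached:
        raise SimulationError(
            f"no tip reached suture row {target_row} within {config.max_steps} steps"
        )


def _make_roots(
    config: SimulationConfig, n_roots: int, rng: np.random.Generator, birth: int = 0
) -> list[Segment]:
    cx, cy = config.centre
    lo, hi = (math.radians(a) for a in config.limbal_span_deg)
    angles = rng.uniform(lo, hi, size=n_roots)
    segments = []
    margin = config.root_radius + 1.0
    for ang in angles:
        start = np.array(
            [cx + config.limbal_radius * math.cos(ang),
             cy + config.limbal_radius * math.sin(ang)]
        )
        inward = np.array([cx, cy]) - start
        inward = inward / np.linalg.norm(inward)
        end = _clamp(start + config.step_len * inward, config.canvas, margin)
        start = _clamp(start, config.canvas, margin)
        segments.append(
            Segment(
                start=(float(start[0]), float(start[1])),
                end=(float(end[0]), float(end[1])),
                radius=config.root_radius,
                birth_step=birth,
                parent=-1,
            )
        )
    return segments


def grow_tree(
    config: SimulationConfig, weeks_of_growth: int, rng: np.random.Generator
) -> VesselTree:
    """Grow a fresh tree from the limbal arc for the given number of weeks.

    Week targets come from ``config.growth_target_row``; growth beyond the
    last configured week keeps the innermost target.
    """
    config.validate()
    if weeks_of_growth < 1:
        raise ValidationError("weeks_of_growth must be >= 1")
    tree = VesselTree(
        segments=_make_roots(config, config.n_roots, rng),
        arc_centre=config.centre,
        arc_radius=config.limbal_radius,
        arc_span_deg=config.limbal_span_deg,
        canvas=config.canvas,
    )
    last_week = max(config.growth_target_row)
    for week in range(1, weeks_of_growth + 1):
        target = config.growth_target_row[min(week, last_week)]
        _advance(tree, config, target, rng)
    return tree


def regress_tree(
    tree: VesselTree, prune_fraction: float, rng: np.random.Generator | None = None
) -> VesselTree:
    """Remove the most recently grown fraction of non-root segments.

    Distal-first pruning: segments are ranked by (birth_step, index)
    descending and the top ``prune_fraction`` of non-root segments is
    removed.  Children are always born after their parents, so the
    removed set is closed under descent and the result is a valid tree.
    The ordering is fully deterministic; ``rng`` is accepted for
    interface symmetry but unused.
    """
    if not 0.0 <= prune_fraction <= 1.0:
        raise ValidationError("prune_fraction outside [0, 1]")
    non_root = [i for i, s in enumerate(tree.segments) if s.parent >= 0]
    n_remove = int(round(prune_fraction * len(non_root)))
    if n_remove == 0:
        return VesselTree(
            segments=list(tree.segments),
            arc_centre=tree.arc_centre,
            arc_radius=tree.arc_radius,
            arc_span_deg=tree.arc_span_deg,
            canvas=tree.canvas,
        )
    order = sorted(
        non_root, key=lambda i: (tree.segments[i].birth_step, i), reverse=True
    )
    removed = set(order[:n_remove])
    keep = [i for i in range(len(tree.segments)) if i not in removed]
    remap = {old: new for new, old in enumerate(keep)}
    segments = [
        replace(
            tree.segments[i],
            parent=remap[tree.segments[i].parent]
            if tree.segments[i].parent >= 0
            else -1,
        )
        for i in keep
    ]
    return VesselTree(
        segments=segments,
        arc_centre=tree.arc_centre,
        arc_radius=tree.arc_radius,
        arc_span_deg=tree.arc_span_deg,
        canvas=tree.canvas,
    )


def rasterize(
    tree: VesselTree,
    canvas: tuple[int, int] | None = None,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Draw every segment as a thick capsule (distance <= radius) and union.

    Segments partly or fully outside the canvas are clipped.  If ``roi``
    is given the result is restricted to it.
    """
    shape = canvas if canvas is not None else tree.canvas
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    for seg in tree.segments:
        x0, y0 = seg.start
        x1, y1 = seg.end
        r = seg.radius
        cmin = max(int(math.floor(min(x0, x1) - r - 1)), 0)
        cmax = min(int(math.ceil(max(x0, x1) + r + 1)), w - 1)
        rmin = max(int(math.floor(min(y0, y1) - r - 1)), 0)
        rmax = min(int(math.ceil(max(y0, y1) + r + 1)), h - 1)
        if cmin > cmax or rmin > rmax:
            continue
        yy, xx = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
        dx, dy = x1 - x0, y1 - y0
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            dist2 = (xx - x0) ** 2 + (yy - y0) ** 2
        else:
            t = ((xx - x0) * dx + (yy - y0) * dy) / seg_len2
            t = np.clip(t, 0.0, 1.0)
            dist2 = (xx - (x0 + t * dx)) ** 2 + (yy - (y0 + t * dy)) ** 2
        out[rmin : rmax + 1, cmin : cmax + 1] |= dist2 <= r * r
    if roi is not None:
        out &= roi
    return out


# ---------------------------------------------------------------------------
# rendering


def render_modality(
    mask: np.ndarray,
    modality: str,
    noise: NoiseParams,
    rng: np.random.Generator,
    **frame_meta,
) -> ImageFrame:
    """Render a boolean vessel raster as a noisy modality-specific image.

    With all noise parameters zero and levels (1, 0), the output equals
    the mask cast to float — the noiseless limit used for oracle tests.
    """
    noise.validate()
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    img = np.where(mask, noise.vessel_level, noise.background_level).astype(np.float64)
    if noise.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, noise.psf_sigma)
    if noise.speckle_sigma > 0:
        # unit-mean log-normal speckle
        s = noise.speckle_sigma
        img = img * np.exp(rng.normal(0.0, s, size=(h, w)) - 0.5 * s * s)
    if noise.gradient_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        gx, gy = rng.uniform(-1.0, 1.0, size=2)
        plane = gx * (xx / (w - 1) - 0.5) + gy * (yy / (h - 1) - 0.5)
        img = img + noise.gradient_amplitude * (plane - plane.min()) / max(
            float(np.ptp(plane)), 1e-12
        )
    if noise.additive_sigma > 0:
        img = img + rng.normal(0.0, noise.additive_sigma, size=(h, w))
    if noise.motion_line_rate > 0:
        n_lines = int(rng.poisson(noise.motion_line_rate))
        if n_lines > 0:
            rows = rng.choice(h, size=min(n_lines, h // 4), replace=False)
            img[rows, :] += noise.motion_line_strength
    img = np.clip(img, 0.0, 1.0)
    return ImageFrame(pixels=img, modality=modality, **frame_meta)


# ---------------------------------------------------------------------------
# study generation


@dataclass
class GroundTruth:
    """Everything the simulator knows: masks, densities, poses, transforms."""

    roi: np.ndarray
    arms: dict[str, tuple[str, str]]  # animal -> (arm, route)
    masks: dict[tuple[str, int], np.ndarray]  # (animal, week) -> posed mask
    true_density_pct: dict[tuple[str, int], float]
    poses: dict[tuple[str, int], RigidTransform]  # canonical -> week frame
    pair_transforms: dict[tuple[str, int], RigidTransform]  # key (animal, wk):
    # transform mapping the week wk+1 (moving) frame onto the week wk frame
    true_growth_pct: dict[tuple[str, int], float]  # (animal, wk): wk -> wk+1

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_image(self.roi, out_dir / "roi.png")
        for (animal, week), mask in self.masks.items():
            write_image(mask, out_dir / f"mask_{animal}_week{week}.png")
        payload = {
            "arms": {a: list(v) for a, v in self.arms.items()},
            "true_density_pct": {
                f"{a}|{w}": v for (a, w), v in self.true_density_pct.items()
            },
            "poses": {f"{a}|{w}": t.to_dict() for (a, w), t in self.poses.items()},
            "pair_transforms": {
                f"{a}|{w}": t.to_dict() for (a, w), t in self.pair_transforms.items()
            },
            "true_growth_pct": {
                f"{a}|{w}": v for (a, w), v in self.true_growth_pct.items()
            },
        }
        (out_dir / "truth.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "GroundTruth":
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        payload = json.loads((out_dir / "truth.json").read_text())

        def unkey(s: str) -> tuple[str, int]:
            a, w = s.rsplit("|", 1)
            return a, int(w)

        masks = {}
        for p in sorted(out_dir.glob("mask_*_week*.png")):
            stem = p.stem[len("mask_"):]
            animal, week = stem.rsplit("_week", 1)
            masks[(animal, int(week))] = iio.imread(p) > 127
        return cls(
            roi=iio.imread(out_dir / "roi.png") > 127,
            arms={a: tuple(v) for a, v in payload["arms"].items()},
            masks=masks,
            true_density_pct={unkey(k): v for k, v in payload["true_density_pct"].items()},
            poses={
                unkey(k): RigidTransform.from_dict(v)
                for k, v in payload["poses"].items()
            },
            pair_transforms={
                unkey(k): RigidTransform.from_dict(v)
                for k, v in payload["pair_transforms"].items()
            },
            true_growth_pct={
                unkey(k): v for k, v in payload["true_growth_pct"].items()
            },
        )


def _study_animals(config: SimulationConfig) -> list[tuple[str, str, str]]:
    """(animal_id, arm, route) triples for the configured design."""
    out = []
    i = 1
    for route in ("subconjunctival", "topical"):
        for arm in ("aflibercept", "ranibizumab"):
            for _ in range(config.animals_per_drug_arm):
                out.append((f"R{i:02d}", arm, route))
                i += 1
        for _ in range(config.animals_per_control_arm):
            out.append((f"R{i:02d}", "saline", route))
            i += 1
    return out


def _evolve_weekly_trees(
    config: SimulationConfig,
    arm: str,
    route: str,
    rng: np.random.Generator,
) -> list[VesselTree]:
    """Canonical (unposed) trees for weeks 1..config.weeks of one animal."""

    def snapshot(tree: VesselTree) -> VesselTree:
        return VesselTree(
            segments=list(tree.segments),
            arc_centre=tree.arc_centre,
            arc_radius=tree.arc_radius,
            arc_span_deg=tree.arc_span_deg,
            canvas=tree.canvas,
        )

    tree = grow_tree(config, 1, rng)
    trees = [snapshot(tree)]
    last_target = max(config.growth_target_row)
    schedule = config.regression_schedule.get((arm, route), {})
    for week in range(2, config.weeks + 1):
        if week in config.growth_target_row or (
            week <= last_target and week not in schedule
        ):
            target = config.growth_target_row[min(week, last_target)]
            _advance(tree, config, target, rng)
        elif week in schedule:
            kind, value = schedule[week]
            if kind == PRUNE:
                tree = regress_tree(tree, float(value), rng)
            elif kind == REGROW:
                _advance(tree, config, int(value), rng)
            elif kind == GROW:
                tree.segments.extend(
                    _make_roots(config, int(value), rng, birth=tree.max_birth_step + 1)
                )
                innermost = len(config.suture_row_fracs)
                _advance(tree, config, innermost, rng)
        trees.append(snapshot(tree))
    return trees


def _random_pose(config: SimulationConfig, rng: np.random.Generator) -> RigidTransform:
    h, w = config.canvas
    return RigidTransform(
        dx=float(rng.uniform(-config.max_shift_frac, config.max_shift_frac) * w),
        dy=float(rng.uniform(-config.max_shift_frac, config.max_shift_frac) * h),
        rotation_deg=float(
            rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
        ),
    )


def generate_study(
    config: SimulationConfig, out_dir: str | Path
) -> tuple[StudyManifest, GroundTruth]:
    """Simulate a full longitudinal study and write it to ``out_dir``.

    Writes ``images/`` (8-bit PNG angiograms), ``manifest.csv`` and
    ``truth/`` (ground-truth masks, densities, poses, pair transforms).
    Fully deterministic for a fixed ``config.seed``.
    """
    config.validate()
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    roi = config.roi_mask()
    n_roi = int(roi.sum())
    animals = _study_animals(config)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(animals))

    records: list[ManifestRecord] = []
    truth = GroundTruth(
        roi=roi,
        arms={},
        masks={},
        true_density_pct={},
        poses={},
        pair_transforms={},
        true_growth_pct={},
    )

    for (animal, arm, route), child in zip(animals, children):
        grow_ss, pose_ss, render_ss = child.spawn(3)
        grow_rng = np.random.default_rng(grow_ss)
        pose_rng = np.random.default_rng(pose_ss)
        render_rng = np.random.default_rng(render_ss)
        truth.arms[animal] = (arm, route)

        trees = _evolve_weekly_trees(config, arm, route, grow_rng)
        poses = [RigidTransform()] + [
            _random_pose(config, pose_rng) for _ in range(config.weeks - 1)
        ]
        for week_idx, (tree, pose) in enumerate(zip(trees, poses), start=1):
            posed = tree if pose.is_identity else tree.transformed(pose)
            mask = rasterize(posed, config.canvas)
            truth.masks[(animal, week_idx)] = mask
            truth.poses[(animal, week_idx)] = pose
            truth.true_density_pct[(animal, week_idx)] = (
                100.0 * int((mask & roi).sum()) / n_roi
            )
            for modality in config.modalities:
                for rep in range(1, config.replicates + 1):
                    frame = render_modality(
                        mask,
                        modality,
                        config.noise[modality],
                        render_rng,
                        animal_id=animal,
                        eye="OD",
                        week=week_idx,
                        arm=arm,
                        route=route,
                        replicate=rep,
                    )
                    rel = f"images/{animal}_{modality}_week{week_idx}_rep{rep}.png"
                    write_image(frame.pixels, out_dir / rel)
                    records.append(
                        ManifestRecord(
                            animal_id=animal,
                            eye="OD",
                            modality=modality,
                            week=week_idx,
                            arm=arm,
                            route=route,
                            replicate=rep,
                            file_path=rel,
                        )
                    )
        for week_idx in range(1, config.weeks):
            t_pair = poses[week_idx - 1].compose(poses[week_idx].inverse())
            truth.pair_transforms[(animal, week_idx)] = t_pair
            truth.true_growth_pct[(animal, week_idx)] = (
                truth.true_density_pct[(animal, week_idx + 1)]
                - truth.true_density_pct[(animal, week_idx)]
            )

    manifest = StudyManifest(records=records)
    manifest.save(out_dir / "manifest.csv")
    truth.save(out_dir / "truth")
    return manifest, truth
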