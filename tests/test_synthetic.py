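"""Simulator contracts: growth, pruning, rasterization, rendering, truth."""

import numpy as np
import pytest

from cnvquant.errors import ValidationError
from cnvquant.synthetic import (
    NOISELESS,
    OCTA_NOISE,
    SimulationConfig,
    grow_tree,
    rasterize,
    regress_tree,
    render_modality,
)


def small_config(**kw):
    base = dict(seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGrowTree:
    def test_degenerate_walk_is_straight_radial_chain(self):
        cfg = small_config(n_roots=1, branch_prob=0.0, direction_noise_sd=0.0)
        tree = grow_tree(cfg, 1, np.random.default_rng(3))
        tree.validate()
        # one chain: every segment has exactly the previous as parent
        assert [s.parent for s in tree.segments] == list(range(-1, len(tree.segments) - 1))
        # all points collinear with the centre (pure centripetal walk)
        cx, cy = cfg.centre
        pts = np.array([s.end for s in tree.segments])
        v = pts - np.array([cx, cy])
        cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
        assert np.abs(cross).max() < 1e-6 * np.abs(v).max() ** 2
        # the chain reaches its target suture row
        assert np.linalg.norm(v[-1]) <= cfg.row_radius(cfg.growth_target_row[1]) + 1e-9

    def test_same_seed_gives_identical_segments(self):
        cfg = small_config()
        t1 = grow_tree(cfg, 2, np.random.default_rng(7))
        t2 = grow_tree(cfg, 2, np.random.default_rng(7))
        assert t1.segments == t2.segments

    def test_grown_tree_is_valid_and_radii_taper(self):
        cfg = small_config()
        tree = grow_tree(cfg, 2, np.random.default_rng(5))
        tree.validate()
        for seg in tree.segments:
            if seg.parent >= 0:
                assert seg.radius <= tree.segments[seg.parent].radius + 1e-12

    def test_density_regression_band_for_frozen_seed(self):
        # frozen-seed fixture: value established by running the generator
        # once and banding it; guards against silent geometry drift
        cfg = small_config()
        tree = grow_tree(cfg, 2, np.random.default_rng(0))
        roi = cfg.roi_mask()
        density = 100.0 * (rasterize(tree, cfg.canvas) & roi).sum() / roi.sum()
        assert 24.0 <= density <= 30.0


class TestRegressTree:
    def test_prune_zero_is_identity(self):
        cfg = small_config()
        tree = grow_tree(cfg, 2, np.random.default_rng(2))
        assert regress_tree(tree, 0.0).segments == tree.segments

    def test_prune_one_leaves_roots_only(self):
        cfg = small_config()
        tree = grow_tree(cfg, 2, np.random.default_rng(2))
        pruned = regress_tree(tree, 1.0)
        assert all(s.parent == -1 for s in pruned.segments)
        assert len(pruned.segments) == cfg.n_roots

    def test_pruning_reduces_density_monotonically(self):
        cfg = small_config()
        tree = grow_tree(cfg, 2, np.random.default_rng(2))
        roi = cfg.roi_mask()

        def density(t):
            return (rasterize(t, cfg.canvas) & roi).sum()

        d0 = density(tree)
        last = d0
        for frac in (0.25, 0.5, 0.75, 1.0):
            d = density(regress_tree(tree, frac))
            assert d <= last
            last = d
        assert density(regress_tree(tree, 0.5)) < d0

    def test_pruned_tree_remains_valid(self):
        cfg = small_config()
        tree = grow_tree(cfg, 2, np.random.default_rng(2))
        regress_tree(tree, 0.37).validate()

    def test_bad_fraction_rejected(self):
        cfg = small_config()
        tree = grow_tree(cfg, 1, np.random.default_rng(2))
        with pytest.raises(ValidationError):
            regress_tree(tree, 1.5)


class TestRasterize:
    def test_empty_tree_rasterizes_to_false(self):
        from cnvquant.synthetic import VesselTree

        tree = VesselTree(
            segments=[], arc_centre=(32, 32), arc_radius=30,
            arc_span_deg=(0, 360), canvas=(64, 64),
        )
        assert not rasterize(tree).any()

    def test_single_segment_matches_brute_force_distance(self):
        from cnvquant.synthetic import Segment, VesselTree

        seg = Segment(start=(20.0, 32.0), end=(30.0, 32.0), radius=1.0,
                      birth_step=0, parent=-1)
        tree = VesselTree(segments=[seg], arc_centre=(32, 32), arc_radius=30,
                          arc_span_deg=(0, 360), canvas=(64, 64))
        got = rasterize(tree)
        yy, xx = np.mgrid[0:64, 0:64]
        t = np.clip((xx - 20.0) * 10.0 / 100.0, 0, 1)  # projection onto the segment
        dist2 = (xx - (20.0 + 10.0 * t)) ** 2 + (yy - 32.0) ** 2
        assert np.array_equal(got, dist2 <= 1.0)

    def test_union_property(self, rng):
        cfg = small_config(n_roots=4)
        tree = grow_tree(cfg, 1, np.random.default_rng(9))
        half = len(tree.segments) // 2
        from cnvquant.synthetic import VesselTree

        def sub(segs):
            return VesselTree(segments=segs, arc_centre=tree.arc_centre,
                              arc_radius=tree.arc_radius,
                              arc_span_deg=tree.arc_span_deg, canvas=tree.canvas)

        a = rasterize(sub(tree.segments[:half]))
        b = rasterize(sub(tree.segments[half:]))
        assert np.array_equal(rasterize(tree), a | b)

    def test_roi_restriction(self):
        cfg = small_config()
        tree = grow_tree(cfg, 1, np.random.default_rng(9))
        roi = np.zeros(cfg.canvas, dtype=bool)
        roi[:100, :100] = True
        assert not (rasterize(tree, roi=roi) & ~roi).any()


class TestRender:
    def test_noiseless_limit_equals_mask(self, rng):
        cfg = small_config()
        mask = rasterize(grow_tree(cfg, 1, np.random.default_rng(4)), cfg.canvas)
        frame = render_modality(mask, "OCTA", NOISELESS, rng)
        assert np.array_equal(frame.pixels, mask.astype(float))

    def test_fixed_seed_repeats_identically(self):
        cfg = small_config()
        mask = rasterize(grow_tree(cfg, 1, np.random.default_rng(4)), cfg.canvas)
        f1 = render_modality(mask, "OCTA", OCTA_NOISE, np.random.default_rng(5))
        f2 = render_modality(mask, "OCTA", OCTA_NOISE, np.random.default_rng(5))
        assert np.array_equal(f1.pixels, f2.pixels)

    @pytest.mark.parametrize("modality", ["OCTA", "ICGA"])
    def test_vessel_pixels_brighter_than_background(self, modality, rng):
        from cnvquant.synthetic import ICGA_NOISE

        cfg = small_config()
        mask = rasterize(grow_tree(cfg, 2, np.random.default_rng(4)), cfg.canvas)
        noise = OCTA_NOISE if modality == "OCTA" else ICGA_NOISE
        frame = render_modality(mask, modality, noise, rng)
        assert frame.pixels[mask].mean() > frame.pixels[~mask].mean() + 0.1


class TestGroundTruth:
    def test_growth_equals_density_difference_exactly(self, study):
        truth = study["truth"]
        for (animal, week), g in truth.true_growth_pct.items():
            assert g == truth.true_density_pct[(animal, week + 1)] - \
                truth.true_density_pct[(animal, week)]

    def test_true_density_matches_recorded_masks_exactly(self, study):
        truth = study["truth"]
        n_roi = truth.roi.sum()
        for key, mask in truth.masks.items():
            expect = 100.0 * (mask & truth.roi).sum() / n_roi
            assert truth.true_density_pct[key] == pytest.approx(expect, abs=1e-9)

    def test_saline_densities_strictly_increase(self, study):
        truth = study["truth"]
        for animal, (arm, _) in truth.arms.items():
            if arm != "saline":
                continue
            d = [truth.true_density_pct[(animal, w)] for w in range(1, 5)]
            # canonical-frame growth is monotone; the posed-frame wobble is
            # bounded well below the weekly saline increment
            assert d[1] > d[0] and d[3] > d[1]
            assert d[2] > d[1] - 2.0 and d[3] > d[2] - 2.0

    def test_rebound_arm_week4_exceeds_week3(self, study):
        truth = study["truth"]
        for animal, (arm, route) in truth.arms.items():
            if arm == "ranibizumab":
                assert truth.true_density_pct[(animal, 4)] > \
                    truth.true_density_pct[(animal, 3)]

    def test_week2_pretreatment_density_in_reported_band(self, study):
        truth = study["truth"]
        week2 = [truth.true_density_pct[(a, 2)] for a in truth.arms]
        assert all(20.0 <= d <= 35.0 for d in week2)

    def test_regeneration_is_bit_identical(self, study, tmp_path):
        from cnvquant.synthetic import generate_study

        _, truth2 = generate_study(study["config"], tmp_path / "again")
        truth = study["truth"]
        assert set(truth2.masks) == set(truth.masks)
        for key in truth.masks:
            assert np.array_equal(truth2.masks[key], truth.masks[key])
        a_png = sorted((study["dir"] / "images").glob("*.png"))[0]
        b_png = tmp_path / "again" / "images" / a_png.name
        assert a_png.read_bytes() == b_png.read_bytes()
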