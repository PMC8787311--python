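"""Shaft extraction, spine segmentation, measurement, classification."""

import numpy as np
import pytest

import golgi3d as g
from golgi3d.classification import (ClassifierRules, SpineFeatures,
                                    classify_spine, classify_volume,
                                    extract_shaft_axis, measure_spine,
                                    segment_spines, spine_density)
from golgi3d.image_io import VoxelSpacing
from golgi3d.reconstruction import BinaryVolume
from golgi3d.synthetic import (PhantomTruth, SpineSpec, decorate_with_spines,
                               invariance_phantom, straight_segment,
                               voxelize_truth)

SP = VoxelSpacing(0.1, 0.1, 0.1)


def cylinder_volume(radius=0.5, length=12.0, start=(1.0, 3.0, 3.0)):
    seg = straight_segment(length, radius=radius, start=start,
                           direction=(1, 0, 0), node_spacing=2.0)
    truth = PhantomTruth(seg, [], 0.0, length)
    return truth, voxelize_truth(truth, SP, origin=(0, 0, 0), pad=0.5)


def single_spine_volume(spec: SpineSpec, seed=0):
    """One spine of the given geometry on a straight shaft."""
    seg = straight_segment(8.0, radius=0.45, start=(1.0, 3.0, 3.0),
                           direction=(1, 0, 0), node_spacing=1.0)
    truth = decorate_with_spines(seg, 0.0, {"stubby": 1.0}, seed=seed,
                                 positions=[4.0], spec_sequence=[spec],
                                 max_axial_component=0.5)
    vol = voxelize_truth(truth, SP, origin=(0, 0, 0), pad=0.5)
    return truth, vol


class TestShaftAxis:
    def test_cylinder_axis_within_one_voxel(self):
        _, vol = cylinder_volume()
        axis = extract_shaft_axis(vol)
        # true centreline: y = z = 3.0 (in physical coordinates)
        dev = np.linalg.norm(axis.points[:, 1:] - np.array([3.0, 3.0]), axis=1)
        assert dev.max() <= np.sqrt(3) * SP.dx

    def test_cylinder_radius_within_one_voxel(self):
        _, vol = cylinder_volume(radius=0.5)
        axis = extract_shaft_axis(vol)
        interior = slice(5, -5)
        assert np.abs(axis.radii[interior] - 0.5).max() <= SP.dx

    def test_sphere_rejected_as_not_elongated(self):
        m = np.zeros((31, 31, 31), dtype=bool)
        zz, yy, xx = np.mgrid[:31, :31, :31]
        m[(zz - 15) ** 2 + (yy - 15) ** 2 + (xx - 15) ** 2 <= 100] = True
        with pytest.raises(ValueError, match="elongated"):
            extract_shaft_axis(BinaryVolume(m, SP))

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            extract_shaft_axis(BinaryVolume(np.zeros((4, 4, 4), bool), SP))


class TestSegmentSpines:
    def test_bare_shaft_yields_no_records(self):
        _, vol = cylinder_volume()
        axis = extract_shaft_axis(vol)
        assert segment_spines(vol, axis) == []

    def test_three_separated_spines_found_at_positions(self):
        seg = straight_segment(16.0, radius=0.45, start=(1.0, 3.0, 3.0),
                               direction=(1, 0, 0), node_spacing=1.0)
        truth = decorate_with_spines(
            seg, 0.0, {"mushroom": 1.0}, seed=1, positions=[3.0, 8.0, 13.0],
            class_sequence=["mushroom", "stubby", "wide"],
            max_axial_component=0.5)
        vol = voxelize_truth(truth, SP, origin=(0, 0, 0), pad=0.5)
        axis = extract_shaft_axis(vol)
        cands = segment_spines(vol, axis)
        assert len(cands) == 3
        # axis orientation is arbitrary; match by nearest attachment
        ta = np.array([s.attachment for s in truth.spines])
        for cand in cands:
            d = np.linalg.norm(ta - np.array(cand.attachment), axis=1)
            assert d.min() < 0.35

    def test_merged_contact_is_flagged_not_split(self):
        seg = straight_segment(10.0, radius=0.45, start=(1.0, 3.0, 3.0),
                               direction=(1, 0, 0), node_spacing=1.0)
        # two fat spines almost touching along the shaft; rotate the second
        # onto the first's azimuth so the bumps fuse into one component
        spec = SpineSpec("wide", 0.0, 1.0, 1.0, length=0.62)
        truth = decorate_with_spines(
            seg, 0.0, {"wide": 1.0}, seed=3, positions=[4.5, 5.3],
            spec_sequence=[spec], max_axial_component=0.5)
        d0 = np.asarray(truth.spines[0].direction)
        s1 = truth.spines[1]
        d1 = np.asarray(s1.direction)
        th = np.arctan2(d0[2], d0[1]) - np.arctan2(d1[2], d1[1])
        c, s_ = np.cos(th), np.sin(th)
        centre = np.array([0.0, 3.0, 3.0])

        def rot(p):
            p = np.asarray(p, dtype=float) - centre
            return centre + np.array([p[0], c * p[1] - s_ * p[2],
                                      s_ * p[1] + c * p[2]])

        s1.direction = tuple(rot(centre + d1) - centre)
        s1.attachment = tuple(rot(s1.attachment))
        s1.primitives = [
            (p[0], rot(p[1]), p[2]) if p[0] == "sphere"
            else (p[0], rot(p[1]), rot(p[2]), p[3], p[4])
            for p in s1.primitives]
        vol = voxelize_truth(truth, SP, origin=(0, 0, 0), pad=0.5)
        axis = extract_shaft_axis(vol)
        cands = segment_spines(vol, axis)
        assert len(cands) == 1  # merged into one candidate
        assert cands[0].contact_ambiguous


class TestMeasureSpine:
    def test_mushroom_features_within_voxel_tolerance(self):
        spec = SpineSpec("mushroom", neck_length=0.6, neck_diameter=0.15,
                         head_diameter=0.6)
        truth, vol = single_spine_volume(spec)
        axis = extract_shaft_axis(vol)
        (cand,) = segment_spines(vol, axis)
        f = measure_spine(cand, SP)
        assert f.neck_present
        assert f.neck_diameter == pytest.approx(0.15, abs=0.11)
        assert f.head_diameter == pytest.approx(0.6, abs=0.11)
        assert f.protrusion_length == pytest.approx(0.6 + 0.6, abs=0.2)

    def test_hemispherical_bump_has_no_neck(self):
        spec = SpineSpec("stubby", 0.0, 0.6, 0.6, length=0.5)
        truth, vol = single_spine_volume(spec)
        axis = extract_shaft_axis(vol)
        (cand,) = segment_spines(vol, axis)
        f = measure_spine(cand, SP)
        assert not f.neck_present

    def test_double_headed_spine_counts_two_protrusions(self):
        spec = SpineSpec("ramified", neck_length=0.6, neck_diameter=0.24,
                         head_diameter=0.5, n_heads=2)
        truth, vol = single_spine_volume(spec)
        axis = extract_shaft_axis(vol)
        (cand,) = segment_spines(vol, axis)
        f = measure_spine(cand, SP)
        assert f.n_protrusions == 2

    def test_tiny_subvolume_rejected(self):
        from golgi3d.classification import SpineCandidate
        cand = SpineCandidate(
            spine_mask=np.zeros((2, 2, 2), bool),
            context_mask=np.zeros((2, 2, 2), bool),
            box_origin=(0, 0, 0), attachment_voxel=(0, 0, 0),
            attachment=(0, 0, 0), branch_arclen=0.0, radial_extent=0.0)
        with pytest.raises(ValueError):
            measure_spine(cand, SP)


class TestClassifyRules:
    def features(self, **kw):
        base = dict(neck_present=False, neck_length=0.0, neck_diameter=0.3,
                    head_diameter=0.3, n_protrusions=1, head_shape=0.9,
                    protrusion_length=0.5, base_diameter=0.5, spinule_count=0,
                    radial_height=0.5, lateral_extent=0.5)
        base.update(kw)
        return SpineFeatures(**base)

    def test_ramified_priority_overrides_everything(self):
        f = self.features(n_protrusions=2, neck_present=True,
                          neck_diameter=0.2, head_diameter=0.6)
        assert classify_spine(f) == "ramified"

    def test_mushroom_by_head_neck_contrast(self):
        # independent rule-table oracle: head/neck = 4 >= 1.5
        f = self.features(neck_present=True, neck_diameter=0.15,
                          head_diameter=0.6, protrusion_length=1.2)
        assert classify_spine(f) == "mushroom"

    def test_thin_long_slender_with_modest_head(self):
        f = self.features(neck_present=True, neck_diameter=0.25,
                          head_diameter=0.33, protrusion_length=1.4)
        assert classify_spine(f) == "thin"

    def test_stubby_vs_wide_on_aspect(self):
        stubby = self.features(radial_height=0.5, lateral_extent=0.5)
        wide = self.features(radial_height=0.5, lateral_extent=0.9)
        assert classify_spine(stubby) == "stubby"
        assert classify_spine(wide) == "wide"

    def test_transitional_band_at_mushroom_boundary(self):
        f = self.features(neck_present=True, neck_diameter=0.2,
                          head_diameter=0.2 * 1.5, protrusion_length=0.8)
        assert classify_spine(f) == "transitional"

    def test_serial_double_bulb_is_atypical(self):
        f = self.features(neck_present=True, neck_diameter=0.2,
                          head_diameter=0.5, n_bulges=2)
        assert classify_spine(f) == "atypical"

    def test_every_feature_vector_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        labels = set()
        for _ in range(300):
            f = self.features(
                neck_present=bool(rng.random() < 0.5),
                neck_diameter=float(rng.uniform(0.05, 1.0)),
                head_diameter=float(rng.uniform(0.05, 1.5)),
                protrusion_length=float(rng.uniform(0.1, 2.5)),
                n_protrusions=int(rng.integers(1, 4)),
                radial_height=float(rng.uniform(0.1, 2.0)),
                lateral_extent=float(rng.uniform(0.1, 2.0)),
            )
            label = classify_spine(f)
            labels.add(label)
            assert label in ("thin", "stubby", "wide", "mushroom", "ramified",
                             "transitional", "atypical")
        assert len(labels) >= 5  # the rule table actually discriminates


class TestDensity:
    def record(self, cls="thin"):
        from golgi3d.classification import SpineRecord
        f = SpineFeatures(False, 0, 0.2, 0.2, 1, 1.0, 0.5, 0.3, 0)
        return SpineRecord(1, (0, 0, 0), 0.0, f, cls, False)

    def test_ten_spines_on_twenty_um(self):
        out = spine_density([self.record() for _ in range(10)], 20.0)
        assert out["density_per_um"] == pytest.approx(0.5)
        assert out["band"] == "moderate"

    def test_zero_spines_sparse(self):
        out = spine_density([], 30.0)
        assert out["density_per_um"] == 0.0
        assert out["band"] == "sparse"

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            spine_density([], 0.0)


class TestInvariances:
    def test_rotation_90deg_preserves_labels(self):
        truth, vol = invariance_phantom()
        r1, _ = classify_volume(vol)
        rot = BinaryVolume(np.rot90(vol.mask, k=1, axes=(1, 2)).copy(), SP)
        r2, _ = classify_volume(rot)
        assert sorted(x.class_label for x in r1) == \
            sorted(x.class_label for x in r2)
        assert len(r1) == len(truth.spines)

    def test_uniform_scaling_preserves_labels(self):
        _, vol = invariance_phantom()
        r1, _ = classify_volume(vol)
        s = 2.0
        scaled = BinaryVolume(vol.mask.copy(), VoxelSpacing(0.2, 0.2, 0.2))
        r2, _ = classify_volume(scaled, ClassifierRules().rescaled(s),
                                margin=0.15 * s, noise_floor=0.2 * s,
                                attach_gap=0.3 * s, end_margin=0.7 * s)
        assert sorted(x.class_label for x in r1) == \
            sorted(x.class_label for x in r2)
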