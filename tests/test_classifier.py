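import numpy as np
import pytest

from whealsim.classifier import (
    WhealMask, binarize, boundary_structure, classify, classify_series,
    measure_features, punctate_score, segment, track_fusion,
)
from whealsim.synthetic import gen_mask_fixtures

from conftest import (flood_fill_components, flood_fill_holes, make_disk,
                      make_ring)


class TestBinarize:
    def test_uniform_subthreshold_field_empty(self):
        assert not binarize(np.full((8, 8), 0.4), 0.5).mask.any()

    def test_tie_pixels_included_by_ge_convention(self):
        assert binarize(np.full((8, 8), 0.5), 0.5).mask.all()

    def test_area_matches_direct_enumeration(self):
        rng = np.random.default_rng(2)
        field = rng.uniform(0, 1, (32, 32))
        mask = binarize(field, 0.6).mask
        assert mask.sum() == int((field >= 0.6).sum())

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((4, 4)), 1.0)


class TestSegment:
    def test_two_disks_no_holes(self):
        m = make_disk(64, 16, 16, 6) | make_disk(64, 48, 48, 6)
        comps = segment(WhealMask(m, 0.1))
        assert len(comps) == 2
        assert all(c.hole_count == 0 for c in comps)

    def test_ring_has_one_hole(self, ring_mask):
        comps = segment(ring_mask)
        assert len(comps) == 1
        assert comps[0].hole_count == 1

    def test_matches_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = rng.random((32, 32)) < 0.45
            comps = segment(WhealMask(m, 0.1))
            labels, n = flood_fill_components(m, connectivity=8)
            assert len(comps) == n
            assert sorted(c.area_px for c in comps) == sorted(
                int((labels == k).sum()) for k in range(1, n + 1))
            _, holes = flood_fill_holes(m)
            got = sorted((c.hole_count, c.hole_area_px) for c in comps)
            want = sorted((hc, ha) for hc, ha in holes.values())
            assert got == want


class TestBoundaryStructure:
    def test_perfect_ring_annularity_and_single_arc(self):
        mask = make_ring(64, 32, 32, 20, 12)
        hole_px = int(make_disk(64, 32, 32, 12).sum())
        filled_px = int(make_disk(64, 32, 32, 20).sum())
        groups = boundary_structure(WhealMask(mask, 0.1))
        assert len(groups) == 1
        assert groups[0].annularity == pytest.approx(hole_px / filled_px)
        assert groups[0].annularity == pytest.approx(0.36, abs=0.02)
        assert groups[0].arc_count == 1

    def test_ring_with_three_removed_sectors_has_three_arcs(self):
        n = 64
        ii, jj = np.mgrid[0:n, 0:n]
        ring = make_ring(n, 32, 32, 20, 12)
        ang = np.degrees(np.arctan2(ii - 32, jj - 32)) % 360
        for a0 in (0.0, 120.0, 240.0):
            ring &= ~(((ang - a0) % 360) < 10.0)
        groups = boundary_structure(WhealMask(ring, 0.1))
        assert len(groups) == 1
        assert groups[0].arc_count == 3
        assert groups[0].annularity >= 0.15

    def test_filled_disk_is_area_type(self):
        groups = boundary_structure(WhealMask(make_disk(64, 32, 32, 16), 0.1))
        assert len(groups) == 1
        assert groups[0].annularity == 0.0

    def test_degenerate_specks_ignored(self):
        m = np.zeros((32, 32), bool)
        m[4, 4] = m[10, 20] = True
        assert boundary_structure(WhealMask(m, 0.1)) == []


class TestTrackFusion:
    def _growing_disks(self, radii_a, radii_b):
        frames = []
        for ra, rb in zip(radii_a, radii_b):
            frames.append(WhealMask(
                make_disk(64, 32, 20, ra) | make_disk(64, 32, 44, rb),
                0.1, time=float(len(frames))))
        return frames

    def test_two_disks_growing_to_contact_is_one_merge(self):
        series = self._growing_disks([4, 7, 10, 13], [4, 7, 10, 13])
        merges, growth = track_fusion(series)
        assert merges == 1
        assert growth > 0

    def test_static_masks_no_merges_no_growth(self):
        series = [WhealMask(make_disk(64, 32, 32, 8), 0.1, t)
                  for t in range(3)]
        merges, growth = track_fusion(series)
        assert merges == 0
        assert growth == 0.0

    def test_merge_count_invariant_under_frame_duplication(self):
        series = self._growing_disks([4, 7, 10, 13], [4, 7, 10, 13])
        doubled = []
        for w in series:
            doubled.append(w)
            doubled.append(WhealMask(w.mask, w.pixel_size_cm,
                                     w.time + 0.5))
        assert track_fusion(doubled)[0] == track_fusion(series)[0]

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            track_fusion([WhealMask(np.zeros((8, 8)), 0.1, 0),
                          WhealMask(np.zeros((16, 16)), 0.1, 1)])

    def test_single_snapshot_rejected(self):
        with pytest.raises(ValueError):
            track_fusion([WhealMask(np.zeros((8, 8)), 0.1)])


class TestPunctate:
    def test_static_small_disks_are_punctate(self):
        m = make_disk(64, 20, 20, 3) | make_disk(64, 44, 44, 3)  # 0.6 cm
        series = [WhealMask(m, 0.1, t) for t in range(4)]
        assert punctate_score(series)

    def test_static_large_disks_are_not(self):
        m = make_disk(64, 32, 32, 10)  # 2 cm
        series = [WhealMask(m, 0.1, t) for t in range(4)]
        assert not punctate_score(series)

    def test_growing_small_disks_are_not(self):
        series = [WhealMask(make_disk(64, 32, 32, r), 0.1, t)
                  for t, r in enumerate([1, 1, 2, 3])]
        assert not punctate_score(series)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            punctate_score([])


class TestClassify:
    def test_growing_ring_series_is_annular(self):
        series = [WhealMask(make_ring(96, 48, 48, 14 + 4 * t, 7 + 4 * t),
                            0.1, float(t)) for t in range(4)]
        label = classify_series(series)
        assert (label.class_, label.type_) == ("boundary", "annular")

    def test_merging_disk_series_is_geographic(self):
        series = [WhealMask(make_disk(96, 48, 32, 6 + 4 * t)
                            | make_disk(96, 48, 64, 6 + 4 * t),
                            0.1, float(t)) for t in range(4)]
        label = classify_series(series)
        assert (label.class_, label.type_) == ("area", "geographic")

    def test_static_small_dot_series_is_dot(self):
        m = make_disk(96, 30, 30, 3) | make_disk(96, 70, 70, 3)
        series = [WhealMask(m, 0.1, float(t)) for t in range(4)]
        label = classify_series(series)
        assert (label.class_, label.type_) == ("area", "dot")

    def test_fusion_outranks_punctate(self):
        from whealsim.classifier import FeatureVector
        fv = FeatureVector(
            kf1_boundary_score=0.0, kf2_arc_count=1.0, kf3_area_score=1.0,
            kf4_merge_events=2, kf4_growth_rate=0.5, kf5_punctate=True,
            n_components=3, mean_diameter_cm=0.8, max_diameter_cm=0.9)
        label = classify(fv)
        assert label.type_ == "geographic"
        assert "warning" in label.evidence

    def test_empty_mask_rejected(self):
        series = [WhealMask(np.zeros((32, 32)), 0.1, float(t))
                  for t in range(3)]
        with pytest.raises(ValueError, match="no wheal"):
            classify_series(series)


class TestSymmetryInvariance:
    @pytest.mark.parametrize("pattern", ["annular", "broken-annular",
                                         "geographic", "circular", "dot"])
    def test_features_invariant_under_rotation_and_reflection(self, pattern):
        series, _ = gen_mask_fixtures(pattern, seed=4)
        fv = measure_features(series)
        for op in (lambda m: np.rot90(m), lambda m: m[::-1, :]):
            tseries = [WhealMask(op(w.mask), w.pixel_size_cm, w.time)
                       for w in series]
            tfv = measure_features(tseries)
            assert tfv.kf1_boundary_score == pytest.approx(
                fv.kf1_boundary_score, abs=1e-12)
            assert tfv.kf2_arc_count == fv.kf2_arc_count
            assert tfv.kf4_merge_events == fv.kf4_merge_events
            assert tfv.kf5_punctate == fv.kf5_punctate
            assert tfv.mean_diameter_cm == pytest.approx(
                fv.mean_diameter_cm, abs=1e-12)


class TestFixtureSuite:
    @pytest.mark.parametrize("pattern", ["annular", "broken-annular",
                                         "geographic", "circular", "dot"])
    def test_randomized_fixtures_classified_correctly(self, pattern):
        for seed in range(5):
            series, truth = gen_mask_fixtures(pattern, seed=seed)
            label = classify_series(series)
            assert label.type_ == truth, f"{pattern} seed={seed}"
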