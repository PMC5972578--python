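import numpy as np
import pytest

from endograd.bodymetrics import (body_distances, body_size_histograms,
                                  bodies_to_frame, extract_bodies)
from endograd.imgio import mask_from_polygon
from endograd.mlclassify import ProteinMask
from endograd.zonegrad import make_zones

from oracles import (flood_fill_components, point_to_polygon_distance,
                     random_star_polygon)


def _pm(arr):
    return ProteinMask(protein=np.asarray(arr, dtype=bool))


class TestExtractBodies:
    def test_square_blob_area_and_centroid(self):
        arr = np.zeros((10, 10), dtype=bool)
        arr[3:6, 4:7] = True
        bodies = extract_bodies(_pm(arr), scale=1.0, min_area_px=1)
        assert len(bodies) == 1
        assert bodies[0].area == pytest.approx(9.0)
        assert bodies[0].midpoint == pytest.approx((4.0, 5.0))

    def test_diagonal_pixels_form_one_body(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[1, 1] = arr[2, 2] = True
        assert len(extract_bodies(_pm(arr), scale=1.0, min_area_px=1)) == 1

    def test_min_area_filter(self):
        arr = np.zeros((8, 8), dtype=bool)
        arr[0, 0] = True          # single-pixel speck
        arr[3:5, 3:5] = True      # 4-px body
        bodies = extract_bodies(_pm(arr), scale=1.0, min_area_px=4)
        assert len(bodies) == 1
        assert bodies[0].area_px == 4

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            arr = rng.random((24, 24)) < 0.25
            bodies = extract_bodies(_pm(arr), scale=1.0, min_area_px=1)
            oracle = flood_fill_components(arr)
            assert len(bodies) == len(oracle)
            got = sorted((b.area_px, b.midpoint) for b in bodies)
            want = sorted((o["area_px"], o["centroid"]) for o in oracle)
            for (a1, c1), (a2, c2) in zip(got, want):
                assert a1 == a2
                assert c1 == pytest.approx(c2)

    def test_areas_conserve_mask_area_before_filter(self, small_scene):
        config, _, _, truth = small_scene
        bodies = extract_bodies(truth.protein, config.scale, min_area_px=1)
        assert sum(b.area_px for b in bodies) == truth.protein.area_px


class TestBodyDistances:
    def test_disc_centre_body_distance(self, disc_mask):
        arr = np.zeros(disc_mask.shape, dtype=bool)
        arr[59:62, 59:62] = True
        bodies = extract_bodies(_pm(arr), scale=0.5, min_area_px=1)
        bodies = body_distances(bodies, disc_mask, scale=0.5)
        # radius-50 disc, scale 0.5 um/px -> centre is ~25 um from the outline
        assert bodies[0].distance == pytest.approx(25.0, abs=0.5)

    def test_point_near_straight_edge(self):
        verts = np.array([[2, 2], [2, 28], [28, 28], [28, 2]], dtype=float)
        mask = mask_from_polygon(verts, (32, 32))
        arr = np.zeros((32, 32), dtype=bool)
        arr[3, 15] = True  # one pixel inside the top edge
        bodies = body_distances(extract_bodies(_pm(arr), 2.0, min_area_px=1),
                                mask, scale=2.0)
        assert bodies[0].distance == pytest.approx(1.0 * 2.0)

    def test_matches_segment_oracle_on_random_polygons(self):
        from endograd.imgio import ImageFormatError
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 12:
            verts = random_star_polygon(rng)
            try:
                mask = mask_from_polygon(verts, (32, 32))
            except ImageFormatError:
                continue
            checked += 1
            rr, cc = np.nonzero(mask.region)
            pick = rng.choice(len(rr), size=min(10, len(rr)), replace=False)
            arr = np.zeros((32, 32), dtype=bool)
            arr[rr[pick], cc[pick]] = True
            bodies = extract_bodies(_pm(arr), scale=1.0, min_area_px=1)
            bodies = body_distances(bodies, mask, scale=1.0)
            verts_xy = verts[:, ::-1]
            for b in bodies:
                want = point_to_polygon_distance(b.midpoint[1], b.midpoint[0],
                                                 verts_xy)
                assert b.distance == pytest.approx(want, abs=1e-9)

    def test_midpoint_outside_mask_rejected(self, disc_mask):
        arr = np.zeros(disc_mask.shape, dtype=bool)
        arr[0, 0] = True
        bodies = extract_bodies(_pm(arr), scale=1.0, min_area_px=1)
        with pytest.raises(ValueError, match="outside"):
            body_distances(bodies, disc_mask, scale=1.0)

    def test_zone_assignment_consistent_with_bands(self, small_scene):
        config, _, mask, truth = small_scene
        part = truth.partition
        for b in truth.bodies:
            assert 1 <= b.zone <= part.K
            d_px = b.distance / config.scale
            k = min(part.K, int(d_px / part.band_width) + 1)
            assert abs(b.zone - k) <= 1  # polygon vs raster distance, sub-pixel


class TestHistograms:
    def test_one_body_per_zone_single_bin(self):
        from endograd.bodymetrics import ProteinBody
        bodies = [ProteinBody(body_id=k, area=10.0 * k, midpoint=(0, 0),
                              distance=5.0 * k, zone=k) for k in range(1, 6)]
        hist = body_size_histograms(bodies, K=5, bin_edges=[1.0, 100.0])
        assert (hist.groupby("zone")["count"].sum() == 1).all()

    def test_counts_conserve_bodies(self, small_scene):
        config, _, _, truth = small_scene
        hist = body_size_histograms(truth.bodies, K=truth.partition.K)
        assert hist["count"].sum() == len(truth.bodies)

    def test_matches_ground_truth_distribution(self, small_scene):
        config, _, _, truth = small_scene
        edges = np.geomspace(min(b.area for b in truth.bodies),
                             max(b.area for b in truth.bodies) * 1.0001, 13)
        hist = body_size_histograms(truth.bodies, truth.partition.K, edges)
        for k in range(1, truth.partition.K + 1):
            areas = [b.area for b in truth.bodies if b.zone == k]
            want, _ = np.histogram(areas, bins=edges)
            got = hist.loc[hist["zone"] == k, "count"].to_numpy()
            np.testing.assert_array_equal(got, want)

    def test_bad_bins_rejected(self, small_scene):
        _, _, _, truth = small_scene
        with pytest.raises(ValueError):
            body_size_histograms(truth.bodies, 5, bin_edges=[1.0])
        with pytest.raises(ValueError):
            body_size_histograms(truth.bodies, 5, bin_edges=[2.0, 1.0])

    def test_frame_schema(self, small_scene):
        config, _, _, truth = small_scene
        frame = bodies_to_frame(truth.bodies, section_id="s", replicate_id=1)
        assert list(frame.columns) == ["section_id", "replicate_id", "body_id",
                                       "area_um2", "midpoint_row", "midpoint_col",
                                       "distance_um", "zone"]
        assert len(frame) == len(truth.bodies)
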