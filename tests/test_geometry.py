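"""Geometry: placement, rasterization, mitochondria, longitudinal zoning."""

import math
import warnings

import numpy as np
import pytest
from scipy import ndimage

from rosnerve import geometry as geo


class TestPlacement:
    def test_same_seed_identical_layout(self):
        dist = geo.DiameterDistribution.default()
        a = geo.place_axons(8.0, dist, 42)
        b = geo.place_axons(8.0, dist, 42)
        assert a == b

    def test_different_seed_differs(self):
        dist = geo.DiameterDistribution.default()
        assert geo.place_axons(8.0, dist, 1) != geo.place_axons(8.0, dist, 2)

    def test_non_overlap_and_containment(self, small_axons):
        pts = np.array([[a.x, a.y] for a in small_axons])
        rr = np.array([a.radius for a in small_axons])
        # containment: |center| + radius <= nerve radius
        assert np.all(np.hypot(pts[:, 0], pts[:, 1]) + rr <= 10.0 + 1e-9)
        # exhaustive pairwise non-overlap
        d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                     pts[:, None, 1] - pts[None, :, 1])
        s = rr[:, None] + rr[None, :]
        iu = np.triu_indices(len(small_axons), 1)
        assert np.all(d[iu] >= s[iu] - 1e-12)

    def test_octant_label_matches_center_angle(self, small_axons):
        for a in small_axons:
            assert a.octant == geo.octant_of_point(a.x, a.y)

    def test_reduced_model_count_scaling(self):
        """A 10 % model of a 1.2 M-axon nerve holds ~12,000 axons."""
        radius = geo.reduced_model_radius(10.0)
        axons = geo.place_axons(radius, geo.DiameterDistribution.default(), 42)
        expected = geo.FULL_NERVE_AXON_COUNT * (10.0 / 100.0) ** 2
        assert abs(len(axons) - expected) / expected < 0.05

    def test_zero_density_gives_empty_list(self):
        dist = geo.DiameterDistribution.uniform(density_per_um2=0.0)
        assert geo.place_axons(10.0, dist, 0) == []

    def test_unreachable_density_warns_not_silent(self):
        dist = geo.DiameterDistribution.uniform(median_um=1.5,
                                                density_per_um2=3.0)
        with pytest.warns(geo.PlacementWarning, match="density"):
            geo.place_axons(5.0, dist, 0, max_attempts=20)

    def test_diameters_follow_configured_law(self):
        law = geo.OctantLaw(median_um=0.8, sigma_log=0.3, density_per_um2=0.3)
        dist = geo.DiameterDistribution(laws={k: law for k in geo.OCTANTS})
        axons = geo.place_axons(12.0, dist, 7)
        diam = 2 * np.array([a.radius for a in axons])
        assert 0.5 <= np.median(diam) <= 1.1   # median near 0.8
        assert diam.min() >= dist.min_diameter_um
        assert diam.max() <= dist.max_diameter_um


class TestRasterization:
    def test_voxel_volume(self, small_model):
        assert small_model.voxel_volume_um3 == pytest.approx(1.0 / 49.0)

    def test_single_axon_area_within_ten_percent(self):
        """Pixel count of a rasterized disc matches πr² at res >= 5 px/µm."""
        axon = geo.AxonSpec(0, 0.0, 0.0, 2.0, "T")
        model = geo.rasterize_model([axon], res_xy=5.0, nz=1,
                                    nerve_radius_um=3.0)
        n = int((model.axon_id == 0).sum())
        # independent oracle: exhaustive pixel-centre scan
        res = 5.0
        half = model.grid_shape[0] / 2.0
        cnt = 0
        for i in range(model.grid_shape[0]):
            for j in range(model.grid_shape[1]):
                if ((i + 0.5 - half) ** 2 + (j + 0.5 - half) ** 2
                        <= (2.0 * res) ** 2):
                    cnt += 1
        assert n == cnt
        assert abs(n - math.pi * 4 * 25) / (math.pi * 4 * 25) < 0.10

    def test_area_converges_with_resolution(self):
        axon = geo.AxonSpec(0, 0.0, 0.0, 1.0, "T")
        errs = []
        for res in (5.0, 10.0, 20.0):
            m = geo.rasterize_model([axon], res_xy=res, nz=1,
                                    nerve_radius_um=2.0)
            area = (m.axon_id == 0).sum() / res**2
            errs.append(abs(area - math.pi) / math.pi)
        assert errs[2] < errs[0]

    def test_membrane_is_adjacent_boundary(self, small_model):
        """Every membrane voxel touches (8-adjacency) an interior voxel of
        the same axon, and membranes are one voxel thick."""
        lab = small_model.labels[:, :, 0]
        aid = small_model.axon_id[:, :, 0]
        eight = np.ones((3, 3), dtype=bool)
        for a in small_model.axons[:40]:
            own_i = (aid == a.id) & (lab == geo.AXON_INTERIOR)
            own_m = (aid == a.id) & (lab == geo.AXON_MEMBRANE)
            assert own_m.sum() > 0
            assert np.all(own_m <= ndimage.binary_dilation(own_i, eight))
            # one voxel thick: membrane minus (dilated exterior) is empty
            outside = ~(own_i | own_m)
            assert np.all(own_m <= ndimage.binary_dilation(outside, eight))

    def test_too_small_axon_rejected(self):
        axon = geo.AxonSpec(0, 0.0, 0.0, 0.1, "T")
        with pytest.raises(geo.GeometryError, match="too small"):
            geo.rasterize_model([axon], res_xy=5.0, nz=1, nerve_radius_um=1.0)

    def test_zero_axons_all_extra_axonal(self):
        m = geo.rasterize_model([], res_xy=5.0, nz=2, nerve_radius_um=2.0)
        assert np.all(m.labels == geo.EXTRA_AXONAL)

    def test_model_digest_reproducible(self, small_axons):
        m1 = geo.rasterize_model(small_axons, 7.0, 1.0, 1, nerve_radius_um=10.0)
        m2 = geo.rasterize_model(small_axons, 7.0, 1.0, 1, nerve_radius_um=10.0)
        assert m1.digest() == m2.digest()


class TestMitochondria:
    def test_zero_percent_no_mitochondria(self, small_model):
        m = geo.place_mitochondria(small_model, 0.0, 0.0, 3)
        assert m.mito.sum() == 0

    @pytest.mark.parametrize("pct,compartment",
                             [(4.0, geo.AXON_INTERIOR),
                              (10.0, geo.EXTRA_AXONAL)])
    def test_fraction_within_three_binomial_se(self, pct, compartment):
        axons = geo.place_axons(12.0, geo.DiameterDistribution.default(), 5)
        model = geo.rasterize_model(axons, res_xy=10.0, nz=10,
                                    nerve_radius_um=12.0)
        kwargs = {"mito_axon_pct": pct, "mito_glia_pct": 0.0} \
            if compartment == geo.AXON_INTERIOR \
            else {"mito_axon_pct": 0.0, "mito_glia_pct": pct}
        m = geo.place_mitochondria(model, rng_seed=11, **kwargs)
        cand = model.labels == compartment
        n = int(cand.sum())
        assert n >= 1e5
        p = pct / 100.0
        se = math.sqrt(p * (1 - p) / n)
        assert abs(m.mito[cand].mean() - p) < 3 * se

    def test_compartment_purity(self, small_model):
        m = geo.place_mitochondria(small_model, 5.0, 5.0, 4)
        assert not np.any(m.mito & (m.labels == geo.AXON_MEMBRANE))
        axonal = m.mito & (m.labels == geo.AXON_INTERIOR)
        glial = m.mito & (m.labels == geo.EXTRA_AXONAL)
        assert np.array_equal(m.mito, axonal | glial)


class TestLongitudinal:
    def test_abridged_zone_thicknesses(self, small_axons):
        m = geo.build_longitudinal_model(geo.abridged_layout(), small_axons,
                                         res_xy=7.0, res_z=0.2,
                                         nerve_radius_um=10.0)
        dz = 5.0
        assert m.grid_shape[2] == 82
        unmyel = (m.zone_z == geo.ZONE_UNMYELINATED).sum() * dz
        node = (m.zone_z == geo.ZONE_NODE).sum() * dz
        myel = ((m.zone_z == geo.ZONE_INTERNODAL)
                | (m.zone_z == geo.ZONE_PARANODAL)).sum() * dz
        assert (unmyel, node, myel) == (50.0, 5.0, 355.0)
        # slabs appear in order: unmyelinated first, node inside myelin
        assert m.zone_z[0] == geo.ZONE_UNMYELINATED
        assert m.zone_z[50] == geo.ZONE_NODE

    def test_myelin_wraps_membrane_except_at_node(self, small_axons):
        m = geo.build_longitudinal_model(geo.node_slice_layout(), small_axons,
                                         res_xy=7.0, res_z=1.0,
                                         nerve_radius_um=10.0)
        node_k = np.flatnonzero(m.zone_z == geo.ZONE_NODE)
        myel_k = np.flatnonzero(m.zone_z != geo.ZONE_NODE)
        assert not np.any(m.labels[:, :, node_k] == geo.MYELIN)
        assert np.any(m.labels[:, :, myel_k] == geo.MYELIN)
        assert not np.any(m.labels[:, :, myel_k] == geo.NODE_GAP)

    def test_node_slice_has_no_node_mitochondria(self, small_axons):
        m = geo.build_longitudinal_model(geo.node_slice_layout(), small_axons,
                                         res_xy=7.0, res_z=1.0,
                                         nerve_radius_um=10.0)
        m = geo.place_mitochondria(m, 20.0, 20.0, 1)
        node_k = m.zone_z == geo.ZONE_NODE
        assert m.mito[:, :, node_k].sum() == 0
        assert m.mito.sum() > 0

    def test_node_position_in_slice_layout(self, small_axons):
        """Node slab sits 6 µm from the proximal side of the 10 µm slice."""
        m = geo.build_longitudinal_model(geo.node_slice_layout(), small_axons,
                                         res_xy=7.0, res_z=1.0,
                                         nerve_radius_um=10.0)
        assert np.flatnonzero(m.zone_z == geo.ZONE_NODE).tolist() == [6]

    def test_unmyelinated_single_slice_allowed(self, small_axons):
        m = geo.rasterize_model(small_axons, res_xy=7.0, nz=1,
                                nerve_radius_um=10.0)
        assert m.grid_shape[2] == 1
        assert np.all(m.zone_z == geo.ZONE_UNMYELINATED)
        # one segment per axon in a single-slice model
        assert len(m.segments) == len(small_axons)

    def test_bad_layout_total_rejected(self, small_axons):
        layout = [geo.Slab("unmyelinated", 3.3)]
        with pytest.raises(geo.GeometryError):
            geo.build_longitudinal_model(layout, small_axons, res_xy=7.0,
                                         res_z=1.0, nerve_radius_um=10.0)

    def test_segments_tile_z_extent(self, small_axons):
        m = geo.build_longitudinal_model([geo.Slab("unmyelinated", 20.0)],
                                         small_axons, res_xy=7.0, res_z=1.0,
                                         nerve_radius_um=10.0,
                                         segment_um=5.0)
        per_axon = {}
        for s in m.segments:
            per_axon.setdefault(s.axon_id, []).append((s.z_lo, s.z_hi))
        for spans in per_axon.values():
            spans.sort()
            assert spans[0][0] == 0 and spans[-1][1] == 20
            assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
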