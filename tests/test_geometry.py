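"""Geometry: closed forms, root solves, placement and the carved mid-surface."""

import math

import numpy as np
import pytest

from alveoflow import geometry as geo
from alveoflow.errors import (InvalidGeometryError, MeshingError,
                              NoSolutionError, PlacementError)


class TestAlveolarBase:
    def test_diameter_construction_closed_form(self):
        b = geo.solve_base_from_diameter(225.0, 181.0)
        assert b.sphere_radius == 112.5
        assert b.mouth_radius == 90.5
        assert b.mouth_plane_offset == pytest.approx(66.8281, abs=1e-3)
        assert b.depth == pytest.approx(179.328, abs=1e-2)
        assert b.segment_volume() == pytest.approx(5.3267e6, rel=1e-4)

    def test_hemisphere_limit(self):
        b = geo.solve_base_from_diameter(200.0, 200.0)
        assert b.mouth_plane_offset == 0.0
        assert b.depth == 100.0
        assert b.segment_volume() == pytest.approx(2 * math.pi * 100 ** 3 / 3)

    def test_mouth_wider_than_alveolus_rejected(self):
        with pytest.raises(InvalidGeometryError):
            geo.solve_base_from_diameter(180.0, 181.0)

    def test_volume_construction_matches_reference_outputs(self):
        b = geo.solve_base_from_volume(4.6e6, 181.0)
        assert 2 * b.sphere_radius == pytest.approx(216.204, abs=1e-2)
        assert round(2 * b.sphere_radius) == 216
        assert round(b.depth) == 167

    def test_volume_round_trip(self):
        b = geo.solve_base_from_volume(4.6e6, 181.0)
        assert b.segment_volume() == pytest.approx(4.6e6, rel=1e-8)

    def test_full_sphere_limit_recovers_radius(self):
        R = 80.0
        v_sphere = 4 * math.pi * R ** 3 / 3
        b = geo.solve_base_from_volume(v_sphere, 1e-4)
        assert b.sphere_radius == pytest.approx(R, rel=1e-6)

    def test_volume_below_attainable_raises(self):
        with pytest.raises(NoSolutionError):
            geo.solve_base_from_volume(1e3, 181.0)

    def test_segment_plus_cap_equals_sphere(self):
        b = geo.solve_base_from_diameter(225.0, 181.0)
        cap_depth = b.sphere_radius - b.mouth_plane_offset
        cap = math.pi / 3 * cap_depth ** 2 * (3 * b.sphere_radius - cap_depth)
        full = 4 * math.pi * b.sphere_radius ** 3 / 3
        assert b.segment_volume() + cap == pytest.approx(full, rel=1e-14)


class TestMorphometrics:
    def test_segment_report_values(self, base):
        pores = geo.PoreSet(centers=np.zeros((17, 3)), pore_diameter=12.3)
        rep = geo.segment_morphometrics(base, pores)
        assert rep.mouth_area == pytest.approx(2.5730e4, rel=1e-4)
        assert rep.lateral_area == pytest.approx(1.2474e5, rel=1e-3)

    def test_zero_pores_lateral_area_exact(self, base):
        rep = geo.segment_morphometrics(base, None)
        assert rep.lateral_area == pytest.approx(
            2 * math.pi * base.sphere_radius * base.depth, rel=1e-14)

    def test_acn_morphometrics_reference_cells(self, default_domain, lattice):
        rep = geo.acn_morphometrics(default_domain, lattice)
        assert rep.capillary_volume == pytest.approx(7.21e5, rel=0.01)
        assert rep.capillary_surface_gas_exchange == pytest.approx(1.138e5, rel=0.01)
        assert rep.capillary_surface_gas_exchange <= rep.capillary_surface_total

    def test_no_pillars_surface_is_two_layers(self, default_domain, params):
        lat = geo.build_pillar_lattice(
            geo.MorphoParams(pillar_diameter=0.0), "square")
        rep = geo.acn_morphometrics(default_domain, lat)
        assert rep.capillary_surface_total == pytest.approx(
            2 * rep.capillary_surface_gas_exchange, rel=1e-14)


class TestPillarLattice:
    def test_square_lattice_defaults(self, params):
        lat = geo.build_pillar_lattice(params, "square")
        assert lat.pitch == pytest.approx(9.27)
        assert lat.area_fraction == pytest.approx(0.08783, abs=1e-4)

    def test_zero_pillars(self):
        lat = geo.build_pillar_lattice(
            geo.MorphoParams(pillar_diameter=0.0), "square")
        assert lat.area_fraction == 0.0

    def test_pillar_count_estimate(self, params):
        lat = geo.build_pillar_lattice(params, "square",
                                       reference_area=1.2474e5)
        assert lat.pillar_count_estimate == pytest.approx(1.45e3, rel=0.01)

    def test_hexagonal_denser_than_square(self, params):
        sq = geo.build_pillar_lattice(params, "square")
        hx = geo.build_pillar_lattice(params, "hexagonal")
        assert hx.area_fraction == pytest.approx(
            sq.area_fraction * math.pi / (2 * math.sqrt(3)) / (math.pi / 4))

    def test_overpacked_lattice_rejected(self):
        with pytest.raises(InvalidGeometryError):
            geo.build_pillar_lattice(
                geo.MorphoParams(interpillar_distance=0.5, pillar_diameter=3.1),
                "square")


class TestPlacement:
    def test_default_ports_opposite(self, base, params):
        ports = geo.place_ports(base, geo.ConnectivityConfig())
        assert len(ports) == 2
        art, ven = ports
        assert art.kind == "arteriole" and ven.kind == "venule"
        assert float(art.center @ ven.center) == pytest.approx(-1.0)
        assert art.center[2] == pytest.approx(0.0, abs=1e-12)

    def test_five_arterioles_disjoint(self, base):
        cfg = geo.ConnectivityConfig(n_arterioles=5)
        ports = geo.place_ports(base, cfg)
        arts = [p for p in ports if p.kind == "arteriole"]
        assert len(arts) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                sep = math.acos(float(np.clip(arts[i].center @ arts[j].center, -1, 1)))
                assert sep > arts[i].angular_radius + arts[j].angular_radius

    def test_port_disc_radius_on_surface(self, base):
        ports = geo.place_ports(base, geo.ConnectivityConfig(d_arteriole=60.0),
                                mid_surface_radius=base.sphere_radius)
        art = ports[0]
        assert base.sphere_radius * math.sin(art.angular_radius) == pytest.approx(30.0)

    def test_overlapping_stack_rejected(self, base):
        # five 60-um vessels cannot fit on one meridian between mouth and pole
        with pytest.raises(InvalidGeometryError):
            geo.place_ports(base, geo.ConnectivityConfig(
                n_arterioles=5, d_arteriole=60.0))

    def test_pore_seeding_deterministic(self, base):
        ports = geo.place_ports(base, geo.ConnectivityConfig())
        a = geo.place_pores(base, 17, 12.3, seed=1, exclusions=ports)
        b = geo.place_pores(base, 17, 12.3, seed=1, exclusions=ports)
        assert np.array_equal(a.centers, b.centers)

    def test_zero_pores(self, base):
        assert len(geo.place_pores(base, 0, 12.3, seed=1)) == 0

    def test_pores_disjoint_and_clear_of_exclusions(self, base):
        ports = geo.place_ports(base, geo.ConnectivityConfig())
        pores = geo.place_pores(base, 17, 12.3, seed=7, exclusions=ports)
        c = pores.centers
        R = base.sphere_radius
        min_sep = math.inf
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                min_sep = min(min_sep, math.acos(float(np.clip(c[i] @ c[j], -1, 1))))
        # center separation exceeds one pore diameter (chord ~ R * angle)
        assert R * min_sep > 12.3
        alpha = pores.angular_radius(R)
        for p in ports:
            for x in c:
                sep = math.acos(float(np.clip(x @ p.center, -1, 1)))
                assert sep > p.angular_radius + alpha
        # all pore discs fully below the mouth rim
        assert all(math.acos(float(x[2])) - alpha > base.mouth_cap_angle for x in c)

    def test_impossible_packing_raises(self, base):
        with pytest.raises(PlacementError):
            geo.place_pores(base, 300, 25.0, seed=1, max_attempts_per_pore=50)


class TestSheetMidsurface:
    def test_area_matches_spherical_cap_oracle(self, default_domain):
        assert default_domain.total_area() == pytest.approx(
            default_domain.analytic_area(), rel=0.02)

    def test_boundary_loops_labeled_one_per_hole(self, default_domain):
        labels = set(default_domain.boundary_loops)
        assert "mouth" in labels
        assert sum(1 for l in labels if l.startswith("pore_")) == 17
        assert sum(1 for l in labels if l.startswith("port_")) == 2

    def test_mesh_is_manifold(self, default_domain):
        f = default_domain.faces
        edges = np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert counts.max() <= 2

    def test_mouth_only_gives_single_loop(self, base, params):
        dom = geo.build_sheet_midsurface(base, None, [], 4.0, params.sheet_height)
        assert set(dom.boundary_loops) == {"mouth"}

    def test_area_converges_under_refinement(self, base, params):
        # mouth-only domain so the coarse level satisfies every hole's
        # resolution precondition
        errs = []
        for edge in (8.0, 4.0, 2.0):
            dom = geo.build_sheet_midsurface(base, None, [], edge,
                                             params.sheet_height)
            errs.append(abs(dom.total_area() / dom.analytic_area() - 1.0))
        assert errs[2] < errs[1] < errs[0]
        # observed convergence order at least ~1
        order = math.log(errs[0] / errs[2]) / math.log(4.0)
        assert order >= 0.9

    def test_too_coarse_for_pores_rejected(self, base, params):
        pores = geo.place_pores(base, 17, 12.3, seed=1)
        with pytest.raises(MeshingError):
            geo.build_sheet_midsurface(base, pores, [], 5.0, params.sheet_height)

    def test_mirror_preserves_morphometrics_bitwise(self, default_domain):
        mirrored = geo.mirror_domain(default_domain)
        assert np.array_equal(np.sort(mirrored.face_areas),
                              np.sort(default_domain.face_areas))
        back = geo.mirror_domain(mirrored)
        assert np.array_equal(back.vertices, default_domain.vertices)
        assert np.array_equal(np.sort(back.face_areas),
                              np.sort(default_domain.face_areas))
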