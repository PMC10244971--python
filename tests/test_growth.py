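import numpy as np
import pytest

import samsce
from samsce import (
    GrowthParams,
    PotentialParams,
    advance_cycle,
    apply_polarization,
    choose_division_plane,
    execute_division,
    execute_out_of_plane_division,
    insert_wall_nodes,
    sample_polarization,
)
from samsce.growth import DEFAULT_PERICLINAL_TABLE, plane_angle_to_surface, surface_frame
from samsce.tissue import signed_area

from conftest import ring_cell, square_cell_tissue


@pytest.fixture
def gp():
    return GrowthParams()


class TestAdvanceCycle:
    def test_full_cycle_inserts_nodes_and_flags_division(self, gp):
        t = ring_cell(12, radius=3.0, n_cyt=2)
        cell = t.cells[0]
        cell.wus = 0.0
        n0 = len(cell.cytoplasm)
        due = advance_cycle(cell, gp.cycle_hours_max, gp, t, seed=1)
        assert due
        assert cell.cycle_progress == pytest.approx(1.0)
        assert len(cell.cytoplasm) == n0 + gp.nodes_per_cycle

    def test_zero_wus_gives_slowest_cycle(self, gp):
        assert gp.cycle_hours(0.0) == gp.cycle_hours_max
        assert gp.cycle_hours(10.0) == gp.cycle_hours_min
        assert gp.cycle_hours(0.3) <= gp.cycle_hours(0.1)

    def test_higher_wus_halves_time_to_division(self, gp):
        # oracle: two otherwise identical cells; wus chosen so the cycle
        # rate doubles -> time to division halves
        gp2 = GrowthParams(cycle_hours_max=40.0, cycle_hours_min=10.0, cycle_wus_slope=20.0)
        t1 = ring_cell(12, radius=3.0, n_cyt=2)
        t2 = ring_cell(12, radius=3.0, n_cyt=2)
        c1, c2 = t1.cells[0], t2.cells[0]
        c1.wus = 0.0  # cycle 40 h
        c2.wus = 1.0  # cycle 20 h
        hours1 = hours2 = 0.0
        while not advance_cycle(c1, 0.5, gp2, t1, seed=0):
            hours1 += 0.5
        while not advance_cycle(c2, 0.5, gp2, t2, seed=0):
            hours2 += 0.5
        assert hours1 == pytest.approx(2 * hours2, abs=1.0)

    def test_growth_capped_at_target_area(self, gp):
        t = ring_cell(12, radius=3.0, n_cyt=2)
        cell = t.cells[0]
        cell.target_area = 1.0  # already larger than this
        n0 = len(cell.cytoplasm)
        advance_cycle(cell, gp.cycle_hours_max, gp, t, seed=1)
        assert len(cell.cytoplasm) == n0


class TestInsertWallNodes:
    def test_rest_edges_untouched(self):
        pp = PotentialParams()
        # ring with all edges exactly at rest length
        n = 12
        r = pp.extensibility.l_eq / (2 * np.sin(np.pi / n))
        t = ring_cell(n, radius=r, n_cyt=1)
        assert insert_wall_nodes(t.cells[0], t, pp) == 0

    def test_single_stretched_edge_bisected(self):
        pp = PotentialParams()
        n = 8
        r = pp.extensibility.l_eq / (2 * np.sin(np.pi / n))
        t = ring_cell(n, radius=r, n_cyt=1)
        cell = t.cells[0]
        # stretch one edge to 2.2 l_eq by moving one node outward along the edge
        a, b = cell.wall_ring[0], cell.wall_ring[1]
        pa = t.nodes[a].position
        direction = t.nodes[b].position - pa
        t.nodes[b].position = pa + 2.2 * pp.extensibility.l_eq * direction / np.linalg.norm(direction)
        before = len(cell.wall_ring)
        inserted = insert_wall_nodes(cell, t, pp, threshold=0.5)
        assert inserted >= 1
        assert len(cell.wall_ring) == before + inserted
        # the midpoint node sits between the two original nodes
        mid = t.nodes[cell.wall_ring[1]].position
        np.testing.assert_allclose(mid, (pa + t.nodes[cell.wall_ring[2]].position) / 2, atol=1e-9)

    def test_repeated_insertion_terminates(self):
        pp = PotentialParams()
        t = ring_cell(6, radius=6.0, n_cyt=1)  # strongly inflated ring
        cell = t.cells[0]
        total = 0
        for _ in range(50):
            k = insert_wall_nodes(cell, t, pp, threshold=0.5)
            total += k
            if k == 0:
                break
        assert k == 0  # reached a fixed point
        limit = (1 + 0.5) * pp.extensibility.l_eq
        pts = t.ring_positions(cell)
        lengths = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        assert np.all(lengths <= limit + 1e-9)


class TestSamplePolarization:
    @pytest.mark.parametrize(
        "zone,layer,expected",
        [
            ("central", "L1", 0.474),
            ("peripheral", "apical_corpus", 0.290),
            ("central", "basal_corpus", 0.105),
        ],
    )
    def test_table_frequencies_recovered(self, gp, zone, layer, expected):
        t = ring_cell(8, radius=2.0, layer=layer)
        cell = t.cells[0]
        cell.zone = zone
        n = 6000
        rng = np.random.default_rng(123)
        draws = [sample_polarization(cell, rng, gp, variant="p3d") for _ in range(n)]
        freq = sum(d == "out_of_plane" for d in draws) / n
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) < 3 * sigma

    def test_2d_never_out_of_plane(self, gp):
        t = ring_cell(8, radius=2.0, layer="L1")
        cell = t.cells[0]
        rng = np.random.default_rng(5)
        draws = {sample_polarization(cell, rng, gp, variant="2d") for _ in range(500)}
        assert "out_of_plane" not in draws

    def test_tunica_bias_is_anticlinal(self, gp):
        # CK = 0 in tunica, so in-plane draws lean anticlinal
        t = ring_cell(8, radius=2.0, layer="L2")
        cell = t.cells[0]
        cell.wus = 1.0
        rng = np.random.default_rng(6)
        draws = [sample_polarization(cell, rng, gp, variant="2d") for _ in range(400)]
        frac_anti = np.mean([d == "in_plane_anticlinal" for d in draws])
        assert frac_anti > 0.9

    def test_stream_alignment_between_variants(self, gp):
        # with the out-of-plane table zeroed, P3D draws match 2D draws
        t = ring_cell(8, radius=2.0, layer="L1")
        cell = t.cells[0]
        zeroed = GrowthParams(periclinal_table={k: 0.0 for k in DEFAULT_PERICLINAL_TABLE})
        a = [sample_polarization(cell, np.random.default_rng(s), zeroed, "p3d") for s in range(50)]
        b = [sample_polarization(cell, np.random.default_rng(s), gp, "2d") for s in range(50)]
        assert a == b


class TestApplyPolarization:
    def test_out_of_plane_uniform_walls_and_smaller_target(self, gp):
        pp = PotentialParams()
        t = ring_cell(10, radius=3.0)
        cell = t.cells[0]
        cell.polarization = "out_of_plane"
        apply_polarization(cell, t, pp, gp)
        assert np.all(cell.edge_stiffness == 1.0)
        assert cell.target_area == pytest.approx(0.75 * gp.inplane_terminal_area)

    def test_anticlinal_softens_radial_edges(self, gp):
        pp = PotentialParams()
        t = ring_cell(16, radius=3.0, centre=(0.0, 10.0))
        t.apex = np.array([0.0, 13.0])
        t.base_y = 0.0
        cell = t.cells[0]
        cell.polarization = "in_plane_anticlinal"
        apply_polarization(cell, t, pp, gp)
        assert set(np.unique(cell.edge_stiffness)) == {pp.anisotropy_factor, 1.0}
        # softened edges are those roughly parallel to the radial (vertical) axis
        pts = t.ring_positions(cell)
        for e, s in enumerate(cell.edge_stiffness):
            d = pts[(e + 1) % len(pts)] - pts[e]
            vertical = abs(d[1]) > abs(d[0])
            assert (s == pp.anisotropy_factor) == vertical

    def test_anticlinal_cell_elongates_radially(self, gp):
        pp = PotentialParams()
        t = ring_cell(16, radius=3.0, centre=(0.0, 20.0), n_cyt=6)
        t.apex = np.array([0.0, 23.0])
        t.base_y = 0.0
        cell = t.cells[0]
        cell.polarization = "in_plane_anticlinal"
        apply_polarization(cell, t, pp, gp)
        state = samsce.MechanicalState(t, pp)
        state.integrate(0.4, 10000)
        state.sync_to_tissue()
        pts = t.ring_positions(cell)
        centred = pts - pts.mean(axis=0)
        _, vecs = np.linalg.eigh(np.cov(centred.T))
        major = vecs[:, -1]
        radial = np.array([0.0, 1.0])
        angle = np.degrees(np.arccos(abs(float(major @ radial))))
        assert angle < 30.0
        assert samsce.aspect_ratio(cell, t) > 1.1


class TestChooseDivisionPlane:
    def test_tunica_plane_is_anticlinal(self, gp):
        pp = PotentialParams()
        t = ring_cell(12, radius=3.0, centre=(0.0, 30.0), layer="L1")
        t.apex = np.array([0.0, 33.0])
        t.base_y = 0.0
        cell = t.cells[0]
        cell.cycle_progress = 1.0
        point, normal = choose_division_plane(cell, t, pp, gp)
        _, t_hat = surface_frame(point, t)
        angle = np.degrees(np.arccos(abs(float(normal @ t_hat))))
        assert angle < 15.0  # normal along the layer tangent

    def test_basal_corpus_degenerate_weights(self, gp):
        pp = PotentialParams()
        t = ring_cell(12, radius=3.0, centre=(0.0, 10.0), layer="basal_corpus")
        t.apex = np.array([0.0, 13.0])
        cell = t.cells[0]
        cell.wus, cell.ck = 0.0, 100.0  # overwhelming periclinal weight
        gp0 = GrowthParams(bias_floor=0.0)
        point, normal = choose_division_plane(cell, t, pp, gp0, rng=np.random.default_rng(0))
        r_hat, _ = surface_frame(point, t)
        # periclinal plane: normal along the radial direction
        assert abs(float(normal @ r_hat)) > np.cos(np.radians(15))

    def test_apical_corpus_follows_maximal_tension(self, gp):
        # constructed stress state: stretch a ring uniaxially along x so
        # the x-direction carries the most wall tension
        pp = PotentialParams()
        t = ring_cell(20, radius=3.0, layer="apical_corpus")
        cell = t.cells[0]
        for nid in cell.wall_ring:
            t.nodes[nid].position[0] *= 2.0  # uniaxial pre-stretch
        cell.cycle_progress = 1.0
        point, normal = choose_division_plane(cell, t, pp, gp)
        angle = np.degrees(np.arccos(abs(float(normal @ np.array([1.0, 0.0])))))
        assert angle < 15.0

    def test_boundary_cells_never_divide(self, gp):
        pp = PotentialParams()
        t = ring_cell(8, radius=2.0, layer="boundary_cell")
        assert choose_division_plane(t.cells[0], t, pp, gp) is None

    def test_tiny_cell_deferred_with_warning(self, gp):
        pp = PotentialParams()
        t = ring_cell(8, radius=0.5, layer="apical_corpus")
        with pytest.warns(UserWarning):
            assert choose_division_plane(t.cells[0], t, pp, gp) is None


class TestExecuteDivision:
    def test_symmetric_square_divides_equally(self):
        pp = PotentialParams()
        n = 16
        r = 3.0
        t = ring_cell(n, radius=r, n_cyt=4)
        cell = t.cells[0]
        area0 = t.cell_area(0)
        plane = (np.zeros(2), np.array([1.0, 0.0]))  # vertical cut through centre
        da, db = execute_division(cell, plane, t, pp)
        assert len(t.cells) == 2
        a1, a2 = t.cell_area(da.id), t.cell_area(db.id)
        assert a1 == pytest.approx(a2, rel=0.01)
        assert a1 + a2 == pytest.approx(area0, rel=0.05)
        # both daughter rings are closed, positively oriented polygons
        for d in (da, db):
            pts = t.ring_positions(d)
            assert signed_area(pts) > 0
            assert d.cycle_progress == 0.0
        # the new shared walls adhere pairwise
        assert t.adhesion_pairs
        t.validate()

    def test_in_plane_division_adds_exactly_one_cell(self):
        pp = PotentialParams()
        t = ring_cell(14, radius=3.0, n_cyt=3)
        n0 = len(t.cells)
        execute_division(t.cells[0], (np.zeros(2), np.array([0.0, 1.0])), t, pp)
        assert len(t.cells) == n0 + 1

    def test_out_of_plane_division_keeps_cell_count(self):
        gp = GrowthParams()
        t = ring_cell(14, radius=3.0, n_cyt=8)
        cell = t.cells[0]
        cell.cycle_progress = 1.0
        n_cyt0 = len(cell.cytoplasm)
        execute_out_of_plane_division(cell, t, gp)
        assert len(t.cells) == 1
        assert cell.cycle_progress == 0.0
        assert len(cell.cytoplasm) == max(int(round(0.75 * n_cyt0)), 1)
        t.validate()

    def test_plane_missing_polygon_raises(self):
        pp = PotentialParams()
        t = ring_cell(10, radius=2.0, n_cyt=2)
        from samsce.growth import DivisionGeometryError

        with pytest.raises(DivisionGeometryError):
            execute_division(
                t.cells[0], (np.array([50.0, 0.0]), np.array([1.0, 0.0])), t, pp
            )

    def test_lineage_ids_are_fresh(self):
        pp = PotentialParams()
        t = ring_cell(12, radius=3.0, n_cyt=2)
        da, db = execute_division(t.cells[0], (np.zeros(2), np.array([1.0, 0.0])), t, pp)
        assert 0 not in t.cells
        assert da.id != db.id


class TestPlaneAngle:
    def test_uniform_angles_give_half_periclinal(self):
        import pandas as pd

        from samsce import percent_periclinal

        rng = np.random.default_rng(11)
        angles = rng.uniform(0.0, 90.0, size=4000)
        df = pd.DataFrame({"kind": "in_plane", "layer": "apical_corpus", "angle_deg": angles})
        pct = percent_periclinal(df, "apical_corpus")
        assert pct == pytest.approx(50.0, abs=3.0)

    def test_exact_45_degrees_counts_anticlinal(self):
        import pandas as pd

        from samsce import percent_periclinal

        df = pd.DataFrame(
            {"kind": "in_plane", "layer": "apical_corpus", "angle_deg": [45.0] * 10}
        )
        assert percent_periclinal(df, "apical_corpus") == 0.0

    def test_three_periclinal_one_anticlinal(self):
        import pandas as pd

        from samsce import percent_periclinal

        df = pd.DataFrame(
            {"kind": "in_plane", "layer": "L1", "angle_deg": [10.0, 20.0, 30.0, 80.0]}
        )
        assert percent_periclinal(df, "L1") == 75.0
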