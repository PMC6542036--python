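"""Geometry construction, sink density and finite-volume grids."""

import math

import numpy as np
import pytest

from tumortrans.geometry import build_grid, make_geometry, sink_density
from tumortrans.params import load_solute_preset


class TestMakeGeometry:
    def test_dual_blood_co_current(self):
        g = make_geometry("2BC", L=100e-6, flow_mode="CO")
        assert g.n == 2
        assert all(v.kind == "blood" for v in g.vessels)
        assert g.vessels[0].flow_sign == g.vessels[1].flow_sign
        assert g.D == pytest.approx(200e-6)

    def test_blood_lymph_counter_current(self):
        g = make_geometry("BC_LC", L=100e-6, flow_mode="CN")
        assert tuple(v.kind for v in g.vessels) == ("blood", "lymph")
        assert g.vessels[0].flow_sign != g.vessels[1].flow_sign
        assert g.vessels[1].lp == pytest.approx(10 * g.vessels[0].lp)

    def test_single_capillary_defaults(self):
        g = make_geometry("SBC")
        assert g.n == 1
        assert g.D == pytest.approx(200e-6)
        assert g.L == pytest.approx(100e-6)   # L := D/2 convention
        assert g.flow_mode == "NA"
        assert g.layout == "axisym"

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            make_geometry("SBC", flow_mode="CN")
        with pytest.raises(ValueError):
            make_geometry("2BC", L=300e-6, flow_mode="CO", D=200e-6)
        with pytest.raises(ValueError):
            make_geometry("2BC", L=100e-6)  # flow mode required


class TestSinkDensity:
    def test_single_capillary_baseline(self):
        g = make_geometry("SBC")
        assert sink_density(g).s_density == pytest.approx(1000.0)

    def test_decay_time_for_70kda(self):
        g = make_geometry("SBC")
        k = sink_density(g, load_solute_preset(70.0)).k_decay
        assert 1.0 / k == pytest.approx(3333.33, rel=1e-3)

    def test_linearity_in_vessel_count(self):
        s1 = sink_density(make_geometry("SBC", D=200e-6)).s_density
        s2 = sink_density(make_geometry("2BC", L=100e-6, flow_mode="CO",
                                        D=200e-6)).s_density
        assert s2 == pytest.approx(2 * s1)

    def test_pair_matches_doubled_diameter_single(self):
        # two merged capillaries expose the same wall area per tissue volume
        # as one capillary of twice the diameter
        import dataclasses
        from tumortrans.params import baseline_tumor
        _, v = baseline_tumor()
        g_pair = make_geometry("2BC", L=10e-6, flow_mode="CO", D=200e-6)
        v2 = dataclasses.replace(v, d=2 * v.d)
        g_single = make_geometry("SBC", D=200e-6, vessel=v2)
        assert sink_density(g_pair).s_density == pytest.approx(
            sink_density(g_single).s_density
        )


class TestGrids:
    def test_axisym_cell_and_wall_face_counts(self):
        grid = build_grid(make_geometry("SBC"), nr=40, nz=40)
        assert grid.n_cells == 1600
        wall = grid.bf_kind == 1
        assert wall.sum() == 1            # one wall face record per side
        # wall faces span all nz slices in the solver; area closure below

    @pytest.mark.parametrize("config,L", [
        ("SBC", None), ("2BC", 100e-6), ("BC_LC", 100e-6),
        ("2BC", 10e-6), ("2BC", 1250e-6),
    ])
    def test_volume_and_wall_area_closure(self, config, L):
        kw = {} if config == "SBC" else {"L": L, "flow_mode": "CO"}
        g = make_geometry(config, **kw)
        grid = build_grid(g, nr=32, nz=10)
        d = g.vessels[0].d
        l = g.vessels[0].length
        v_exact = math.pi * (g.D**2 - g.n * d**2) / 4 * l
        assert grid.tissue_volume() == pytest.approx(v_exact, rel=1e-3)
        assert grid.wall_area() == pytest.approx(g.n * math.pi * d * l, rel=1e-3)
        assert np.all(grid.vol_per_dz > 0)

    def test_refinement_halves_max_spacing(self):
        g = make_geometry("SBC")
        w1 = build_grid(g, nr=20, nz=8).col_width.max()
        w2 = build_grid(g, nr=40, nz=8).col_width.max()
        assert w1 / w2 == pytest.approx(2.0, rel=0.1)

    def test_degenerate_geometry_rejected(self):
        import dataclasses
        from tumortrans.params import baseline_tumor
        _, v = baseline_tumor()
        fat = dataclasses.replace(v, d=250e-6)
        with pytest.raises(ValueError):
            build_grid(make_geometry("SBC", D=200e-6, vessel=fat), nr=16, nz=8)

    def test_station_weights_average_to_one(self):
        for config, L in (("SBC", None), ("BC_LC", 100e-6)):
            kw = {} if config == "SBC" else {"L": L, "flow_mode": "CO"}
            grid = build_grid(make_geometry(config, **kw), nr=24, nz=8)
            w = grid.station_weights(0.2 * grid.geometry.L)
            assert w.sum() == pytest.approx(1.0)
            assert np.all(w >= 0)

    def test_volume_average_weights_partition(self):
        grid = build_grid(make_geometry("BC_LC", L=100e-6, flow_mode="CO"),
                          nr=24, nz=8)
        w_all = grid.volume_average_weights("all")
        w_blood = grid.volume_average_weights("blood")
        assert w_all.sum() == pytest.approx(1.0)
        assert w_blood.sum() == pytest.approx(1.0)
        # the blood Voronoi region is a strict subset of the domain
        assert (w_blood > 0).sum() < (w_all > 0).sum()
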