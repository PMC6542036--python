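"""Numerical-core oracles: lumen flow, transmural fluxes, Darcy pressure,
conservation, homogenized-sink limit and self-convergence."""

import dataclasses
import math

import numpy as np
import pytest

from tumortrans.geometry import make_geometry
from tumortrans.params import load_solute_preset
from tumortrans.solver import (
    PerfusionModel,
    SolverOptions,
    effective_diffusivity,
    run_simulation,
    solve_lumen_flow,
    transmural_fluid_flux,
    transmural_solute_flux,
)


class TestEffectiveDiffusivity:
    @pytest.mark.parametrize("mw, printed", [(0.1, 25.4), (3.0, 133.4)])
    def test_diffusion_timescale_matches_published(self, mw, printed, tissue):
        # oracle: direct arithmetic L^2 / (phi * R_F * D_f) at L = 100 um
        s = load_solute_preset(mw)
        tau = (100e-6) ** 2 / effective_diffusivity(s, tissue)
        assert tau == pytest.approx(printed, rel=2.5e-3)

    def test_identity_limit(self, tissue):
        s = load_solute_preset(10.0)
        t1 = dataclasses.replace(tissue, phi=0.999999)
        s1 = dataclasses.replace(s, r_f=1.0)
        assert effective_diffusivity(s1, t1) == pytest.approx(s.d_f, rel=1e-5)


class TestLumenFlow:
    def test_poiseuille_velocity_and_pressure_profile(self, vessel):
        p, u = solve_lumen_flow(vessel, nz=4)
        # U = dP d^2 / (32 mu l) with baseline parameters
        assert u == pytest.approx(2394 * (1e-5) ** 2 / (32 * 3e-3 * 1e-3), rel=1e-12)
        assert u == pytest.approx(2.49e-3, rel=2e-3)
        # cell-center pressures bracket the 4394 -> 2000 Pa drop
        assert p[0] == pytest.approx(4394 - 2394 / 8)
        assert p[-1] == pytest.approx(2000 + 2394 / 8)
        assert np.all(np.diff(p) < 0)

    def test_no_pressure_drop_means_no_flow(self, vessel):
        v = dataclasses.replace(vessel, dp=0.0)
        p, u = solve_lumen_flow(v, nz=3)
        assert u == 0.0
        assert np.ptp(p) == 0.0

    def test_lymph_vessel_is_stagnant(self):
        g = make_geometry("BC_LC", L=100e-6, flow_mode="CO")
        p, u = solve_lumen_flow(g.vessels[1], nz=5)
        assert u == 0.0
        assert np.all(p == g.vessels[1].p_arteriole)


class TestTransmuralFluxes:
    def test_starling_filtration_arithmetic(self, vessel):
        s = load_solute_preset(0.1)
        jv = transmural_fluid_flux(4394.0, 2700.0, vessel, s)
        assert jv == pytest.approx(1.694e-6, rel=1e-3)

    def test_starling_equilibrium(self, vessel):
        s = load_solute_preset(70.0)
        p_i = 3000.0
        jv = transmural_fluid_flux(p_i + s.sigma * vessel.dpi_osm, p_i, vessel, s)
        assert jv == pytest.approx(0.0, abs=1e-18)

    def test_lymph_wall_is_one_way(self):
        g = make_geometry("BC_LC", L=100e-6, flow_mode="CO")
        lymph = g.vessels[1]
        s = load_solute_preset(3.0)
        assert transmural_fluid_flux(0.0, 2700.0, lymph, s) < 0
        assert transmural_fluid_flux(0.0, -10.0, lymph, s) == 0.0

    def test_solute_flux_cases(self, vessel):
        s = load_solute_preset(0.1)
        assert transmural_solute_flux(0.0, 1.0, 1.0, s) == pytest.approx(0.0)
        # diffusive flux at the inlet concentration
        assert transmural_solute_flux(0.0, s.c0, 0.0, s) == pytest.approx(
            4.888e-5, rel=1e-3
        )
        # perfect reflection with no diffusive leak
        s_wall = dataclasses.replace(s, sigma=1.0, p_d=1e-30)
        assert transmural_solute_flux(1e-6, 5.0, 0.0, s_wall) == pytest.approx(
            0.0, abs=1e-25
        )

    def test_upwinding_switches_with_flow_direction(self):
        s = load_solute_preset(10.0)
        out = transmural_solute_flux(1e-6, 2.0, 1.0, s)
        back = transmural_solute_flux(-1e-6, 2.0, 1.0, s)
        # filtration carries lumen fluid; reabsorption carries tissue fluid
        assert out - s.p_d * 1.0 == pytest.approx((1 - s.sigma) * 1e-6 * 2.0)
        assert back - s.p_d * 1.0 == pytest.approx(-(1 - s.sigma) * 1e-6 * 1.0)


class TestInterstitialPressure:
    def test_uniform_equilibrium(self, tissue, vessel):
        # wall pressure balancing the boundary pressure gives p == Po, u == 0
        s = load_solute_preset(0.1)
        v = dataclasses.replace(
            vessel, dp=0.0, p_arteriole=tissue.p0 + s.sigma * vessel.dpi_osm
        )
        g = make_geometry("SBC", vessel=v)
        m = PerfusionModel(g, s, tissue, SolverOptions(nr=16, nz=8))
        assert np.allclose(m.p_tissue, tissue.p0, atol=1e-8)
        assert np.allclose(m.q_if, 0.0, atol=1e-20)

    def test_discrete_conservation(self, tissue, vessel):
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        m = PerfusionModel(g, s, tissue, SolverOptions(nr=16, nz=8))
        nz = m.grid.nz
        # per-cell divergence: interior fluxes + wall inflow + envelope outflow
        div = np.zeros(m.grid.n_cells)
        for f in range(m.grid.if_left.size):
            for j in range(nz):
                q = m.q_if[f * nz + j]
                div[m.grid.if_left[f] * nz + j] -= q
                div[m.grid.if_right[f] * nz + j] += q
        for c in range(m.grid.ncols):
            for j in range(nz - 1):
                q = m.q_ax[c * (nz - 1) + j]
                div[c * nz + j] -= q
                div[c * nz + j + 1] += q
        for f in range(m.grid.bf_col.size):
            for j in range(nz):
                div[m.grid.bf_col[f] * nz + j] += m.q_wall[f * nz + j]
                div[m.grid.bf_col[f] * nz + j] -= m.q_env[f * nz + j]
        assert np.max(np.abs(div)) < 1e-16

    def test_axisymmetric_annulus_matches_closed_form(self, tissue, vessel):
        # z-uniform wall pressure -> p(r) = Po + B ln(r/b) with B from the
        # Robin wall condition (independent log-profile oracle)
        s = load_solute_preset(0.1)
        v = dataclasses.replace(vessel, dp=0.0)
        g = make_geometry("SBC", vessel=v)
        m = PerfusionModel(g, s, tissue, SolverOptions(nr=80, nz=8))
        a, b = v.d / 2, g.D / 2
        pv_eff = v.p_arteriole - s.sigma * v.dpi_osm
        B = -v.lp * a * (pv_eff - tissue.p0) / (
            tissue.k_hyd + v.lp * a * math.log(b / a)
        )
        r = m.grid.col_center
        p_exact = tissue.p0 + B * np.log(r / b)
        p_num = m.p_tissue.reshape(m.grid.ncols, m.grid.nz)[:, 4]
        scale = p_exact.max() - tissue.p0
        assert np.max(np.abs(p_num - p_exact)) / scale < 0.01

    def test_all_neumann_rejected_with_guidance(self, tissue, vessel):
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        with pytest.raises(ValueError, match="outer"):
            PerfusionModel(g, s, tissue,
                           SolverOptions(nr=12, nz=8, outer_pressure_bc="noflux"))


class TestAdvanceSolute:
    def test_no_wall_exchange_keeps_tissue_empty(self, tissue):
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        opts = SolverOptions(nr=12, nz=8, dt=5.0, duration=600.0,
                             vascular_porosity=0.0, no_flow=True)
        h = run_simulation(g, s, tissue, options=opts)
        assert np.all(h.c_norm_volume == 0.0)

    def test_closed_system_conserves_mass(self, tissue):
        # sealed fluid (no flow), inlet off, solute preloaded in the tissue:
        # total moles constant over many steps
        s = load_solute_preset(10.0)
        g = make_geometry("SBC")
        opts = SolverOptions(nr=10, nz=6, dt=1.0, duration=100.0,
                             inlet_mode="off", no_flow=True, c_tissue0=1.0)
        m = PerfusionModel(g, s, tissue, opts)
        state = m.initial_state()
        total0 = float(m.mass @ m._pack(state))
        for _ in range(10_000):
            state = m.advance_solute(state, 1.0)
        total = float(m.mass @ m._pack(state))
        assert total == pytest.approx(total0, rel=5e-3)

    def test_well_mixed_limit_matches_homogenized_sink(self, tissue):
        # with very fast interstitial mixing and an empty reservoir lumen the
        # volume-mean decays as exp(-P_d S t / phi) (closed-form ODE oracle)
        s = load_solute_preset(10.0)
        g = make_geometry("SBC")
        opts = SolverOptions(nr=16, nz=8, dt=1.0, duration=1000.0,
                             output_dt=100.0, inlet_mode="off", no_flow=True,
                             prescribed_lumen=True, c_tissue0=1.0,
                             d_tissue=1e-6)
        h = run_simulation(g, s, tissue, options=opts)
        k = s.p_d * 1000.0          # P_d * S at baseline geometry
        expected = (1.0 / s.c0) * np.exp(-k * h.time_s / tissue.phi)
        assert np.allclose(h.c_norm_volume, expected, rtol=0.02)

    def test_concentrations_remain_nonnegative(self, tissue):
        for mw in (0.1, 70.0):
            s = load_solute_preset(mw)
            g = make_geometry("BC_LC", L=100e-6, flow_mode="CO")
            h = run_simulation(g, s, tissue,
                               options=SolverOptions(nr=16, nz=10, dt=2.0,
                                                     duration=1800.0))
            assert h.c_norm_volume.min() >= 0.0
            assert h.c_norm_surface.min() >= 0.0


class TestRunSimulation:
    def test_history_starts_at_zero_and_is_unimodal(self, tissue):
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        h = run_simulation(g, s, tissue,
                           options=SolverOptions(nr=20, nz=20, dt=2.0,
                                                 duration=3600.0))
        y = h.c_norm_volume
        assert y[0] == 0.0
        ipk = int(np.argmax(y))
        assert 0 < ipk < y.size - 1
        assert np.all(np.diff(y[:ipk]) > 0)          # monotone rise
        assert np.all(np.diff(y[ipk:]) < 1e-12)      # monotone decay

    def test_short_run_flags_unbracketed_peak(self, tissue):
        s = load_solute_preset(70.0)
        g = make_geometry("SBC")
        h = run_simulation(g, s, tissue,
                           options=SolverOptions(nr=12, nz=8, dt=5.0,
                                                 duration=120.0))
        assert not h.peak_bracketed

    def test_mass_ledger_closes(self, tissue):
        s = load_solute_preset(3.0)
        g = make_geometry("BC_LC", L=100e-6, flow_mode="CO")
        h = run_simulation(g, s, tissue,
                           options=SolverOptions(nr=16, nz=10, dt=2.0,
                                                 duration=1800.0))
        led = h.ledger
        assert abs(led["residual"]) <= 5e-3 * led["inlet_in"]
        assert led["lymph_drain"] > 0.0

    def test_time_step_halving_changes_peak_below_one_percent(self, tissue):
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        peaks = []
        for dt in (2.0, 1.0):
            h = run_simulation(g, s, tissue,
                               options=SolverOptions(nr=20, nz=20, dt=dt,
                                                     duration=1800.0))
            peaks.append(h.c_norm_volume.max())
        assert abs(peaks[1] - peaks[0]) / peaks[1] < 0.01

    def test_grid_self_convergence_is_at_least_first_order(self, tissue):
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        peaks = {}
        for nr in (10, 20, 40):
            h = run_simulation(g, s, tissue,
                               options=SolverOptions(nr=nr, nz=10, dt=1.0,
                                                     duration=1200.0))
            peaks[nr] = h.c_norm_volume.max()
        e1 = abs(peaks[20] - peaks[10])
        e2 = abs(peaks[40] - peaks[20])
        order = math.log2(e1 / e2)
        assert order >= 1.0
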