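"""Timescale decomposition, T*/C* rescaling and peak aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumortrans.geometry import make_geometry
from tumortrans.nondim import (
    TimescaleSet,
    aggregate_t_peak,
    compute_timescales,
    nondimensionalize,
    parabolic_peak,
)
from tumortrans.params import SOLUTE_MWS, load_solute_preset
from tumortrans.solver import ConcentrationHistory


def _history(t, y, phi=0.4):
    z = np.zeros_like(np.asarray(t, float))
    return ConcentrationHistory(
        time_s=np.asarray(t, float),
        c_norm_volume=np.asarray(y, float),
        c_norm_surface=z,
        metadata={"phi": phi, "d_m": 10e-6},
    )


class TestTimescales:
    @pytest.mark.parametrize("mw, decay", [
        (0.1, 125.0), (3.0, 574.7), (10.0, 1428.6), (40.0, 3030.3), (70.0, 3333.33),
    ])
    def test_decay_timescales_match_published_to_4_sig_figs(self, mw, decay, tissue):
        ts = compute_timescales(load_solute_preset(mw), make_geometry("SBC"), tissue)
        assert ts.tau_decay == pytest.approx(decay, rel=5e-4)

    def test_scaled_input_timescale(self, tissue):
        ts = compute_timescales(load_solute_preset(0.1), make_geometry("SBC"), tissue)
        assert ts.tau_input_scaled == pytest.approx(2845.0)   # 1 * 284.5 * 10

    def test_denominator_is_exact_sum(self, tissue):
        for mw in SOLUTE_MWS:
            ts = compute_timescales(load_solute_preset(mw), make_geometry("SBC"), tissue)
            assert ts.t_star_denominator == ts.tau_input_scaled + ts.tau_diff + ts.tau_decay

    def test_dual_configuration_scales_input_and_decay(self, tissue):
        s = load_solute_preset(10.0)
        sbc = compute_timescales(s, make_geometry("SBC"), tissue)
        dual = compute_timescales(
            s, make_geometry("2BC", L=100e-6, flow_mode="CO"), tissue
        )
        assert dual.tau_input_scaled == pytest.approx(2 * sbc.tau_input_scaled)
        assert dual.tau_decay == pytest.approx(sbc.tau_decay / 2)
        assert dual.tau_diff == pytest.approx(sbc.tau_diff)


class TestParabolicPeak:
    def test_recovers_quadratic_exactly(self):
        t = np.linspace(0, 10, 21)
        y = 3.0 - (t - 4.321) ** 2
        tp, yp, ok = parabolic_peak(t, y)
        assert ok
        assert tp == pytest.approx(4.321, abs=1e-9)
        assert yp == pytest.approx(3.0, abs=1e-9)

    def test_edge_maximum_is_flagged(self):
        t = np.arange(5.0)
        tp, yp, ok = parabolic_peak(t, t)
        assert not ok
        assert tp == 4.0

    @given(st.floats(1.0, 9.0), st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_interior_peak_is_bracketed(self, center, height):
        t = np.linspace(0, 10, 41)
        y = height * np.exp(-((t - center) ** 2))
        tp, yp, ok = parabolic_peak(t, y)
        assert ok
        assert abs(tp - center) < 0.3
        assert yp >= y.max() - 1e-12


class TestNondimensionalize:
    def test_printed_small_solute_peak_time_maps_into_band(self, tissue):
        # arithmetic oracle: a 2.4 min peak against the single-capillary
        # timescale sum 2845 + 25.4 + 125 s gives T*_peak ~ 0.048
        s = load_solute_preset(0.1)
        g = make_geometry("SBC")
        ts = compute_timescales(s, g, tissue)
        t = np.arange(0.0, 600.0, 6.0)
        y = np.exp(-((t - 144.0) / 80.0) ** 2)
        nd = nondimensionalize(_history(t, y), ts, s, g)
        assert nd.t_star_peak == pytest.approx(144.0 / 2995.4, rel=2e-3)
        assert not nd.excluded

    def test_t_star_zero_at_time_zero(self, tissue):
        s = load_solute_preset(3.0)
        g = make_geometry("SBC")
        ts = compute_timescales(s, g, tissue)
        t = np.arange(0.0, 100.0, 10.0)
        nd = nondimensionalize(_history(t, np.sin(t / 40)), ts, s, g)
        assert nd.t_star[0] == 0.0

    def test_invariance_to_time_units_and_concentration_scale(self, tissue):
        # T*_peak is a pure number: rescaling concentration leaves it fixed
        s = load_solute_preset(10.0)
        g = make_geometry("SBC")
        ts = compute_timescales(s, g, tissue)
        t = np.arange(0.0, 1200.0, 6.0)
        y = np.exp(-((t - 400.0) / 150.0) ** 2)
        a = nondimensionalize(_history(t, y), ts, s, g)
        b = nondimensionalize(_history(t, 7.3 * y), ts, s, g)
        assert a.t_star_peak == pytest.approx(b.t_star_peak, rel=1e-12)
        assert b.c_star_peak == pytest.approx(7.3 * a.c_star_peak, rel=1e-9)

    def test_large_separation_runs_are_flagged(self, tissue):
        s = load_solute_preset(3.0)
        g = make_geometry("2BC", L=1250e-6, flow_mode="CO")
        ts = compute_timescales(s, g, tissue)
        t = np.arange(0.0, 1200.0, 60.0)
        nd = nondimensionalize(_history(t, np.exp(-((t - 300) / 200.0) ** 2)),
                               ts, s, g)
        assert nd.excluded


class TestAggregate:
    def test_mean_and_population_std(self):
        runs = [_nd(0.02), _nd(0.04)]
        assert aggregate_t_peak(runs) == (pytest.approx(0.03), pytest.approx(0.01))

    def test_identical_runs_have_zero_spread(self):
        runs = [_nd(0.025)] * 5
        mean, std = aggregate_t_peak(runs)
        assert mean == pytest.approx(0.025)
        assert std == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_t_peak([])

    def test_exclusion_drops_outlier_candidates(self):
        runs = [_nd(0.03), _nd(0.003, excluded=True)]
        mean_all, _ = aggregate_t_peak(runs)
        mean_ex, _ = aggregate_t_peak(runs, exclude_ld125=True)
        assert mean_all == pytest.approx(0.0165)
        assert mean_ex == pytest.approx(0.03)


def _nd(tp, excluded=False):
    from tumortrans.nondim import NondimHistory
    ts = TimescaleSet(tau_input_scaled=100.0, tau_diff=10.0, tau_decay=10.0)
    t = np.array([0.0, 1.0, 2.0])
    return NondimHistory(
        t_star=t, c_star=t, t_star_peak=tp, c_star_peak=1.0,
        excluded=excluded, peak_bracketed=True, timescales=ts,
    )
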