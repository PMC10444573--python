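import numpy as np
import pytest

from hnburst import _kernels
from hnburst.kinetics import nernst_ena
from hnburst.reduced_model import (ReducedModelParams,
                                   ReducedState, currents_2d,
                                   measure_2d_cycle, na_flux, rhs_2d,
                                   simulate_2d, total_current)
from hnburst.trace import Trace


class TestCurrents:
    def test_k2_vanishes_at_k_reversal(self, reduced_params):
        cur = currents_2d(reduced_params.e_k, 0.012, reduced_params)
        assert cur["i_k2"] == pytest.approx(0.0, abs=1e-15)
        assert cur["i_leak_k"] == pytest.approx(0.0, abs=1e-15)

    def test_na_currents_vanish_at_na_reversal(self, reduced_params):
        nai = 0.012
        ena = nernst_ena(reduced_params.na_o, nai)
        cur = currents_2d(ena, nai, reduced_params)
        for name in ("i_nap", "i_nap_native", "i_naf", "i_leak_na"):
            assert cur[name] == pytest.approx(0.0, abs=1e-15)

    def test_h_split_is_three_sevenths(self, reduced_params):
        cur = currents_2d(-0.045, 0.012, reduced_params)
        assert cur["i_h_na"] / (cur["i_h_na"] + cur["i_h_k"]) == \
            pytest.approx(3.0 / 7.0, rel=1e-12)

    def test_printed_steady_state_formulas(self, reduced_params):
        # independent scalar evaluation of each published activation curve
        V, nai = -0.045, 0.012
        p = reduced_params
        ena = 0.02526 * np.log(p.na_o / nai)
        cur = currents_2d(V, nai, p)
        assert cur["i_nap_native"] == pytest.approx(
            9.85 / (1 + np.exp(-160 * (V + 0.0376))) * (V - ena), rel=1e-12)
        assert cur["i_nap"] == pytest.approx(
            6.0 / (1 + np.exp(-120 * (V + 0.04))) * (V - ena), rel=1e-12)
        assert cur["i_naf"] == pytest.approx(
            150.0 / (1 + np.exp(-210 * (V + 0.032))) ** 3
            / (1 + np.exp(500 * (V + 0.04))) * (V - ena), rel=1e-12)
        assert cur["i_k2"] == pytest.approx(
            138.0 / (1 + np.exp(-83 * (V + 0.0285))) ** 2 * (V + 0.07),
            rel=1e-12)
        mh = 1.0 / (1 + 2 * np.exp(184.14 * (V + 0.057))
                    + np.exp(511.5 * (V + 0.057)))
        assert cur["i_h_na"] + cur["i_h_k"] == pytest.approx(
            6.0 * mh ** 2 * (V + 0.021), rel=1e-12)

    def test_kernel_agrees_with_numpy_reference(self, reduced_params):
        rng = np.random.default_rng(0)
        p = reduced_params.to_vector()
        for _ in range(50):
            V = rng.uniform(-0.08, 0.01)
            nai = rng.uniform(0.005, 0.03)
            kern = _kernels.reduced_currents(V, nai, p)
            ref = currents_2d(V, nai, reduced_params)
            assert np.allclose(kern, list(ref.values()), rtol=1e-12)


class TestRhs:
    def test_zero_currents_give_zero_rhs(self):
        p = ReducedModelParams(g_nap_native=0, g_nap=0, g_naf=0, g_h=0,
                               g_k2=0, g_leak_na=0, g_leak_k=0, ipump_max=0)
        dv, dna = rhs_2d(ReducedState(-0.05, 0.012), p)
        assert dv == 0.0 and dna == 0.0

    def test_rhs_matches_assembly_from_currents(self, reduced_params):
        state = ReducedState(-0.05, 0.013)
        cur = currents_2d(state.v_m, state.na_i, reduced_params)
        dv, dna = rhs_2d(state, reduced_params)
        assert dv == pytest.approx(-sum(cur.values()) / reduced_params.c_m,
                                   rel=1e-12)
        na_terms = (cur["i_nap_native"] + cur["i_nap"] + 3 * cur["i_pump"]
                    + cur["i_naf"] + cur["i_h_na"] + cur["i_leak_na"])
        assert dna == pytest.approx(-na_terms / reduced_params.vf, rel=1e-12)

    def test_na_nullcline_balance(self, reduced_params):
        # when Na influx equals 3x pump flux the Na derivative vanishes
        V = -0.05
        from scipy.optimize import brentq
        nastar = brentq(lambda n: na_flux(V, n, reduced_params), 1e-4, 0.1)
        _, dna = rhs_2d(ReducedState(V, nastar), reduced_params)
        assert abs(dna) < 1e-9


class TestSimulate:
    def test_deterministic(self, reduced_params):
        a = simulate_2d(reduced_params, 5.0)
        b = simulate_2d(reduced_params, 5.0)
        assert np.array_equal(a.v_m, b.v_m)

    def test_rk4_matches_lsoda_timing(self, reduced_params):
        bd, ibi = {}, {}
        for method in ("lsoda", "rk4"):
            tr = simulate_2d(reduced_params, 60.0, method=method)
            c = measure_2d_cycle(tr, transient=20.0)
            bd[method], ibi[method] = c.bd, c.ibi
        assert bd["rk4"] == pytest.approx(bd["lsoda"], rel=5e-3)
        assert ibi["rk4"] == pytest.approx(ibi["lsoda"], rel=5e-3)

    def test_tolerance_halving_changes_timing_little(self, reduced_params):
        res = []
        for rtol in (1e-8, 5e-9):
            tr = simulate_2d(reduced_params, 60.0, rtol=rtol)
            c = measure_2d_cycle(tr, transient=20.0)
            res.append((c.bd, c.ibi))
        assert res[0][0] == pytest.approx(res[1][0], rel=5e-3)
        assert res[0][1] == pytest.approx(res[1][1], rel=5e-3)

    def test_per_cycle_na_flux_closes(self, reduced_trace_03):
        # over a full period the net Na+ change is below 1% of its amplitude
        c = measure_2d_cycle(reduced_trace_03, transient=20.0)
        tr = reduced_trace_03.window(20.0)
        ups = np.flatnonzero((tr.v_m[:-1] <= -0.045) & (tr.v_m[1:] > -0.045))
        i0, i1 = ups[0], ups[1]
        dna_cycle = abs(tr.na_i[i1] - tr.na_i[i0])
        assert dna_cycle < 0.01 * c.na_amplitude

    def test_time_scale_separation(self, reduced_params, reduced_trace_03):
        # total membrane current is small except during the two fast jumps
        tr = reduced_trace_03.window(20.0)
        itot = np.abs(total_current(tr.v_m, tr.na_i, reduced_params))
        frac = np.mean(itot > 0.05 * itot.max())
        assert frac < 0.10


class TestMeasure:
    @staticmethod
    def _trace_from(t, v):
        z = np.zeros_like(t)
        return Trace(t, v, z, z, np.full_like(t, 0.012))

    def test_square_wave(self):
        t = np.arange(0.0, 25.0, 1e-3)
        v = np.where((t % 5.0) < 2.0, -0.02, -0.06)
        c = measure_2d_cycle(self._trace_from(t, v))
        assert c.bd == pytest.approx(2.0, abs=2e-3)
        assert c.ibi == pytest.approx(3.0, abs=2e-3)
        assert c.period == pytest.approx(5.0, abs=2e-3)

    def test_sinusoid_symmetric_about_threshold(self):
        t = np.arange(0.0, 20.0, 1e-3)
        v = -0.045 + 0.01 * np.sin(2 * np.pi * t / 4.0)
        c = measure_2d_cycle(self._trace_from(t, v))
        assert c.bd == pytest.approx(2.0, rel=1e-3)
        assert c.ibi == pytest.approx(2.0, rel=1e-3)

    def test_flat_trace_raises(self):
        t = np.arange(0.0, 5.0, 1e-3)
        with pytest.raises(ValueError):
            measure_2d_cycle(self._trace_from(t, np.full_like(t, -0.06)))

    def test_fixed_point_init_stays_constant(self):
        # with only K+ currents left, rest at E_K is a stable fixed point
        p = ReducedModelParams(g_nap_native=0, g_nap=0, g_naf=0, g_h=0,
                               g_leak_na=0, ipump_max=0)
        tr = simulate_2d(p, 30.0, init=ReducedState(-0.07, 0.012))
        assert np.std(tr.v_m[-5000:]) < 1e-9
        assert np.std(tr.na_i[-5000:]) < 1e-12


class TestMonotoneTrends:
    def test_bd_and_ibi_decrease_with_pump_maximum(self, reduced_params):
        vals = []
        for imax in (0.2, 0.5, 0.9):
            tr = simulate_2d(reduced_params.with_(ipump_max=imax), 60.0,
                             method="rk4")
            c = measure_2d_cycle(tr, transient=20.0)
            vals.append((c.bd, c.ibi))
        bds, ibis = zip(*vals)
        assert bds[0] > bds[1] > bds[2]
        assert ibis[0] > ibis[1] > ibis[2]
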