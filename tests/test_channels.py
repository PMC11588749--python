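import numpy as np
import pytest

from cablehh.channels import (
    CHANNEL_PRESETS,
    ChannelSpec,
    GateSpec,
    accumulate_currents,
    build_rate_table,
    get_preset,
    steady_state,
    table_index,
    update_gates,
)
from cablehh.rates import RateFunction, vtrap


class TestVtrap:
    def test_limit_at_zero(self):
        assert vtrap(0.0, 10.0) == 10.0

    def test_matches_formula_away_from_zero(self):
        x = np.array([-25.0, -1.0, 0.5, 13.0])
        np.testing.assert_allclose(vtrap(x, 4.0), x / np.expm1(x / 4.0), rtol=1e-12)

    def test_continuous_across_the_guard(self):
        left, right = vtrap(-1e-7, 5.0), vtrap(1e-7, 5.0)
        assert abs(left - 5.0) < 1e-6 and abs(right - 5.0) < 1e-6


class TestRateExpressions:
    def test_parameters_bound_at_compile(self):
        f = RateFunction("0.5 * exp(-(v - vt) / 10.0)", {"vt": -60.0})
        np.testing.assert_allclose(f(-60.0), 0.5)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            RateFunction("alpha * v")

    def test_no_arbitrary_calls(self):
        with pytest.raises(ValueError):
            RateFunction("__import__('os').system('true')")
        with pytest.raises(ValueError):
            RateFunction("abs(v)")


class TestBuildRateTable:
    def test_zero_rates_give_identity_update(self):
        gate = GateSpec("z", "alpha-beta", 1, alpha="0.0 * v", beta="0.0 * v")
        t = build_rate_table(gate, dt=0.1, vgrid=(-100, 50, 64))
        np.testing.assert_array_equal(t.r1, 1.0)
        np.testing.assert_array_equal(t.r2, 0.0)
        x = np.array([0.3, 0.8])
        np.testing.assert_array_equal(update_gates(x, np.array([-65.0, 0.0]), t), x)

    def test_tau_equal_dt_jumps_to_xinf(self):
        gate = GateSpec("q", "tau-inf", 1, tau="0.0 * v + 0.02",
                        inf="1.0 / (1.0 + exp(-v / 10.0))")
        t = build_rate_table(gate, dt=0.02, vgrid=(-100, 50, 256), warn_unstable=False)
        np.testing.assert_allclose(t.r1, 0.0, atol=1e-15)
        v = t.bin_centers[100]
        x = update_gates(np.array([0.77]), np.array([v]), t)
        np.testing.assert_allclose(x, 1.0 / (1.0 + np.exp(-v / 10.0)), rtol=1e-12)

    def test_constant_rates_converge_to_alpha_fraction(self):
        # brute-force iteration oracle: fixed point of the affine map
        gate = GateSpec("c", "alpha-beta", 1, alpha="0.0 * v + 2.0",
                        beta="0.0 * v + 3.0")
        t = build_rate_table(gate, dt=0.01, vgrid=(-100, 50, 16))
        x = 0.97
        for _ in range(20000):
            x_new = float(update_gates(np.array([x]), np.array([-30.0]), t)[0])
            if abs(x_new - x) < 1e-16:
                break
            x = x_new
        assert abs(x - 0.4) < 1e-12

    def test_nonfinite_rate_raises(self):
        gate = GateSpec("bad", "alpha-beta", 1, alpha="exp(v * 50.0)", beta="0.0 * v")
        with pytest.raises(ValueError, match="mV"):
            build_rate_table(gate, dt=0.1, vgrid=(-100, 50, 64))

    def test_stability_guard_warns(self):
        gate = GateSpec("fast", "alpha-beta", 1, alpha="0.0 * v + 30.0",
                        beta="0.0 * v + 30.0")
        with pytest.warns(RuntimeWarning, match="stability"):
            build_rate_table(gate, dt=0.05, vgrid=(-100, 50, 64))


class TestUpdateGates:
    def test_fixed_voltage_converges_to_table_steady_state(self):
        gate = CHANNEL_PRESETS["squid_na"].gates[0]  # m
        t = build_rate_table(gate, dt=0.025, vgrid=(-100, 50, 4096))
        v = np.array([-40.0])
        idx = int(table_index(v, t.vmin, t.vmax, t.nbins)[0])
        fixed = t.r2[idx] / (1.0 - t.r1[idx])
        x = np.array([0.0])
        for _ in range(5000):
            x = update_gates(x, v, t)
        np.testing.assert_allclose(x, fixed, rtol=1e-12)

    def test_bin_center_lookup_equals_direct_formula(self):
        # at bin-centre voltages the table reproduces the direct update exactly
        for name in ("squid_na", "squid_k", "fs_na", "fs_kd", "fs_m"):
            for gate in CHANNEL_PRESETS[name].gates:
                dt = 0.03125
                t = build_rate_table(gate, dt, vgrid=(-100, 50, 512))
                v = t.bin_centers
                x = np.full_like(v, 0.5)
                got = update_gates(x, v, t)
                if gate.formalism == "alpha-beta":
                    a, b = gate.alpha(v), gate.beta(v)
                    direct = (1 - dt * (a + b)) * x + dt * a
                else:
                    tau, inf = gate.tau(v), gate.inf(v)
                    direct = (1 - dt / tau) * x + dt * inf / tau
                np.testing.assert_array_equal(got, direct)

    def test_out_of_range_voltage_saturates(self):
        gate = CHANNEL_PRESETS["squid_k"].gates[0]
        t = build_rate_table(gate, dt=0.025, vgrid=(-100, 50, 128))
        lo = update_gates(np.array([0.5]), np.array([-500.0]), t)
        hi = update_gates(np.array([0.5]), np.array([500.0]), t)
        lo_ref = update_gates(np.array([0.5]), np.array([t.bin_centers[0]]), t)
        hi_ref = update_gates(np.array([0.5]), np.array([t.bin_centers[-1]]), t)
        np.testing.assert_array_equal(lo, lo_ref)
        np.testing.assert_array_equal(hi, hi_ref)

    def test_monotone_approach_to_fixed_point(self):
        # frozen voltage: the affine recursion approaches its fixed point
        # monotonically whenever 0 < r1 < 1
        gate = CHANNEL_PRESETS["squid_na"].gates[1]  # h
        t = build_rate_table(gate, dt=0.03125, vgrid=(-100, 50, 1024))
        v = np.array([-55.0])
        x = np.array([0.99])
        prev = x.copy()
        diffs = []
        for _ in range(400):
            x = update_gates(x, v, t)
            diffs.append(float((x - prev)[0]))
            prev = x.copy()
        signs = np.sign([d for d in diffs if abs(d) > 1e-13])
        assert np.all(signs == signs[0])

    def test_table_error_shrinks_with_resolution(self):
        # global max error vs the direct update, off bin centres
        rng = np.random.default_rng(5)
        v = rng.uniform(-99.0, 49.0, 2000)
        x = rng.uniform(0.0, 1.0, 2000)
        for name, spec in CHANNEL_PRESETS.items():
            for gate in spec.gates:
                errs = {}
                for nbins in (1024, 8192):
                    t = build_rate_table(gate, 0.03125, vgrid=(-100, 50, nbins))
                    got = update_gates(x, v, t)
                    if gate.formalism == "alpha-beta":
                        a, b = gate.alpha(v), gate.beta(v)
                        direct = (1 - 0.03125 * (a + b)) * x + 0.03125 * a
                    else:
                        tau, inf = gate.tau(v), gate.inf(v)
                        direct = (1 - 0.03125 / tau) * x + 0.03125 * inf / tau
                    errs[nbins] = np.abs(got - direct).max()
                assert errs[8192] <= errs[1024], (name, gate.name, errs)

    def test_interpolated_lookup_is_closer_between_bins(self):
        gate = CHANNEL_PRESETS["squid_na"].gates[0]
        t = build_rate_table(gate, 0.025, vgrid=(-100, 50, 256))
        v = t.bin_centers[:-1] + 0.4 * t.bin_width
        x = np.full_like(v, 0.5)
        a, b = gate.alpha(v), gate.beta(v)
        direct = (1 - 0.025 * (a + b)) * x + 0.025 * a
        err_near = np.abs(update_gates(x, v, t) - direct).max()
        err_lin = np.abs(update_gates(x, v, t, interpolate=True) - direct).max()
        assert err_lin < err_near


class TestAccumulateCurrents:
    def test_leak_only(self):
        spec = get_preset("pas", erev=-70.0)
        idx = np.arange(3)
        gbar = np.array([1.0, 2.0, 3.0])
        g, gE = accumulate_currents({}, [(spec, idx, gbar)], n_nodes=3)
        np.testing.assert_allclose(g, gbar)
        np.testing.assert_allclose(gE, gbar * -70.0)

    def test_all_zero_densities(self):
        spec = get_preset("squid_na")
        g, gE = accumulate_currents({"m": np.ones(2), "h": np.ones(2)},
                                    [(spec, np.arange(2), np.zeros(2))], n_nodes=2)
        assert np.all(g == 0) and np.all(gE == 0)

    def test_squid_rest_matches_hand_computation(self):
        # direct steady-state gate evaluation is the oracle
        v = -65.0
        na, k, leak = (get_preset(n) for n in ("squid_na", "squid_k", "squid_leak"))
        m = float(na.gates[0].steady_state(v))
        h = float(na.gates[1].steady_state(v))
        n_ = float(k.gates[0].steady_state(v))
        gbar_na, gbar_k, gbar_l = 120.0, 36.0, 0.3  # uS (scaled)
        states = {"m": np.array([m]), "h": np.array([h]), "n": np.array([n_])}
        chans = [(na, np.array([0]), np.array([gbar_na])),
                 (k, np.array([0]), np.array([gbar_k])),
                 (leak, np.array([0]), np.array([gbar_l]))]
        g, gE = accumulate_currents(states, chans, n_nodes=1)
        expected_g = gbar_na * m**3 * h + gbar_k * n_**4 + gbar_l
        expected_gE = (gbar_na * m**3 * h * 50.0 + gbar_k * n_**4 * -77.0
                       + gbar_l * -54.3)
        np.testing.assert_allclose(g, [expected_g], rtol=1e-12)
        np.testing.assert_allclose(gE, [expected_gE], rtol=1e-12)

    def test_nan_conductance_raises(self):
        spec = get_preset("squid_k")
        with pytest.raises(FloatingPointError):
            accumulate_currents({"n": np.array([np.nan])},
                                [(spec, np.array([0]), np.ones(1))], n_nodes=1)


class TestSteadyState:
    def test_direct_value_preferred(self):
        gate = CHANNEL_PRESETS["squid_na"].gates[0]
        v = -65.0
        a, b = gate.alpha(v), gate.beta(v)
        assert np.isclose(steady_state(gate, v), a / (a + b))

    def test_table_fallback_when_rates_vanish(self):
        gate = GateSpec("z", "alpha-beta", 1, alpha="0.0 * v", beta="0.0 * v")
        t = build_rate_table(gate, 0.1, vgrid=(-100, 50, 16))
        with pytest.raises(ValueError):
            steady_state(gate, -65.0, t)  # 0/0 direct and r1 == 1 in table

    def test_gate_spec_validation(self):
        with pytest.raises(ValueError):
            GateSpec("m", "alpha-beta", 0, alpha="v", beta="v")
        with pytest.raises(ValueError):
            GateSpec("m", "weird", 1)
        with pytest.raises(ValueError):
            GateSpec("m", "tau-inf", 1, tau="1.0 + 0.0 * v")
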