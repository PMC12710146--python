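"""Deterministic model: rate functions, steady states, fixed points,
and the saddle-node (type-I) bifurcation."""

import numpy as np
import pytest

import hhcrit as hc
from hhcrit.hh import (DeterministicState, GatingState, ModelParams,
                      steady_gating, _current_balance)


class TestGatingRates:
    @pytest.mark.parametrize("gate,v,expected", [
        ("h_alpha", -48.0, 0.128),          # exponent exactly 0
        ("n_alpha", -50.0, 0.160),          # removable singularity limit
        ("m_alpha", -52.0, 1.280),
        ("m_beta", -25.0, 1.400),
        ("m_beta", -63.0, 10.645327),       # direct evaluation
    ])
    def test_values(self, gate, v, expected):
        assert hc.gating_rate(gate, v) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("gate,vstar", [
        ("n_alpha", -50.0), ("m_alpha", -52.0), ("m_beta", -25.0)])
    def test_continuity_at_singularities(self, gate, vstar):
        at = hc.gating_rate(gate, vstar)
        for dv in (-1e-6, 1e-6):
            assert abs(at - hc.gating_rate(gate, vstar + dv)) < 1e-6

    def test_nonnegative_and_finite(self):
        v = np.linspace(-120.0, 60.0, 361)
        for g in ("n_alpha", "m_alpha", "h_alpha",
                  "n_beta", "m_beta", "h_beta"):
            r = hc.gating_rate(g, v)
            assert np.all(r >= 0) and np.all(np.isfinite(r))

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            hc.gating_rate("n_alpha", np.nan)

    def test_scalar_vs_compiled_kernel_agree(self):
        from hhcrit import _kernels as k
        fns = {"n_alpha": k.alpha_n_s, "m_alpha": k.alpha_m_s,
               "h_alpha": k.alpha_h_s, "n_beta": k.beta_n_s,
               "m_beta": k.beta_m_s, "h_beta": k.beta_h_s}
        for v in np.linspace(-100, 40, 57):
            for name, f in fns.items():
                assert f(v) == pytest.approx(hc.gating_rate(name, v),
                                             rel=1e-12, abs=1e-300)


class TestSteadyStates:
    def test_known_values(self):
        assert hc.steady_state("m", -63.0) == pytest.approx(0.02208, abs=2e-4)
        assert hc.steady_state("h", -63.0) == pytest.approx(0.9933, abs=1e-3)

    def test_fixed_point_equation(self):
        # alpha(1-x) - beta*x = 0 at x = x_inf, over a voltage grid
        for v in np.linspace(-100.0, 60.0, 100):
            for gate in ("m", "h", "n"):
                x = hc.steady_state(gate, v)
                a = hc.gating_rate(f"{gate}_alpha", v)
                b = hc.gating_rate(f"{gate}_beta", v)
                assert abs(a * (1 - x) - b * x) < 1e-12 * max(a, b, 1.0)

    def test_long_time_limit_of_kinetics(self):
        # integrating dx/dt = a(1-x) - b x relaxes onto x_inf
        v = -63.0
        st = DeterministicState(V=v, gating=GatingState(0.5, 0.5, 0.5))
        # clamp V by zeroing all conductances and currents
        params = ModelParams(gNa_bar=0, gK_bar=0, gL=1e-9)
        tr = hc.integrate_deterministic(st, 0.0, 200.0, params=params)
        # V barely moves; gates relax to steady state at ~v
        assert tr["m"][-1] == pytest.approx(hc.steady_state("m", tr["V"][-1]),
                                            abs=1e-6)
        assert tr["h"][-1] == pytest.approx(hc.steady_state("h", tr["V"][-1]),
                                            abs=1e-6)


class TestIonicCurrents:
    def test_zero_driving_force(self):
        p = ModelParams()
        ina, _, _ = hc.ionic_currents(p.ENa, GatingState(0.5, 0.5, 0.5), p)
        assert ina == 0.0

    def test_all_zero_at_leak_reversal_with_closed_gates(self):
        p = ModelParams()
        ina, ik, il = hc.ionic_currents(p.EL, GatingState(0, 0, 0), p)
        assert ina == ik == il == 0.0

    def test_potassium_negligible_subthreshold(self):
        # voltage-clamp decomposition: |IK| smallest in the resting band
        p = ModelParams()
        for v in (-64.0, -62.0, -60.0):
            ina, ik, il = hc.ionic_currents(v, steady_gating(v), p)
            assert abs(ik) < abs(ina) and abs(ik) < abs(il)

    def test_blocked_K_removes_current(self):
        p = ModelParams().blocked()
        _, ik, _ = hc.ionic_currents(-30.0, GatingState(0.9, 0.5, 0.9), p)
        assert ik == 0.0


class TestFixedPoints:
    def test_rest_bracket(self):
        vr = hc.find_fixed_point(0.0)
        assert -63.563 < vr < -62.5

    def test_leak_only_closed_form(self):
        p = ModelParams(gNa_bar=0.0, gK_bar=0.0)
        for iex in (-0.1, 0.0, 0.2):
            assert hc.find_fixed_point(iex, p) == pytest.approx(
                p.EL + iex / p.gL, abs=1e-8)

    def test_monotone_in_current(self):
        vrs = [hc.find_fixed_point(i) for i in (-0.2, -0.1, 0.0, 0.2, 0.35)]
        assert np.all(np.diff(vrs) > 0)

    def test_current_balance_at_rest(self):
        for iex in (0.0, 0.2):
            vr = hc.find_fixed_point(iex)
            assert abs(_current_balance(vr, iex, ModelParams())) < 1e-9

    def test_above_bifurcation_raises(self):
        # no stable root remains in the resting band at strong drive
        with pytest.raises(ValueError):
            hc.find_fixed_point(5.0, v_hi=-50.0)


class TestIntegration:
    def test_equilibrium_stays_put(self):
        vr = hc.find_fixed_point(0.0)
        st = DeterministicState(V=vr, gating=steady_gating(vr))
        tr = hc.integrate_deterministic(st, 0.0, 100.0)
        assert np.max(np.abs(tr["V"] - vr)) < 1e-6

    def test_convergence_to_rest(self):
        st = DeterministicState(V=-70.0, gating=steady_gating(-70.0))
        tr = hc.integrate_deterministic(st, 0.0, 500.0)
        vr = hc.find_fixed_point(0.0)
        assert abs(tr["V"][-1] - vr) < 1e-6
        assert ModelParams().EL < tr["V"][-1] < ModelParams().EL + 1.0

    def test_blocked_K_plateau(self):
        p = ModelParams().blocked()
        st = DeterministicState(V=-20.0, gating=steady_gating(-20.0))
        tr = hc.integrate_deterministic(st, 0.0, 500.0, params=p)
        root = hc.find_fixed_point(0.0, p, v_lo=-40.0, v_hi=5.0)
        assert tr["V"][-1] == pytest.approx(root, abs=0.01)
        assert -12.0 < tr["V"][-1] < -5.0

    def test_invalid_steps_rejected(self):
        st = DeterministicState(V=-63.0, gating=steady_gating(-63.0))
        with pytest.raises(ValueError):
            hc.integrate_deterministic(st, 0.0, -1.0)


class TestBifurcation:
    @pytest.fixture(scope="class")
    def bif(self):
        return hc.find_bifurcation()

    def test_rheobase_above_sweep(self, bif):
        assert bif.Ic > 0.35

    def test_vc_above_rest(self, bif):
        assert bif.Vc > bif.Vr(0.0)

    def test_vr_approaches_vc(self, bif):
        d1 = bif.Vc - hc.find_fixed_point(bif.Ic - 0.02)
        d2 = bif.Vc - hc.find_fixed_point(bif.Ic - 0.005)
        assert d1 > d2 >= 0

    def test_type_one_frequency_onset(self, bif):
        # firing rate rises continuously from zero above rheobase
        freqs = []
        for di in (0.01, 0.05, 0.2):
            st = DeterministicState(V=-63.0, gating=steady_gating(-63.0))
            tr = hc.integrate_deterministic(st, bif.Ic + di, 1100.0)
            v = tr["V"][tr["t"] >= 100.0]
            ups = np.count_nonzero((v[:-1] < 0) & (v[1:] >= 0))
            freqs.append(ups)
        assert freqs[0] < freqs[1] < freqs[2]
        assert freqs[0] < 0.5 * freqs[2]


def test_params_json_roundtrip(tmp_path):
    p = ModelParams(A=60.0)
    f = tmp_path / "params.json"
    p.to_json(f)
    assert ModelParams.from_json(f) == p


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams(C=-1.0)
    with pytest.raises(ValueError):
        ModelParams(A=0.001)   # no channels
    # blocked model may drop K channels entirely
    assert ModelParams(blocked_K=True).n_k == 0
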