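"""Unit tests of the HCO vector field against independently coded
formulas, plus the model's structural invariants."""

import math

import numpy as np
import pytest

from pawshake.model import (ModelParameters, NeuronState, HCOState,
                            PulseSpec, gate_kinetics, membrane_currents,
                            derivatives, GATE_IDS)

# ---------------------------------------------------------------------------
# Independent oracle: every printed equation retyped from scratch, kept
# free of any pawshake internals.
# ---------------------------------------------------------------------------

def oracle_rates(V, h_naf, m_nas, h_nas, m_k, m_cas, h_cas, m_syn, v_pre,
                 p, g_e):
    e = math.exp
    m_naf = 1 / (1 + e((V + 20) / -7.8))
    i_naf = p.g_NaF * m_naf ** 3 * h_naf * (V - p.E_Na)
    i_nas = p.g_NaS * m_nas * h_nas * (V - p.E_Na)
    i_k = p.g_K * m_k ** 4 * (V - p.E_K)
    i_cas = p.g_CaS * m_cas ** 3 * h_cas * (V - p.E_Ca)
    i_leak = p.g_leak * (V - p.E_leak)
    m_syn_pre = 1 / (1 + e(v_pre / -0.4))  # instantaneous target, not used
    i_syn = p.g_Syn * m_syn * (V - p.E_Syn)  # m_syn here: presyn activation
    i_e = g_e * (V - p.E_E)
    dv = -(i_naf + i_nas + i_k + i_cas + i_leak + i_syn + i_e) / p.C
    dh_naf = ((1 / (1 + e((V + 23) / 7)) - h_naf)
              / (0.03 / (e((V + 40) / 15) + e((V + 40) / -16))))
    dm_nas = (1 / (1 + e((V + 42) / -4.1)) - m_nas) / 0.001
    dh_nas = (1 / (1 + e((V + 55) / 5)) - h_nas) / 0.1
    dm_k = ((1 / (1 + e((V + 21) / -15)) - m_k)
            / (0.007 / (e((V + 46) / 40) + e((V + 46) / -50))))
    t1 = 0.02 * (V + 48) / (1 - e((V + 48) / -4.5))
    t2 = -0.05 * (V + 51) / (1 - e((V + 51) / 4.5))
    dm_cas = (1 / (1 + e((V + 45.59) / -4.27)) - m_cas) / (0.001 / (t1 + t2))
    dh_cas = (1 / (1 + e((V + 58.93) / 0.75)) - h_cas) / 0.485
    return dv, dh_naf, dm_nas, dh_nas, dm_k, dm_cas, dh_cas


def oracle_msyn_rate(v_pre, m_syn):
    return (1 / (1 + math.exp(v_pre / -0.4)) - m_syn) / 0.009


class TestGateKinetics:
    @pytest.mark.parametrize("gate, V, x_inf, tau", [
        ("m_NaF_inf", -20.0, 0.5, 0.0),
        ("h_NaS", -55.0, 0.5, 0.1),
        ("h_CaS", -58.93, 0.5, 0.485),
        ("m_NaS", -42.0, 0.5, 0.001),
        ("m_Syn", 0.0, 0.5, 0.009),
    ])
    def test_midpoints_and_constant_taus(self, gate, V, x_inf, tau):
        xi, t = gate_kinetics(gate, V)
        assert xi == pytest.approx(x_inf, abs=1e-12)
        assert t == pytest.approx(tau, abs=1e-12)

    def test_bounded_and_positive_over_voltage_range(self):
        for gate in GATE_IDS:
            for V in np.linspace(-100, 60, 401):
                xi, tau = gate_kinetics(gate, float(V))
                assert 0.0 <= xi <= 1.0
                assert tau > 0 or gate == "m_NaF_inf"

    def test_mcas_tau_continuous_at_removable_singularities(self):
        # x/(1 - exp(-x/k)) -> k as x -> 0, at V = -48 and V = -51
        for v0 in (-48.0, -51.0):
            _, at = gate_kinetics("m_CaS", v0)
            _, near = gate_kinetics("m_CaS", v0 + 1e-7)
            assert at == pytest.approx(near, rel=1e-5)

    def test_unknown_gate_raises(self):
        with pytest.raises(KeyError):
            gate_kinetics("m_bogus", -50.0)
        with pytest.raises(ValueError):
            gate_kinetics("h_NaS", float("nan"))


class TestMembraneCurrents:
    def test_zero_driving_force(self, params):
        st = NeuronState.at_rest(params.E_Na)
        cur = membrane_currents(st, m_syn_pre=0.3, params=params)
        assert cur["I_NaF"] == pytest.approx(0.0)
        assert cur["I_NaS"] == pytest.approx(0.0)
        st = NeuronState.at_rest(params.E_leak)
        cur = membrane_currents(st, m_syn_pre=0.0, params=params)
        assert cur["I_leak"] == pytest.approx(0.0)

    def test_currents_match_independent_evaluation(self, params):
        V = -50.0
        st = NeuronState.at_rest(V)
        m_syn_pre, _ = gate_kinetics("m_Syn", V)
        cur = membrane_currents(st, m_syn_pre, params, g_E_now=1.0)
        e = math.exp
        m_naf = 1 / (1 + e((V + 20) / -7.8))
        assert cur["I_NaF"] == pytest.approx(
            50.0 * m_naf ** 3 * st.h_NaF * (V - 65.0), rel=1e-12)
        assert cur["I_K"] == pytest.approx(
            40.0 * st.m_K ** 4 * (V + 70.0), rel=1e-12)
        assert cur["I_CaS"] == pytest.approx(
            12.3 * st.m_CaS ** 3 * st.h_CaS * (V - 160.0), rel=1e-12)
        assert cur["I_Syn"] == pytest.approx(
            5.5 * m_syn_pre * (V + 75.0), rel=1e-12)
        assert cur["I_E"] == pytest.approx(1.0 * (V - 0.0), rel=1e-12)


class TestDerivatives:
    def test_symmetric_state_gives_symmetric_derivative(self, params):
        n = NeuronState.at_rest(-47.3)
        dy = derivatives(HCOState(n, n, t=0.0), params)
        np.testing.assert_allclose(dy[:8], dy[8:], rtol=1e-12)

    def test_neuron_swap_commutes(self, params):
        a = NeuronState.at_rest(-30.0)
        b = NeuronState.at_rest(-62.0)
        dy = derivatives(HCOState(a, b), params)
        dy_sw = derivatives(HCOState(b, a), params)
        np.testing.assert_allclose(dy[:8], dy_sw[8:], rtol=1e-12)
        np.testing.assert_allclose(dy[8:], dy_sw[:8], rtol=1e-12)

    def test_gates_at_steady_state_have_zero_derivative(self, params):
        n = NeuronState.at_rest(-47.0)
        dy = derivatives(HCOState(n, n), params)
        # indices 1..6 are this neuron's relaxing gates; m_Syn (7) tracks
        # the same neuron's own V so it is also at rest here
        np.testing.assert_allclose(dy[1:8], 0.0, atol=1e-12)

    def test_full_rhs_matches_independent_oracle(self, params):
        state1 = [-42.1, 0.31, 0.62, 0.45, 0.21, 0.18, 0.12, 0.05]
        state2 = [-58.7, 0.73, 0.11, 0.64, 0.05, 0.02, 0.21, 0.67]
        hco = HCOState(NeuronState(*state1), NeuronState(*state2), t=0.0)
        pulse = PulseSpec(g_E=0.8, d_pul=1.0, t_pul=0.0)
        dy = derivatives(hco, params, pulse)
        for pre, post, offset in ((state1, state2, 0), (state2, state1, 8)):
            V = pre[0]
            # I_Syn into this neuron is gated by the OTHER neuron's m_Syn
            exp = oracle_rates(V, *pre[1:7], m_syn=post[7], v_pre=post[0],
                               p=params, g_e=0.8)
            np.testing.assert_allclose(dy[offset:offset + 7], exp,
                                       rtol=1e-10)
            assert dy[offset + 7] == pytest.approx(
                oracle_msyn_rate(V, pre[7]), rel=1e-10)

    def test_nonfinite_state_rejected(self, params):
        n = NeuronState.at_rest(-50.0)
        bad = HCOState(n, n)
        bad.neuron1.V = float("nan")
        with pytest.raises(FloatingPointError):
            derivatives(bad, params)


class TestModelParameters:
    def test_canonical_values(self, params):
        assert (params.g_NaF, params.g_NaS, params.g_K, params.g_CaS,
                params.g_leak, params.g_Syn, params.g_E_max) == \
            (50.0, 3.83, 40.0, 12.3, 2.96, 5.5, 1.0)
        assert (params.E_Na, params.E_K, params.E_Ca, params.E_leak,
                params.E_Syn, params.E_E) == (65, -70, 160, -54, -75, 0)
        assert params.C == 0.001

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(g_K=-1.0)
        with pytest.raises(ValueError):
            ModelParameters(C=0.0)

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_config_roundtrip(self, tmp_path, suffix):
        p = ModelParameters(g_CaS=11.0)
        f = tmp_path / ("params" + suffix)
        p.to_file(f)
        assert ModelParameters.from_file(f) == p

    def test_gate_range_validation(self):
        with pytest.raises(ValueError):
            NeuronState(V=-50, h_NaF=1.2, m_NaS=0, h_NaS=0, m_K=0,
                        m_CaS=0, h_CaS=0, m_Syn=0)


class TestPulseSpec:
    def test_square_shape(self):
        p = PulseSpec(g_E=2.0, d_pul=0.5, t_pul=1.0)
        assert p.conductance_at(0.99) == 0.0
        assert p.conductance_at(1.0) == 2.0
        assert p.conductance_at(1.5) == 2.0
        assert p.conductance_at(1.51) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            PulseSpec(g_E=-1.0)
        with pytest.raises(ValueError):
            PulseSpec(d_pul=0.0)
        with pytest.raises(ValueError):
            PulseSpec(p_pul=100.0)
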