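import math

import numpy as np
import pytest

from opioidltp import biophysics as bio
from opioidltp.errors import ModelConsistencyError
from opioidltp.params import (
    AMPARParameters,
    CalciumParameters,
    FARADAY,
    GAS_CONSTANT,
    MembraneParameters,
    NMDARParameters,
    OpioidCondition,
    VGCCParameters,
)


@pytest.fixture
def nm():
    return NMDARParameters()


@pytest.fixture
def am():
    return AMPARParameters()


@pytest.fixture
def ca():
    return CalciumParameters()


class TestMgBlock:
    def test_extreme_hyperpolarization_blocks_completely(self, nm):
        assert bio.mg_block(-1000.0, 0.0, nm) < 1e-20
        assert bio.mg_block(-1000.0, 5.0, nm) < 1e-10

    def test_extreme_depolarization_relieves_block(self, nm):
        assert bio.mg_block(1000.0, 0.0, nm) == pytest.approx(1.0)

    def test_value_at_zero_mv_without_opioid(self, nm):
        # independent hand evaluation: at V = 0 the exponential is 1 and the
        # opioid shift vanishes, leaving 1 / (1 + Mg_out / k0)
        expected = 1.0 / (1.0 + nm.Mg_out / nm.k0)
        assert bio.mg_block(0.0, 0.0, nm) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("op", [0.0, 0.2, 1.0, 10.0])
    def test_monotone_in_voltage(self, nm, op):
        v = np.linspace(-100, 100, 401)
        vals = [bio.mg_block(float(x), op, nm) for x in v]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0 < x <= 1 for x in vals)

    def test_opioid_relieves_block_at_fixed_voltage(self, nm):
        vals = [bio.mg_block(-60.0, op, nm) for op in (0.0, 0.1, 0.5, 1.0, 5.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_mg_effect_off_freezes_opioid_terms(self, nm):
        assert bio.mg_block(-40.0, 3.0, nm, mg_effect_on=False) == \
            bio.mg_block(-40.0, 0.0, nm)

    def test_woodhull_exponent_at_baseline(self, nm):
        # with Op = 0 the expression reduces to a standard Woodhull form with
        # effective electrical distance delta + mg_delta_shift
        V = -55.0
        b = nm.z * (nm.delta + nm.mg_delta_shift) * FARADAY * 1e-3 \
            / (GAS_CONSTANT * nm.T)
        expected = 1.0 / (1.0 + nm.Mg_out / nm.k0 * math.exp(-b * V))
        assert bio.mg_block(V, 0.0, nm) == pytest.approx(expected, rel=1e-12)

    def test_printed_form_matches_literal_expression(self, nm):
        # the literal printed dependence: both terms decay with
        # 1 / (1 + (0.1 Op)^1.2)
        nm.opioid_form = "printed"
        V, op = -60.0, 5.0
        decay = 1.0 / (1.0 + (0.1 * op) ** 1.2)
        K = nm.k0 + nm.mg_k_shift * decay
        b = nm.z * (nm.delta + nm.mg_delta_shift * decay) * FARADAY * 1e-3 \
            / (GAS_CONSTANT * nm.T)
        expected = 1.0 / (1.0 + nm.Mg_out / K * math.exp(-b * V))
        assert bio.mg_block(V, op, nm) == pytest.approx(expected, rel=1e-12)


class TestNMDARConductance:
    def test_no_opioid_no_history_gives_gvi(self, nm):
        cond = OpioidCondition.normal()
        assert bio.nmdar_conductance(0.0, 0.0, cond, nm) == nm.g_VI

    def test_conductance_effect_off_equals_opioid_free(self, nm):
        ck0 = OpioidCondition.ck0(Op=1.0)
        assert bio.nmdar_conductance(0.1, 1.0, ck0, nm) == \
            bio.nmdar_conductance(0.1, 0.0, OpioidCondition.normal(), nm)

    def test_saturation_limit(self, nm):
        cond = OpioidCondition.opioid(1e9)
        g = bio.nmdar_conductance(0.0, 1e9, cond, nm)
        assert g == pytest.approx(nm.g_VI + nm.cond_sat, rel=1e-4)

    def test_monotone_in_op(self, nm):
        gs = [bio.nmdar_conductance(0.0, op, OpioidCondition.opioid(max(op, 0.0)), nm)
              for op in (0.0, 0.05, 0.2, 1.0, 5.0)]
        assert all(b > a for a, b in zip(gs, gs[1:]))

    def test_negative_total_rejected(self, nm):
        with pytest.raises(ModelConsistencyError):
            bio.nmdar_conductance(-10.0, 0.0, OpioidCondition.normal(), nm)

    def test_printed_form_keeps_increment_at_zero_op(self, nm):
        nm.opioid_form = "printed"
        g0 = bio.nmdar_conductance(0.0, 0.0, OpioidCondition.normal(), nm)
        assert g0 == nm.g_VI  # Op = 0 short-circuits the opioid term entirely


class TestGvdRelaxation:
    def test_fixed_point_at_v0(self, nm):
        assert bio.g_vd_derivative(0.0, nm.V0, nm) == 0.0

    def test_exponential_relaxation_matches_closed_form(self, nm):
        V = nm.V0 + 20.0
        target = nm.k_slope * 20.0
        g, dt = 0.0, 0.001
        for _ in range(int(3 * nm.tau_g / dt)):
            g += dt * bio.g_vd_derivative(g, V, nm)
        expected = target * (1.0 - math.exp(-3.0))
        assert g == pytest.approx(expected, rel=1e-3)

    def test_floor_below_v0(self, nm):
        # target conductance is floored at zero below V0
        assert bio.g_vd_derivative(0.0, nm.V0 - 30.0, nm) == 0.0
        assert bio.g_vd_derivative(0.5, nm.V0 - 30.0, nm) == \
            pytest.approx(-0.5 / nm.tau_g)


class TestReceptorGating:
    def test_closed_stays_closed_without_glutamate(self):
        assert bio.receptor_gating_derivative(0.0, 0.0, 1.0, 0.2) == 0.0

    def test_analytic_steady_state(self):
        alpha, beta, g = 1.8, 0.15, 0.2
        m_inf = alpha * g / (alpha * g + beta)
        assert bio.receptor_gating_derivative(m_inf, g, alpha, beta) == \
            pytest.approx(0.0, abs=1e-15)

    def test_pulse_train_matches_stiff_solver(self):
        # single gating ODE driven by a pulse train vs scipy at tight tol
        from scipy.integrate import solve_ivp

        alpha, beta = 1.8, 0.15
        width, period, amp = 4.0, 200.0, 0.2
        m, dt = 0.0, 0.05
        t_end = 1000.0
        euler = [0.0]
        for i in range(int(t_end / dt)):
            g = amp if (i * dt) % period < width else 0.0
            m += dt * bio.receptor_gating_derivative(m, g, alpha, beta)
            euler.append(m)
        y, ref = 0.0, {0.0: 0.0}
        t = 0.0
        edges = []
        while t < t_end:
            edges += [(t, t + width, amp), (t + width, t + period, 0.0)]
            t += period
        for a, b, g in edges:
            b = min(b, t_end)
            sol = solve_ivp(lambda s, yy: [bio.receptor_gating_derivative(
                yy[0], g, alpha, beta)], (a, b), [y], rtol=1e-10, atol=1e-12)
            y = float(sol.y[0, -1])
            ref[b] = y
        for tb, yref in ref.items():
            ye = euler[int(round(tb / dt))]
            assert abs(ye - yref) < 0.005 * max(yref, 0.05)


class TestCurrents:
    def test_ampar_zero_gate_and_reversal(self, am):
        assert bio.ampar_current(-70.0, 0.0, 0.4, am) == 0.0
        assert bio.ampar_current(am.V_AMPA, 0.7, 0.4, am) == 0.0

    def test_ampar_arithmetic(self, am):
        # g = 0.4 nS, m = 0.5, driving force -70 mV -> -14 pA (inward)
        assert bio.ampar_current(-70.0, 0.5, 0.4, am) == pytest.approx(-14.0)

    def test_nmdar_zero_factors(self, nm):
        assert bio.nmdar_current(-30.0, 0.5, 1.0, 0.0, nm) == 0.0
        assert bio.nmdar_current(nm.V_NMDA, 0.5, 1.0, 0.5, nm) == 0.0

    def test_nmdar_product_form_cross_check(self, nm):
        V, m, gvd, op = -42.0, 0.37, 0.21, 1.0
        cond = OpioidCondition.opioid(op)
        mg = bio.mg_block(V, op, nm)
        g = bio.nmdar_conductance(gvd, op, cond, nm)
        # product of independently evaluated factors
        assert bio.nmdar_current(V, m, g, mg, nm) == \
            pytest.approx(g * m * mg * (V - nm.V_NMDA), rel=1e-12)


class TestAMPARConductanceFromCaMKII:
    @pytest.mark.parametrize("phospho, expected", [
        (0.0, 0.4),      # sigmoid term < 1e-43 at the unphosphorylated limit
        (40.0, 0.6),     # midpoint: 1.5x baseline
        (1e9, 0.8),      # saturation: 2x baseline
    ])
    def test_endpoints(self, am, phospho, expected):
        assert bio.ampar_conductance_from_camkii(phospho, am) == \
            pytest.approx(expected, abs=1e-9)

    def test_increasing_and_bounded(self, am):
        # monotone everywhere; strictly so near the midpoint (far from it
        # the sigmoid underflows to the exact bounds in double precision)
        ph = np.linspace(0, 100, 201)
        g = [bio.ampar_conductance_from_camkii(float(p), am) for p in ph]
        assert all(b >= a for a, b in zip(g, g[1:]))
        assert all(am.g_AMPA0 <= x <= 2 * am.g_AMPA0 for x in g)
        near = np.linspace(am.P_half - 4, am.P_half + 4, 41)
        gn = [bio.ampar_conductance_from_camkii(float(p), am) for p in near]
        assert all(b > a for a, b in zip(gn, gn[1:]))


class TestVGCC:
    def test_disabled_gives_exact_zero(self):
        p = VGCCParameters()
        rng = np.random.RandomState(0)
        cond = OpioidCondition.icr0()
        assert bio.vgcc_current(50.0, cond, p, rng) == 0.0

    def test_reversal_potential_zeros_current(self):
        p = VGCCParameters(Vh_open=-100.0)  # force channels open
        rng = np.random.RandomState(0)
        assert bio.vgcc_current(p.V_R, OpioidCondition.opioid(), p, rng) == 0.0

    def test_monte_carlo_mean_matches_binomial_mean(self):
        p = VGCCParameters()
        V = -5.0
        n_draw = 100_000
        rng = np.random.RandomState(42)
        cond = OpioidCondition.opioid()
        draws = np.array([bio.vgcc_current(V, cond, p, rng)
                          for _ in range(n_draw)])
        p_open = bio.vgcc_open_probability(V, p)
        mean = p.g_R * p.N * p_open * (V - p.V_R)
        single = p.g_R * (V - p.V_R)
        se = abs(single) * math.sqrt(p.N * p_open * (1 - p_open) / n_draw)
        assert abs(draws.mean() - mean) < 3 * se

    def test_resting_open_probability_negligible(self):
        p = VGCCParameters()
        # a 10 s run at rest makes ~N * P * 2e5 draws; require << 1 opening
        assert p.N * bio.vgcc_open_probability(-70.0, p) * 2e5 < 0.05


class TestCalcium:
    def test_rest_is_fixed_point(self, ca):
        assert bio.calcium_derivative(ca.c_rest, 0.0, 0.0, 0.0, ca) == 0.0

    def test_pump_decay_above_rest(self, ca):
        assert bio.calcium_derivative(1.0, 0.0, 0.0, 0.0, ca) < 0.0

    def test_hand_computed_nmdar_flux(self, ca):
        # -10 pA NMDAR current alone at rest: influx gamma*10 pA / (Z F Vsp)
        # scaled by the rapid-buffer factor 1/(1+theta(c_rest))
        conv = 1e-12 / (2.0 * FARADAY * 0.9048e-15) * 1e6 * 1e-3  # uM/ms per pA
        theta = 200.0 * 10.0 / (10.0 + 0.1) ** 2
        expected = 0.06 * 10.0 * conv / (1.0 + theta)
        got = bio.calcium_derivative(ca.c_rest, 0.0, -10.0, 0.0, ca)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_calcium_rejected(self, ca):
        with pytest.raises(ModelConsistencyError):
            bio.calcium_derivative(-0.1, 0.0, 0.0, 0.0, ca)

    @pytest.mark.parametrize("c, expected", [
        (0.1, 0.0),        # rest
        (1.1, 0.1),        # 100/s * 1 uM = 0.1 uM/ms
        (0.05, -0.005),    # symmetric below rest: -5 uM/s
    ])
    def test_pump_rate(self, ca, c, expected):
        assert bio.pump_rate(c, ca) == pytest.approx(expected)


class TestMembrane:
    def test_rest_fixed_point(self):
        mb = MembraneParameters()
        assert bio.membrane_derivative(mb.V_rest, 0.0, 0.0, mb) == 0.0

    def test_relaxation_to_shifted_fixed_point(self):
        mb = MembraneParameters()
        I_A = -10.0  # constant inward synaptic current
        V_inf = mb.V_rest + mb.R_m * (-I_A) * 1e-3
        assert bio.membrane_derivative(V_inf, I_A, 0.0, mb) == \
            pytest.approx(0.0, abs=1e-12)
        V, dt = mb.V_rest, 0.01
        for _ in range(int(3 * mb.tau_post / dt)):
            V += dt * bio.membrane_derivative(V, I_A, 0.0, mb)
        assert V == pytest.approx(
            mb.V_rest + (V_inf - mb.V_rest) * (1 - math.exp(-3.0)), rel=1e-3)
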