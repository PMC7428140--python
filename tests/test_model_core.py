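"""Unit and property tests for the corrected whole-body rate laws and RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorensen import model_core as mc
from sorensen.model_core import IDX, NCORE, STATE_NAMES


# ---------------------------------------------------------------------------
# kidney excretion
# ---------------------------------------------------------------------------

class TestKidneyExcretion:
    def test_threshold_value(self, p_a1):
        assert mc.rate_kidney_glucose_excretion(460.0, p_a1) == pytest.approx(71.0)

    def test_zero_glucose(self, p_a1):
        # 71*(1 + tanh(-0.011*460)) evaluated directly
        expected = 71.0 * (1.0 + math.tanh(-5.06))
        got = mc.rate_kidney_glucose_excretion(0.0, p_a1)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.0057, abs=5e-4)

    def test_linear_branch(self, p_a1):
        assert mc.rate_kidney_glucose_excretion(1000.0, p_a1) == pytest.approx(542.0)

    def test_branch_continuity(self, p_a1):
        below = mc.rate_kidney_glucose_excretion(460.0 - 1e-9, p_a1)
        above = mc.rate_kidney_glucose_excretion(460.0 + 1e-9, p_a1)
        assert abs(below - above) < 0.2

    def test_corrected_slope_not_legacy(self, p_a1):
        # the erroneous 0.11 factor gives a visibly different sub-threshold curve
        good = mc.rate_kidney_glucose_excretion(300.0, p_a1)
        bad = mc.legacy_errors.rate_kidney_glucose_excretion(300.0, p_a1)
        assert abs(good - bad) > 1.0

    def test_negative_domain_error(self, p_a1):
        with pytest.raises(ValueError):
            mc.rate_kidney_glucose_excretion(-1.0, p_a1)


# ---------------------------------------------------------------------------
# tanh multiplier laws: printed centers, bounds, monotonicity
# ---------------------------------------------------------------------------

class TestMultipliers:
    def test_printed_centers(self, p_a1):
        assert mc.m_pgu_insulin(5.82, p_a1) == pytest.approx(7.03)
        assert mc.m_hgp_glucose(0.497, p_a1) == pytest.approx(1.42)
        assert mc.m_hgu_glucose(1.48, p_a1) == pytest.approx(5.66)
        assert mc.m_pgr_glucose(0.61, p_a1) == pytest.approx(2.93)
        assert mc.m_pgr_insulin(0.47, p_a1) == pytest.approx(1.31)
        assert mc.m_hgp_insulin_inf(0.89, p_a1) == pytest.approx(1.21)

    @given(x=st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, x):
        p = __import__("sorensen").params.appendix_a1()
        assert 7.03 - 6.52 <= mc.m_pgu_insulin(x, p) <= 7.03 + 6.52
        assert 1.42 - 1.41 <= mc.m_hgp_glucose(x, p) <= 1.42 + 1.41
        assert 0.0 <= mc.m_hgu_glucose(x, p) <= 2 * 5.66
        assert 2.93 - 2.10 <= mc.m_pgr_glucose(x, p) <= 2.93 + 2.10
        assert 1.31 - 0.61 <= mc.m_pgr_insulin(x, p) <= 1.31 + 0.61
        assert 1.21 - 1.14 <= mc.m_hgp_insulin_inf(x, p) <= 1.21 + 1.14
        assert 0.0 <= mc.m_hgu_insulin_inf(x, p) <= 2.0
        assert 0.0 <= mc.m_hgp_gamma0(x, p) <= 2.7

    def test_monotonicity_on_grid(self, p_a1):
        grid = np.linspace(0.0, 10.0, 201)
        pgu = [mc.m_pgu_insulin(x, p_a1) for x in grid]
        hgp = [mc.m_hgp_glucose(x, p_a1) for x in grid]
        pgr = [mc.m_pgr_glucose(x, p_a1) for x in grid]
        assert np.all(np.diff(pgu) >= 0)
        assert np.all(np.diff(hgp) <= 0)
        assert np.all(np.diff(pgr) <= 0)


# ---------------------------------------------------------------------------
# peripheral uptake and hepatic rates
# ---------------------------------------------------------------------------

class TestMetabolicRates:
    def test_pgu_at_insulin_center(self, p_a1):
        assert mc.peripheral_glucose_uptake(5.82, 1.0, p_a1) == pytest.approx(246.05)

    def test_pgu_zero_glucose(self, p_a1):
        assert mc.peripheral_glucose_uptake(5.82, 0.0, p_a1) == 0.0

    def test_pgu_at_basal_normals(self, p_a1):
        expected = 35.0 * (7.03 + 6.52 * math.tanh(0.338 * (1.0 - 5.82)))
        assert mc.peripheral_glucose_uptake(1.0, 1.0, p_a1) == pytest.approx(expected)

    def test_pgu_domain(self, p_a1):
        with pytest.raises(ValueError):
            mc.peripheral_glucose_uptake(-0.1, 1.0, p_a1)

    def test_hgp_at_glucose_center(self, p_a1):
        # choose Gamma_N so that (m_gamma0 - f2) = 1 with f2 = 0
        gamma_n = math.atanh(1.0 / 2.7) / 0.39
        r_hgp, _ = mc.hepatic_rates(1.0, 0.0, gamma_n, 0.497, 1.0, p_a1)
        assert r_hgp == pytest.approx(1.42 * 155.0)

    def test_hgu_at_glucose_center(self, p_a1):
        _, r_hgu = mc.hepatic_rates(1.0, 0.0, 1.0, 1.48, 1.0, p_a1)
        assert r_hgu == pytest.approx(5.66 * 20.0)

    def test_hgp_all_multipliers_one(self, p_a1):
        gamma_n = math.atanh(1.0 / 2.7) / 0.39
        g_l_n = 0.497  # glucose multiplier = 1.42 there; instead pick where it is 1
        g_l_n = 0.497 + math.atanh(0.42 / 1.41) / 0.62
        r_hgp, _ = mc.hepatic_rates(1.0, 0.0, gamma_n, g_l_n, 1.0, p_a1)
        assert r_hgp == pytest.approx(155.0)


class TestRegulatory:
    def test_hgp_inf_at_center(self, p_a1):
        assert mc.m_hgp_insulin_inf(0.89, p_a1) == pytest.approx(1.21)

    def test_hgu_inf_at_zero(self, p_a1):
        assert mc.m_hgu_insulin_inf(0.0, p_a1) == 0.0

    def test_fixed_point_zero_derivative(self, p_a1):
        target = mc.m_hgp_insulin_inf(1.3, p_a1)
        d1, _, _ = mc.regulatory_derivatives(target, 1.0, 0.0, 1.3, 1.0, p_a1)
        assert d1 == pytest.approx(0.0, abs=1e-15)


class TestPancreas:
    def test_zero_glucose(self, p_a1):
        out = mc.pancreas_secretion(0.0, 1.0, 0.5, 10.0, p_a1)
        assert out["X"] == 0.0
        assert out["Y"] == 0.0
        assert out["S"] == 0.0

    def test_positive_part_boundary(self, p_a1):
        out = mc.pancreas_secretion(120.0, 1.0, 0.0, 10.0, p_a1)
        x = out["X"]
        out2 = mc.pancreas_secretion(120.0, 1.0, x, 10.0, p_a1)
        # inhibitor equal to X removes the early-phase term
        assert out2["S"] == pytest.approx(p_a1.M1 * out2["Y"] * 10.0)

    def test_basal_ratio_is_one(self, basal_a1, p_a1):
        out = mc.pancreas_secretion(
            basal_a1.G_HB, basal_a1.P_B, basal_a1.I_inh_B, basal_a1.Q_B, p_a1,
            S_B=basal_a1.S_B, r_B_PIR=basal_a1.r_B_PIR,
        )
        assert out["r_PIR"] == pytest.approx(basal_a1.r_B_PIR)

    def test_negative_glucose_error(self, p_a1):
        with pytest.raises(ValueError):
            mc.pancreas_secretion(-1.0, 1.0, 0.5, 10.0, p_a1)

    def test_corrected_pool_sign_stabilizes(self, p_a1):
        # corrected form pulls the pool toward the set point; the legacy sign pushes away
        dq_good = p_a1.K * (p_a1.Q0 - 10.0)
        dq_bad = mc.legacy_errors.labile_pool_derivative(10.0, 0.0, 0.0, p_a1)
        assert dq_good < 0 < dq_bad or dq_bad < 0 < dq_good or dq_good == -dq_bad


class TestInsulinClearances:
    def test_zero_inputs(self, p_a1):
        r_lic, _, _ = mc.insulin_clearances(0.0, 0.0, 0.0, 0.0, p_a1)
        assert r_lic == 0.0

    def test_kidney_uses_heart_concentration(self, p_a1):
        _, r_kic, _ = mc.insulin_clearances(10.0, 0.0, 0.0, 0.0, p_a1)
        assert r_kic == pytest.approx(0.30 * 0.72 * 10.0)  # = 2.16
        # legacy form would instead scale with the kidney concentration
        assert mc.legacy_errors.renal_insulin_clearance(5.0, p_a1) != r_kic

    def test_peripheral_clearance_balances_basal_delivery(self, p_a1, basal_a1):
        # at equilibrium the transcapillary delivery equals r_PIC (balance of
        # the periphery interstitial insulin equation)
        I_PV, I_PI = basal_a1.state[IDX["I_PV"]], basal_a1.state[IDX["I_PI"]]
        delivery = p_a1.V_I_PI / p_a1.T_I_P * (I_PV - I_PI)
        _, _, r_pic = mc.insulin_clearances(0.0, 0.0, I_PI, 0.0, p_a1)
        assert r_pic == pytest.approx(delivery, rel=1e-9)


class TestGlucagon:
    def test_release_centers(self, p_a1):
        assert mc.m_pgr_glucose(0.61, p_a1) == pytest.approx(2.93)
        assert mc.m_pgr_insulin(0.47, p_a1) == pytest.approx(1.31)

    def test_basal_closure(self, p_a1, basal_a1):
        release, clearance = mc.glucagon_rates(1.0, 1.0, 1.0, p_a1, basal_a1.r_B_PGR)
        assert release == pytest.approx(clearance, rel=1e-12)


# ---------------------------------------------------------------------------
# basal initialization
# ---------------------------------------------------------------------------

class TestBasalInitialization:
    def test_exact_equilibrium_residual(self, p_a1, basal_a1):
        d = mc.full_derivatives(basal_a1.state, p_a1, basal_a1)
        assert np.max(np.abs(d)) < 1e-6

    def test_exact_state_close_to_inputs(self, basal_a1):
        assert basal_a1.state[IDX["G_PV"]] == pytest.approx(89.0, rel=0.01)
        assert basal_a1.state[IDX["I_PV"]] == pytest.approx(12.8, rel=0.01)

    def test_heart_insulin_anchor(self, p_a1):
        b = mc.basal_initialization(p_a1, I_PVB=12.8, mode="paper")
        assert b.I_HB == pytest.approx(12.8 / 0.85)

    def test_kidney_equals_heart_in_paper_mode(self, basal_a1_paper):
        assert basal_a1_paper.G_KB == basal_a1_paper.G_HB
        assert (basal_a1_paper.state[IDX["G_K"]]
                == basal_a1_paper.state[IDX["G_H"]])

    def test_paper_mode_printed_regulatory_ics(self, basal_a1_paper):
        assert basal_a1_paper.state[IDX["M_HGP_I"]] == 1.0
        assert basal_a1_paper.state[IDX["M_HGU_I"]] == 1.0
        assert basal_a1_paper.state[IDX["f2"]] == 0.0

    def test_corrected_interstitial_glucose(self, p_a1, basal_a1_paper):
        # peripheral uptake (35), not brain uptake (70), sets the gradient
        expected = 89.0 - 35.0 * 5.0 / 67.4
        assert basal_a1_paper.G_PIB == pytest.approx(expected)
        legacy = mc.legacy_errors.basal_peripheral_interstitial_glucose(89.0, p_a1)
        assert abs(legacy - basal_a1_paper.G_PIB) > 1.0

    def test_pancreas_pool_closure(self, p_a1, basal_a1):
        b = basal_a1
        q_expected = (p_a1.K * p_a1.Q0 + p_a1.gamma * b.P_B) / (p_a1.K + p_a1.M1 * b.Y_B)
        assert b.Q_B == pytest.approx(q_expected)

    def test_infeasible_basal_raises(self, p_a1):
        with pytest.raises(ValueError, match="basal"):
            mc.basal_initialization(p_a1, G_PVB=1e-3, I_PVB=12.8)

    def test_nonpositive_inputs_rejected(self, p_a1):
        with pytest.raises(ValueError):
            mc.basal_initialization(p_a1, G_PVB=0.0)

    def test_bad_mode(self, p_a1):
        with pytest.raises(ValueError):
            mc.basal_initialization(p_a1, mode="approximate")


# ---------------------------------------------------------------------------
# full RHS: oracle, scaling, error handling
# ---------------------------------------------------------------------------

def _oracle_rhs(y, p, b):
    """Independent term-by-term recomputation of every compartment balance."""
    th = math.tanh
    (G_BV, G_BI, G_H, G_J, G_L, G_K, G_PV, G_PI,
     I_B, I_H, I_J, I_L, I_K, I_PV, I_PI,
     Gam, MHGPI, MHGUI, f2, P, Iinh, Q) = y[:22]

    # rates, written out from the printed laws
    if G_K <= 460.0:
        rKGE = 71.0 + 71.0 * th(0.011 * (G_K - 460.0))
    else:
        rKGE = -330.0 + 0.872 * G_K
    rPGU = (7.03 + 6.52 * th(0.338 * (I_PI / b.I_PIB - 5.82))) * (G_PI / b.G_PIB) * 35.0
    mgam = 2.7 * th(0.39 * Gam / b.Gamma_B) - f2
    rHGP = MHGPI * mgam * (1.42 - 1.41 * th(0.62 * (G_L / b.G_LB - 0.497))) * 155.0
    rHGU = MHGUI * (5.66 + 5.66 * th(2.44 * (G_L / b.G_LB - 1.48))) * 20.0
    g = G_H * p.pancreas_glucose_scale
    X = g ** p.beta_pir1 / (p.beta_pir2 ** p.beta_pir1 + p.beta_pir3 * g ** p.beta_pir4)
    Y = X ** p.beta_pir5
    S = (p.M1 * Y + p.M2 * max(0.0, X - Iinh)) * Q
    rPIR = S / b.S_B * b.r_B_PIR
    rLIC = 0.40 * (0.18 * I_H + 0.72 * I_J + rPIR)
    rKIC = 0.30 * 0.72 * I_H
    rPIC = I_PI / ((0.85 / 0.15) * (1 / 1.05) - 20.0 / 6.74)

    d = np.empty(22)
    d[0] = (5.9 * (G_H - G_BV) - 4.5 / 2.1 * (G_BV - G_BI)) / 3.5
    d[1] = (4.5 / 2.1 * (G_BV - G_BI) - 70.0) / 4.5
    d[2] = (5.9 * G_BV + 12.6 * G_L + 10.1 * G_K + 15.1 * G_PV
            - 43.7 * G_H - 10.0) / 13.8
    d[3] = (10.1 * (G_H - G_J) - 20.0) / 11.2
    d[4] = (2.5 * G_H + 10.1 * G_J - 12.6 * G_L + rHGP - rHGU) / 25.1
    d[5] = (10.1 * (G_H - G_K) - rKGE) / 6.6
    d[6] = (15.1 * (G_H - G_PV) - 67.4 / 5.0 * (G_PV - G_PI)) / 10.4
    d[7] = (67.4 / 5.0 * (G_PV - G_PI) - rPGU) / 67.4
    d[8] = 0.45 * (I_H - I_B) / 0.26
    d[9] = (0.45 * I_B + 0.90 * I_L + 0.72 * I_K + 1.05 * I_PV - 3.12 * I_H) / 0.99
    d[10] = 0.72 * (I_H - I_J) / 0.94
    d[11] = (0.18 * I_H + 0.72 * I_J - 0.90 * I_L + rPIR - rLIC) / 1.14
    d[12] = (0.72 * (I_H - I_K) - rKIC) / 0.51
    d[13] = (1.05 * (I_H - I_PV) - 6.74 / 20.0 * (I_PV - I_PI)) / 0.74
    d[14] = (6.74 / 20.0 * (I_PV - I_PI) - rPIC) / 6.74
    rel = (2.93 - 2.10 * th(4.18 * (G_H / b.G_HB - 0.61))) \
        * (1.31 - 0.61 * th(1.06 * (I_H / b.I_HB - 0.47))) * b.r_B_PGR
    d[15] = (rel - 9.10 * Gam) / 11310.0
    d[16] = ((1.21 - 1.14 * th(1.66 * (I_L / b.I_LB - 0.89))) - MHGPI) / 25.0
    d[17] = (2.0 * th(0.55 * I_L / b.I_LB) - MHGUI) / 25.0
    d[18] = ((2.7 * th(0.39 * Gam / b.Gamma_B) - 1.0) / 2.0 - f2) / 65.0
    d[19] = p.alpha * (Y - P)
    d[20] = p.beta * (X - Iinh)
    d[21] = p.K * (p.Q0 - Q) + p.gamma * P - S
    return d


def _random_feasible_state(rng, basal):
    y = basal.state.copy()
    y[:8] *= rng.uniform(0.5, 2.0, 8)       # glucose
    y[8:15] *= rng.uniform(0.5, 3.0, 7)     # insulin
    y[15] *= rng.uniform(0.5, 2.0)          # glucagon
    y[16:18] *= rng.uniform(0.5, 1.5, 2)    # multipliers
    y[18] = rng.uniform(-0.2, 0.5)          # f2
    y[19:22] *= rng.uniform(0.5, 2.0, 3)    # pancreas
    return y


class TestFullDerivatives:
    def test_term_by_term_oracle(self, p_a1, basal_a1, rng):
        for _ in range(100):
            y = _random_feasible_state(rng, basal_a1)
            got = mc.full_derivatives(y, p_a1, basal_a1)[:NCORE]
            want = _oracle_rhs(y, p_a1, basal_a1)
            scale = np.maximum(np.abs(want), 1e-30)
            assert np.max(np.abs(got - want) / scale) < 1e-12

    def test_equilibrium(self, p_a1, basal_a1):
        d = mc.full_derivatives(basal_a1.state, p_a1, basal_a1)
        assert np.max(np.abs(d)) < 1e-6

    def test_volume_scaling(self, p_a1, basal_a1, rng):
        # doubling the pure-accumulation volumes halves those concentration
        # derivatives at a fixed state (fluxes unchanged)
        y = _random_feasible_state(rng, basal_a1)
        doubled = {n: 2 * getattr(p_a1, n) for n in
                   ("V_G_BV", "V_G_H", "V_G_L", "V_G_J", "V_G_K", "V_G_PV",
                    "V_I_B", "V_I_H", "V_I_J", "V_I_L", "V_I_K", "V_I_PV",
                    "V_Gamma")}
        p2 = p_a1.replace(**doubled)
        d1 = mc.full_derivatives(y, p_a1, basal_a1)
        d2 = mc.full_derivatives(y, p2, basal_a1)
        idx = [IDX[n] for n in ("G_BV", "G_H", "G_L", "G_J", "G_K", "G_PV",
                                "I_B", "I_H", "I_J", "I_L", "I_K", "I_PV",
                                "Gamma")]
        np.testing.assert_allclose(d2[idx], d1[idx] / 2.0, rtol=1e-12)

    def test_nan_state_identified(self, p_a1, basal_a1):
        y = basal_a1.state.copy()
        y[IDX["G_L"]] = np.nan
        with pytest.raises(FloatingPointError, match="G_L"):
            mc.full_derivatives(y, p_a1, basal_a1)

    def test_iv_inputs_enter_heart_only(self, p_a1, basal_a1):
        d0 = mc.full_derivatives(basal_a1.state, p_a1, basal_a1)
        dg = mc.full_derivatives(basal_a1.state, p_a1, basal_a1, iv_glucose=138.0)
        di = mc.full_derivatives(basal_a1.state, p_a1, basal_a1, iv_insulin=99.0)
        assert dg[IDX["G_H"]] - d0[IDX["G_H"]] == pytest.approx(138.0 / p_a1.V_G_H)
        assert di[IDX["I_H"]] - d0[IDX["I_H"]] == pytest.approx(99.0 / p_a1.V_I_H)
        others = [i for i in range(NCORE) if i not in (IDX["G_H"], IDX["I_H"])]
        np.testing.assert_allclose(dg[others], d0[others])
        np.testing.assert_allclose(di[others], d0[others])


class TestParams:
    def test_flow_consistency(self, p_a1):
        assert p_a1.Q_G_H == pytest.approx(
            p_a1.Q_G_B + p_a1.Q_G_L + p_a1.Q_G_K + p_a1.Q_G_P)
        assert p_a1.Q_G_L == pytest.approx(p_a1.Q_G_A + p_a1.Q_G_J)
        assert p_a1.Q_I_H == pytest.approx(
            p_a1.Q_I_B + p_a1.Q_I_L + p_a1.Q_I_K + p_a1.Q_I_P)

    def test_unit_system_consistency_across_presets(self, p_a1, p_t3):
        # the mg/dl and mM "before" parameterizations give the same drive X
        from sorensen.params import MGDL_PER_MMOL
        p_mm = p_a1.replace(
            beta_pir2=p_a1.beta_pir2 / MGDL_PER_MMOL,
            beta_pir3=p_a1.beta_pir3 / MGDL_PER_MMOL ** (p_a1.beta_pir1 - p_a1.beta_pir4),
            pancreas_glucose_scale=1.0 / MGDL_PER_MMOL,
        )
        for g in (80.0, 120.0, 250.0):
            assert mc.pancreas_glucose_drive(g, p_mm) == pytest.approx(
                mc.pancreas_glucose_drive(g, p_a1), rel=1e-10)

    def test_validation_rejects_bad_fraction(self, p_a1):
        with pytest.raises(ValueError, match="F_PIC"):
            p_a1.replace(F_PIC=1.5).validate()

    def test_replace_unknown_key(self, p_a1):
        with pytest.raises(KeyError):
            p_a1.replace(no_such_param=1.0)

    def test_json_round_trip(self, p_a1, tmp_path):
        from sorensen.params import SorensenParams
        path = tmp_path / "p.json"
        p_a1.to_json(path)
        assert SorensenParams.from_json(path) == p_a1
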