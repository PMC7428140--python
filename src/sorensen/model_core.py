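"""Corrected whole-body glucose-insulin-glucagon model.

State layout (26 entries; concentrations unless noted)::

    0  G_BV   brain vascular glucose            mg/dl
    1  G_BI   brain interstitial glucose        mg/dl
    2  G_H    heart/lungs glucose               mg/dl
    3  G_J    gut glucose                       mg/dl
    4  G_L    liver glucose                     mg/dl
    5  G_K    kidney glucose                    mg/dl
    6  G_PV   periphery vascular glucose        mg/dl
    7  G_PI   periphery interstitial glucose    mg/dl
    8  I_B    brain insulin                     mU/l
    9  I_H    heart/lungs insulin               mU/l
    10 I_J    gut insulin                       mU/l
    11 I_L    liver insulin                     mU/l
    12 I_K    kidney insulin                    mU/l
    13 I_PV   periphery vascular insulin        mU/l
    14 I_PI   periphery interstitial insulin    mU/l
    15 Gamma  glucagon, normalized (basal 1)    --
    16 M_HGP_I  hepatic production insulin multiplier (dynamic)
    17 M_HGU_I  hepatic uptake insulin multiplier (dynamic)
    18 f2       glucagon-offset state
    19 P        pancreas potentiator
    20 I_inh    pancreas inhibitor
    21 Q        pancreas labile pool            U
    22 S_sto    stomach glucose                 mg
    23 J_jej    jejunum glucose                 mg
    24 R_dly    delay-compartment glucose       mg
    25 L_ile    ileum glucose                   mg

Only the corrected forms of the legacy rate laws are implemented: the kidney
excretion slope factor is 0.011 (never 0.11), the renal insulin clearance uses
the heart/lungs concentration, the labile-pool balance relaxes toward its set
point with the stabilizing sign, and the basal periphery interstitial glucose
is derived from the peripheral (not brain) uptake.  The widely circulated
erroneous variants are available under ``legacy_errors`` for regression tests
only.

Normalization convention: a superscript-N quantity is the concentration
divided by its basal anchor from :class:`BasalSolution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .params import SimoParams, SorensenParams
from . import gut_simo

__all__ = [
    "STATE_NAMES", "IDX", "NSTATES", "NCORE",
    "GlucoseState", "InsulinState", "BasalSolution",
    "m_pgu_insulin", "m_hgp_insulin_inf", "m_hgp_gamma0", "m_hgp_glucose",
    "m_hgu_insulin_inf", "m_hgu_glucose", "m_pgr_glucose", "m_pgr_insulin",
    "rate_kidney_glucose_excretion", "peripheral_glucose_uptake",
    "hepatic_rates", "regulatory_derivatives", "pancreas_secretion",
    "insulin_clearances", "glucagon_rates", "full_derivatives",
    "basal_initialization",
]

STATE_NAMES = (
    "G_BV", "G_BI", "G_H", "G_J", "G_L", "G_K", "G_PV", "G_PI",
    "I_B", "I_H", "I_J", "I_L", "I_K", "I_PV", "I_PI",
    "Gamma", "M_HGP_I", "M_HGU_I", "f2", "P", "I_inh", "Q",
    "S_sto", "J_jej", "R_dly", "L_ile",
)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
NSTATES = len(STATE_NAMES)
NCORE = 22  # states excluding the gut chain


@dataclass
class GlucoseState:
    """Glucose compartment concentrations (mg/dl)."""

    G_BV: float
    G_BI: float
    G_H: float
    G_J: float
    G_L: float
    G_K: float
    G_PV: float
    G_PI: float


@dataclass
class InsulinState:
    """Insulin compartment concentrations (mU/l)."""

    I_B: float
    I_H: float
    I_J: float
    I_L: float
    I_K: float
    I_PV: float
    I_PI: float


# ---------------------------------------------------------------------------
# tanh multiplier laws
# ---------------------------------------------------------------------------

def m_pgu_insulin(I_PI_N: float, p: SorensenParams) -> float:
    """Insulin multiplier of peripheral glucose uptake."""
    return p.m_pgu_i_a + p.m_pgu_i_b * math.tanh(p.m_pgu_i_c * (I_PI_N - p.m_pgu_i_d))


def m_hgp_insulin_inf(I_L_N: float, p: SorensenParams) -> float:
    """Asymptote toward which the hepatic-production insulin multiplier relaxes."""
    return p.m_hgp_i_a - p.m_hgp_i_b * math.tanh(p.m_hgp_i_c * (I_L_N - p.m_hgp_i_d))


def m_hgp_gamma0(Gamma_N: float, p: SorensenParams) -> float:
    """Instantaneous glucagon multiplier of hepatic glucose production."""
    return p.m_hgp_gamma_a * math.tanh(p.m_hgp_gamma_b * Gamma_N)


def m_hgp_glucose(G_L_N: float, p: SorensenParams) -> float:
    """Glucose multiplier of hepatic glucose production (nonincreasing)."""
    return p.m_hgp_g_a - p.m_hgp_g_b * math.tanh(p.m_hgp_g_c * (G_L_N - p.m_hgp_g_d))


def m_hgu_insulin_inf(I_L_N: float, p: SorensenParams) -> float:
    """Asymptote of the hepatic-uptake insulin multiplier."""
    return p.m_hgu_i_a * math.tanh(p.m_hgu_i_b * I_L_N)


def m_hgu_glucose(G_L_N: float, p: SorensenParams) -> float:
    """Glucose multiplier of hepatic glucose uptake."""
    return p.m_hgu_g_a + p.m_hgu_g_b * math.tanh(p.m_hgu_g_c * (G_L_N - p.m_hgu_g_d))


def m_pgr_glucose(G_H_N: float, p: SorensenParams) -> float:
    """Glucose multiplier of pancreatic glucagon release (nonincreasing)."""
    return p.m_pgr_g_a - p.m_pgr_g_b * math.tanh(p.m_pgr_g_c * (G_H_N - p.m_pgr_g_d))


def m_pgr_insulin(I_H_N: float, p: SorensenParams) -> float:
    """Insulin multiplier of pancreatic glucagon release."""
    return p.m_pgr_i_a - p.m_pgr_i_b * math.tanh(p.m_pgr_i_c * (I_H_N - p.m_pgr_i_d))


# ---------------------------------------------------------------------------
# metabolic source/sink rate laws
# ---------------------------------------------------------------------------

def rate_kidney_glucose_excretion(G_K: float, p: SorensenParams) -> float:
    """Renal glucose excretion (mg/min), piecewise in kidney glucose (mg/dl).

    Below the 460 mg/dl threshold the corrected shallow tanh branch applies
    (slope factor 0.011); at and above the threshold the affine branch.
    """
    if G_K < 0:
        raise ValueError(f"kidney glucose concentration must be >= 0, got {G_K}")
    if G_K <= p.kge_d:
        return p.kge_a + p.kge_b * math.tanh(p.kge_c * (G_K - p.kge_d))
    return p.kge_lin_a + p.kge_lin_b * G_K


def peripheral_glucose_uptake(I_PI_N: float, G_PI_N: float, p: SorensenParams) -> float:
    """Peripheral glucose uptake (mg/min) from normalized interstitial drivers."""
    if I_PI_N < 0 or G_PI_N < 0:
        raise ValueError("normalized drivers must be >= 0")
    return m_pgu_insulin(I_PI_N, p) * G_PI_N * p.r_B_PGU


def hepatic_rates(
    M_HGP_I: float,
    f2: float,
    Gamma_N: float,
    G_L_N: float,
    M_HGU_I: float,
    p: SorensenParams,
) -> tuple[float, float]:
    """Hepatic glucose production and uptake (mg/min)."""
    m_gamma = m_hgp_gamma0(Gamma_N, p) - f2
    r_HGP = M_HGP_I * m_gamma * m_hgp_glucose(G_L_N, p) * p.r_B_HGP
    r_HGU = M_HGU_I * m_hgu_glucose(G_L_N, p) * p.r_B_HGU
    return r_HGP, r_HGU


def regulatory_derivatives(
    M_HGP_I: float,
    M_HGU_I: float,
    f2: float,
    I_L_N: float,
    Gamma_N: float,
    p: SorensenParams,
) -> tuple[float, float, float]:
    """First-order relaxations of the two insulin multipliers and f2."""
    dM_HGP_I = (m_hgp_insulin_inf(I_L_N, p) - M_HGP_I) / p.tau_I
    dM_HGU_I = (m_hgu_insulin_inf(I_L_N, p) - M_HGU_I) / p.tau_I
    df2 = ((m_hgp_gamma0(Gamma_N, p) - 1.0) / 2.0 - f2) / p.tau_Gamma
    return dM_HGP_I, dM_HGU_I, df2


def pancreas_glucose_drive(G_H: float, p: SorensenParams) -> float:
    """Early-phase secretory drive X as a function of heart glucose (mg/dl)."""
    if G_H < 0:
        raise ValueError(f"heart glucose concentration must be >= 0, got {G_H}")
    g = G_H * p.pancreas_glucose_scale
    return g ** p.beta_pir1 / (p.beta_pir2 ** p.beta_pir1 + p.beta_pir3 * g ** p.beta_pir4)


def pancreas_secretion(
    G_H: float,
    P: float,
    I_inh: float,
    Q: float,
    p: SorensenParams,
    S_B: float | None = None,
    r_B_PIR: float | None = None,
) -> dict[str, float]:
    """Pancreatic insulin secretion.

    Returns X (glucose drive), Y = P_inf (potentiator target), S (U/min) and,
    when the basal anchors ``S_B`` / ``r_B_PIR`` are supplied, the released
    rate ``r_PIR = S/S_B * r_B_PIR`` in mU/min.
    """
    if Q < 0:
        raise ValueError(f"labile pool must be >= 0, got {Q}")
    X = pancreas_glucose_drive(G_H, p)
    Y = X ** p.beta_pir5
    S = (p.M1 * Y + p.M2 * max(0.0, X - I_inh)) * Q
    out = {"X": X, "Y": Y, "P_inf": Y, "S": S}
    if S_B is not None and r_B_PIR is not None:
        out["r_PIR"] = S / S_B * r_B_PIR
    return out


def insulin_clearances(
    I_H: float, I_J: float, I_PI: float, r_PIR: float, p: SorensenParams
) -> tuple[float, float, float]:
    """Liver, kidney and periphery insulin clearance rates (mU/min)."""
    r_LIC = p.F_LIC * (p.Q_I_A * I_H + p.Q_I_J * I_J + r_PIR)
    r_KIC = p.F_KIC * p.Q_I_K * I_H
    denom = (1.0 - p.F_PIC) / (p.F_PIC * p.Q_I_P) - p.T_I_P / p.V_I_PI
    r_PIC = I_PI / denom
    return r_LIC, r_KIC, r_PIC


def glucagon_rates(
    G_H_N: float, I_H_N: float, Gamma: float, p: SorensenParams,
    r_B_PGR: float,
) -> tuple[float, float]:
    """Normalized glucagon release and clearance (1/min before volume division).

    ``r_B_PGR`` is the basal release anchor chosen so that release equals
    clearance at the basal point (see :func:`basal_initialization`).
    """
    release = m_pgr_glucose(G_H_N, p) * m_pgr_insulin(I_H_N, p) * r_B_PGR
    clearance = p.r_MGammaC * Gamma
    return release, clearance


# ---------------------------------------------------------------------------
# basal steady state
# ---------------------------------------------------------------------------

@dataclass
class BasalSolution:
    """Basal equilibrium of the whole-body model.

    ``state`` is the 26-vector initial condition; the ``*_B`` anchors define
    the normalization used by every multiplier law during simulation.  In
    ``exact`` mode the state is refined by a root solve of the full
    right-hand side so that max\\|dX/dt\\| is at machine-level zero; in
    ``paper`` mode the printed cascade is returned unrefined (multipliers at
    1, f2 = 0, kidney at the heart concentration).
    """

    state: np.ndarray
    mode: str
    # normalization anchors
    G_HB: float
    G_LB: float
    G_PIB: float
    G_KB: float
    G_BVB: float
    G_BIB: float
    G_JB: float
    G_PVB: float
    I_HB: float
    I_LB: float
    I_PIB: float
    I_PVB: float
    Gamma_B: float
    # derived basal rates and pancreas state
    r_B_PIR: float      # mU/min
    S_B: float          # U/min
    X_B: float
    Y_B: float
    P_B: float
    I_inh_B: float
    Q_B: float
    r_B_PGR: float      # normalized glucagon release anchor
    max_residual: float = field(default=float("nan"))

    def anchors(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("G_HB", "G_LB", "G_PIB", "G_KB", "G_BVB", "G_BIB", "G_JB",
                      "G_PVB", "I_HB", "I_LB", "I_PIB", "I_PVB", "Gamma_B",
                      "r_B_PIR", "S_B", "r_B_PGR")
        }


def _printed_cascade(
    p: SorensenParams, G_PVB: float, I_PVB: float, Gamma_B: float, paper_ic: bool
) -> BasalSolution:
    """Corrected printed initial-condition cascade (the normalization anchors)."""
    # glucose side
    G_HB = G_PVB + p.r_B_PGU / p.Q_G_P
    G_KB = G_HB
    G_BVB = G_HB - p.r_BGU / p.Q_G_B
    G_JB = G_HB - p.r_JGU / p.Q_G_J
    # liver from its own steady balance with basal production/uptake rates
    G_LB = (p.Q_G_A * G_HB + p.Q_G_J * G_JB + p.r_B_HGP - p.r_B_HGU) / p.Q_G_L
    G_BIB = G_BVB - p.r_BGU * p.T_B / p.V_BI
    G_PIB = G_PVB - p.r_B_PGU * p.T_G_P / p.V_PI   # peripheral uptake, corrected
    if min(G_HB, G_KB, G_BVB, G_JB, G_LB, G_BIB, G_PIB) < 0:
        names = ("G_HB", "G_KB", "G_BVB", "G_JB", "G_LB", "G_BIB", "G_PIB")
        vals = (G_HB, G_KB, G_BVB, G_JB, G_LB, G_BIB, G_PIB)
        bad = [n for n, v in zip(names, vals) if v < 0]
        raise ValueError(f"infeasible basal state: negative concentration in {bad}")

    # insulin side (exactly zeroes every insulin balance)
    I_HB = I_PVB / (1.0 - p.F_PIC)
    I_BB = I_HB
    I_JB = I_HB
    I_KB = I_HB * (1.0 - p.F_KIC)
    I_PIB = I_PVB - p.Q_I_P * p.T_I_P / p.V_I_PI * (I_HB - I_PVB)
    # liver insulin from the heart/lungs steady balance (not the printed sign pattern)
    I_LB = (p.Q_I_H * I_HB - p.Q_I_B * I_BB - p.Q_I_K * I_KB - p.Q_I_P * I_PVB) / p.Q_I_L
    if min(I_HB, I_KB, I_PIB, I_LB) < 0:
        raise ValueError("infeasible basal state: negative basal insulin concentration")
    r_B_PIR = p.Q_I_L / (1.0 - p.F_LIC) * I_LB - p.Q_I_J * I_JB - p.Q_I_A * I_HB
    if r_B_PIR <= 0:
        raise ValueError("infeasible basal state: nonpositive basal insulin release")

    # pancreas
    X_B = pancreas_glucose_drive(G_HB, p)
    Y_B = X_B ** p.beta_pir5
    P_B = Y_B
    I_inh_B = X_B
    Q_B = (p.K * p.Q0 + p.gamma * P_B) / (p.K + p.M1 * Y_B)
    S_B = p.M1 * Y_B * Q_B   # early-phase term vanishes at basal

    # glucagon closure: release = clearance at the basal anchors
    r_B_PGR = p.r_MGammaC * Gamma_B / (m_pgr_glucose(1.0, p) * m_pgr_insulin(1.0, p))

    if paper_ic:
        M_HGP_I0, M_HGU_I0, f2_0 = 1.0, 1.0, 0.0
    else:
        M_HGP_I0 = m_hgp_insulin_inf(1.0, p)
        M_HGU_I0 = m_hgu_insulin_inf(1.0, p)
        f2_0 = (m_hgp_gamma0(Gamma_B, p) - 1.0) / 2.0

    state = np.zeros(NSTATES)
    state[IDX["G_BV"]] = G_BVB
    state[IDX["G_BI"]] = G_BIB
    state[IDX["G_H"]] = G_HB
    state[IDX["G_J"]] = G_JB
    state[IDX["G_L"]] = G_LB
    state[IDX["G_K"]] = G_KB
    state[IDX["G_PV"]] = G_PVB
    state[IDX["G_PI"]] = G_PIB
    state[IDX["I_B"]] = I_BB
    state[IDX["I_H"]] = I_HB
    state[IDX["I_J"]] = I_JB
    state[IDX["I_L"]] = I_LB
    state[IDX["I_K"]] = I_KB
    state[IDX["I_PV"]] = I_PVB
    state[IDX["I_PI"]] = I_PIB
    state[IDX["Gamma"]] = Gamma_B
    state[IDX["M_HGP_I"]] = M_HGP_I0
    state[IDX["M_HGU_I"]] = M_HGU_I0
    state[IDX["f2"]] = f2_0
    state[IDX["P"]] = P_B
    state[IDX["I_inh"]] = I_inh_B
    state[IDX["Q"]] = Q_B

    return BasalSolution(
        state=state, mode="paper" if paper_ic else "cascade",
        G_HB=G_HB, G_LB=G_LB, G_PIB=G_PIB, G_KB=G_KB, G_BVB=G_BVB, G_BIB=G_BIB,
        G_JB=G_JB, G_PVB=G_PVB, I_HB=I_HB, I_LB=I_LB, I_PIB=I_PIB, I_PVB=I_PVB,
        Gamma_B=Gamma_B, r_B_PIR=r_B_PIR, S_B=S_B, X_B=X_B, Y_B=Y_B, P_B=P_B,
        I_inh_B=I_inh_B, Q_B=Q_B, r_B_PGR=r_B_PGR,
    )


def basal_initialization(
    params: SorensenParams,
    G_PVB: float | None = None,
    I_PVB: float | None = None,
    Gamma_B: float | None = None,
    mode: str = "exact",
) -> BasalSolution:
    """Compute the basal equilibrium from input glycemia/insulinemia.

    Parameters
    ----------
    mode:
        ``"exact"`` (default) refines the printed cascade by a root solve on
        the 22 core balances so the returned state is a true equilibrium of
        the simulated system; ``"paper"`` returns the printed cascade with the
        multipliers at 1 and f2 = 0.
    """
    if mode not in ("exact", "paper"):
        raise ValueError(f"mode must be 'exact' or 'paper', got {mode!r}")
    G_PVB = params.G_PVB if G_PVB is None else float(G_PVB)
    I_PVB = params.I_PVB if I_PVB is None else float(I_PVB)
    Gamma_B = params.Gamma_B if Gamma_B is None else float(Gamma_B)
    if G_PVB <= 0 or I_PVB <= 0 or Gamma_B <= 0:
        raise ValueError("basal inputs must be > 0")
    params.validate()

    basal = _printed_cascade(params, G_PVB, I_PVB, Gamma_B, paper_ic=(mode == "paper"))
    if mode == "paper":
        basal.max_residual = float(
            np.max(np.abs(full_derivatives(basal.state, params, basal)))
        )
        return basal

    # exact mode: Newton-refine the core states with the anchors frozen;
    # variables and residuals are both scaled to their basal magnitudes so
    # the solver sees comparable relative rates across U, mU/l and mg/dl
    scale = np.where(np.abs(basal.state[:NCORE]) > 1e-6,
                     np.abs(basal.state[:NCORE]), 1.0)

    def resid(z: np.ndarray) -> np.ndarray:
        y = basal.state.copy()
        y[:NCORE] = z * scale
        return full_derivatives(y, params, basal)[:NCORE] / scale

    sol = optimize.root(resid, basal.state[:NCORE] / scale, method="hybr", tol=1e-13)
    refined = basal.state.copy()
    refined[:NCORE] = sol.x * scale
    raw = full_derivatives(refined, params, basal)[:NCORE]
    if np.max(np.abs(raw)) > 1e-8:
        raise RuntimeError(
            f"basal equilibrium refinement failed (max residual "
            f"{np.max(np.abs(raw)):.3e}): {sol.message}"
        )
    basal.state = refined
    if np.any(basal.state[:NCORE] < 0):
        bad = [STATE_NAMES[i] for i in range(NCORE) if basal.state[i] < 0]
        raise ValueError(f"infeasible basal state: negative concentration in {bad}")
    basal.mode = "exact"
    basal.max_residual = float(
        np.max(np.abs(full_derivatives(basal.state, params, basal)))
    )
    return basal


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------

def full_derivatives(
    state: np.ndarray,
    p: SorensenParams,
    basal: BasalSolution,
    simo: SimoParams | None = None,
    iv_glucose: float = 0.0,
    iv_insulin: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full 26-state vector.

    ``iv_glucose`` (mg/min) and ``iv_insulin`` (mU/min) enter the heart/lungs
    balances; the oral route enters only through the gut chain, whose
    absorption output feeds the gut glucose balance.
    """
    if not np.all(np.isfinite(state)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(state))]
        raise FloatingPointError(f"non-finite state variable(s): {bad}")

    (G_BV, G_BI, G_H, G_J, G_L, G_K, G_PV, G_PI,
     I_B, I_H, I_J, I_L, I_K, I_PV, I_PI,
     Gamma, M_HGP_I, M_HGU_I, f2, P, I_inh, Q) = state[:NCORE]

    # normalized drivers
    G_H_N = G_H / basal.G_HB
    G_L_N = G_L / basal.G_LB
    G_PI_N = G_PI / basal.G_PIB
    I_H_N = I_H / basal.I_HB
    I_L_N = I_L / basal.I_LB
    I_PI_N = I_PI / basal.I_PIB
    Gamma_N = Gamma / basal.Gamma_B

    # metabolic rates
    r_KGE = rate_kidney_glucose_excretion(max(G_K, 0.0), p)
    r_PGU = m_pgu_insulin(I_PI_N, p) * G_PI_N * p.r_B_PGU
    r_HGP, r_HGU = hepatic_rates(M_HGP_I, f2, Gamma_N, G_L_N, M_HGU_I, p)
    panc = pancreas_secretion(max(G_H, 0.0), P, I_inh, max(Q, 0.0), p,
                              S_B=basal.S_B, r_B_PIR=basal.r_B_PIR)
    r_PIR = panc["r_PIR"]
    r_LIC, r_KIC, r_PIC = insulin_clearances(I_H, I_J, I_PI, r_PIR, p)
    release, clearance = glucagon_rates(G_H_N, I_H_N, Gamma, p, basal.r_B_PGR)

    # gut chain
    if simo is None:
        d_gut = np.zeros(4)
        r_oga = 0.0
    else:
        gut = state[NCORE:]
        d_gut = gut_simo.simo_derivatives(gut, simo)
        r_oga = gut_simo.oral_absorption_rate(gut, simo)

    d = np.empty(NSTATES)
    # glucose balances
    d[0] = (p.Q_G_B * (G_H - G_BV) - p.V_BI / p.T_B * (G_BV - G_BI)) / p.V_G_BV
    d[1] = (p.V_BI / p.T_B * (G_BV - G_BI) - p.r_BGU) / p.V_BI
    d[2] = (p.Q_G_B * G_BV + p.Q_G_L * G_L + p.Q_G_K * G_K + p.Q_G_P * G_PV
            - p.Q_G_H * G_H - p.r_RBCU + iv_glucose) / p.V_G_H
    d[3] = (p.Q_G_J * (G_H - G_J) - p.r_JGU + r_oga) / p.V_G_J
    d[4] = (p.Q_G_A * G_H + p.Q_G_J * G_J - p.Q_G_L * G_L + r_HGP - r_HGU) / p.V_G_L
    d[5] = (p.Q_G_K * (G_H - G_K) - r_KGE) / p.V_G_K
    d[6] = (p.Q_G_P * (G_H - G_PV) - p.V_PI / p.T_G_P * (G_PV - G_PI)) / p.V_G_PV
    d[7] = (p.V_PI / p.T_G_P * (G_PV - G_PI) - r_PGU) / p.V_PI
    # insulin balances
    d[8] = p.Q_I_B * (I_H - I_B) / p.V_I_B
    d[9] = (p.Q_I_B * I_B + p.Q_I_L * I_L + p.Q_I_K * I_K + p.Q_I_P * I_PV
            - p.Q_I_H * I_H + iv_insulin) / p.V_I_H
    d[10] = p.Q_I_J * (I_H - I_J) / p.V_I_J
    d[11] = (p.Q_I_A * I_H + p.Q_I_J * I_J - p.Q_I_L * I_L + r_PIR - r_LIC) / p.V_I_L
    d[12] = (p.Q_I_K * (I_H - I_K) - r_KIC) / p.V_I_K
    d[13] = (p.Q_I_P * (I_H - I_PV) - p.V_I_PI / p.T_I_P * (I_PV - I_PI)) / p.V_I_PV
    d[14] = (p.V_I_PI / p.T_I_P * (I_PV - I_PI) - r_PIC) / p.V_I_PI
    # glucagon (normalized)
    d[15] = (release - clearance) / p.V_Gamma
    # regulatory states
    d[16], d[17], d[18] = regulatory_derivatives(
        M_HGP_I, M_HGU_I, f2, I_L_N, Gamma_N, p
    )
    # pancreas
    d[19] = p.alpha * (panc["P_inf"] - P)
    d[20] = p.beta * (panc["X"] - I_inh)
    d[21] = p.K * (p.Q0 - Q) + p.gamma * P - panc["S"]
    # gut
    d[NCORE:] = d_gut
    return d


# ---------------------------------------------------------------------------
# legacy erroneous forms -- regression fixtures only, never used by the model
# ---------------------------------------------------------------------------

class legacy_errors:
    """The uncorrected rate-law variants, kept to prove divergence in tests."""

    @staticmethod
    def rate_kidney_glucose_excretion(G_K: float, p: SorensenParams) -> float:
        # erroneous steep slope 0.11
        if G_K < p.kge_d:
            return p.kge_a + p.kge_b * math.tanh(0.11 * (G_K - p.kge_d))
        return p.kge_lin_a + p.kge_lin_b * G_K

    @staticmethod
    def renal_insulin_clearance(I_K: float, p: SorensenParams) -> float:
        # erroneous use of the kidney concentration
        return p.F_KIC * p.Q_I_K * I_K

    @staticmethod
    def labile_pool_derivative(Q: float, P: float, S: float, p: SorensenParams) -> float:
        # erroneous destabilizing sign K(Q - Q0)
        return p.K * (Q - p.Q0) + p.gamma * P - S

    @staticmethod
    def basal_peripheral_interstitial_glucose(G_PVB: float, p: SorensenParams) -> float:
        # erroneous use of the brain uptake rate
        return G_PVB - p.r_BGU * p.T_G_P / p.V_PI
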