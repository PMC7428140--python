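"""Parameter sets for the whole-body glucose-insulin-glucagon model and the gut chain.

Two whole-body presets are shipped:

``appendix_a1``
    The corrected literature parameterization (glucose in mg/dl for the
    pancreas glucose-sensing law).
``table3_after``
    The OGTT-recalibrated insulin-secretion parameters (pancreas glucose
    sensing in mM; the ``pancreas_glucose_scale`` field carries the unit
    conversion so each preset is used only with its own unit system).

Gut-chain presets: ``simo_after`` (OGTT-calibrated, default), ``simo_prior``
(original published averages) and ``simo_table3_after``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Any

__all__ = [
    "SorensenParams",
    "SimoParams",
    "appendix_a1",
    "table3_after",
    "simo_after",
    "simo_prior",
    "simo_table3_after",
    "get_preset",
    "get_simo_preset",
    "PMOL_PER_U",
    "MGDL_PER_MMOL",
    "K_APPENDIX_A1_PRINTED",
]

#: Unit conversions implied by the shipped parameter pairs
#: (Q0 = 6.33 U <-> 44310 pmol; beta_pir2 = 132 mg/dl <-> 7.333 mM).
PMOL_PER_U = 7000.0
MGDL_PER_MMOL = 18.0

#: The labile-pool rate constant as printed in the legacy summary (U/min).
#: Dimensionally inconsistent with its balance equation, which requires 1/min;
#: the shipped presets use the 1/min value (0.00794). Kept for the record only.
K_APPENDIX_A1_PRINTED = 0.575


@dataclass
class SorensenParams:
    """All constants of the 22-state whole-body model.

    Units: glucose concentrations mg/dl, glucose volumes dl, glucose flows
    dl/min; insulin concentrations mU/l, insulin volumes l, flows l/min;
    glucagon normalized (basal = 1); times in minutes; secretion pool in U.
    """

    # --- glucose side: volumes (dl) ---
    V_G_BV: float = 3.5     # brain vascular
    V_BI: float = 4.5       # brain interstitial (shared glucose/insulin naming)
    V_G_H: float = 13.8     # heart and lungs
    V_G_L: float = 25.1     # liver
    V_G_J: float = 11.2     # gut
    V_G_K: float = 6.6      # kidney
    V_G_PV: float = 10.4    # periphery vascular
    V_PI: float = 67.4      # periphery interstitial
    # --- glucose side: flows (dl/min) ---
    Q_G_B: float = 5.9
    Q_G_H: float = 43.7     # = Q_G_B + Q_G_L + Q_G_K + Q_G_P
    Q_G_A: float = 2.5      # hepatic artery
    Q_G_L: float = 12.6     # = Q_G_A + Q_G_J
    Q_G_J: float = 10.1
    Q_G_K: float = 10.1
    Q_G_P: float = 15.1
    # --- transcapillary diffusion times (min) ---
    T_B: float = 2.1
    T_G_P: float = 5.0
    # --- insulin side: volumes (l) ---
    V_I_B: float = 0.26
    V_I_H: float = 0.99
    V_I_J: float = 0.94
    V_I_L: float = 1.14
    V_I_K: float = 0.51
    V_I_PV: float = 0.74
    V_I_PI: float = 6.74
    # --- insulin side: flows (l/min) ---
    Q_I_B: float = 0.45
    Q_I_H: float = 3.12     # = Q_I_B + Q_I_L + Q_I_K + Q_I_P
    Q_I_A: float = 0.18
    Q_I_K: float = 0.72
    Q_I_P: float = 1.05
    Q_I_J: float = 0.72
    Q_I_L: float = 0.90     # = Q_I_A + Q_I_J
    T_I_P: float = 20.0
    # --- fractional insulin clearances ---
    F_LIC: float = 0.40
    F_KIC: float = 0.30
    F_PIC: float = 0.15
    # --- constant glucose uptakes (mg/min) ---
    r_BGU: float = 70.0
    r_RBCU: float = 10.0
    r_JGU: float = 20.0
    # --- basal metabolic rates (mg/min) ---
    r_B_PGU: float = 35.0
    r_B_HGP: float = 155.0
    r_B_HGU: float = 20.0
    # --- multiplier relaxation time constants (min) ---
    tau_I: float = 25.0
    tau_Gamma: float = 65.0
    # --- tanh law coefficients ---
    # peripheral glucose uptake, insulin multiplier
    m_pgu_i_a: float = 7.03
    m_pgu_i_b: float = 6.52
    m_pgu_i_c: float = 0.338
    m_pgu_i_d: float = 5.82
    # hepatic glucose production, insulin multiplier (asymptote)
    m_hgp_i_a: float = 1.21
    m_hgp_i_b: float = 1.14
    m_hgp_i_c: float = 1.66
    m_hgp_i_d: float = 0.89
    # hepatic glucose production, glucagon multiplier
    m_hgp_gamma_a: float = 2.7
    m_hgp_gamma_b: float = 0.39
    # hepatic glucose production, glucose multiplier
    m_hgp_g_a: float = 1.42
    m_hgp_g_b: float = 1.41
    m_hgp_g_c: float = 0.62
    m_hgp_g_d: float = 0.497
    # hepatic glucose uptake, insulin multiplier (asymptote)
    m_hgu_i_a: float = 2.0
    m_hgu_i_b: float = 0.55
    # hepatic glucose uptake, glucose multiplier
    m_hgu_g_a: float = 5.66
    m_hgu_g_b: float = 5.66
    m_hgu_g_c: float = 2.44
    m_hgu_g_d: float = 1.48
    # kidney glucose excretion (corrected 0.011 factor)
    kge_a: float = 71.0
    kge_b: float = 71.0
    kge_c: float = 0.011
    kge_d: float = 460.0
    kge_lin_a: float = -330.0
    kge_lin_b: float = 0.872
    # glucagon release multipliers
    m_pgr_g_a: float = 2.93
    m_pgr_g_b: float = 2.10
    m_pgr_g_c: float = 4.18
    m_pgr_g_d: float = 0.61
    m_pgr_i_a: float = 1.31
    m_pgr_i_b: float = 0.61
    m_pgr_i_c: float = 1.06
    m_pgr_i_d: float = 0.47
    # --- pancreas secretion submodel ---
    alpha: float = 0.0482       # 1/min, potentiator relaxation
    beta: float = 0.931         # 1/min, inhibitor relaxation
    K: float = 0.00794          # 1/min, labile pool turnover
    Q0: float = 6.33            # U, labile pool set point
    gamma: float = 0.575        # U/min, potentiator-driven provision
    M1: float = 0.00747         # 1/min
    M2: float = 0.0958          # 1/min
    beta_pir1: float = 3.27
    beta_pir2: float = 132.0    # glucose units of the preset's unit system
    beta_pir3: float = 5.93
    beta_pir4: float = 3.02
    beta_pir5: float = 1.11
    #: multiply heart glucose (mg/dl) by this before the secretion law
    #: (1.0 -> mg/dl system; 1/18 -> mM system).
    pancreas_glucose_scale: float = 1.0
    # --- glucagon ---
    r_MGammaC: float = 9.10     # ml/min metabolic clearance
    V_Gamma: float = 11310.0    # ml distribution volume
    # --- basal inputs ---
    G_PVB: float = 89.0         # mg/dl basal peripheral vascular glucose
    I_PVB: float = 12.8         # mU/l basal peripheral vascular insulin
    Gamma_B: float = 1.0        # normalized basal glucagon

    def validate(self) -> None:
        """Raise ``ValueError`` on any structurally invalid entry."""
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or v != v:
                raise ValueError(f"parameter {f.name} is not a finite number: {v!r}")
        positive = [f.name for f in dataclasses.fields(self)
                    if f.name.startswith(("V_", "Q_", "T_", "tau_"))]
        positive += ["alpha", "beta", "K", "Q0", "gamma", "M1", "M2",
                     "pancreas_glucose_scale", "r_MGammaC", "G_PVB", "I_PVB", "Gamma_B"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {getattr(self, name)}")
        for name in ("F_LIC", "F_KIC", "F_PIC"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"fractional clearance {name} must lie in (0, 1), got {v}")

    def replace(self, **kwargs: float) -> "SorensenParams":
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SorensenParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p

    @classmethod
    def from_json(cls, path: str) -> "SorensenParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimoParams:
    """Rate constants (1/min) and bioavailable fraction of the gut transit chain."""

    k_js: float = 0.028237      # stomach -> jejunum
    k_gj: float = 0.0329673     # jejunum -> blood
    k_rj: float = 0.0344046     # jejunum -> delay
    k_lr: float = 0.0513802     # delay -> ileum
    k_gl: float = 0.0180942     # ileum -> blood
    f: float = 1.0              # fraction of absorbed flux appearing in plasma

    def validate(self) -> None:
        for name in ("k_js", "k_gj", "k_rj", "k_lr", "k_gl"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate constant {name} must be > 0")
        if not 0.0 < self.f <= 1.0:
            raise ValueError(f"fraction f must lie in (0, 1], got {self.f}")

    def replace(self, **kwargs: float) -> "SimoParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimoParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown gut parameter(s): {sorted(unknown)}")
        p = cls(**d)
        p.validate()
        return p


def appendix_a1() -> SorensenParams:
    """Corrected literature preset (pancreas glucose sensing in mg/dl)."""
    return SorensenParams()


def table3_after() -> SorensenParams:
    """OGTT-recalibrated secretion preset (pancreas glucose sensing in mM).

    Pool and provision constants are converted pmol -> U with the factor
    implied by the shipped pair Q0 = 6.33 U <-> 44310 pmol (7000 pmol/U);
    the secretion law ratio is invariant under that common rescaling.
    """
    return SorensenParams(
        alpha=0.014,
        beta=15.558,
        K=0.0145,
        Q0=44310.0 / PMOL_PER_U,
        gamma=2138.76 / PMOL_PER_U,
        M1=0.00012,
        M2=0.2488,
        beta_pir1=4.164,
        beta_pir2=3.776,
        beta_pir3=1.837,
        beta_pir4=3.577,
        beta_pir5=2.876,
        pancreas_glucose_scale=1.0 / MGDL_PER_MMOL,
    )


def simo_prior() -> SimoParams:
    """Original published average gut parameters (pre-calibration)."""
    return SimoParams(k_js=0.25, k_gj=0.042, k_rj=0.09, k_lr=0.06, k_gl=0.1, f=0.7)


def simo_after() -> SimoParams:
    """Gut parameters calibrated on the legacy absorption-rate curve (default)."""
    return SimoParams()


def simo_table3_after() -> SimoParams:
    """Gut parameters from the joint whole-model OGTT refit."""
    return SimoParams(k_js=0.026, k_gj=0.032, k_rj=0.029, k_lr=0.026, k_gl=0.035, f=1.0)


_PRESETS = {"appendix_a1": appendix_a1, "table3_after": table3_after}
_SIMO_PRESETS = {
    "simo_after": simo_after,
    "simo_prior": simo_prior,
    "simo_table3_after": simo_table3_after,
}


def get_preset(name: str) -> SorensenParams:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown parameter preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def get_simo_preset(name: str) -> SimoParams:
    try:
        return _SIMO_PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown gut preset {name!r}; available: {sorted(_SIMO_PRESETS)}"
        ) from None
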