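"""Experiment engine: dosing events, integration, observable extraction.

Routes
------
``iv_glucose_bolus``
    dose in g/kg, delivered as a constant rate into the heart/lungs glucose
    balance over the administration window (default 3 min).
``iv_insulin_bolus``
    dose in U/kg, same windowed delivery into the heart/lungs insulin balance.
``iv_insulin_infusion``
    dose in mU/kg/min, constant for ``infusion_duration`` minutes.
``oral_glucose``
    dose in g, loaded into the stomach compartment at the administration time.

Derived observation channels follow the venous conversion conventions:
peripheral venous *blood* glucose is 0.84 * G_PV and venous *plasma* glucose
is 0.925 * G_PV; insulin channels are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import gut_simo, model_core
from .model_core import BasalSolution, IDX, NCORE, NSTATES, STATE_NAMES
from .params import SimoParams, SorensenParams

__all__ = [
    "Protocol", "SolverConfig", "TimeSeries", "run_protocol", "to_observed",
    "VENOUS_BLOOD_FACTOR", "VENOUS_PLASMA_FACTOR", "ROUTES", "CHANNELS",
]

VENOUS_BLOOD_FACTOR = 0.84
VENOUS_PLASMA_FACTOR = 0.925

ROUTES = ("iv_glucose_bolus", "iv_insulin_bolus", "iv_insulin_infusion",
          "oral_glucose", "none")

_DERIVED_CHANNELS = ("glucose_venous_blood", "glucose_venous_plasma",
                     "insulin_plasma", "r_oga", "r_PIR")
CHANNELS = STATE_NAMES + _DERIVED_CHANNELS

_DOSE_UNITS = {
    "iv_glucose_bolus": "g/kg",
    "iv_insulin_bolus": "U/kg",
    "iv_insulin_infusion": "mU/kg/min",
    "oral_glucose": "g",
    "none": "",
}


@dataclass
class Protocol:
    """A dosing/sampling experiment description."""

    route: str = "none"
    dose: float = 0.0
    dose_unit: str = ""
    body_weight: float = 70.0       # kg; standard-man default
    window: float = 3.0             # min, IV bolus administration window
    start_time: float = 0.0         # min, administration start
    infusion_duration: float = 0.0  # min, for iv_insulin_infusion
    duration: float = 180.0         # min, total simulated time
    grid_step: float = 1.0          # min, output sampling step

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}; valid: {ROUTES}")
        if not self.dose_unit:
            self.dose_unit = _DOSE_UNITS[self.route]
        elif self.dose_unit != _DOSE_UNITS[self.route]:
            raise ValueError(
                f"route {self.route!r} expects dose unit "
                f"{_DOSE_UNITS[self.route]!r}, got {self.dose_unit!r}"
            )
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.window < 0:
            raise ValueError("administration window must be >= 0")
        if self.route == "iv_insulin_infusion" and self.dose > 0 \
                and self.infusion_duration <= 0:
            raise ValueError("iv_insulin_infusion requires infusion_duration > 0")

    def input_events(self) -> tuple[float, float, float, float]:
        """(t_on, t_off, iv_glucose mg/min, iv_insulin mU/min) for the IV routes."""
        t_on = self.start_time
        if self.route == "iv_glucose_bolus" and self.dose > 0:
            total_mg = self.dose * self.body_weight * 1000.0
            w = max(self.window, 1e-9)
            return t_on, t_on + w, total_mg / w, 0.0
        if self.route == "iv_insulin_bolus" and self.dose > 0:
            total_mU = self.dose * self.body_weight * 1000.0
            w = max(self.window, 1e-9)
            return t_on, t_on + w, 0.0, total_mU / w
        if self.route == "iv_insulin_infusion" and self.dose > 0:
            rate_mU = self.dose * self.body_weight
            return t_on, t_on + self.infusion_duration, 0.0, rate_mU
        return 0.0, 0.0, 0.0, 0.0

    def oral_dose_mg(self) -> float:
        return self.dose * 1000.0 if self.route == "oral_glucose" else 0.0


@dataclass
class SolverConfig:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    negative_tolerance: float = 1e-6  # warn when states dip below -this


@dataclass
class TimeSeries:
    """Aligned per-channel trajectories on a common time grid."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    def channel(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise KeyError(
                f"unknown channel {name!r}; available: "
                f"{[c for c in self.frame.columns if c != 'time']}"
            )
        return self.frame[name].to_numpy()

    def at(self, name: str, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of one channel at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.time, self.channel(name))


def _output_grid(protocol: Protocol, breakpoints: list[float]) -> np.ndarray:
    grid = np.arange(0.0, protocol.duration + 0.5 * protocol.grid_step,
                     protocol.grid_step)
    grid = np.clip(grid, 0.0, protocol.duration)
    pts = [b for b in breakpoints if 0.0 < b < protocol.duration]
    return np.unique(np.concatenate([grid, [protocol.duration], pts]))


def run_protocol(
    protocol: Protocol,
    params: SorensenParams,
    simo: SimoParams | None = None,
    solver: SolverConfig | None = None,
    basal: BasalSolution | None = None,
) -> TimeSeries:
    """Integrate the model from its basal equilibrium under one protocol."""
    solver = solver or SolverConfig()
    if basal is None:
        basal = model_core.basal_initialization(params)
    if simo is None and protocol.route == "oral_glucose" and protocol.dose > 0:
        from .params import simo_after
        simo = simo_after()

    t_on, t_off, u_glc, u_ins = protocol.input_events()
    breaks = sorted({t_on, t_off, protocol.start_time})
    t_eval = _output_grid(protocol, breaks)

    y0 = basal.state.copy()
    oral_pending = protocol.oral_dose_mg()
    if oral_pending > 0 and protocol.start_time == 0.0:
        y0[IDX["S_sto"]] += oral_pending
        oral_pending = 0.0

    segments: list[float] = sorted(
        {0.0, protocol.duration}
        | {b for b in breaks if 0.0 < b < protocol.duration}
    )

    def rhs(t: float, y: np.ndarray, glc: float, ins: float) -> np.ndarray:
        return model_core.full_derivatives(
            y, params, basal, simo=simo, iv_glucose=glc, iv_insulin=ins
        )

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = y0
    for a, bseg in zip(segments[:-1], segments[1:]):
        if oral_pending > 0 and np.isclose(a, protocol.start_time):
            y = y.copy()
            y[IDX["S_sto"]] += oral_pending
            oral_pending = 0.0
        glc = u_glc if (a >= t_on - 1e-12 and bseg <= t_off + 1e-12) else 0.0
        ins = u_ins if (a >= t_on - 1e-12 and bseg <= t_off + 1e-12) else 0.0
        te = t_eval[(t_eval >= a - 1e-12) & (t_eval <= bseg + 1e-12)]
        if len(te) == 0 or not np.isclose(te[0], a):
            te = np.concatenate([[a], te])
        if not np.isclose(te[-1], bseg):
            te = np.concatenate([te, [bseg]])
        sol = solve_ivp(
            rhs, (a, bseg), y, t_eval=te, args=(glc, ins),
            method=solver.method, rtol=solver.rtol, atol=solver.atol,
            max_step=solver.max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed in [{a}, {bseg}] min at t = {sol.t[-1] if len(sol.t) else a}"
                f": {sol.message}"
            )
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        y = sol.y[:, -1]

    t_all = np.concatenate(times_out)
    y_all = np.vstack(states_out)
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    t_all, y_all = t_all[keep], y_all[keep]
    # restrict to the requested grid
    mask = np.isin(np.round(t_all, 9), np.round(t_eval, 9))
    t_all, y_all = t_all[mask], y_all[mask]

    # f2 is a signed offset state; every other core state is a nonnegative quantity
    nonneg = [i for i in range(NCORE) if STATE_NAMES[i] != "f2"]
    low = y_all[:, nonneg].min(initial=0.0)
    if low < -solver.negative_tolerance:
        i = np.unravel_index(np.argmin(y_all[:, nonneg]), y_all[:, nonneg].shape)
        warnings.warn(
            f"state {STATE_NAMES[nonneg[i[1]]]} fell to {low:.3e} "
            f"(below -{solver.negative_tolerance:g}) during the run",
            RuntimeWarning, stacklevel=2,
        )

    frame = pd.DataFrame({"time": t_all})
    for i, name in enumerate(STATE_NAMES):
        frame[name] = y_all[:, i]
    frame["glucose_venous_blood"] = VENOUS_BLOOD_FACTOR * frame["G_PV"]
    frame["glucose_venous_plasma"] = VENOUS_PLASMA_FACTOR * frame["G_PV"]
    frame["insulin_plasma"] = frame["I_PV"]
    if simo is not None:
        frame["r_oga"] = [
            gut_simo.oral_absorption_rate(row, simo) for row in y_all[:, NCORE:]
        ]
    else:
        frame["r_oga"] = 0.0
    s_ratio = np.array([
        model_core.pancreas_secretion(
            max(g, 0.0), pp, ii, max(q, 0.0), params,
            S_B=basal.S_B, r_B_PIR=basal.r_B_PIR,
        )["r_PIR"]
        for g, pp, ii, q in zip(
            frame["G_H"], frame["P"], frame["I_inh"], frame["Q"]
        )
    ])
    frame["r_PIR"] = s_ratio

    meta = {
        "route": protocol.route,
        "dose": protocol.dose,
        "dose_unit": protocol.dose_unit,
        "body_weight": protocol.body_weight,
        "duration": protocol.duration,
        "solver": {"method": solver.method, "rtol": solver.rtol, "atol": solver.atol},
        "basal_mode": basal.mode,
        "basal_max_residual": basal.max_residual,
    }
    return TimeSeries(frame=frame, metadata=meta)


_OBSERVED_FACTORS = {
    "glucose_venous_blood": ("G_PV", VENOUS_BLOOD_FACTOR),
    "glucose_venous_plasma": ("G_PV", VENOUS_PLASMA_FACTOR),
}


def to_observed(series: TimeSeries, channel: str) -> np.ndarray:
    """Return one observable channel, applying venous conversion if needed.

    ``glucose_venous_blood``/``glucose_venous_plasma`` rescale G_PV by 0.84 /
    0.925; any other known channel is returned unchanged (identity for
    insulin channels and raw states).
    """
    if channel in _OBSERVED_FACTORS:
        src, factor = _OBSERVED_FACTORS[channel]
        return factor * series.channel(src)
    return series.channel(channel)
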