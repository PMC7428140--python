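"""Synthetic observation generation.

The legacy absorption-rate and secretion-rate "data" were digitized from
figures and never printed, so they are irreproducible; these generators
produce declared stand-ins from the shipped parameter presets, with the
mean-proportional noise structure y_j = f_j * (1 + sigma * z_j), z_j iid
standard normal.  Every output is labelled STANDIN in its metadata and is
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gut_simo, protocols
from .estimation import ObservationSet
from .params import SimoParams, SorensenParams, simo_after, table3_after

__all__ = [
    "NoiseModel", "standin_grid", "generate_observations",
    "generate_roga_standin", "generate_rpir_standin",
]


@dataclass
class NoiseModel:
    """Mean-proportional normal noise: y = f * (1 + sigma * z)."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, f: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(self.seed)
        f = np.asarray(f, dtype=float)
        if self.sigma == 0:
            return f.copy()
        return f * (1.0 + self.sigma * rng.standard_normal(len(f)))


def standin_grid(n_points: int, t_max: float = 300.0, exponent: float = 1.7) -> np.ndarray:
    """Sampling grid t_i = t_max * (i/(n-1))^exponent: dense early, sparse late."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    i = np.arange(n_points, dtype=float)
    return np.round(t_max * (i / (n_points - 1)) ** exponent, 1)


def generate_observations(
    times: np.ndarray,
    channel: str,
    values: np.ndarray,
    noise: NoiseModel,
    sigma_weight: float | None = None,
) -> ObservationSet:
    """Wrap model expectations into a noisy observation set.

    ``values`` are the model expectations f(t_j, theta) at ``times``;
    requesting a time where the expectation is <= 0 is an error (the
    constant-CV weighting degenerates there).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(values <= 0):
        j = int(np.argmin(values))
        raise ValueError(
            f"model expectation is {values[j]:g} <= 0 at t = {times[j]:g}; "
            "constant-CV observations are undefined there"
        )
    y = noise.apply(values)
    frame = pd.DataFrame({"time": times, "channel": channel, "value": y})
    return ObservationSet(
        frame=frame,
        sigma=noise.sigma if sigma_weight is None else sigma_weight,
        metadata={"label": "STANDIN", "noise_sigma": noise.sigma, "seed": noise.seed},
    )


def generate_roga_standin(
    simo: SimoParams | None = None,
    n_points: int = 27,
    dose_mg: float = 100_000.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> ObservationSet:
    """Stand-in absorption-rate observations from a 100 g oral dose.

    Samples ``r_oga`` at ``n_points`` times on the declared 0-300 min grid.
    The t = 0 record has expectation 0 and is therefore reported with value 0
    and excluded from the constant-CV noise model.
    """
    simo = simo or simo_after()
    times = standin_grid(n_points)
    res = gut_simo.simulate_simo(times, dose_mg, simo)
    vals = res["r_oga"]
    pos = vals > 1e-9 * vals.max()
    noisy = vals.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noisy[pos] = vals[pos] * (1.0 + sigma * rng.standard_normal(int(pos.sum())))
    frame = pd.DataFrame({"time": times, "channel": "r_oga", "value": noisy})
    return ObservationSet(
        frame=frame, sigma=sigma if sigma > 0 else 0.05,
        metadata={
            "label": "STANDIN", "dose_mg": dose_mg, "noise_sigma": sigma,
            "seed": seed, "grid": "t_i = 300*(i/(n-1))^1.7",
        },
    )


def generate_rpir_standin(
    params: SorensenParams | None = None,
    simo: SimoParams | None = None,
    n_points: int = 25,
    dose_g: float = 100.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> ObservationSet:
    """Stand-in secretion-rate observations from an OGTT simulation.

    Uses the OGTT-recalibrated preset by default, mirroring the 25-point
    count of the legacy digitized curve.
    """
    params = params or table3_after()
    simo = simo or simo_after()
    times = standin_grid(n_points)
    proto = protocols.Protocol(route="oral_glucose", dose=dose_g,
                               duration=float(times.max() or 300.0))
    series = protocols.run_protocol(proto, params, simo=simo)
    vals = series.at("r_PIR", times)
    noise = NoiseModel(sigma=sigma, seed=seed)
    obs = generate_observations(times, "r_PIR", vals, noise)
    obs.metadata.update({"dose_g": dose_g, "preset": "table3_after",
                         "grid": "t_i = 300*(i/(n-1))^1.7"})
    return obs
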