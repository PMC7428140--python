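"""Weighted least-squares fitting, multistart protocol, asymptotic covariance.

The loss is the sum of squared residuals weighted by the inverse squared
model expectations (constant-coefficient-of-variation error model):

    L(theta) = sum_j w_j * (y_j - f(t_j, theta))^2 / f(t_j, theta)^2

with w_j = 1 by default (shared scale sigma across channels) or
(sigma / sigma_channel)^2 when a per-channel override is supplied.

A *predictor* is any callable ``predict(theta) -> np.ndarray`` returning
model expectations aligned with the observation records.  Helpers build
predictors for the gut chain alone (fast, matrix-exponential route) and for
the full whole-body model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import gut_simo, model_core, protocols
from .params import SimoParams, SorensenParams

__all__ = [
    "ObservationSet", "FitConfig", "FitResult", "wls_loss", "draw_starts",
    "multistart_fit", "asymptotic_covariance", "make_simo_predictor",
    "make_sorensen_predictor", "run_paper_pipeline", "PENALIZED_LOSS",
    "VALID_OBS_CHANNELS",
]

PENALIZED_LOSS = 1e9
VALID_OBS_CHANNELS = ("glucose", "insulin", "r_oga", "r_PIR")

#: map observation channel tags to simulated series channels
_CHANNEL_TO_SERIES = {
    "glucose": "glucose_venous_blood",
    "insulin": "insulin_plasma",
    "r_oga": "r_oga",
    "r_PIR": "r_PIR",
}


@dataclass
class ObservationSet:
    """Timestamped observations of the observable channels.

    ``frame`` has columns ``time``, ``channel``, ``value``; ``sigma`` is the
    shared coefficient of variation; ``channel_sigma`` optionally overrides
    it per channel (relative weighting only).
    """

    frame: pd.DataFrame
    sigma: float = 0.05
    channel_sigma: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time", "channel", "value"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"observation frame needs columns {sorted(required)}")
        if len(self.frame) == 0:
            raise ValueError("empty observation set")
        bad = set(self.frame["channel"]) - set(VALID_OBS_CHANNELS)
        if bad:
            raise ValueError(
                f"unknown channel(s) {sorted(bad)}; valid: {list(VALID_OBS_CHANNELS)}"
            )
        for ch, grp in self.frame.groupby("channel"):
            if not grp["time"].is_monotonic_increasing:
                raise ValueError(f"times must be nondecreasing within channel {ch!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def channels(self) -> np.ndarray:
        return self.frame["channel"].to_numpy()

    def weights(self) -> np.ndarray:
        """Per-record relative weights (sigma / sigma_channel)^2."""
        w = np.ones(len(self))
        for ch, s in self.channel_sigma.items():
            if s <= 0:
                raise ValueError(f"channel sigma for {ch!r} must be > 0")
            w[self.channels == ch] = (self.sigma / s) ** 2
        return w


@dataclass
class FitConfig:
    """Multistart configuration."""

    free_names: Sequence[str]
    center: np.ndarray                      # start-draw centers, one per free param
    n_starts: int = 1
    perturbation_cv: float = 0.15
    bounds: Sequence[tuple[float, float]] | None = None
    maxiter: int | None = None
    optimizer: str = "Nelder-Mead"
    positivity_floor: float = 1e-8          # times the center value
    #: optimize in log-parameter space (scale-free; keeps iterates positive)
    log_scale: bool = True
    #: restart the local search once from its own optimum (simplex refresh)
    polish: bool = True

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if len(self.free_names) != len(self.center):
            raise ValueError("free_names and center must have equal length")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    free_names: list[str]
    theta_hat: np.ndarray
    loss: float
    starts: np.ndarray          # (n_starts, n_params) initial points
    estimates: np.ndarray       # (n_starts, n_params) per-start optima
    losses: np.ndarray          # (n_starts,)
    n_failed: int = 0
    covariance: np.ndarray | None = None
    cvs_percent: np.ndarray | None = None
    log: dict = field(default_factory=dict)

    def estimate_summary(self) -> pd.DataFrame:
        """Mean/SD/CV%/pairwise correlations of the per-start estimate cloud."""
        ok = np.isfinite(self.losses) & (self.losses < PENALIZED_LOSS)
        est = self.estimates[ok]
        mean = est.mean(axis=0)
        sd = est.std(axis=0, ddof=1) if len(est) > 1 else np.zeros_like(mean)
        return pd.DataFrame({
            "parameter": self.free_names,
            "mean": mean,
            "sd": sd,
            "cv_percent": 100.0 * sd / np.abs(mean),
        })

    def correlation_matrix(self) -> pd.DataFrame:
        ok = np.isfinite(self.losses) & (self.losses < PENALIZED_LOSS)
        c = np.corrcoef(self.estimates[ok].T)
        return pd.DataFrame(c, index=self.free_names, columns=self.free_names)

    def loss_summary(self) -> dict[str, float]:
        ok = np.isfinite(self.losses) & (self.losses < PENALIZED_LOSS)
        ls = self.losses[ok]
        return {
            "min": float(ls.min()), "max": float(ls.max()),
            "mean": float(ls.mean()),
            "sd": float(ls.std(ddof=1)) if len(ls) > 1 else 0.0,
            "n": int(ok.sum()),
        }


def wls_loss(
    theta: np.ndarray,
    obs: ObservationSet,
    predict: Callable[[np.ndarray], np.ndarray],
) -> float:
    """Weighted sum of squared relative residuals; penalized on failure."""
    try:
        f = np.asarray(predict(np.asarray(theta, dtype=float)), dtype=float)
        if f.shape != (len(obs),):
            raise ValueError(
                f"predictor returned shape {f.shape}, expected ({len(obs)},)"
            )
        if not np.all(np.isfinite(f)) or np.any(f == 0):
            return PENALIZED_LOSS
        r = (obs.values - f) / f
        return float(np.sum(obs.weights() * r * r))
    except (FloatingPointError, RuntimeError, OverflowError):
        return PENALIZED_LOSS


def draw_starts(cfg: FitConfig, rng: np.random.Generator) -> np.ndarray:
    """Normal(center, cv*center) start draws, truncated at the positivity floor."""
    starts = rng.normal(
        cfg.center, cfg.perturbation_cv * np.abs(cfg.center),
        size=(cfg.n_starts, len(cfg.center)),
    )
    floor = cfg.positivity_floor * np.abs(cfg.center)
    return np.maximum(starts, floor)


def _minimize_one(
    start: np.ndarray,
    obs: ObservationSet,
    predict: Callable,
    cfg: FitConfig,
) -> tuple[np.ndarray, float]:
    log_scale = cfg.log_scale and np.all(start > 0)

    def objective(z: np.ndarray) -> float:
        theta = np.exp(np.clip(z, -60.0, 60.0)) if log_scale else z
        if cfg.bounds is not None:
            for v, (lo, hi) in zip(theta, cfg.bounds):
                if v < lo or v > hi:
                    return PENALIZED_LOSS
        if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
            return PENALIZED_LOSS
        return wls_loss(theta, obs, predict)

    options = {"xatol": 1e-10, "fatol": 1e-12}
    if cfg.maxiter is not None:
        options["maxiter"] = cfg.maxiter
    z0 = np.log(start) if log_scale else start
    res = optimize.minimize(objective, z0, method=cfg.optimizer, options=options)
    if cfg.polish and cfg.maxiter is None:
        res2 = optimize.minimize(objective, res.x, method=cfg.optimizer,
                                 options=options)
        if res2.fun < res.fun:
            res = res2
    x = np.exp(np.clip(res.x, -60.0, 60.0)) if log_scale else np.asarray(res.x)
    return x, float(res.fun)


def multistart_fit(
    cfg: FitConfig,
    obs: ObservationSet,
    predict: Callable[[np.ndarray], np.ndarray],
    seed: int | np.random.Generator = 0,
) -> FitResult:
    """Run the multistart local-search protocol and keep the best optimum.

    Start ``k`` uses a deterministic substream of the master seed, so results
    are reproducible and independent of execution order.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    starts = draw_starts(cfg, rng)
    estimates = np.empty_like(starts)
    losses = np.full(cfg.n_starts, np.inf)
    for k in range(cfg.n_starts):
        estimates[k], losses[k] = _minimize_one(starts[k], obs, predict, cfg)
    n_failed = int(np.sum(losses >= PENALIZED_LOSS))
    if n_failed == cfg.n_starts:
        raise RuntimeError("all multistart optimizations failed")
    best = int(np.argmin(losses))
    return FitResult(
        free_names=list(cfg.free_names),
        theta_hat=estimates[best].copy(),
        loss=float(losses[best]),
        starts=starts,
        estimates=estimates,
        losses=losses,
        n_failed=n_failed,
        log={
            "optimizer": cfg.optimizer,
            "n_starts": cfg.n_starts,
            "perturbation_cv": cfg.perturbation_cv,
        },
    )


def asymptotic_covariance(
    theta_hat: np.ndarray,
    obs: ObservationSet,
    predict: Callable[[np.ndarray], np.ndarray],
    sigma: float | None = None,
    rel_step: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic covariance sigma^2 [J^T F^-1 J]^-1 and percent CVs.

    J is the central finite-difference Jacobian of the predictions with
    respect to the free parameters at ``theta_hat``; F is the diagonal matrix
    of squared expectations (so S = sigma^2 F is the error covariance).
    A singular information matrix (e.g. a parameter with no effect) degrades
    to the Moore-Penrose pseudo-inverse with a warning.
    """
    import warnings

    theta_hat = np.asarray(theta_hat, dtype=float)
    sigma = obs.sigma if sigma is None else float(sigma)
    f0 = np.asarray(predict(theta_hat), dtype=float)
    if np.any(f0 == 0):
        raise ZeroDivisionError("model expectation is zero at an observation time")
    npar = len(theta_hat)
    J = np.empty((len(obs), npar))
    for i in range(npar):
        h = rel_step * max(abs(theta_hat[i]), 1e-12)
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (np.asarray(predict(tp)) - np.asarray(predict(tm))) / (2 * h)
    w = obs.weights() / f0**2   # F^-1 with per-channel relative weights
    info = J.T @ (w[:, None] * J)
    zero_cols = np.flatnonzero(np.all(J == 0, axis=0))
    cond = np.linalg.cond(info)
    if len(zero_cols) or cond > 1e12:
        warnings.warn(
            "singular or near-singular information matrix"
            + (f"; zero Jacobian column(s) at index {list(zero_cols)}"
               if len(zero_cols) else f" (cond = {cond:.2e})")
            + "; using pseudo-inverse",
            RuntimeWarning, stacklevel=2,
        )
        cov = sigma**2 * np.linalg.pinv(info)
    else:
        cov = sigma**2 * np.linalg.inv(info)
    cvs = 100.0 * np.sqrt(np.maximum(np.diag(cov), 0.0)) / np.abs(theta_hat)
    return cov, cvs


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def make_simo_predictor(obs: ObservationSet, dose_mg: float) -> Callable:
    """Fast r_oga predictor over theta = (k_js, k_gj, k_rj, k_lr, k_gl[, f]).

    Only ``r_oga`` observations are supported; uses the closed-form
    matrix-exponential trajectory of the linear gut chain.
    """
    if set(obs.channels) != {"r_oga"}:
        raise ValueError("the gut-chain predictor supports only r_oga observations")
    times = obs.times

    def predict(theta: np.ndarray) -> np.ndarray:
        if len(theta) == 5:
            p = SimoParams(*theta, f=1.0)
        elif len(theta) == 6:
            p = SimoParams(*theta)
        else:
            raise ValueError("gut-chain theta must have 5 or 6 entries")
        return gut_simo.simulate_simo(times, dose_mg, p)["r_oga"]

    return predict


_SIMO_FIELDS = ("k_js", "k_gj", "k_rj", "k_lr", "k_gl", "f")


def make_sorensen_predictor(
    obs: ObservationSet,
    protocol: protocols.Protocol,
    params: SorensenParams,
    simo: SimoParams,
    free_names: Sequence[str],
    solver: protocols.SolverConfig | None = None,
) -> Callable:
    """Whole-body predictor mapping a free-parameter vector to expectations.

    Free names may address whole-body fields (e.g. ``beta``, ``M2``,
    ``beta_pir1``) or gut fields (``k_js`` ... ``f``).  Each call rebuilds
    the basal state and runs the protocol.
    """
    solver = solver or protocols.SolverConfig(rtol=1e-6, atol=1e-8)
    body_fields = {f.name for f in dataclasses.fields(SorensenParams)}
    for name in free_names:
        if name not in body_fields and name not in _SIMO_FIELDS:
            raise KeyError(f"unknown free parameter {name!r}")
    times = obs.times
    chans = obs.channels

    def predict(theta: np.ndarray) -> np.ndarray:
        body_kw = {n: v for n, v in zip(free_names, theta) if n in body_fields}
        simo_kw = {n: v for n, v in zip(free_names, theta) if n in _SIMO_FIELDS}
        p = params.replace(**body_kw)
        s = simo.replace(**simo_kw)
        p.validate()
        s.validate()
        series = protocols.run_protocol(protocol, p, simo=s, solver=solver)
        out = np.empty(len(times))
        for ch in np.unique(chans):
            m = chans == ch
            out[m] = series.at(_CHANNEL_TO_SERIES[ch], times[m])
        return out

    return predict


# ---------------------------------------------------------------------------
# the four-step identification pipeline
# ---------------------------------------------------------------------------

#: the insulin-secretion free parameters (the labile-pool set point stays fixed)
SECRETION_FREE = ("alpha", "beta", "K", "gamma", "M1", "M2",
                  "beta_pir1", "beta_pir2", "beta_pir3", "beta_pir4", "beta_pir5")
GUT_FREE = ("k_js", "k_gj", "k_rj", "k_lr", "k_gl")


def run_paper_pipeline(
    step: int,
    seed: int = 0,
    *,
    obs_roga: ObservationSet | None = None,
    obs_full: ObservationSet | None = None,
    params: SorensenParams | None = None,
    simo_start: SimoParams | None = None,
    protocol: protocols.Protocol | None = None,
    prior_results: dict | None = None,
    n_starts: int | None = None,
    maxiter: int | None = None,
    solver: protocols.SolverConfig | None = None,
) -> dict:
    """One stage of the four-step identification protocol.

    STEP 1 fits the 5 gut rate constants (f fixed at 1) to an r_oga curve.
    STEP 2 fixes the gut chain and runs a multistart (default 100 starts)
    over the 11 secretion parameters against the full observation set.
    STEP 3 frees all 16, starting from the STEP 1 optimum plus the best
    STEP 2 optimum. STEP 4 reruns (default 200) perturbed restarts about the
    STEP 3 optimum and emits distribution summaries.

    ``prior_results`` carries earlier stage outputs forward; reduced
    ``n_starts``/``maxiter`` permit scaled-down runs.
    """
    from .params import appendix_a1, simo_prior

    params = params or appendix_a1()
    simo_start = simo_start or simo_prior()
    prior_results = prior_results or {}
    rng = np.random.default_rng(seed)

    if step == 1:
        if obs_roga is None:
            raise ValueError(
                "STEP 1 needs r_oga observations; generate a stand-in with "
                "sorensen.fixtures.generate_roga_standin"
            )
        dose = float(obs_roga.metadata.get("dose_mg", 100_000.0))
        # records with nonpositive values carry no information under
        # constant-CV weighting (zero expectation at t = 0)
        keep = obs_roga.frame["value"] > 0
        if not keep.all():
            obs_roga = ObservationSet(
                frame=obs_roga.frame[keep].reset_index(drop=True),
                sigma=obs_roga.sigma,
                channel_sigma=obs_roga.channel_sigma,
                metadata=obs_roga.metadata,
            )
        predict = make_simo_predictor(obs_roga, dose)
        center = np.array([getattr(simo_start, n) for n in GUT_FREE])
        cfg = FitConfig(
            free_names=list(GUT_FREE), center=center,
            n_starts=n_starts if n_starts is not None else 20,
            maxiter=maxiter,
        )
        fit = multistart_fit(cfg, obs_roga, predict, seed=rng)
        return {"step": 1, "fit": fit,
                "simo": SimoParams(*fit.theta_hat, f=simo_start.f)}

    if obs_full is None:
        raise ValueError("STEPs 2-4 need the full observation set")
    protocol = protocol or protocols.Protocol(route="oral_glucose", dose=100.0,
                                              duration=300.0)

    if step == 2:
        simo_fixed = prior_results.get("simo") or simo_start
        center = np.array([getattr(params, n) for n in SECRETION_FREE])
        predict = make_sorensen_predictor(
            obs_full, protocol, params, simo_fixed, SECRETION_FREE, solver=solver
        )
        cfg = FitConfig(
            free_names=list(SECRETION_FREE), center=center,
            n_starts=n_starts if n_starts is not None else 100,
            maxiter=maxiter,
        )
        fit = multistart_fit(cfg, obs_full, predict, seed=rng)
        return {"step": 2, "fit": fit, "simo": simo_fixed}

    if step == 3:
        simo_fixed = prior_results.get("simo") or simo_start
        theta2 = prior_results.get("theta_secretion")
        if theta2 is None:
            theta2 = np.array([getattr(params, n) for n in SECRETION_FREE])
        free = list(GUT_FREE) + list(SECRETION_FREE)
        start = np.concatenate(
            [[getattr(simo_fixed, n) for n in GUT_FREE], theta2]
        )
        predict = make_sorensen_predictor(
            obs_full, protocol, params, simo_fixed, free, solver=solver
        )
        cfg = FitConfig(free_names=free, center=start, n_starts=1,
                        perturbation_cv=0.0, maxiter=maxiter)
        fit = multistart_fit(cfg, obs_full, predict, seed=rng)
        cov, cvs = asymptotic_covariance(fit.theta_hat, obs_full, predict)
        fit.covariance, fit.cvs_percent = cov, cvs
        return {"step": 3, "fit": fit, "free_names": free}

    if step == 4:
        theta3 = prior_results.get("theta_all")
        free = prior_results.get("free_names", list(GUT_FREE) + list(SECRETION_FREE))
        if theta3 is None:
            raise ValueError("STEP 4 needs the STEP 3 optimum (prior_results['theta_all'])")
        simo_fixed = prior_results.get("simo") or simo_start
        predict = make_sorensen_predictor(
            obs_full, protocol, params, simo_fixed, free, solver=solver
        )
        cfg = FitConfig(
            free_names=list(free), center=np.asarray(theta3, dtype=float),
            n_starts=n_starts if n_starts is not None else 200,
            maxiter=maxiter,
        )
        fit = multistart_fit(cfg, obs_full, predict, seed=rng)
        return {
            "step": 4, "fit": fit,
            "estimate_summary": fit.estimate_summary(),
            "correlations": fit.correlation_matrix(),
            "loss_summary": fit.loss_summary(),
        }

    raise ValueError(f"step must be 1..4, got {step}")
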