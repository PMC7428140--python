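"""Metropolis-within-Gibbs a-posteriori identifiability analysis.

The sampled parameter is xi = (eta, sigma^2) with eta = log(theta) for the
target parameters.  sigma^2 has an inverse-gamma prior GI(nu/2, tau/2) and an
inverse-gamma full conditional (exact Gibbs draw); eta has a uniform prior on
a box D and is updated by a random-walk Metropolis step with a fixed
multinormal proposal whose variances come from the asymptotic CVs
(Var(log theta) = CV^2).  Nine chains start on the 3x3 lattice of D
(vertices, edge midpoints, center) for the two-parameter case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "McmcConfig", "ChainSet", "CredibilityRegion",
    "sample_sigma2", "model_log_posterior", "mh_step", "run_mh_chain",
    "run_chains", "lattice_starts", "credibility_region",
]


@dataclass
class McmcConfig:
    """Configuration of the Metropolis-within-Gibbs run."""

    target_names: Sequence[str] = ("beta", "M2")
    n_chains: int = 9
    n_iter: int = 10_000
    burn_in: int = 1_000
    nu: float = 0.01
    tau: float = 0.01
    seed: int = 0
    #: per-target fractional CVs defining the proposal Var(log theta) = CV^2
    proposal_cvs: Sequence[float] = (0.1, 0.1)
    #: optional explicit prior box; default is eta0 +/- |eta0| per axis
    region: np.ndarray | None = None
    sigma2_init: float = 0.01

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("iterations must exceed burn-in")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if len(self.proposal_cvs) != len(self.target_names):
            raise ValueError("one proposal CV per target parameter")

    def prior_region(self, eta0: np.ndarray) -> np.ndarray:
        """The box D: per-axis [c - |c|, c + |c|] around the log-optimum."""
        if self.region is not None:
            return np.asarray(self.region, dtype=float)
        c = np.asarray(eta0, dtype=float)
        half = np.abs(c)
        if np.any(half == 0):
            raise ValueError(
                "log-optimum component is 0; supply an explicit region"
            )
        return np.column_stack([c - half, c + half])


@dataclass
class ChainSet:
    """Draws and diagnostics of all chains."""

    eta: np.ndarray          # (n_chains, n_iter, n_params)
    sigma2: np.ndarray       # (n_chains, n_iter)
    acceptance: np.ndarray   # (n_chains,)
    starts: np.ndarray       # (n_chains, n_params)
    burn_in: int
    target_names: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        """Total realizations across chains, as counted before burn-in removal."""
        return self.eta.shape[0] * self.eta.shape[1]

    def pooled(self) -> np.ndarray:
        """Post-burn-in eta draws pooled over chains, shape (n, n_params)."""
        return self.eta[:, self.burn_in:, :].reshape(-1, self.eta.shape[2])

    def pooled_sigma2(self) -> np.ndarray:
        return self.sigma2[:, self.burn_in:].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_iter, npar = self.eta.shape
        rows = {
            "chain": np.repeat(np.arange(n_chains), n_iter),
            "iteration": np.tile(np.arange(n_iter), n_chains),
        }
        names = self.target_names or [f"eta{i}" for i in range(npar)]
        for j, name in enumerate(names):
            rows[f"log_{name}"] = self.eta[:, :, j].reshape(-1)
        rows["sigma2"] = self.sigma2.reshape(-1)
        return pd.DataFrame(rows)


def sample_sigma2(
    residuals: np.ndarray,
    predictions: np.ndarray,
    nu: float,
    tau: float,
    rng: np.random.Generator,
) -> float:
    """One inverse-gamma Gibbs draw of sigma^2.

    Shape (n + nu)/2 and scale [(y-f)^T F^-1 (y-f) + tau]/2 with F the
    diagonal matrix of squared expectations.
    """
    residuals = np.asarray(residuals, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    n = len(residuals)
    if n < 1:
        raise ValueError("need at least one observation")
    if np.any(predictions == 0):
        raise ZeroDivisionError("degenerate weight: zero model expectation")
    shape = (n + nu) / 2.0
    scale = 0.5 * (np.sum(residuals**2 / predictions**2) + tau)
    return float(stats.invgamma.rvs(shape, scale=scale, random_state=rng))


def model_log_posterior(
    eta: np.ndarray,
    sigma2: float,
    y: np.ndarray,
    predict: Callable[[np.ndarray], np.ndarray],
) -> float:
    """Unnormalized log full-conditional of eta = log(theta).

    Includes the |S|^(-1/2) term: S depends on theta through the
    mean-proportional error variances sigma^2 f(t_j, theta)^2.
    """
    f = np.asarray(predict(np.exp(np.asarray(eta, dtype=float))), dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f <= 0):
        return -np.inf
    r = y - f
    return float(
        -0.5 * np.sum(np.log(sigma2 * f**2)) - 0.5 * np.sum(r**2 / (sigma2 * f**2))
    )


def _in_region(eta: np.ndarray, region: np.ndarray) -> bool:
    return bool(np.all(eta >= region[:, 0]) and np.all(eta <= region[:, 1]))


def mh_step(
    eta: np.ndarray,
    log_post: Callable[[np.ndarray], float],
    proposal_chol: np.ndarray,
    region: np.ndarray,
    rng: np.random.Generator,
    current_lp: float | None = None,
) -> tuple[np.ndarray, float, bool]:
    """One random-walk Metropolis update of eta.

    The multinormal proposal is centered on the current point with a fixed
    covariance (Cholesky factor supplied); being symmetric, the Hastings
    correction cancels and the acceptance ratio uses posterior densities
    only.  Proposals outside the prior box D are rejected outright.
    Returns (new eta, its log-posterior, accepted flag).
    """
    if current_lp is None:
        current_lp = log_post(eta)
    if not np.isfinite(current_lp):
        raise FloatingPointError("non-finite log posterior at the current point")
    prop = eta + proposal_chol @ rng.standard_normal(len(eta))
    if not _in_region(prop, region):
        return eta, current_lp, False
    lp = log_post(prop)
    if np.log(rng.uniform()) < lp - current_lp:
        return prop, lp, True
    return eta, current_lp, False


def run_mh_chain(
    log_post: Callable[[np.ndarray], float],
    start: np.ndarray,
    proposal_cov: np.ndarray,
    region: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """A plain fixed-target MH chain (no sigma^2 Gibbs step).

    Used for oracle checks against analytic targets; returns the draw matrix
    and the acceptance rate.
    """
    eta = np.asarray(start, dtype=float).copy()
    chol = np.linalg.cholesky(np.asarray(proposal_cov, dtype=float))
    draws = np.empty((n_iter, len(eta)))
    lp = log_post(eta)
    accepted = 0
    for i in range(n_iter):
        eta, lp, acc = mh_step(eta, log_post, chol, region, rng, current_lp=lp)
        accepted += acc
        draws[i] = eta
    return draws, accepted / n_iter


def lattice_starts(region: np.ndarray, n_chains: int, rng: np.random.Generator) -> np.ndarray:
    """Chain starting points.

    For two parameters and nine chains: the four vertices of D, the four edge
    midpoints and the center (a 3x3 lattice).  Otherwise: uniform draws in D.
    """
    npar = region.shape[0]
    if npar == 2 and n_chains == 9:
        g0 = np.array([region[0, 0], (region[0, 0] + region[0, 1]) / 2, region[0, 1]])
        g1 = np.array([region[1, 0], (region[1, 0] + region[1, 1]) / 2, region[1, 1]])
        return np.array([[a, b] for a in g0 for b in g1])
    return rng.uniform(region[:, 0], region[:, 1], size=(n_chains, npar))


def run_chains(
    cfg: McmcConfig,
    y: np.ndarray,
    predict: Callable[[np.ndarray], np.ndarray],
    theta_opt: np.ndarray,
) -> ChainSet:
    """Full Metropolis-within-Gibbs run.

    Each iteration draws sigma^2 from its exact inverse-gamma full
    conditional at the current theta, then updates eta by one MH step.
    Chains use counter-based independent substreams of the master seed.
    """
    y = np.asarray(y, dtype=float)
    eta0 = np.log(np.asarray(theta_opt, dtype=float))
    region = cfg.prior_region(eta0)
    proposal_cov = np.diag(np.asarray(cfg.proposal_cvs, dtype=float) ** 2)
    chol = np.linalg.cholesky(proposal_cov)
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cfg.n_chains)
    starts = lattice_starts(region, cfg.n_chains, np.random.default_rng(master.spawn(1)[0]))

    npar = len(eta0)
    eta_draws = np.empty((cfg.n_chains, cfg.n_iter, npar))
    s2_draws = np.empty((cfg.n_chains, cfg.n_iter))
    acc_rates = np.empty(cfg.n_chains)

    for c in range(cfg.n_chains):
        rng = np.random.default_rng(streams[c])
        eta = starts[c].copy()
        sigma2 = cfg.sigma2_init
        f = np.asarray(predict(np.exp(eta)), dtype=float)
        accepted = 0
        for i in range(cfg.n_iter):
            sigma2 = sample_sigma2(y - f, f, cfg.nu, cfg.tau, rng)

            def log_post(e: np.ndarray) -> float:
                return model_log_posterior(e, sigma2, y, predict)

            eta, _, acc = mh_step(eta, log_post, chol, region, rng)
            if acc:
                f = np.asarray(predict(np.exp(eta)), dtype=float)
            accepted += acc
            eta_draws[c, i] = eta
            s2_draws[c, i] = sigma2
        acc_rates[c] = accepted / cfg.n_iter
        if cfg.n_iter > cfg.burn_in and accepted == 0:
            raise RuntimeError(
                f"chain {c} accepted no proposal; diagnostic failure "
                f"(start {starts[c]}, proposal CVs {list(cfg.proposal_cvs)})"
            )

    return ChainSet(
        eta=eta_draws, sigma2=s2_draws, acceptance=acc_rates,
        starts=starts, burn_in=cfg.burn_in,
        target_names=list(cfg.target_names),
    )


@dataclass
class CredibilityRegion:
    """Smallest 20x20-histogram superlevel set holding >= 95% of the draws."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    level: float
    selected: np.ndarray     # boolean mask over cells
    mass: float
    coverage: float = 0.95

    def cell_table(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.selected)
        freq = self.counts / self.counts.sum()
        return pd.DataFrame({"i": ii, "j": jj, "frequency": freq[ii, jj]})


def credibility_region(
    draws: np.ndarray,
    bins: int = 20,
    coverage: float = 0.95,
) -> CredibilityRegion:
    """Empirical credibility region from pooled bivariate draws.

    Builds a ``bins x bins`` frequency histogram on the draw bounding box and
    selects cells in order of decreasing frequency until the requested mass
    is reached (ties beyond the cut excluded), reporting the threshold level
    as the last included cell's frequency.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != 2:
        raise ValueError("draws must have shape (n, 2)")
    if len(draws) < 400:
        raise ValueError("need at least 400 draws for a 20x20 histogram")
    if np.ptp(draws[:, 0]) == 0 or np.ptp(draws[:, 1]) == 0:
        raise ValueError("degenerate draws: zero variance along an axis")
    counts, xe, ye = np.histogram2d(draws[:, 0], draws[:, 1], bins=bins)
    freq = counts / counts.sum()
    flat = freq.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, coverage) + 1)
    selected = np.zeros(flat.shape, dtype=bool)
    selected[order[:k]] = True
    level = float(flat[order[k - 1]])
    return CredibilityRegion(
        counts=counts, x_edges=xe, y_edges=ye, level=level,
        selected=selected.reshape(freq.shape), mass=float(csum[k - 1]),
        coverage=coverage,
    )
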