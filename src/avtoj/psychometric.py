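"""Cumulative-Gaussian psychometric model and its maximum-likelihood fit.

The probability of a "light first" judgment at SOA τ is modelled as
``P(τ) = Φ((τ − d) / σ)`` where ``d`` (ms) is the point of subjective
simultaneity (PSE; the SOA with P = 0.5) and ``σ`` (ms) the temporal
resolution.  Responses at each SOA are binomial, so the fit maximises the
binomial log-likelihood over ``(d, σ)``.  The optimiser is a coarse grid
followed by Nelder-Mead refinement from the best grid points, which is
robust for this well-conditioned 2-parameter surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BinnedResponses",
    "FitConfig",
    "PsychometricFit",
    "bin_responses",
    "curve",
    "neg_log_likelihood",
    "fit_psychometric",
    "bootstrap_ci",
]

#: floor/ceiling guard on predicted probabilities inside the likelihood
P_EPS = 1e-9


@dataclass(frozen=True)
class BinnedResponses:
    """Per-SOA trial and "light first" counts.

    ``tau`` ms (sorted, distinct), ``n`` trials, ``k`` light-first responses.
    """

    tau: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        n = np.asarray(self.n, dtype=int)
        k = np.asarray(self.k, dtype=int)
        if not (tau.shape == n.shape == k.shape) or tau.ndim != 1:
            raise ValueError("tau, n, k must be 1-D arrays of equal length")
        if len(np.unique(tau)) != len(tau):
            raise ValueError("SOA bins must be distinct")
        if np.count_nonzero(n > 0) < 2:
            raise ValueError("need at least 2 SOAs with trials")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("counts must satisfy 0 <= k <= n")
        order = np.argsort(tau)
        object.__setattr__(self, "tau", tau[order])
        object.__setattr__(self, "n", n[order])
        object.__setattr__(self, "k", k[order])

    @property
    def n_trials(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class FitConfig:
    d_bounds: tuple[float, float] = (-500.0, 500.0)
    sigma_bounds: tuple[float, float] = (1.0, 1000.0)
    grid_step: float = 25.0
    n_starts: int = 5
    tol: float = 1e-8


@dataclass(frozen=True)
class PsychometricFit:
    d: float
    sigma: float
    loglik: float
    converged: bool
    n_trials: int
    degenerate: bool = False
    ci: dict = field(default_factory=dict)


def bin_responses(dataset: pd.DataFrame, **selectors) -> BinnedResponses:
    """Bin test-phase responses of a trial table by SOA.

    ``selectors`` are equality filters on columns (e.g. ``pitch="low"`` or
    ``participant="p0"``).  Adaptation-phase rows are always excluded.
    """
    df = dataset
    for col, val in selectors.items():
        if col not in df.columns:
            raise KeyError(f"no column {col!r} in dataset")
        df = df[df[col] == val]
    if "phase" in df.columns:
        df = df[df["phase"] == "test"]
    if df.empty:
        raise ValueError(f"no test trials for group {selectors!r}")
    grouped = df.groupby("soa_ms")["response"]
    tau = np.array(sorted(df["soa_ms"].unique()), dtype=float)
    n = grouped.size().reindex(tau).to_numpy()
    k = grouped.apply(lambda r: int((r == "light_first").sum())).reindex(tau).to_numpy()
    return BinnedResponses(tau=tau, n=n, k=k)


def curve(tau, d: float, sigma: float):
    """P(light first | τ): Gaussian CDF with mean ``d`` and SD ``sigma``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return stats.norm.cdf(tau, loc=d, scale=sigma)


def neg_log_likelihood(d: float, sigma: float, binned: BinnedResponses) -> float:
    p = np.clip(curve(binned.tau, d, sigma), P_EPS, 1.0 - P_EPS)
    return float(-np.sum(binned.k * np.log(p) + (binned.n - binned.k) * np.log1p(-p)))


def _grid_nll(binned: BinnedResponses, d_grid: np.ndarray, sigma_grid: np.ndarray):
    """Vectorised NLL over a (d, sigma) grid; returns array [len(d), len(sigma)]."""
    z = (binned.tau[None, None, :] - d_grid[:, None, None]) / sigma_grid[None, :, None]
    p = np.clip(stats.norm.cdf(z), P_EPS, 1.0 - P_EPS)
    return -np.sum(
        binned.k[None, None, :] * np.log(p)
        + (binned.n - binned.k)[None, None, :] * np.log1p(-p),
        axis=2,
    )


def fit_psychometric(
    binned: BinnedResponses, config: FitConfig = FitConfig()
) -> PsychometricFit:
    """Maximum-likelihood fit of ``(d, σ)``.

    A coarse grid over the bounded box seeds ``n_starts`` Nelder-Mead
    refinements; the best refined point is returned.  All-zero or all-one
    response sets cannot pin σ, so they are flagged ``degenerate`` with σ at
    its bound rather than silently reported as converged.
    """
    lo_d, hi_d = config.d_bounds
    lo_s, hi_s = config.sigma_bounds
    d_grid = np.arange(lo_d, hi_d + 1e-9, config.grid_step)
    sigma_grid = np.arange(lo_s, hi_s + 1e-9, config.grid_step)
    nll = _grid_nll(binned, d_grid, sigma_grid)

    flat = np.argsort(nll, axis=None)[: config.n_starts]
    starts = [(d_grid[i // len(sigma_grid)], sigma_grid[i % len(sigma_grid)])
              for i in flat]

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            lambda x: neg_log_likelihood(x[0], x[1], binned),
            x0=np.array(x0),
            method="Nelder-Mead",
            bounds=[config.d_bounds, config.sigma_bounds],
            options={"fatol": config.tol, "xatol": 1e-6, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)

    degenerate = bool(
        np.all(binned.k == 0)
        or np.all(binned.k == binned.n)
        or best.x[1] <= lo_s + 1e-6
        or best.x[1] >= hi_s - 1e-6
    )
    return PsychometricFit(
        d=float(best.x[0]),
        sigma=float(best.x[1]),
        loglik=-float(best.fun),
        converged=bool(any_converged and not degenerate),
        n_trials=binned.n_trials,
        degenerate=degenerate,
    )


def bootstrap_ci(
    binned: BinnedResponses,
    config: FitConfig = FitConfig(),
    n_boot: int = 1000,
    level: float = 0.95,
    seed=0,
) -> dict:
    """Nonparametric bootstrap percentile CI for (d, σ).

    Resamples responses within each SOA bin (binomial resampling of the
    observed proportion), refits, and returns percentile intervals.
    """
    rng = np.random.default_rng(seed)
    phat = binned.k / np.maximum(binned.n, 1)
    draws = np.empty((n_boot, 2))
    for b in range(n_boot):
        kb = rng.binomial(binned.n, phat)
        fit = fit_psychometric(BinnedResponses(binned.tau, binned.n, kb), config)
        draws[b] = (fit.d, fit.sigma)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    d_lo, d_hi = np.percentile(draws[:, 0], [lo, hi])
    s_lo, s_hi = np.percentile(draws[:, 1], [lo, hi])
    return {"d": (float(d_lo), float(d_hi)), "sigma": (float(s_lo), float(s_hi)),
            "level": level, "n_boot": n_boot}
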