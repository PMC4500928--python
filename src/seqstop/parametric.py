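"""Parametric recovery: maximum-likelihood ex-Gaussian fits.

The Stop (or Go) latency is modeled as an ex-Gaussian with the signed
tau convention.  For last-press data the model density is the ex-Gauss
convolved with the reflected gap distribution X; for first-press (GoRT)
data X is a point mass at zero and the fit is direct.  Likelihoods are
binned on the standard 4 ms grid, mixed with a 1% lapse rate spread
evenly over all bins so that no observed bin has zero probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .gap import GapDistribution, mean_x
from .grid import (
    BIN_WIDTH_MS,
    GRID_START_MS,
    N_BINS,
    BinnedDensity,
    bin_edges,
)
from .simulate import ExGaussParams

#: Fraction of probability spread evenly over all bins during fitting.
LAPSE_RATE = 0.01

_MIN_SIGMA_S = 1e-3  # fits collapsing below 1 ms Gaussian SD are degenerate
_TAU_GAUSS_S = 1e-6  # |tau| below this is treated as a pure Gaussian


def exgauss_cdf_ms(params: ExGaussParams, t_ms: np.ndarray) -> np.ndarray:
    """Ex-Gaussian CDF (signed-tau convention) evaluated at times in ms."""
    mu, sigma, tau = 1000.0 * params.mu, 1000.0 * params.sigma, 1000.0 * params.tau
    t_ms = np.asarray(t_ms, dtype=float)
    if abs(tau) < 1000.0 * _TAU_GAUSS_S:
        return stats.norm.cdf(t_ms, loc=mu, scale=sigma)
    if tau > 0:
        return stats.exponnorm.cdf(t_ms, K=tau / sigma, loc=mu, scale=sigma)
    # Y = N(mu, sigma) - Exp(|tau|)  =>  -Y ~ exponnorm(|tau|/sigma, -mu, sigma)
    return stats.exponnorm.sf(-t_ms, K=-tau / sigma, loc=-mu, scale=sigma)


def exgauss_binned_density(params: ExGaussParams, warn_offgrid: bool = True) -> BinnedDensity:
    """Ex-Gaussian probability mass integrated over each 4 ms bin.

    The result is renormalized on the grid; if more than 1% of the mass
    falls off-grid a warning is emitted.
    """
    cdf = exgauss_cdf_ms(params, bin_edges())
    probs = np.diff(cdf)
    on_grid = probs.sum()
    if warn_offgrid and on_grid < 0.99:
        warnings.warn(
            f"{100 * (1 - on_grid):.1f}% of ex-Gaussian mass falls off-grid",
            stacklevel=2,
        )
    if on_grid <= 0:
        raise ValueError("ex-Gaussian has no mass on the analysis grid")
    return BinnedDensity(probs / on_grid)


def convolved_model_density(params: ExGaussParams, x: GapDistribution) -> np.ndarray:
    """Model bin probabilities: (ex-Gauss * reflected X), mixed with lapse."""
    from .deconvolve import convolve_gap

    base = convolve_gap(exgauss_binned_density(params, warn_offgrid=False), x).probs
    base = np.clip(base, 0.0, None)
    base /= base.sum()
    return (1.0 - LAPSE_RATE) * base + LAPSE_RATE / N_BINS


def _bin_indices(samples_ms: np.ndarray) -> np.ndarray:
    idx = np.floor((np.asarray(samples_ms, dtype=float) - GRID_START_MS) / BIN_WIDTH_MS)
    return idx.astype(int)


def convolved_negloglik(
    params: ExGaussParams, tn_samples_ms: np.ndarray, x: GapDistribution
) -> float:
    """Negative log-likelihood of binned samples under the convolved model.

    Samples outside the grid contribute the lapse floor only.
    """
    model = convolved_model_density(params, x)
    idx = _bin_indices(tn_samples_ms)
    inside = (idx >= 0) & (idx < N_BINS)
    ll = np.sum(np.log(model[idx[inside]]))
    ll += np.sum(~inside) * np.log(LAPSE_RATE / N_BINS)
    return float(-ll)


@dataclass
class FitResult:
    """Outcome of an ex-Gaussian maximum-likelihood fit."""

    params: ExGaussParams
    log_likelihood: float
    converged: bool
    n_obs: int

    @property
    def mean_ms(self) -> float:
        return self.params.mean_ms

    @property
    def sd_ms(self) -> float:
        return self.params.sd_ms

    @property
    def skew(self) -> float:
        return self.params.skew

    def summary_dict(self) -> dict:
        return {
            "mu_s": self.params.mu,
            "sigma_s": self.params.sigma,
            "tau_s": self.params.tau,
            "mean_ms": self.mean_ms,
            "sd_ms": self.sd_ms,
            "skew": self.skew,
            "loglik": self.log_likelihood,
            "converged": self.converged,
        }


def _moment_init(samples_ms: np.ndarray, x: GapDistribution) -> ExGaussParams:
    """Method-of-moments start values from the de-gapped sample."""
    shifted = np.asarray(samples_ms, dtype=float) + mean_x(x)
    m = float(np.mean(shifted)) / 1000.0
    sd = max(float(np.std(shifted)), 2.0) / 1000.0
    g = float(stats.skew(shifted)) if shifted.size > 2 else 0.0
    if not np.isfinite(g):  # constant samples have undefined skew
        g = 0.0
    g = float(np.clip(g, -1.8, 1.8))
    tau = np.sign(g) * sd * (abs(g) / 2.0) ** (1.0 / 3.0)
    sigma_sq = sd**2 - tau**2
    if sigma_sq < (0.2 * sd) ** 2:
        sigma_sq = (0.2 * sd) ** 2
    return ExGaussParams(mu=m - tau, sigma=float(np.sqrt(sigma_sq)), tau=float(tau))


def fit_exgauss_convolved(
    tn_samples_ms: np.ndarray,
    x: GapDistribution,
    init: ExGaussParams | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    optimizer_options: dict | None = None,
) -> FitResult:
    """Fit the convolved ex-Gaussian to last-press times by maximum likelihood.

    Derivative-free simplex (Nelder-Mead) with jittered restarts; tau is
    a signed real so both skew directions are reachable.  Non-convergence
    is flagged on the result, never raised.
    """
    tn_samples_ms = np.asarray(tn_samples_ms, dtype=float)
    if tn_samples_ms.size < 50:
        warnings.warn(
            f"fitting {tn_samples_ms.size} samples; at least 50 are recommended",
            stacklevel=2,
        )
    if init is None:
        init = _moment_init(tn_samples_ms, x)
    rng = np.random.default_rng(seed)
    options = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000}
    if optimizer_options:
        options.update(optimizer_options)

    def objective(theta: np.ndarray) -> float:
        mu, sigma, tau = theta
        if sigma < _MIN_SIGMA_S / 2:
            return 1e12
        return convolved_negloglik(ExGaussParams(mu, sigma, tau), tn_samples_ms, x)

    x0 = np.array([init.mu, init.sigma, init.tau])
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        jitter = rng.normal(0, [0.01, 0.25 * init.sigma, 0.01])
        cand = x0 + jitter
        cand[1] = max(cand[1], _MIN_SIGMA_S)
        starts.append(cand)

    best = None
    success = False
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead", options=options)
        if best is None or res.fun < best.fun:
            best = res
            success = bool(res.success)
    mu, sigma, tau = best.x
    converged = success and sigma > _MIN_SIGMA_S and np.isfinite(best.fun)
    return FitResult(
        params=ExGaussParams(float(mu), float(max(sigma, _MIN_SIGMA_S)), float(tau)),
        log_likelihood=float(-best.fun),
        converged=converged,
        n_obs=int(tn_samples_ms.size),
    )


def fit_exgauss_direct(
    samples_ms: np.ndarray,
    init: ExGaussParams | None = None,
    **kwargs,
) -> FitResult:
    """Fit an ex-Gaussian directly (identity gap kernel), e.g. to GoRT."""
    return fit_exgauss_convolved(
        samples_ms, GapDistribution.point_mass(0.0), init=init, **kwargs
    )
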