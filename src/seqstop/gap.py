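"""Estimators of the gap distribution X = S - T_N.

X is the unobservable time between the last executed press and the
moment the Stop process terminates.  Because the stop time falls at an
effectively uniform position within an ongoing press sequence, X is the
backward-recurrence ("age") time of the inter-press renewal process.
Two estimators are provided:

* virtual stop — replay each trial against simulated stop times S'
  placed before the real stop signal and measure X' = S' - T_M directly;
* IRI integral — derive the density of X from the density of the
  inter-response intervals Delta.

For the integral route, the interval that contains the stop time is a
length-biased draw from the IRI distribution (longer intervals are more
likely to contain it), and X is uniform on that interval.  The default
``weighting="interval"`` applies this inspection-paradox correction,
which makes the two estimators agree and gives
E[X] = E[Delta^2] / (2 E[Delta]).  ``weighting="raw"`` drops the
correction (integrating f_Delta(u)/u directly, E[X] = E[Delta]/2) and is
retained for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import BIN_WIDTH_MS, BinnedDensity, bin_density
from .trials import TrialSet


@dataclass
class GapDistribution:
    """Distribution of the gap X on a grid of nonnegative lags (ms).

    ``lags`` are the support points (bin centers of the 4 ms lag grid in
    the estimated case; arbitrary points for analytic constructions such
    as point masses); ``probs`` are the probabilities, summing to one.
    """

    lags: np.ndarray
    probs: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.lags = np.atleast_1d(np.asarray(self.lags, dtype=float))
        self.probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        if self.lags.shape != self.probs.shape:
            raise ValueError("lags and probs must have the same shape")
        if np.any(self.probs < -1e-12):
            raise ValueError("gap probabilities must be nonnegative")
        if np.any(self.lags < 0):
            raise ValueError("gap lags must be nonnegative")
        total = self.probs.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"gap probabilities must sum to 1, got {total}")
        self.probs = np.clip(self.probs, 0.0, None) / self.probs.sum()

    @classmethod
    def point_mass(cls, lag_ms: float = 0.0) -> "GapDistribution":
        """Degenerate gap (identity deconvolution kernel at ``lag_ms``)."""
        return cls(lags=np.array([lag_ms]), probs=np.array([1.0]), source="point_mass")

    @classmethod
    def from_binned(cls, density: BinnedDensity, source: str) -> "GapDistribution":
        keep = density.centers >= 0
        probs = density.probs[keep]
        return cls(lags=density.centers[keep], probs=probs / probs.sum(), source=source)

    def mean(self) -> float:
        return float(np.sum(self.probs * self.lags))

    def cdf_at(self, t: np.ndarray) -> np.ndarray:
        """P(X <= t) from the discrete representation."""
        t = np.asarray(t, dtype=float)
        order = np.argsort(self.lags)
        lags, probs = self.lags[order], np.cumsum(self.probs[order])
        idx = np.searchsorted(lags, t, side="right")
        out = np.where(idx > 0, probs[np.minimum(idx, lags.size) - 1], 0.0)
        return np.where(idx == 0, 0.0, out)

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw n gaps (ms)."""
        rng = np.random.default_rng(rng)
        return rng.choice(self.lags, size=n, p=self.probs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_ms": self.lags, "density": self.probs})


def default_s_prime_grid() -> np.ndarray:
    """Simulated stop times: every 4 ms from -1000 to 0 ms (rel. stop)."""
    return np.arange(-1000.0, 0.0 + 0.5 * BIN_WIDTH_MS, BIN_WIDTH_MS)


def estimate_x_virtual_stop(
    trial_set: TrialSet,
    s_prime_grid: np.ndarray | None = None,
    min_after_first_press_ms: float = 500.0,
) -> GapDistribution:
    """Estimate X by replaying trials against simulated stop times.

    For each trial and each simulated stop time S' (relative to the stop
    signal, all <= 0 so the real Stop process cannot have censored
    anything), the gap X' = S' - T_M is recorded, where T_M is the last
    press at or before S'.  S' values closer than
    ``min_after_first_press_ms`` to the first press are skipped so that
    the pressing routine has reached a steady state.  All admissible
    (trial, S') pairs are pooled with equal weight and binned on the 4 ms
    lag grid.
    """
    if s_prime_grid is None:
        s_prime_grid = default_s_prime_grid()
    s_prime_grid = np.asarray(s_prime_grid, dtype=float)
    if np.any(s_prime_grid > 0):
        raise ValueError("S' values must lie at or before the stop signal (<= 0)")

    gaps = []
    for trial in trial_set:
        if trial.n_presses == 0:
            continue
        presses = trial.press_times_stop
        admissible = s_prime_grid >= presses[0] + min_after_first_press_ms
        s_primes = s_prime_grid[admissible]
        if s_primes.size == 0:
            continue
        # index of last press at or before each S'
        idx = np.searchsorted(presses, s_primes, side="right") - 1
        ok = idx >= 0
        if not np.any(ok):
            continue
        gaps.append(s_primes[ok] - presses[idx[ok]])
    if not gaps:
        raise ValueError("no admissible (trial, S') pair; cannot estimate X")
    pooled = np.concatenate(gaps)
    return GapDistribution.from_binned(bin_density(pooled), source="virtual_stop")


def estimate_x_from_iri(
    iri_density: BinnedDensity, weighting: str = "interval"
) -> GapDistribution:
    """Estimate X by integrating over the binned IRI density.

    Given that the stop time lands in an interval of length u, X is
    uniform on [0, u].  With ``weighting="interval"`` the containing
    interval is taken as a length-biased draw (probability proportional
    to u * f_Delta(u)); the resulting bin masses are proportional to
    ``sum_j p_j * |[a, a+4) ∩ [0, u_j)|``, the stationary-renewal age
    distribution.  ``weighting="raw"`` uses f_Delta(u)/u directly.

    Raises
    ------
    ValueError
        If the IRI density has mass at nonpositive lags.
    """
    p = iri_density.probs
    u = iri_density.centers
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("IRI density must be nonnegative and sum to 1")
    if np.any(p[u <= 0] > 0):
        raise ValueError("IRI density has mass at nonpositive intervals")
    if weighting not in ("interval", "raw"):
        raise ValueError(f"unknown weighting {weighting!r}")

    pos = p > 0
    p_pos, u_pos = p[pos], u[pos]
    max_u = float(u_pos.max())
    n_lag_bins = int(np.ceil(max_u / BIN_WIDTH_MS))
    lo = BIN_WIDTH_MS * np.arange(n_lag_bins)          # lag-bin left edges
    hi = lo + BIN_WIDTH_MS
    # overlap of [lo_i, hi_i) with [0, u_j): shape (n_lag_bins, n_u)
    overlap = np.clip(np.minimum(hi[:, None], u_pos[None, :]) - lo[:, None], 0.0, None)
    if weighting == "interval":
        mass = overlap @ p_pos
    else:
        mass = overlap @ (p_pos / u_pos)
    mass /= mass.sum()
    return GapDistribution(
        lags=lo + 0.5 * BIN_WIDTH_MS, probs=mass, source="iri_integral"
    )


def mean_x(x: GapDistribution) -> float:
    """Mean gap E[X] (ms) on the lag grid."""
    return x.mean()
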