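"""Fixed analysis grid and binned-density primitives.

All densities in this package live on a single fixed grid of 300
four-millisecond bins covering -400 to +800 ms.  Bins are half-open
``[t, t + 4)``; bin centers sit at the bin midpoints.  The wide grid
leaves >= 400 ms guard bands on either side of the physiologically
relevant support ([90, 550] ms), which keeps the circular FFT
convolutions used elsewhere free of wrap-around artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BINS: int = 300
BIN_WIDTH_MS: float = 4.0
GRID_START_MS: float = -400.0
GRID_STOP_MS: float = 800.0

#: Default SD of the Gaussian smoothing kernel applied to observed
#: last-press densities before deconvolution (ms).
DEFAULT_KERNEL_SD_MS: float = 16.0

#: Physiological support enforced on recovered latency densities (ms).
SUPPORT_LOW_MS: float = 90.0
SUPPORT_HIGH_MS: float = 550.0


def bin_edges() -> np.ndarray:
    """Return the 301 bin edges of the standard grid (ms)."""
    return GRID_START_MS + BIN_WIDTH_MS * np.arange(N_BINS + 1)


def bin_centers() -> np.ndarray:
    """Return the 300 bin centers of the standard grid (ms)."""
    return GRID_START_MS + BIN_WIDTH_MS * (np.arange(N_BINS) + 0.5)


@dataclass
class BinnedDensity:
    """A probability vector on the standard 300-bin, 4 ms grid.

    Parameters
    ----------
    probs : ndarray, shape (300,)
        Probability mass per bin.  Normally nonnegative and summing to
        one; intermediate (raw) stages of the deconvolution relax this.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_BINS,):
            raise ValueError(
                f"expected {N_BINS} bin probabilities, got shape {self.probs.shape}"
            )

    @property
    def centers(self) -> np.ndarray:
        return bin_centers()

    @property
    def edges(self) -> np.ndarray:
        return bin_edges()

    def cdf(self) -> np.ndarray:
        """Cumulative mass evaluated at the right edge of each bin."""
        return np.cumsum(self.probs)

    def normalized(self) -> "BinnedDensity":
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("cannot normalize a density with nonpositive mass")
        return BinnedDensity(self.probs / total)

    def mean(self) -> float:
        return float(np.sum(self.probs * self.centers) / self.probs.sum())

    def copy(self) -> "BinnedDensity":
        return BinnedDensity(self.probs.copy())


@dataclass
class Moments:
    """Grid-weighted mean, SD and standardized skew of a binned density."""

    mean_ms: float
    sd_ms: float
    skew: float
    degenerate: bool = field(default=False)

    def __iter__(self):
        return iter((self.mean_ms, self.sd_ms, self.skew))


def bin_density(samples_ms: np.ndarray) -> BinnedDensity:
    """Histogram samples onto the standard grid and normalize to sum 1.

    Samples outside [-400, 800) are excluded; their count is reported via
    the returned density's ``overflow`` attribute.

    Raises
    ------
    ValueError
        If the sample is empty or no sample falls on the grid.
    """
    samples_ms = np.asarray(samples_ms, dtype=float)
    if samples_ms.size == 0:
        raise ValueError("cannot bin an empty sample")
    counts, _ = np.histogram(samples_ms, bins=bin_edges())
    overflow = int(samples_ms.size - counts.sum())
    if counts.sum() == 0:
        raise ValueError("all samples fall outside the analysis grid")
    d = BinnedDensity(counts / counts.sum())
    d.overflow = overflow  # type: ignore[attr-defined]
    return d


def gaussian_kernel(sd_ms: float, truncate_sd: float = 5.0) -> np.ndarray:
    """Discrete Gaussian kernel on the 4 ms grid, truncated at +/- 5 SD
    and renormalized so that convolution conserves mass."""
    if sd_ms <= 0:
        raise ValueError("kernel SD must be positive")
    half = int(np.ceil(truncate_sd * sd_ms / BIN_WIDTH_MS))
    lags = BIN_WIDTH_MS * np.arange(-half, half + 1)
    k = np.exp(-0.5 * (lags / sd_ms) ** 2)
    return k / k.sum()


def smooth_density(
    d: BinnedDensity, kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS
) -> BinnedDensity:
    """Convolve a binned density with a Gaussian kernel (default SD 16 ms).

    Mass is conserved to ~1e-9 for densities whose support keeps clear of
    the grid edges by the truncated kernel half-width (80 ms at default).
    """
    if kernel_sd_ms == 0:
        return d.copy()
    k = gaussian_kernel(kernel_sd_ms)
    return BinnedDensity(np.convolve(d.probs, k, mode="same"))


def moments(d: BinnedDensity) -> Moments:
    """Mean, SD and standardized third central moment of a binned density.

    A degenerate (single-bin) density has undefined skew; it is reported
    as 0.0 with ``degenerate=True``.
    """
    p = d.probs / d.probs.sum()
    c = d.centers
    m = float(np.sum(p * c))
    var = float(np.sum(p * (c - m) ** 2))
    sd = float(np.sqrt(var))
    if sd < 1e-12:
        return Moments(mean_ms=m, sd_ms=0.0, skew=0.0, degenerate=True)
    skew = float(np.sum(p * (c - m) ** 3) / sd**3)
    return Moments(mean_ms=m, sd_ms=sd, skew=skew)


def correct_sd(sd_smoothed_ms: float, kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS) -> float:
    """Remove the smoothing-kernel contribution from a recovered SD.

    Convolution with a Gaussian of SD ``k`` inflates variance by ``k**2``;
    the underlying SD is ``sqrt(sd**2 - k**2)``.
    """
    if sd_smoothed_ms < kernel_sd_ms:
        raise ValueError(
            "smoothed SD is smaller than the kernel SD; corrected SD undefined"
        )
    return float(np.sqrt(sd_smoothed_ms**2 - kernel_sd_ms**2))
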