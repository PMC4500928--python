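"""Fourier deconvolution of the gap X from observed last-press times.

Under independence of the Stop latency S and the press process, the
observed last-press time satisfies T_N = S - X, so the density of T_N is
the convolution of the density of S with the density of -X.  The Stop
density is recovered by dividing spectra on the fixed 4 ms grid and
post-processing the raw inverse transform into a proper density.

The observed T_N density is smoothed (16 ms Gaussian) before the
division, so the recovered density is the smoothed Stop density: its
mean is unaffected, its SD can be corrected exactly
(:func:`seqstop.grid.correct_sd`), and its skew is attenuated toward
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gap import GapDistribution
from .grid import (
    BIN_WIDTH_MS,
    DEFAULT_KERNEL_SD_MS,
    N_BINS,
    SUPPORT_HIGH_MS,
    SUPPORT_LOW_MS,
    BinnedDensity,
    correct_sd,
    moments,
)

#: Frequency bands where the gap spectrum magnitude falls below this
#: fraction of its maximum are not divided (set to zero).  The gap kernel
#: has a broad power spectrum, so this is a numerical guard only.
SPECTRUM_FLOOR = 1e-8

#: A zeroed band is reported as lossy only if the observed spectrum
#: holds at least this fraction of its peak magnitude there; smaller
#: residues (e.g. truncation leftovers of the smoothing kernel) are
#: irrelevant to the recovered density.
SIGNAL_FLOOR = 1e-6


def _gap_kernel(x: GapDistribution) -> np.ndarray:
    """Circular kernel of the reflected gap on the 4 ms lattice.

    Each gap mass at lag u is split linearly between the two adjacent
    integer bin shifts, which represents arbitrary lags exactly in mean
    and keeps a point mass at 0 an exact identity kernel.
    """
    k = np.zeros(N_BINS)
    shifts = x.lags / BIN_WIDTH_MS
    q = np.floor(shifts).astype(int)
    r = shifts - q
    for qi, ri, p in zip(q, r, x.probs):
        k[(-qi) % N_BINS] += p * (1.0 - ri)
        k[(-qi - 1) % N_BINS] += p * ri
    return k


def convolve_gap(latent: BinnedDensity, x: GapDistribution) -> BinnedDensity:
    """Forward model: density of latent - X on the standard grid."""
    spec = np.fft.fft(latent.probs) * np.fft.fft(_gap_kernel(x))
    return BinnedDensity(np.fft.ifft(spec).real)


def deconvolve(tn_density: BinnedDensity, x: GapDistribution) -> np.ndarray:
    """Divide out the gap spectrum; return the raw complex density.

    Parameters
    ----------
    tn_density : BinnedDensity
        Observed (smoothed) last-press density.
    x : GapDistribution
        Gap distribution; must sum to one.

    Returns
    -------
    ndarray of complex, shape (300,)
        Raw inverse transform, before post-processing.
    """
    kernel_spec = np.fft.fft(_gap_kernel(x))
    obs_spec = np.fft.fft(tn_density.probs)
    floor = SPECTRUM_FLOOR * np.abs(kernel_spec).max()
    weak = np.abs(kernel_spec) < floor
    # warn only if the observed signal actually carries power in a zeroed
    # band; with the standard pre-smoothing those bands hold no signal
    obs_floor = SIGNAL_FLOOR * np.abs(obs_spec).max()
    lossy = weak & (np.abs(obs_spec) > obs_floor)
    if np.any(lossy):
        warnings.warn(
            f"{int(lossy.sum())} frequency bands with observed signal fell "
            "below the regularization floor and were zeroed",
            stacklevel=2,
        )
    latent_spec = np.zeros_like(obs_spec)
    latent_spec[~weak] = obs_spec[~weak] / kernel_spec[~weak]
    return np.fft.ifft(latent_spec)


@dataclass
class RecoveryResult:
    """Finalized recovered density plus its summary statistics.

    ``lower_bound_ms`` is the clipping time found from the raw
    distribution function (None when no negative excursion occurred).
    ``sd_corrected_ms`` removes the 16 ms smoothing-kernel variance.
    """

    density: BinnedDensity
    lower_bound_ms: float | None
    mean_ms: float
    sd_ms: float
    sd_corrected_ms: float | None
    skew: float

    def cdf(self) -> np.ndarray:
        return self.density.cdf()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_ms": self.density.centers, "density": self.density.probs}
        )

    def summary_dict(self) -> dict:
        return {
            "mean_ms": self.mean_ms,
            "sd_ms": self.sd_ms,
            "sd_corrected_ms": self.sd_corrected_ms,
            "skew": self.skew,
            "lower_bound_ms": self.lower_bound_ms,
        }


def postprocess(
    raw: np.ndarray,
    kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS,
    support_ms: tuple[float, float] = (SUPPORT_LOW_MS, SUPPORT_HIGH_MS),
) -> RecoveryResult:
    """Turn the raw complex deconvolution into a proper density.

    Applied in order:

    1. the imaginary component is set to zero;
    2. the raw density is integrated to a raw distribution function and
       the lower bound is defined as the latest time at which that
       function is negative (ripples at the left tail);
    3. all density values at or below the lower-bound time are zeroed;
    4. residual negative density values above it are zeroed;
    5. independently, density outside the physiological support
       (default [90, 550] ms) is zeroed;
    6. the result is normalized to a sum of one.

    Raises
    ------
    ValueError
        If nothing remains after clipping.
    """
    raw = np.asarray(raw)
    density = raw.real.astype(float).copy()
    d = BinnedDensity(density)
    centers = d.centers

    raw_cdf = np.cumsum(density)
    neg = np.nonzero(raw_cdf < 0)[0]
    lower_bound: float | None = None
    if neg.size:
        lower_bound = float(centers[neg[-1]])
        density[centers <= lower_bound] = 0.0
    density[density < 0] = 0.0
    lo, hi = support_ms
    density[(centers < lo) | (centers > hi)] = 0.0
    total = density.sum()
    if total <= 0:
        raise ValueError("recovery failed: no density remains after clipping")
    density /= total

    final = BinnedDensity(density)
    m = moments(final)
    sd_corrected = None
    if m.sd_ms >= kernel_sd_ms:
        sd_corrected = correct_sd(m.sd_ms, kernel_sd_ms)
    return RecoveryResult(
        density=final,
        lower_bound_ms=lower_bound,
        mean_ms=m.mean_ms,
        sd_ms=m.sd_ms,
        sd_corrected_ms=sd_corrected,
        skew=m.skew,
    )


def recover_distribution(
    samples_ms: np.ndarray,
    x: GapDistribution,
    kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS,
) -> RecoveryResult:
    """Full non-parametric pipeline: bin, smooth, deconvolve, post-process."""
    from .grid import bin_density, smooth_density

    tn = smooth_density(bin_density(samples_ms), kernel_sd_ms)
    return postprocess(deconvolve(tn, x), kernel_sd_ms=kernel_sd_ms)
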