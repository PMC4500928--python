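"""Distribution-free summaries and behavioral analyses.

Covers the simple (deconvolution-free) mean-SSRT estimator, z-score
normalization and Vincent averaging of recovered distributions, robust
quantile-based skew, the KS statistic, inter-response-interval (IRI)
profiles and cross-correlations, and GoRT/SSRT trend analyses over the
course of an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gap import GapDistribution, mean_x
from .grid import BinnedDensity, moments
from .trials import TrialSet

#: Fixed z-grid for shape comparisons: -8 to 8 SD in steps of 0.1.
Z_GRID = np.round(np.arange(-80, 81) * 0.1, 10)

#: Probability sequence used for Vincent (quantile) averaging.
VINCENT_PROBS = np.arange(1, 1000) / 1000.0


def mean_ssrt_simple(trial_set: TrialSet, x: GapDistribution) -> float:
    """Mean Stop latency without deconvolution: E[S] = E[T_N] + E[X].

    Reliable from as few as ~75 trials; used by the trend analyses where
    a full distribution per bin would be too noisy.
    """
    tns = trial_set.last_presses_rel_stop()
    if tns.size == 0:
        raise ValueError("no trial has a defined last press")
    return float(np.mean(tns) + mean_x(x))


@dataclass
class NormalizedDistribution:
    """A density or distribution function on the fixed z-score grid."""

    values: np.ndarray
    kind: str  # "density" | "cdf"
    source_mean_ms: float
    source_sd_ms: float

    @property
    def z_grid(self) -> np.ndarray:
        return Z_GRID


def normalize_distribution(
    d: BinnedDensity, kind: str = "density"
) -> NormalizedDistribution:
    """Relabel a binned density's time axis to z-scores and interpolate
    onto the fixed z-grid.

    The bin labels are transformed as z = (t - mean) / SD and the bin
    values (probabilities, or their cumulative sum for ``kind="cdf"``)
    are linearly interpolated onto the grid from -8 to 8 in steps of 0.1.
    """
    m = moments(d)
    if m.sd_ms <= 0:
        raise ValueError("cannot normalize a zero-SD density")
    z_src = (d.centers - m.mean_ms) / m.sd_ms
    if kind == "density":
        vals = np.interp(Z_GRID, z_src, d.probs, left=0.0, right=0.0)
    elif kind == "cdf":
        vals = np.interp(Z_GRID, z_src, d.cdf(), left=0.0, right=1.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return NormalizedDistribution(
        values=vals, kind=kind, source_mean_ms=m.mean_ms, source_sd_ms=m.sd_ms
    )


def vincent_average(
    distributions: list[NormalizedDistribution],
) -> NormalizedDistribution:
    """Average distribution functions by averaging their quantiles.

    For each probability p in 0.001 ... 0.999 (step 0.001) the quantile
    of each input CDF is found by linear interpolation; the mean of these
    quantiles defines the average distribution function, which is then
    interpolated back onto the default z-grid.
    """
    if not distributions:
        raise ValueError("need at least one distribution")
    if any(nd.kind != "cdf" for nd in distributions):
        raise ValueError("Vincent averaging operates on CDF-form distributions")
    quantiles = np.zeros((len(distributions), VINCENT_PROBS.size))
    for i, nd in enumerate(distributions):
        cdf = nd.values
        if np.any(np.diff(cdf) < -1e-9):
            raise ValueError("input CDF is non-monotone")
        # strictify flat stretches so interpolation is well defined
        cdf_mono = cdf + 1e-12 * np.arange(cdf.size)
        quantiles[i] = np.interp(VINCENT_PROBS, cdf_mono, Z_GRID)
    avg_q = quantiles.mean(axis=0)
    vals = np.interp(Z_GRID, avg_q, VINCENT_PROBS, left=0.0, right=1.0)
    return NormalizedDistribution(
        values=vals,
        kind="cdf",
        source_mean_ms=float(np.mean([nd.source_mean_ms for nd in distributions])),
        source_sd_ms=float(np.mean([nd.source_sd_ms for nd in distributions])),
    )


def denormalize(
    nd: NormalizedDistribution, means_ms, variances_ms2
) -> tuple[np.ndarray, np.ndarray]:
    """Map a normalized curve back onto the millisecond axis.

    The z-axis is rescaled by the square root of the mean of the
    individual variances, then shifted by the mean of the individual
    means.  Returns (time_axis_ms, values).
    """
    means_ms = np.asarray(means_ms, dtype=float)
    variances_ms2 = np.asarray(variances_ms2, dtype=float)
    if means_ms.size == 0 or variances_ms2.size == 0:
        raise ValueError("means and variances must be non-empty")
    axis = Z_GRID * float(np.sqrt(variances_ms2.mean())) + float(means_ms.mean())
    return axis, nd.values.copy()


def _quantile(grid: np.ndarray, cdf: np.ndarray, p: float) -> float:
    cdf_mono = cdf + 1e-12 * np.arange(cdf.size)
    return float(np.interp(p, cdf_mono, grid))


def robust_skew(grid: np.ndarray, cdf: np.ndarray, u: float = 0.25) -> float:
    """Quantile-based (Bowley-type) skewness of a distribution function.

    ``(Q(u) + Q(1-u) - 2 Q(0.5)) / (Q(1-u) - Q(u))``, with quantiles by
    linear interpolation of the CDF.  ``u = 0.1`` gives Kelley's absolute
    measure of skewness.
    """
    if not 0 < u < 0.5:
        raise ValueError("u must lie strictly between 0 and 0.5")
    grid = np.asarray(grid, dtype=float)
    cdf = np.asarray(cdf, dtype=float)
    q_lo = _quantile(grid, cdf, u)
    q_hi = _quantile(grid, cdf, 1.0 - u)
    q_med = _quantile(grid, cdf, 0.5)
    spread = q_hi - q_lo
    if spread <= 1e-12:
        raise ValueError("degenerate distribution: zero inter-quantile spread")
    return (q_lo + q_hi - 2.0 * q_med) / spread


def ks_statistic(
    cdf1: np.ndarray,
    cdf2: np.ndarray,
    grid1: np.ndarray | None = None,
    grid2: np.ndarray | None = None,
) -> float:
    """Maximum absolute difference between two distribution functions.

    With no grids the CDFs are assumed to share a common grid; otherwise
    each is interpolated onto the union of the two grids first.
    """
    cdf1 = np.asarray(cdf1, dtype=float)
    cdf2 = np.asarray(cdf2, dtype=float)
    if grid1 is not None or grid2 is not None:
        if grid1 is None or grid2 is None:
            raise ValueError("provide both grids or neither")
        common = np.union1d(grid1, grid2)
        cdf1 = np.interp(common, grid1, cdf1, left=0.0, right=1.0)
        cdf2 = np.interp(common, grid2, cdf2, left=0.0, right=1.0)
    elif cdf1.shape != cdf2.shape:
        raise ValueError("CDFs without grids must share a common grid")
    return float(np.max(np.abs(cdf1 - cdf2)))


@dataclass
class IriProfile:
    """Mean IRI per ordinal press position under a chosen alignment."""

    positions: np.ndarray
    mean_iri_ms: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean_iri_ms": self.mean_iri_ms, "n": self.n}
        )


def iri_profile(
    trial_set: TrialSet,
    align: str = "first",
    event_times_go: np.ndarray | None = None,
    max_positions: int = 40,
) -> IriProfile:
    """Mean IRI as a function of press number.

    Alignments
    ----------
    ``first``
        Position k (k >= 1) is the interval between presses k and k+1.
    ``last``
        Position -k counts backwards from the last press of the trial:
        -1 is the interval ending at the last press.
    ``last_before_event``
        As ``last`` but anchored at the last press strictly before each
        time in ``event_times_go`` (ms relative to go onset).  Because
        longer intervals are more likely to contain a random event, the
        anchor press is sampled with probability proportional to the
        length of the interval that follows it.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}

    def _add(pos: int, value: float) -> None:
        sums[pos] = sums.get(pos, 0.0) + value
        counts[pos] = counts.get(pos, 0) + 1

    if align == "last_before_event" and event_times_go is None:
        raise ValueError("alignment 'last_before_event' requires event times")

    for trial in trial_set:
        iris = trial.iris
        if iris.size == 0:
            continue
        if align == "first":
            for k in range(min(iris.size, max_positions)):
                _add(k + 1, iris[k])
        elif align == "last":
            for k in range(1, min(iris.size, max_positions) + 1):
                _add(-k, iris[iris.size - k])
        elif align == "last_before_event":
            presses = trial.press_times_go
            for e in np.atleast_1d(event_times_go):
                j = int(np.searchsorted(presses, e, side="left")) - 1
                # anchor: last press strictly before the event; need at
                # least one IRI before it
                for k in range(1, min(j, max_positions) + 1):
                    _add(-k, iris[j - k])
        else:
            raise ValueError(f"unknown alignment {align!r}")

    if not sums:
        raise ValueError("no trial contributes to the requested profile")
    positions = np.array(sorted(sums))
    return IriProfile(
        positions=positions,
        mean_iri_ms=np.array([sums[p] / counts[p] for p in positions]),
        n=np.array([counts[p] for p in positions]),
    )


def _acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    a = series - series.mean()
    denom = float(np.sum(a * a))
    if denom <= 1e-12:
        return np.zeros(max_lag + 1)
    return np.array(
        [np.sum(a[: a.size - lag] * a[lag:]) / denom for lag in range(max_lag + 1)]
    )


def iri_crosscorrelation(
    trial_set: TrialSet, mode: str = "mean_first40", max_lag: int = 24
) -> pd.DataFrame:
    """Autocorrelation of IRI sequences, by lag.

    ``mean_first40``
        Correlates the mean-IRI-by-position sequence (positions 1-40)
        with lagged copies of itself; sensitive to mini-sequences that
        are phase-locked to response onset.
    ``singletrial_17to80``
        Per-trial autocorrelations of IRIs at positions 17-80 after
        subtracting the position-wise mean IRI (the signal measured by
        ``mean_first40``), averaged over trials; sensitive to rhythms
        that are *not* phase-locked to response onset.
    """
    if mode == "mean_first40":
        prof = iri_profile(trial_set, align="first", max_positions=40)
        if prof.positions.size < 40:
            raise ValueError("no trial covers the first 40 IRIs")
        corr = _acf(prof.mean_iri_ms, max_lag)
    elif mode == "singletrial_17to80":
        lo, hi = 17, 80  # IRI ordinals, inclusive
        window = []
        for trial in trial_set:
            iris = trial.iris
            if iris.size >= hi:
                window.append(iris[lo - 1 : hi])
        if not window:
            raise ValueError("no trial covers IRIs 17-80")
        mat = np.asarray(window)
        residual = mat - mat.mean(axis=0, keepdims=True)
        corrs = [_acf(row, max_lag) for row in residual]
        corr = np.mean(corrs, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame({"lag": np.arange(max_lag + 1), "correlation": corr})


def _bin_stats(trials: list, x: GapDistribution) -> tuple[float, float, int]:
    sub = TrialSet(trials)
    go = sub.go_rts()
    return (
        float(go.mean()) if go.size else np.nan,
        mean_ssrt_simple(sub, x),
        len(trials),
    )


def trend_analysis(
    trial_set: TrialSet, scheme: str, x: GapDistribution
) -> pd.DataFrame:
    """Mean GoRT and mean SSRT per time bin, per subject.

    Schemes: ``deciles`` (10 equal bins of each subject's trials in
    recording order), ``session_blocks`` (per block number within a
    recording day), ``within_block_thirds`` (three sub-sets of each
    block).  Mean SSRT uses the deconvolution-free estimator with a
    shared gap distribution ``x``.  Rows with subject ``"(all)"`` carry
    the across-subject means.
    """
    meta = trial_set.metadata
    if meta is None:
        if scheme != "deciles":
            raise ValueError(f"scheme {scheme!r} requires subject/session/block metadata")
        meta = pd.DataFrame(
            {"subject": "s0"}, index=[t.trial_id for t in trial_set]
        )
    by_id = {t.trial_id: t for t in trial_set}

    rows = []
    for subject, sub_meta in meta.groupby("subject", sort=False):
        trials = [by_id[i] for i in sub_meta.index if i in by_id]
        if scheme == "deciles":
            for b, chunk in enumerate(np.array_split(np.arange(len(trials)), 10)):
                if chunk.size == 0:
                    continue
                go, ssrt, n = _bin_stats([trials[i] for i in chunk], x)
                rows.append((subject, b + 1, go, ssrt, n))
        elif scheme == "session_blocks":
            _require_columns(sub_meta, ["session", "block"], scheme)
            for block, block_meta in sub_meta.groupby("block", sort=True):
                block_trials = [by_id[i] for i in block_meta.index if i in by_id]
                go, ssrt, n = _bin_stats(block_trials, x)
                rows.append((subject, block, go, ssrt, n))
        elif scheme == "within_block_thirds":
            _require_columns(sub_meta, ["session", "block"], scheme)
            thirds: dict[int, list] = {1: [], 2: [], 3: []}
            for (_, _), block_meta in sub_meta.groupby(["session", "block"], sort=True):
                ids = list(block_meta.index)
                for third, chunk in enumerate(np.array_split(np.arange(len(ids)), 3)):
                    thirds[third + 1].extend(
                        by_id[ids[i]] for i in chunk if ids[i] in by_id
                    )
            for third, ts in thirds.items():
                if not ts:
                    continue
                go, ssrt, n = _bin_stats(ts, x)
                rows.append((subject, third, go, ssrt, n))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")

    df = pd.DataFrame(
        rows, columns=["subject", "bin", "mean_goRT_ms", "mean_ssrt_ms", "n"]
    )
    overall = (
        df.groupby("bin", as_index=False)[["mean_goRT_ms", "mean_ssrt_ms", "n"]]
        .mean()
        .assign(subject="(all)")
    )
    return pd.concat([df, overall[df.columns]], ignore_index=True)


def _require_columns(meta: pd.DataFrame, cols: list[str], scheme: str) -> None:
    missing = [c for c in cols if c not in meta.columns]
    if missing:
        raise ValueError(f"scheme {scheme!r} requires metadata columns {missing}")
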