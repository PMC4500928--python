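"""Synthetic press-sequence generator.

Generates datasets with the statistical structure assumed by the
estimation framework: ex-Gaussian Go and Stop latencies, ~30 ms
inter-response intervals (IRIs), a fixed-length go period, and press
deletion by the winning Stop process.  The named generators SSRT1-SSRT3
are the simulation-study conditions (equal mean 190 ms and SD ~30 ms,
with zero, positive and negative skew).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trials import PressTrial, TrialSet


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian latency parameters, in seconds, with signed tau.

    The distribution is Normal(mu, sigma) plus (tau > 0) or minus
    (tau < 0) an Exponential(|tau|) component; tau = 0 degenerates to a
    pure Gaussian.  For either sign, mean = mu + tau and
    variance = sigma**2 + tau**2.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def mean_s(self) -> float:
        return self.mu + self.tau

    @property
    def sd_s(self) -> float:
        return float(np.sqrt(self.sigma**2 + self.tau**2))

    @property
    def mean_ms(self) -> float:
        return 1000.0 * self.mean_s

    @property
    def sd_ms(self) -> float:
        return 1000.0 * self.sd_s

    @property
    def skew(self) -> float:
        """Standardized third moment: 2 tau^3 / (sigma^2 + tau^2)^1.5."""
        return float(2 * self.tau**3 / (self.sigma**2 + self.tau**2) ** 1.5)


#: Simulation-study Stop-latency generators: equal mean (190 ms),
#: zero / positive / negative skew.
SSRT_GENERATORS: dict[str, ExGaussParams] = {
    "SSRT1": ExGaussParams(mu=0.190, sigma=0.030, tau=0.0),
    "SSRT2": ExGaussParams(mu=0.168, sigma=0.020, tau=0.022),
    "SSRT3": ExGaussParams(mu=0.212, sigma=0.020, tau=-0.022),
}

#: Default Go-latency generator (mean ~208 ms), chosen to mirror the
#: empirical GoRT scale of practiced subjects; configurable everywhere.
DEFAULT_GORT_PARAMS = ExGaussParams(mu=0.180, sigma=0.025, tau=0.028)


def sample_exgauss(params: ExGaussParams, n: int, rng) -> np.ndarray:
    """Draw n ex-Gaussian latencies (seconds) with the signed-tau convention."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    out = rng.normal(params.mu, params.sigma, size=n)
    if params.tau != 0.0:
        out += np.sign(params.tau) * rng.exponential(abs(params.tau), size=n)
    return out


def sample_truncated_exponential(
    time_constant_s: float = 0.572,
    max_value_s: float = 3.5,
    n: int = 1,
    rng=None,
) -> np.ndarray:
    """Sample waiting times from an exponential truncated at ``max_value_s``.

    Uses inverse-CDF sampling on the truncated distribution, so the
    sample count is exact and deterministic under a fixed seed.  The
    defaults are the task's go/stop-period jitter (time constant 0.572 s,
    maximum 3.5 s).
    """
    if time_constant_s <= 0 or max_value_s <= 0:
        raise ValueError("time constant and maximum must be positive")
    rng = np.random.default_rng(rng)
    u = rng.uniform(size=n)
    cap = -np.expm1(-max_value_s / time_constant_s)  # CDF at the truncation point
    return -time_constant_s * np.log1p(-u * cap)


@dataclass(frozen=True)
class IriSpec:
    """Parametric stand-in for the empirical inter-response intervals.

    A gamma-shaped positive distribution (default mean 30 ms, SD 10 ms)
    with optional multiplicative period-8 modulation emulating the
    stereotyped eight-finger mini-sequences.  With ``random_phase`` the
    modulation starts at a random position each trial, emulating rhythms
    that are not phase-locked to response onset.
    """

    mean_ms: float = 30.0
    sd_ms: float = 10.0
    modulation_depth: float = 0.0
    period: int = 8
    random_phase: bool = False

    def __post_init__(self) -> None:
        if self.mean_ms <= 0 or self.sd_ms <= 0:
            raise ValueError("IRI mean and SD must be positive")


def generate_iri_sequence(iri_source, total_duration_ms: float, rng) -> np.ndarray:
    """Draw IRIs from ``iri_source`` until their cumulative sum exceeds
    ``total_duration_ms``.

    ``iri_source`` is either an :class:`IriSpec` or an array of observed
    IRIs (ms) to resample from.  With a modulated :class:`IriSpec` the
    draws are position-dependent (multiplied by the periodic profile);
    otherwise they are i.i.d.
    """
    rng = np.random.default_rng(rng)
    if isinstance(iri_source, IriSpec):
        spec = iri_source
        shape = (spec.mean_ms / spec.sd_ms) ** 2
        scale = spec.sd_ms**2 / spec.mean_ms
        # over-draw in blocks until the duration is covered
        n_guess = max(8, int(1.5 * total_duration_ms / spec.mean_ms) + 8)
        phase = rng.integers(spec.period) if spec.random_phase else 0
        iris = np.array([])
        while iris.sum() < total_duration_ms:
            block = rng.gamma(shape, scale, size=n_guess)
            if spec.modulation_depth:
                i = phase + iris.size + np.arange(n_guess)
                block = block * (
                    1.0
                    + spec.modulation_depth * np.cos(2 * np.pi * i / spec.period)
                )
            iris = np.concatenate([iris, block])
        cum = np.cumsum(iris)
        # stop at the first draw whose cumulative sum reaches the duration
        n_keep = int(np.searchsorted(cum, total_duration_ms, side="left")) + 1
        return iris[:n_keep]

    sample = np.asarray(iri_source, dtype=float)
    if sample.size == 0:
        raise ValueError("empirical IRI source is empty")
    if np.any(sample <= 0):
        raise ValueError("empirical IRI source contains non-positive intervals")
    iris_list = []
    total = 0.0
    while total < total_duration_ms:
        draw = rng.choice(sample, size=64)
        iris_list.append(draw)
        total += draw.sum()
    iris = np.concatenate(iris_list)
    cum = np.cumsum(iris)
    n_keep = int(np.searchsorted(cum, total_duration_ms, side="left")) + 1
    return iris[:n_keep]


@dataclass
class SimulationConfig:
    """Configuration for one synthetic dataset.

    Defaults are the simulation-study conditions: go period 1200 ms,
    SSRT1 Stop generator, ~30 ms IRIs.
    """

    n_trials: int = 750
    go_rt_params: ExGaussParams = DEFAULT_GORT_PARAMS
    ssrt_params: ExGaussParams = SSRT_GENERATORS["SSRT1"]
    iri_source: object = field(default_factory=IriSpec)
    go_period_ms: float = 1200.0
    seed: int | None = None


def simulate_dataset(config: SimulationConfig) -> tuple[TrialSet, pd.DataFrame]:
    """Simulate a dataset of press-sequence trials.

    Per trial: GoRT and SSRT are drawn from their ex-Gaussian generators;
    presses occur at GoRT plus the cumulative sum of IRIs; the stop
    signal occurs at ``go_period_ms``; every press at or after
    stop onset + SSRT is deleted (a press survives iff its time is
    strictly below stop + SSRT).

    Returns
    -------
    trial_set : TrialSet
    ground_truth : DataFrame
        Columns ``trial_id, true_goRT_ms, true_ssrt_ms`` — the hidden
        per-trial latencies, for recovery scoring.
    """
    if config.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(config.seed)
    go_rts = 1000.0 * sample_exgauss(config.go_rt_params, config.n_trials, rng)
    ssrts = 1000.0 * sample_exgauss(config.ssrt_params, config.n_trials, rng)

    trials = []
    truth = []
    for i in range(config.n_trials):
        go_rt, ssrt = go_rts[i], ssrts[i]
        inhibit_at = config.go_period_ms + ssrt  # absolute time of Stop finish
        horizon = max(inhibit_at - go_rt, 0.0) + 1.0
        iris = generate_iri_sequence(config.iri_source, horizon, rng)
        presses = go_rt + np.concatenate([[0.0], np.cumsum(iris)])
        presses = presses[presses < inhibit_at]
        trials.append(PressTrial(trial_id=i, go_period_ms=config.go_period_ms,
                                 press_times_go=presses))
        truth.append((i, go_rt, ssrt))
    ground_truth = pd.DataFrame(
        truth, columns=["trial_id", "true_goRT_ms", "true_ssrt_ms"]
    )
    return TrialSet(trials), ground_truth


def make_crt(trial_set: TrialSet, x, rng) -> np.ndarray:
    """Convolved reaction times: per trial, GoRT minus an independent draw
    from the gap distribution ``x``.

    CRT emulates how the GoRT distribution would look if it had to be
    inferred the same way as the Stop latency (through the gap to a
    discrete event); deconvolving ``x`` back out of CRT is the standard
    validation of the recovery pipeline.
    """
    rng = np.random.default_rng(rng)
    go_rts = trial_set.go_rts()
    if go_rts.size != len(trial_set):
        raise ValueError("every trial must have a defined GoRT")
    return go_rts - x.sample(go_rts.size, rng)
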