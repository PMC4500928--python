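"""Model/Results facade over the estimation pipeline.

`SequentialStopModel` is built from a :class:`~seqstop.trials.TrialSet`
(or a long-format DataFrame); its :meth:`fit` runs the chosen recovery
route and returns a :class:`StopResults` carrying the recovered density,
its moments, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import mean_ssrt_simple
from .deconvolve import RecoveryResult, recover_distribution
from .gap import GapDistribution, estimate_x_from_iri, estimate_x_virtual_stop, mean_x
from .grid import DEFAULT_KERNEL_SD_MS, BinnedDensity, bin_density
from .parametric import FitResult, exgauss_binned_density, fit_exgauss_convolved
from .simulate import make_crt
from .trials import PressTrial, TrialSet, reject_outliers


class SequentialStopModel:
    """Race-model estimation of Stop (and Go) latency distributions from
    rapid press-sequence trials.

    Parameters
    ----------
    trials : TrialSet
        Press-sequence trials (go-period duration plus press times).
    x_method : {"iri_integral", "virtual_stop"}
        How the gap distribution X = S - T_N is estimated.
    reject : bool
        Apply the standard liberal outlier rejection before estimation.
    kernel_sd_ms : float
        SD of the Gaussian kernel used to smooth the observed last-press
        density before deconvolution.

    Examples
    --------
    >>> from seqstop import SequentialStopModel, simulate
    >>> ts, _ = simulate.simulate_dataset(simulate.SimulationConfig(seed=1))
    >>> res = SequentialStopModel(ts).fit()
    >>> 150 < res.mean_ms < 230
    True
    """

    def __init__(
        self,
        trials: TrialSet,
        x_method: str = "iri_integral",
        reject: bool = True,
        kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS,
    ) -> None:
        if x_method not in ("iri_integral", "virtual_stop"):
            raise ValueError(f"unknown x_method {x_method!r}")
        self.x_method = x_method
        self.kernel_sd_ms = kernel_sd_ms
        if reject:
            self.trials, self.rejection_report = reject_outliers(trials)
        else:
            self.trials, self.rejection_report = trials, None
        self._x: GapDistribution | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SequentialStopModel":
        """Build from a long-format frame with columns
        ``trial_id, go_period_ms, press_time_ms``."""
        trials = []
        for trial_id, grp in df.groupby("trial_id", sort=False):
            presses = grp["press_time_ms"].dropna().to_numpy(dtype=float)
            trials.append(
                PressTrial(trial_id, float(grp["go_period_ms"].iloc[0]), presses)
            )
        return cls(TrialSet(trials), **kwargs)

    @property
    def x(self) -> GapDistribution:
        """Estimated gap distribution (lazy, cached)."""
        if self._x is None:
            if self.x_method == "virtual_stop":
                self._x = estimate_x_virtual_stop(self.trials)
            else:
                self._x = estimate_x_from_iri(bin_density(self.trials.pooled_iris()))
        return self._x

    def fit(
        self,
        method: str = "deconvolution",
        target: str = "ssrt",
        seed: int = 0,
    ) -> "StopResults":
        """Recover a latency distribution.

        Parameters
        ----------
        method : {"deconvolution", "exgauss"}
            Non-parametric Fourier deconvolution, or convolved
            ex-Gaussian maximum likelihood.
        target : {"ssrt", "gort"}
            ``ssrt`` recovers the Stop latency from last-press times.
            ``gort`` recovers the Go latency: directly for the
            parametric route; through the convolved-reaction-time (CRT)
            construction GoRT - x for the deconvolution route, which
            validates the pipeline on a known distribution.
        seed : int
            Seeds the CRT gap draws and optimizer restarts.
        """
        if target == "ssrt":
            samples = self.trials.last_presses_rel_stop()
            x = self.x
        elif target == "gort":
            if method == "deconvolution":
                samples = make_crt(self.trials, self.x, np.random.default_rng(seed))
                x = self.x
            else:
                samples = self.trials.go_rts()
                x = GapDistribution.point_mass(0.0)
        else:
            raise ValueError(f"unknown target {target!r}")

        recovery: RecoveryResult | None = None
        fit_result: FitResult | None = None
        if method == "deconvolution":
            recovery = recover_distribution(samples, x, self.kernel_sd_ms)
            density = recovery.density
        elif method == "exgauss":
            fit_result = fit_exgauss_convolved(samples, x, seed=seed)
            density = exgauss_binned_density(fit_result.params, warn_offgrid=False)
        else:
            raise ValueError(f"unknown method {method!r}")

        return StopResults(
            model=self,
            method=method,
            target=target,
            density=density,
            recovery=recovery,
            fit_result=fit_result,
            n_obs=len(samples),
            mean_ssrt_simple_ms=(
                mean_ssrt_simple(self.trials, self.x) if target == "ssrt" else None
            ),
        )


@dataclass
class StopResults:
    """Recovered latency distribution plus diagnostics."""

    model: SequentialStopModel
    method: str
    target: str
    density: BinnedDensity
    recovery: RecoveryResult | None
    fit_result: FitResult | None
    n_obs: int
    mean_ssrt_simple_ms: float | None = field(default=None)

    @property
    def mean_ms(self) -> float:
        if self.recovery is not None:
            return self.recovery.mean_ms
        return self.fit_result.mean_ms

    @property
    def sd_ms(self) -> float:
        """SD of the recovered density.  For the deconvolution route this
        is the smoothed-distribution SD; see ``sd_corrected_ms``."""
        if self.recovery is not None:
            return self.recovery.sd_ms
        return self.fit_result.sd_ms

    @property
    def sd_corrected_ms(self) -> float | None:
        if self.recovery is not None:
            return self.recovery.sd_corrected_ms
        return self.fit_result.sd_ms  # parametric fit is unsmoothed already

    @property
    def skew(self) -> float:
        if self.recovery is not None:
            return self.recovery.skew
        return self.fit_result.skew

    @property
    def converged(self) -> bool:
        if self.fit_result is not None:
            return self.fit_result.converged
        return True

    def cdf(self) -> np.ndarray:
        return self.density.cdf()

    def summary(self) -> str:
        """Plain-text summary table."""
        label = {"ssrt": "Stop latency (SSRT)", "gort": "Go latency (GoRT)"}[
            self.target
        ]
        lines = [
            "Sequential stop-signal model results",
            "=" * 44,
            f"Target:                {label}",
            f"Method:                {self.method}",
            f"Gap estimator:         {self.model.x_method}",
            f"N trials used:         {self.n_obs}",
        ]
        if self.model.rejection_report is not None:
            lines.append(
                f"N trials rejected:     {self.model.rejection_report.n_rejected}"
            )
        lines += [
            f"E[X] (mean gap, ms):   {mean_x(self.model.x):8.2f}",
            "-" * 44,
            f"Mean (ms):             {self.mean_ms:8.2f}",
            f"SD (ms):               {self.sd_ms:8.2f}",
        ]
        if self.method == "deconvolution" and self.sd_corrected_ms is not None:
            lines.append(f"SD, kernel-corrected:  {self.sd_corrected_ms:8.2f}")
        lines.append(f"Skew:                  {self.skew:8.3f}")
        if self.mean_ssrt_simple_ms is not None:
            lines.append(f"Mean SSRT (simple):    {self.mean_ssrt_simple_ms:8.2f}")
        if self.recovery is not None and self.recovery.lower_bound_ms is not None:
            lines.append(f"Lower clip bound (ms): {self.recovery.lower_bound_ms:8.1f}")
        if self.fit_result is not None:
            p = self.fit_result.params
            lines += [
                f"mu / sigma / tau (s):  {p.mu:.4f} / {p.sigma:.4f} / {p.tau:.4f}",
                f"Log-likelihood:        {self.fit_result.log_likelihood:10.2f}",
                f"Converged:             {self.converged}",
            ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center_ms": self.density.centers, "density": self.density.probs}
        )

    def plot_density(self, ax=None, **kwargs):
        """Plot the recovered density on the millisecond axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.density.centers, self.density.probs, **kwargs)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("probability / 4 ms bin")
        ax.set_title(f"Recovered {self.target.upper()} density ({self.method})")
        return ax
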