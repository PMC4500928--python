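# Methods

This note records the statistical model behind `seqstop`, the estimators
it implements, the numerical choices, and the known limitations.

## Problem

In a sequential-inhibition (SeqIn) task a subject produces a rapid
sequence of button presses after a go cue and stops pressing when a stop
signal appears. The stop-signal reaction time (SSRT) — the latency `S`
between stop-signal onset and the internal completion of inhibition — is
never observed directly. What is observed is `T_N`, the time of the last
press relative to the stop signal. The two differ by a gap

```
T_N = S − X,
```

where `X ≥ 0` is the time from the last press to the moment inhibition
takes effect: inhibition rarely lands exactly on a press, so it truncates
the sequence somewhere inside an inter-response interval (IRI). If the
distribution of `X` can be estimated, the full distribution of `S` can be
recovered from the distribution of `T_N` by deconvolution. This package
estimates `X`, performs the deconvolution, and provides a parametric
alternative, simulation machinery to validate both, and the surrounding
behavioral analyses.

## The gap distribution X

`X` is the *backward recurrence time* ("age") of the press renewal
process at the moment of inhibition. Two estimators are provided and
cross-validate each other (`seqstop.gap`):

1. **Virtual-stop replay** (`estimate_x_virtual_stop`). Each trial is
   replayed against simulated stop times `S′ ≤ 0` (i.e. inside the go
   period, where the true inhibition cannot interfere). For each
   admissible `S′` — at least 500 ms after the first press, so the
   sequence is in steady state — the gap `X′ = S′ − T_M` to the last
   press before `S′` is recorded. Pooling over trials and `S′` values
   gives a direct empirical distribution of the gap.

2. **IRI integral** (`estimate_x_from_iri`). From the binned IRI
   distribution, the age density of a stationary renewal process is

   ```
   f_X(t) = (1 − F_Δ(t)) / E[Δ],
   ```

   where `Δ` is the interval length. This is the classical
   length-biased (inspection-paradox) form: a random inspection time is
   more likely to fall into a long interval, so
   `E[X] = E[Δ²] / (2 E[Δ])`, which exceeds `E[Δ]/2` whenever the IRIs
   have positive variance. This is the default (`weighting="interval"`).
   A second mode (`weighting="raw"`) instead weights each interval by
   `1/Δ` (density `∫ f_Δ(u)/u du`), which corresponds to picking an
   interval uniformly at random rather than by inspection time and gives
   `E[X] = E[Δ]/2`. The interval weighting is the physically correct
   model for a stop signal arriving at a time unrelated to the press
   process, and it is what the simulator reproduces empirically; the raw
   mode is retained for comparison. On data simulated from the package's
   own generator the two gap estimators agree to a CDF sup-norm of about
   0.002.

Both estimators assume the press process is approximately stationary at
the time of the stop signal and that the stop time is independent of the
press times — satisfied here because the stop signal is scheduled by the
task, not by the subject's behavior.

## Deconvolution recovery

With `T_N = S − X` and `S ⟂ X`, the distribution of `T_N` is the
convolution of `S` with `−X`. Recovery (`seqstop.deconvolve`) proceeds
on a fixed lattice of 300 four-millisecond bins spanning −400 … 800 ms:

1. **Bin** the observed `T_N` values (half-open bins `[t, t+4)`).
2. **Smooth** with a Gaussian kernel (SD 16 ms, truncated at ±5 SD and
   renormalized). Smoothing regularizes the division in the frequency
   domain; it inflates the variance of the recovered distribution by the
   kernel variance, which is corrected analytically afterwards
   (`sd_corrected = sqrt(sd² − 16²)`), and it attenuates skew, which is
   not corrected (see Limitations).
3. **Divide spectra**: `F̂_S = FFT(T_N density) / FFT(−X kernel)` using
   the circular FFT on the 300-bin lattice. Gap lags that fall between
   bin multiples are placed fractionally across the two adjacent integer
   shifts, which preserves the gap mean exactly and makes a point mass
   at zero an exact identity kernel. Frequency bands where the kernel
   spectrum magnitude falls below `1e-8 ×` its maximum are zeroed, with
   a warning, instead of amplifying noise.
4. **Post-process** the inverse transform in a fixed order: discard the
   imaginary part; find the latest time at which the running CDF is
   still negative and zero everything up to it (removes the oscillatory
   left-tail ripple characteristic of spectral division); zero remaining
   negative excursions; zero mass outside the plausible Stop-latency
   support of 90–550 ms; renormalize.

The grid spans −400 … 800 ms so that the support window 90–550 ms sits
far from the wrap-around boundary; guard bands make circular convolution
indistinguishable from linear convolution for these signals.

## Parametric alternative

`seqstop.parametric` fits an ex-Gaussian to `S` by maximum likelihood,
with the model density for `T_N` formed by convolving the candidate
ex-Gaussian with the reflected estimated gap. The ex-Gaussian uses a
*signed-τ* convention: `Normal(μ, σ)` plus (τ > 0) or minus (τ < 0) an
`Exponential(|τ|)`, so both skew directions are reachable by a smooth
parameter path; mean `= μ + τ`, variance `= σ² + τ²`, skew
`= 2τ³/(σ²+τ²)^{3/2}`. The likelihood is binned on the same 4 ms grid
and mixed with a 1% lapse component spread over all bins so no
observation has zero probability. Optimization is Nelder–Mead from a
method-of-moments start with two additional jittered restarts; a fit is
flagged non-converged if the optimizer fails or σ collapses below 1 ms.
The parametric route is unsmoothed, so its skew estimate is not
attenuated — it complements the non-parametric recovery.

A deconvolution-free estimator of the *mean* only,
`E[S] = E[T_N] + E[X]` (`analysis.mean_ssrt_simple`), is stable from
roughly 75 trials and is used by the trend analyses.

## Synthetic data generator

`seqstop.simulate` generates trials by the same race logic the
estimators assume: per trial, a Go latency and a Stop latency are drawn
from ex-Gaussian generators, presses are laid down at GoRT plus the
cumulative sum of IRIs, and every press at or after
`stop onset + SSRT` is deleted.

* **Stop generators.** Three named generators share a 190 ms mean:
  `SSRT1` = (μ 190 ms, σ 30 ms, τ 0) — zero skew, SD exactly 30 ms;
  `SSRT2` = (168, 20, +22) — positive skew; `SSRT3` = (212, 20, −22) —
  negative skew. Equal means with opposite skews make mean-recovery and
  skew-recovery failures separable.
* **Go generator.** Default (180, 25, +28), mean 208 ms, matching the
  scale of practiced subjects.
* **IRIs.** A gamma-shaped distribution with mean 30 ms and SD 10 ms by
  default. Realism knobs: multiplicative period-8 modulation emulating
  stereotyped eight-finger mini-sequences, optionally with a random
  phase per trial (rhythms not locked to response onset); or resampling
  from an empirical IRI array. The cross-correlation analyses
  (`analysis.iri_crosscorrelation`) distinguish the phase-locked and
  phase-random cases.
* **Timing.** Go period 1200 ms by default; the task's go/stop-period
  jitter is available as a truncated exponential (time constant 572 ms,
  cap 3.5 s).

Outlier rejection (`trials.reject_outliers`) is deliberately liberal:
trials are dropped only if GoRT < 90 ms (anticipation), GoRT exceeds
median + 8 SD, the last press precedes the stop signal, `T_N` exceeds
median + 8 SD, or the trial has no presses. Bounds are computed once on
the full pre-rejection set. On clean simulated data well under 1% of
trials are rejected.

## Recovery accuracy (simulation study)

`seqstop.benchmark` runs the full pipeline on replicated synthetic
datasets. At the headline operating point — 750 trials per dataset,
zero-skew generator, 200 replicates — the deconvolution recovers the
mean and SD with 95% confidence half-widths of roughly 2 ms each and the
skew within ±0.15, and the mean KS distance between the recovered CDF
and the smoothed empirical Stop CDF is about 0.01. Comparing each
recovery to its own generating sample (`compare_to_sample`) shows the
recovery error proper is substantially smaller than the across-replicate
spread, i.e. much of the spread is sampling variability of the
generating draws themselves (recovered and sample means correlate at
about 0.9).

## Numerical choices

* 4 ms bins: fine enough that discretization error is far below
  sampling error at realistic trial counts, coarse enough that 300 bins
  cover the needed range with cheap FFTs.
* Bin centers at `edge + 2 ms`; all moments are computed on centers.
* Gaussian kernel SD 16 ms: large enough to stabilize the spectral
  division at a few hundred trials, small enough that the variance
  correction stays well conditioned.
* Spectrum floor `1e-8 × max`: with the smooth gap kernels that arise
  from real IRI distributions at most an isolated band (typically the
  Nyquist band) is affected.
* Z-score grid −8 … 8 in steps of 0.1 for shape comparisons across
  subjects; Vincent averaging over probabilities 0.001 … 0.999 in steps
  of 0.001.
* Robust skew: Bowley-type quantile skew
  `(Q(u) + Q(1−u) − 2Q(0.5)) / (Q(1−u) − Q(u))`, default `u = 0.25`;
  `u = 0.1` gives Kelley's measure.

## Limitations

* **Skew attenuation.** The smoothing kernel attenuates the skew of the
  non-parametric recovery; the package reports the recovered skew as-is
  and benchmarks it against the *smoothed* truth. Use the parametric
  route when an unattenuated skew estimate matters.
* **Stationarity.** Both gap estimators assume the press process is
  stationary near the stop signal. Strong within-trial IRI drift would
  bias the gap distribution; the IRI profile tools exist to check this.
* **Independence.** The race model assumes `S` is independent of the
  press process. Context independence violations (e.g. pressing faster
  when a stop is anticipated) are not modeled.
* **Support window.** The 90–550 ms support clip encodes a prior on
  plausible Stop latencies; distributions with real mass outside this
  window would be truncated.
* **Left-edge bias at small n.** With few trials the ripple-removal
  step can clip genuine left-tail mass, biasing the recovered mean
  upward by a few ms at n ≈ 100; the benchmark quantifies this.
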