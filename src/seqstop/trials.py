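"""Trial data model, CSV I/O and outlier rejection for press sequences.

A trial is one go period (rapid self-ordered button pressing) followed by
a stop period.  Press times are stored in milliseconds relative to go
onset; the stop signal occurs at ``go_period_ms``, so stop-relative times
are ``press_times_go - go_period_ms``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PressTrial:
    """One trial: go-period duration plus ordered press times.

    Parameters
    ----------
    trial_id : str or int
        Unique trial identifier.
    go_period_ms : float
        Duration of the go period; the stop signal occurs at this time.
    press_times_go : ndarray
        Strictly increasing press times (ms, relative to go onset).
    """

    trial_id: object
    go_period_ms: float
    press_times_go: np.ndarray

    def __post_init__(self) -> None:
        self.press_times_go = np.asarray(self.press_times_go, dtype=float)
        if self.go_period_ms <= 0:
            raise ValueError(f"trial {self.trial_id}: go_period_ms must be > 0")
        if self.press_times_go.size > 1 and np.any(np.diff(self.press_times_go) <= 0):
            raise ValueError(
                f"trial {self.trial_id}: press times must be strictly increasing"
            )

    @property
    def n_presses(self) -> int:
        return int(self.press_times_go.size)

    @property
    def go_rt(self) -> float | None:
        """Time of the first press after the go signal (ms), or None."""
        if self.n_presses == 0:
            return None
        return float(self.press_times_go[0])

    @property
    def press_times_stop(self) -> np.ndarray:
        """Press times relative to the stop signal (ms)."""
        return self.press_times_go - self.go_period_ms

    @property
    def iris(self) -> np.ndarray:
        """Inter-response intervals Delta_i = T_i - T_{i-1} (ms)."""
        return np.diff(self.press_times_go)


def last_press_rel_stop(trial: PressTrial) -> float | None:
    """Time of the last press relative to the stop signal (T_N, ms).

    Returns None for a trial with no presses.
    """
    if trial.n_presses == 0:
        return None
    return float(trial.press_times_go[-1] - trial.go_period_ms)


@dataclass
class TrialSet:
    """A collection of trials with optional per-trial metadata.

    ``metadata`` is a DataFrame indexed by trial_id with columns such as
    subject / block / session, used by the trend analyses.
    """

    trials: list[PressTrial]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(ids) != len(set(ids)):
            raise ValueError("trial_ids must be unique")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def go_rts(self) -> np.ndarray:
        """GoRT (first-press time) of every trial that has presses (ms)."""
        return np.array([t.go_rt for t in self.trials if t.n_presses > 0])

    def last_presses_rel_stop(self) -> np.ndarray:
        """T_N relative to the stop signal for trials with presses (ms)."""
        return np.array(
            [last_press_rel_stop(t) for t in self.trials if t.n_presses > 0]
        )

    def pooled_iris(self) -> np.ndarray:
        """All inter-response intervals pooled across trials (ms)."""
        parts = [t.iris for t in self.trials if t.n_presses >= 2]
        if not parts:
            return np.array([])
        return np.concatenate(parts)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame: trial_id, go_period_ms, press_time_ms."""
        rows = []
        for t in self.trials:
            if t.n_presses == 0:
                rows.append((t.trial_id, t.go_period_ms, np.nan))
            for p in t.press_times_go:
                rows.append((t.trial_id, t.go_period_ms, p))
        return pd.DataFrame(rows, columns=["trial_id", "go_period_ms", "press_time_ms"])


def load_trials(path, metadata_path=None) -> TrialSet:
    """Load trials from a long-format CSV.

    Required columns: ``trial_id, go_period_ms, press_time_ms`` (one row
    per press, times in ms relative to go onset).  A row with an empty
    ``press_time_ms`` marks a press-less trial.  Ordering of trials is
    preserved; press times within a trial are validated as strictly
    increasing.

    Parameters
    ----------
    path : str or Path
        Trials CSV.
    metadata_path : str or Path, optional
        Companion CSV with columns ``trial_id, subject, block, session``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed trials CSV {path}: {err}") from err
    required = {"trial_id", "go_period_ms", "press_time_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trials CSV {path} is missing columns: {sorted(missing)}")
    bad = df["go_period_ms"].isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"trials CSV {path}: missing go_period_ms at line {line}")

    trials: list[PressTrial] = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        presses = grp["press_time_ms"].dropna().to_numpy(dtype=float)
        go_period = float(grp["go_period_ms"].iloc[0])
        if presses.size > 1 and np.any(np.diff(presses) <= 0):
            raise ValueError(
                f"trials CSV {path}: non-monotone press times in trial {trial_id}"
            )
        if presses.size == 0:
            warnings.warn(f"trial {trial_id} has no presses", stacklevel=2)
        trials.append(PressTrial(trial_id, go_period, presses))

    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path).set_index("trial_id")
    return TrialSet(trials, metadata=metadata)


def save_trials(trial_set: TrialSet, path, metadata_path=None) -> None:
    """Write a TrialSet to the long-format CSV schema of :func:`load_trials`."""
    trial_set.to_dataframe().to_csv(path, index=False)
    if metadata_path is not None and trial_set.metadata is not None:
        trial_set.metadata.to_csv(metadata_path)


@dataclass
class RejectionReport:
    """Per-trial rejection record plus the bounds that were applied."""

    rejected: pd.DataFrame
    go_rt_upper_ms: float
    tn_upper_ms: float

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def reject_outliers(
    trial_set: TrialSet, go_rt_min_ms: float = 90.0, sd_multiple: float = 8.0
) -> tuple[TrialSet, RejectionReport]:
    """Apply the deliberately liberal trial-rejection rules.

    A trial is rejected if

    * it has no presses (GoRT undefined),
    * its GoRT is below 90 ms,
    * its last press T_N occurred strictly before the stop signal, or
    * its GoRT or T_N exceeds median + 8 * SD of that quantity.

    The upper bounds are computed once, on the full input set, separately
    for GoRT and T_N (single pass; rejection is therefore idempotent if
    re-applied with the frozen bounds).
    """
    if len(trial_set) < 2:
        raise ValueError("outlier rejection needs at least 2 trials")

    go_rts = trial_set.go_rts()
    tns = trial_set.last_presses_rel_stop()
    go_upper = float(np.median(go_rts) + sd_multiple * np.std(go_rts, ddof=1))
    tn_upper = float(np.median(tns) + sd_multiple * np.std(tns, ddof=1))

    kept: list[PressTrial] = []
    records = []
    for t in trial_set:
        reason = None
        if t.n_presses == 0:
            reason = "no presses (GoRT undefined)"
        else:
            go_rt = t.go_rt
            tn = last_press_rel_stop(t)
            if go_rt < go_rt_min_ms:
                reason = f"GoRT below {go_rt_min_ms:g} ms"
            elif tn < 0:
                reason = "last press before the stop signal"
            elif go_rt > go_upper:
                reason = f"GoRT above median + {sd_multiple:g} SD"
            elif tn > tn_upper:
                reason = f"T_N above median + {sd_multiple:g} SD"
        if reason is None:
            kept.append(t)
        else:
            records.append({"trial_id": t.trial_id, "reason": reason})

    if not kept:
        warnings.warn("all trials rejected", stacklevel=2)
    metadata = trial_set.metadata
    if metadata is not None:
        keep_ids = [t.trial_id for t in kept]
        metadata = metadata.loc[metadata.index.intersection(keep_ids)]
    report = RejectionReport(
        rejected=pd.DataFrame(records, columns=["trial_id", "reason"]),
        go_rt_upper_ms=go_upper,
        tn_upper_ms=tn_upper,
    )
    return TrialSet(kept, metadata=metadata), report
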