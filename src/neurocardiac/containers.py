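"""Shared in-memory containers.

Tabular data (events, features, scores) lives in pandas DataFrames with
documented column conventions; continuous signals and epochs live in
small dataclasses wrapping numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order of the event table (one row per trial).
EVENT_COLUMNS = (
    "participant", "sex", "phase", "phase_code", "run", "trial",
    "stimulus_onset", "response_onset", "response_time",
    "correct", "answered", "max_time",
)


@dataclass
class ContinuousRecording:
    """One modality's continuous samples for a single participant."""

    data: np.ndarray            # (n_channels, n_samples)
    rate: float                 # Hz
    channel_names: list[str]
    modality: str = "eeg"
    start_time: float = 0.0     # s, session clock of sample 0
    participant: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate


@dataclass
class RRSeries:
    """R-peak times with the derived R-R interval series.

    After cleaning, ``rr_intervals`` may deviate from ``diff(r_peak_times)``
    wherever a value was replaced; ``flags`` records the provenance of each
    interval ("kept", "rel_change", "gesd", "interpolated").
    """

    r_peak_times: np.ndarray            # s, monotone
    rr_intervals: np.ndarray            # s, length n_peaks - 1
    flags: np.ndarray                   # str, per interval

    @classmethod
    def from_peaks(cls, r_peak_times: np.ndarray) -> "RRSeries":
        t = np.asarray(r_peak_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        rr = np.diff(t)
        return cls(t, rr, np.full(rr.shape, "kept", dtype=object))

    @property
    def midpoint_times(self) -> np.ndarray:
        return 0.5 * (self.r_peak_times[1:] + self.r_peak_times[:-1])


@dataclass
class HRSignal:
    """Uniformly sampled instantaneous heart rate in bpm."""

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    baseline_mean_by_phase: dict[str, float] = field(default_factory=dict)

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate


@dataclass
class HREpochs:
    """Response-locked HR windows: (n_trials, n_times), common time axis."""

    data: np.ndarray
    times: np.ndarray               # s relative to response onset
    metadata: pd.DataFrame          # one row per kept trial
    n_dropped: int = 0


@dataclass
class EEGEpochs:
    """Response-locked EEG windows: (n_trials, n_channels, n_times)."""

    data: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    metadata: pd.DataFrame
    n_dropped: int = 0


#: Order of the seven HR trajectory features.
HR_FEATURES = (
    "dip_onset_time", "dip_time", "dip_magnitude", "dip_duration",
    "rebound_magnitude", "rebound_time", "rebound_duration",
)


@dataclass
class HRTrajectoryFeatures:
    """Seven dip/rebound metrics of one participant-phase average trace."""

    dip_onset_time: float
    dip_time: float
    dip_magnitude: float
    dip_duration: float
    rebound_magnitude: float
    rebound_time: float
    rebound_duration: float
    valid: bool = True
    notes: str = ""

    def as_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in HR_FEATURES}
                         | {"valid": self.valid, "notes": self.notes})


@dataclass
class LMEResult:
    """Fixed-slope row of a random-intercept linear mixed model."""

    estimate: float
    se: float
    tvalue: float
    df: int
    pvalue: float
    random_intercept_var: float
    resid_var: float
    n_obs: int
    loglik: float
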