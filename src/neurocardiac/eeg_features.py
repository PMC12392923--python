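"""Response-locked EEG spectral features.

Epochs cover -3 to -0.5 s before each response (pre-response window,
clear of stimulus-evoked visual components). After +/-100 uV amplitude
rejection, each 2.5-s trial segment yields relative power in five bands

    delta 0.5-3.5, theta 4-7.5, alpha 8-12.5, beta 13-30, gamma 30-60 Hz

normalized by total power over the broad 0.5-60 Hz band on the same
spectral estimate, the theta/beta and gamma/theta ratios, and a
whole-head alpha laterality index ln(L) - ln(R) over homologous pairs
(sign-flipped on the right, zero on the midline). No EEG baseline
correction is applied; relative power already normalizes per trial.

The spectral estimate is a full-epoch Hann-windowed periodogram
(0.4 Hz resolution on the 2.5-s window) with rectangular band
integration; bands are half-open ``[low, high)`` against the discrete
frequency grid, the broad denominator is ``[0.5, 60]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sig

from .containers import ContinuousRecording, EEGEpochs
from .montage import HOMOLOGOUS_PAIRS, MIDLINE, pair_of, is_left

__all__ = [
    "BandDefinition", "BANDS", "BROAD_BAND", "epoch_eeg", "reject_trials",
    "relative_band_power", "band_ratios", "alpha_laterality",
    "compute_feature_table", "compute_laterality_table", "aggregate_by_run",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("band edges must satisfy 0 < low < high")


#: The five analysis bands, keyed by their single-letter names.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("D", 0.5, 3.5),
    BandDefinition("T", 4.0, 7.5),
    BandDefinition("A", 8.0, 12.5),
    BandDefinition("B", 13.0, 30.0),
    BandDefinition("G", 30.0, 60.0),
)
BROAD_BAND = BandDefinition("broad", 0.5, 60.0)


# ----------------------------------------------------------------- epochs ----

def epoch_eeg(eeg: ContinuousRecording, events: pd.DataFrame,
              window: tuple[float, float] = (-3.0, -0.5)) -> EEGEpochs:
    """Slice per-trial windows relative to response onset.

    Expects already filtered EEG (band-pass 0.5-60 Hz + 50 Hz notch via the
    ecg module's filters). Trials whose window falls outside the recording
    are dropped and counted.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window start must precede window end")
    n_win = int(round((hi - lo) * eeg.rate))
    times = lo + np.arange(n_win) / eeg.rate
    t0 = eeg.start_time

    rows, slices = [], []
    dropped = 0
    for _, ev in events.iterrows():
        start = int(round((ev["response_onset"] + lo - t0) * eeg.rate))
        if start < 0 or start + n_win > eeg.n_samples:
            dropped += 1
            continue
        slices.append(eeg.data[:, start:start + n_win])
        rows.append(ev)
    if not rows:
        raise ValueError("no usable trials inside the recording")
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) at recording edge")
    data = np.stack(slices).astype(float)
    meta = pd.DataFrame(rows).reset_index(drop=True)
    return EEGEpochs(data=data, times=times,
                     channel_names=list(eeg.channel_names),
                     metadata=meta, n_dropped=dropped)


def reject_trials(epochs: EEGEpochs,
                  threshold_uv: float = 100.0) -> tuple[EEGEpochs, pd.DataFrame]:
    """Drop every trial with any |sample| > threshold on any channel.

    Returns the surviving epochs and a per-trial rejection log (trial
    metadata, peak absolute amplitude, kept flag).
    """
    peak = np.abs(epochs.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    log = epochs.metadata.copy()
    log["peak_abs_uv"] = peak
    log["kept"] = keep
    if not keep.any():
        raise ValueError("all trials exceed the amplitude threshold")
    out = EEGEpochs(data=epochs.data[keep], times=epochs.times,
                    channel_names=epochs.channel_names,
                    metadata=epochs.metadata[keep].reset_index(drop=True),
                    n_dropped=epochs.n_dropped + int((~keep).sum()))
    return out, log


# ---------------------------------------------------------- spectral power ----

def relative_band_power(segment: np.ndarray, rate: float,
                        bands: tuple[BandDefinition, ...] = BANDS,
                        broad: BandDefinition = BROAD_BAND) -> np.ndarray:
    """Relative band power of one trial segment, per channel.

    ``segment`` is (n_channels, n_times) with at least 2 s of data so the
    frequency resolution is <= 0.5 Hz. Returns (n_channels, n_bands) with
    each band's integrated periodogram power divided by the broad-band
    total on the same estimate.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n = segment.shape[1]
    if n < 2 * rate:
        raise ValueError("segment must be at least 2 s for 0.5 Hz resolution")
    freqs, psd = sig.periodogram(segment, fs=rate, window="hann", axis=-1,
                                 detrend="constant")
    total_mask = (freqs >= broad.low) & (freqs <= broad.high)
    total = psd[:, total_mask].sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total power in broad band")
    out = np.empty((segment.shape[0], len(bands)))
    for j, band in enumerate(bands):
        mask = (freqs >= band.low) & (freqs < band.high)
        out[:, j] = psd[:, mask].sum(axis=1) / total
    return out


def band_ratios(rel_powers: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Theta/beta and gamma/theta ratios from relative powers.

    Accepts a frame with columns relD..relG (or an (n, 5) array in band
    order). Zero denominators yield NaN so the row is excluded downstream.
    """
    if isinstance(rel_powers, np.ndarray):
        rel_powers = pd.DataFrame(
            rel_powers, columns=[f"rel{b.name}" for b in BANDS])
    out = rel_powers.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tb = np.where(out["relB"] > 0, out["relT"] / out["relB"], np.nan)
        gt = np.where(out["relT"] > 0, out["relG"] / out["relT"], np.nan)
    out["TB_ratio"] = tb
    out["GT_ratio"] = gt
    return out


def alpha_laterality(rel_alpha: pd.Series | dict,
                     pairs=HOMOLOGOUS_PAIRS) -> pd.Series:
    """Whole-head alpha laterality index per channel.

    For each homologous pair (left, right): index(left) = ln(relA_left) -
    ln(relA_right) and index(right) is its negation; midline channels are
    zero by definition. Non-positive relative alpha flags the pair missing
    (NaN).
    """
    rel_alpha = pd.Series(rel_alpha, dtype=float)
    out = pd.Series(np.nan, index=rel_alpha.index, dtype=float)
    for left, right in pairs:
        if left not in rel_alpha.index or right not in rel_alpha.index:
            continue
        a_l, a_r = rel_alpha[left], rel_alpha[right]
        if a_l <= 0 or a_r <= 0:
            continue                       # flagged missing
        idx = float(np.log(a_l) - np.log(a_r))
        out[left] = idx
        out[right] = -idx
    for ch in MIDLINE:
        if ch in out.index:
            out[ch] = 0.0
    return out


# ------------------------------------------------------------ table builders ----

def compute_feature_table(epochs: EEGEpochs, rate: float) -> pd.DataFrame:
    """Trial-level spectral feature table.

    One row per trial x channel: relD..relG, TB_ratio, GT_ratio, plus the
    per-channel alpha laterality of that trial, joined with trial metadata.
    """
    n_trials, n_ch, _ = epochs.data.shape
    meta_cols = ["participant", "sex", "phase", "phase_code", "run", "trial"]
    frames = []
    for i in range(n_trials):
        rel = relative_band_power(epochs.data[i], rate)
        df = pd.DataFrame(rel, columns=[f"rel{b.name}" for b in BANDS])
        df.insert(0, "channel", epochs.channel_names)
        df = band_ratios(df)
        lat = alpha_laterality(
            pd.Series(rel[:, 2], index=epochs.channel_names))
        df["alpha_lat"] = lat.reindex(epochs.channel_names).to_numpy()
        for c in meta_cols:
            df[c] = epochs.metadata.iloc[i][c]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table[meta_cols + ["channel"] +
                 [f"rel{b.name}" for b in BANDS] +
                 ["TB_ratio", "GT_ratio", "alpha_lat"]]


def compute_laterality_table(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Laterality view of the trial-level feature table with pair labels."""
    lat = feature_table.copy()
    lat["pair"] = [
        "midline" if ch in MIDLINE else
        (f"{ch}/{pair_of(ch)}" if is_left(ch) else f"{pair_of(ch)}/{ch}")
        for ch in lat["channel"]
    ]
    cols = ["participant", "sex", "phase", "phase_code", "run", "trial",
            "channel", "pair", "alpha_lat"]
    return lat[cols]


def aggregate_by_run(feature_table: pd.DataFrame,
                     value_columns: list[str] | None = None) -> pd.DataFrame:
    """Run-level means per participant x phase x run x channel.

    The run average is the dependent variable of the channel-wise mixed
    models. Runs that lost every trial to rejection are simply absent.
    """
    if value_columns is None:
        value_columns = [c for c in feature_table.columns
                         if c.startswith("rel") or c.endswith("_ratio")
                         or c == "alpha_lat"]
    keys = ["participant", "sex", "phase", "phase_code", "run", "channel"]
    return (feature_table
            .groupby(keys, sort=True, observed=True)[value_columns]
            .mean()
            .reset_index())
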