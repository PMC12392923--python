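"""ECG to clean, uniformly sampled, baseline-corrected heart rate.

Stages: zero-phase Butterworth band-pass (0.5-60 Hz) and 50 Hz notch
filtering, Pan-Tompkins QRS detection, two-stage R-R artifact repair
(beat-to-beat relative-change screen, then a generalized extreme
studentized deviate pass with linear interpolation of rejected
intervals), conversion to instantaneous HR = 60 / RR on a uniform 256 Hz
grid, and per-phase baseline correction against the 10-s rest preceding
each phase.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sig
from scipy import stats as sps

from .containers import HRSignal, RRSeries

__all__ = [
    "bandpass_filter", "notch_filter", "detect_r_peaks", "clean_rr",
    "gesd_outliers", "rr_to_hr", "baseline_correct_hr",
]


# ---------------------------------------------------------------- filters ----

def bandpass_filter(x, rate: float, low: float = 0.5,
                    high: float = 60.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward).

    The filter is designed at ``order`` and applied with filtfilt, so the
    effective magnitude response is the squared single-pass response.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high < rate / 2:
        raise ValueError(f"band edges ({low}, {high}) must satisfy "
                         f"0 < low < high < Nyquist ({rate / 2})")
    sos = sig.butter(order, [low, high], btype="bandpass", fs=rate,
                     output="sos")
    return sig.sosfiltfilt(sos, x, axis=-1)


def notch_filter(x, rate: float, center: float = 50.0,
                 half_width: float = 2.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-stop around the mains frequency."""
    x = np.asarray(x, dtype=float)
    if not 0 < center < rate / 2:
        raise ValueError(f"notch center {center} must be below Nyquist")
    lo, hi = center - half_width, center + half_width
    sos = sig.butter(order, [lo, hi], btype="bandstop", fs=rate, output="sos")
    return sig.sosfiltfilt(sos, x, axis=-1)


# ----------------------------------------------------------- QRS detection ----

def detect_r_peaks(ecg, rate: float, refractory: float = 0.2) -> RRSeries:
    """Pan-Tompkins QRS detection.

    Classic stages: 5-15 Hz band-pass, five-point derivative, squaring,
    moving-window integration (150 ms), adaptive dual thresholds on both
    the integrated and the filtered signal with search-back for missed
    beats, and a refractory period. Detected fiducials are refined to the
    local maximum of the band-passed ECG.
    """
    ecg = np.asarray(ecg, dtype=float)
    if rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if ecg.size < 5 * rate:
        raise ValueError("need at least 5 s of ECG")
    if np.ptp(ecg) == 0:
        warnings.warn("flat ECG signal: no R peaks detected")
        return RRSeries(np.empty(0), np.empty(0),
                        np.empty(0, dtype=object))

    filt = bandpass_filter(ecg, rate, 5.0, 15.0, order=2)
    deriv = np.convolve(filt, np.array([1, 2, 0, -2, -1]) * rate / 8.0,
                        mode="same")
    squared = deriv ** 2
    win = max(int(round(0.150 * rate)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    # candidate fiducials: local maxima of the integrated signal
    min_dist = max(int(round(refractory * rate)), 1)
    locs, _ = sig.find_peaks(mwi, distance=min_dist)
    if locs.size == 0:
        warnings.warn("no candidate peaks in integrated signal")
        return RRSeries(np.empty(0), np.empty(0),
                        np.empty(0, dtype=object))

    # adaptive thresholds (integrated signal), initialized on the first 2 s;
    # a small global floor guards against silent stretches, where a purely
    # adaptive threshold would collapse to zero and accept filter ringing
    floor = 0.02 * float(mwi.max())
    head = mwi[: int(2 * rate)]
    spki = max(float(head.max()) / 3.0, floor)
    npki = float(np.mean(head)) / 2.0
    threshold = npki + 0.25 * (spki - npki)

    peaks: list[int] = []
    rr_avg: list[float] = []
    for loc in locs:
        val = mwi[loc]
        is_beat = False
        if val > max(threshold, floor):
            is_beat = True
        elif peaks and rr_avg:
            # search-back: accept a half-threshold peak if the expected
            # beat is overdue (> 1.66 x running RR average)
            if (loc - peaks[-1]) > 1.66 * np.mean(rr_avg[-8:]) * rate \
                    and val > max(0.5 * threshold, floor):
                is_beat = True
        if is_beat:
            if peaks and (loc - peaks[-1]) < min_dist:
                if val > mwi[peaks[-1]]:
                    peaks[-1] = loc
                continue
            if peaks:
                rr_avg.append((loc - peaks[-1]) / rate)
            peaks.append(loc)
            spki = 0.125 * val + 0.875 * spki
        else:
            npki = 0.125 * val + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

    if len(peaks) < 2:
        warnings.warn("fewer than 2 beats detected")
        return RRSeries(np.empty(0), np.empty(0),
                        np.empty(0, dtype=object))

    # refine each fiducial to the local maximum of the band-passed ECG,
    # compensating the integrator group delay
    half = int(round(0.100 * rate))
    refined = []
    for loc in peaks:
        a = max(loc - half, 0)
        b = min(loc + half // 2 + 1, filt.size)
        refined.append(a + int(np.argmax(filt[a:b])))
    refined = np.unique(refined)
    return RRSeries.from_peaks(refined / rate)


# ------------------------------------------------------------ R-R cleaning ----

def gesd_outliers(x, alpha: float = 0.05,
                  max_outliers: int | None = None) -> np.ndarray:
    """Indices of outliers by the generalized extreme studentized deviate
    test (two-sided).

    Iteratively removes the most extreme value and compares each test
    statistic R_i against its critical value lambda_i; the declared outlier
    count is the largest i with R_i > lambda_i.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(int(np.ceil(0.1 * n)), 1)
    max_outliers = min(max_outliers, n - 2)
    if max_outliers < 1:
        return np.empty(0, dtype=int)

    remaining = np.arange(n)
    removed: list[int] = []
    stats_r: list[float] = []
    for i in range(1, max_outliers + 1):
        vals = x[remaining]
        sd = vals.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(vals - vals.mean())
        j = int(np.argmax(dev))
        stats_r.append(dev[j] / sd)
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)

    n_out = 0
    for i, r in enumerate(stats_r, start=1):
        m = n - i + 1                      # sample size at step i
        prob = 1.0 - alpha / (2.0 * m)
        tcrit = sps.t.ppf(prob, m - 2)
        lam = (m - 1) * tcrit / np.sqrt((m - 2 + tcrit ** 2) * m)
        if r > lam:
            n_out = i
    return np.asarray(removed[:n_out], dtype=int)


def clean_rr(rr: RRSeries, max_rel_change: float = 0.3,
             gesd_alpha: float = 0.05,
             gesd_max_outliers: int | None = None) -> RRSeries:
    """Two-stage R-R artifact repair with linear interpolation.

    Stage 1 flags intervals whose relative change versus the previous kept
    interval exceeds ``max_rel_change`` (physiologically implausible
    beat-to-beat jumps). Stage 2 applies a two-sided GESD test to the
    survivors. All flagged values are replaced by linear interpolation of
    the kept intervals over interval midpoint time; edge gaps are filled by
    nearest-value extension.
    """
    n = rr.rr_intervals.size
    if n < 5:
        raise ValueError("need at least 5 R-R intervals")
    vals = rr.rr_intervals.astype(float).copy()
    flags = np.full(n, "kept", dtype=object)

    last = vals[0]
    for i in range(1, n):
        if abs(vals[i] - last) / last > max_rel_change:
            flags[i] = "rel_change"
        else:
            last = vals[i]

    survivors = np.flatnonzero(flags == "kept")
    if survivors.size >= 5:
        out = gesd_outliers(vals[survivors], alpha=gesd_alpha,
                            max_outliers=gesd_max_outliers)
        flags[survivors[out]] = "gesd"

    kept = np.flatnonzero(flags == "kept")
    if kept.size == 0:
        raise ValueError("all R-R intervals flagged as artifacts")
    bad = np.flatnonzero(flags != "kept")
    if bad.size:
        t = rr.midpoint_times
        vals[bad] = np.interp(t[bad], t[kept], vals[kept])
    return RRSeries(rr.r_peak_times.copy(), vals, flags)


# ------------------------------------------------------------ HR conversion ----

def rr_to_hr(rr: RRSeries, target_rate: float = 256.0,
             t_start: float | None = None,
             t_end: float | None = None) -> HRSignal:
    """Instantaneous HR (bpm) on a uniform grid.

    HR = 60 / RR is assigned at each interval's midpoint and linearly
    interpolated onto the target grid; beyond the first/last midpoint the
    edge value is held. The midpoint series is piecewise linear, so direct
    linear interpolation onto the final grid is exact for it.
    """
    if rr.rr_intervals.size < 2:
        raise ValueError("need at least 2 R-R intervals")
    if np.any(rr.rr_intervals <= 0):
        raise ValueError("non-positive R-R interval")
    hr = 60.0 / rr.rr_intervals
    mid = rr.midpoint_times
    t0 = mid[0] if t_start is None else t_start
    t1 = mid[-1] if t_end is None else t_end
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate
    samples = np.interp(grid, mid, hr)
    return HRSignal(samples=samples, rate=target_rate, start_time=t0)


def baseline_correct_hr(hr: HRSignal,
                        baseline_windows: dict[str, tuple[float, float]],
                        phase_windows: dict[str, tuple[float, float]]
                        ) -> HRSignal:
    """Per-phase HR change from the immediately preceding rest baseline.

    Within each phase span the output is HR minus the mean HR over that
    phase's baseline window; samples outside any phase are left unchanged.
    Baseline means are stored on the returned signal.
    """
    t = hr.times()
    out = hr.samples.astype(float).copy()
    means: dict[str, float] = {}
    for phase, (b0, b1) in baseline_windows.items():
        if b1 - b0 < 2.0:
            raise ValueError(f"baseline window for {phase} shorter than 2 s")
        if b0 < t[0] - 1e-9 or b1 > t[-1] + 1e-9:
            raise ValueError(f"baseline window for {phase} outside recording")
        mask = (t >= b0) & (t < b1)
        if not mask.any():
            raise ValueError(f"baseline window for {phase} has no samples")
        mu = float(hr.samples[mask].mean())
        means[phase] = mu
        p0, p1 = phase_windows[phase]
        pmask = (t >= p0) & (t < p1)
        out[pmask] = hr.samples[pmask] - mu
    return HRSignal(samples=out, rate=hr.rate, start_time=hr.start_time,
                    baseline_mean_by_phase=means)
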