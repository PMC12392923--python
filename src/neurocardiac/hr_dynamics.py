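"""Response-locked heart-rate dynamics.

Around each response (t = 0) the baseline-corrected HR shows a transient
deceleration (parasympathetic dip) followed by re-acceleration
(sympathetic rebound). This module epochs HR into -4..+6 s windows,
builds participant-level and grand-average traces, and extracts seven
trajectory features per participant-phase average trace:

    dip_onset_time, dip_time, dip_magnitude, dip_duration,
    rebound_magnitude, rebound_time, rebound_duration

The dip onset is the first point before the HR minimum where HR velocity
turns negative after a period of near-zero change; magnitudes are the
drop from onset to minimum and the rise from minimum to the next local
maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as ssig
from scipy import stats as sps

from .containers import HREpochs, HRSignal, HRTrajectoryFeatures, HR_FEATURES
from .stats import bh_adjust

__all__ = [
    "DipConfig", "epoch_hr", "grand_average", "extract_dip_rebound",
    "compute_trajectory_features", "pointwise_phase_comparison",
]


@dataclass(frozen=True)
class DipConfig:
    """Tunables of the dip/rebound extractor.

    smooth_s: centered moving-average width for the velocity estimate (s).
    search_window: dip search interval around the response (s).
    plateau_eps: |velocity| bound defining "near-zero change" (bpm/s).
    plateau_s: minimum plateau duration before the dip onset (s).
    onset_eps: velocity magnitude (bpm/s) whose downward crossing marks the
        dip onset inside the negative-velocity run; a pure sign test would
        place the onset half a smoothing window early because the moving
        average spreads the descent backward in time.
    """

    smooth_s: float = 0.25
    search_window: tuple[float, float] = (-2.0, 2.0)
    plateau_eps: float = 1.0
    plateau_s: float = 0.25
    onset_eps: float = 0.2
    #: minimum prominence (bpm) for the rebound peak; absorbs the ripple
    #: that beat-interval sampling leaves on averaged traces
    rebound_prominence: float = 0.25


def epoch_hr(hr: HRSignal, events: pd.DataFrame,
             window: tuple[float, float] = (-4.0, 6.0)) -> HREpochs:
    """Per-trial HR slices on a common time axis relative to response.

    Trials whose window extends beyond the recording are dropped with a
    warning; an error is raised if nothing is left.
    """
    lo, hi = window
    n_win = int(round((hi - lo) * hr.rate))
    times = lo + np.arange(n_win) / hr.rate
    rows, slices = [], []
    dropped = 0
    for _, ev in events.iterrows():
        start = int(round((ev["response_onset"] + lo - hr.start_time)
                          * hr.rate))
        if start < 0 or start + n_win > hr.samples.size:
            dropped += 1
            continue
        slices.append(hr.samples[start:start + n_win])
        rows.append(ev)
    if not rows:
        raise ValueError("no usable trials inside the HR recording")
    if dropped:
        warnings.warn(f"dropped {dropped} HR trial(s) at recording edge")
    return HREpochs(data=np.stack(slices), times=times,
                    metadata=pd.DataFrame(rows).reset_index(drop=True),
                    n_dropped=dropped)


def participant_traces(epochs: HREpochs,
                       by: list[str]) -> pd.DataFrame:
    """Within-participant trial averages, one row per participant x cell."""
    meta = epochs.metadata.reset_index(drop=True)
    keys = ["participant"] + [k for k in by if k != "participant"]
    rows = []
    for key_vals, idx in meta.groupby(keys, sort=True,
                                      observed=True).groups.items():
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        trace = epochs.data[np.asarray(idx)].mean(axis=0)
        row = dict(zip(keys, key_vals))
        if "sex" in meta.columns and "sex" not in row:
            row["sex"] = meta.loc[idx[0], "sex"]
        row["trace"] = trace
        rows.append(row)
    return pd.DataFrame(rows)


def grand_average(epochs: HREpochs,
                  by: list[str] = ("phase",)) -> pd.DataFrame:
    """Grand-average traces with standard errors.

    Trials are first averaged within participant, then averaged across
    participants per cell; the SE is the cross-participant standard error.
    Cells with fewer than 2 participants are omitted with a warning.
    """
    by = [b for b in by]
    part = participant_traces(epochs, by)
    rows = []
    group_keys = by if by else lambda _: True
    for key_vals, sub in part.groupby(group_keys, sort=True, observed=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        traces = np.stack(sub["trace"].to_list())
        if traces.shape[0] < 2:
            warnings.warn(f"cell {key_vals}: fewer than 2 participants, "
                          "omitted")
            continue
        row = dict(zip(by, key_vals))
        row["mean"] = traces.mean(axis=0)
        row["se"] = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
        row["n_participants"] = traces.shape[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["times"] = epochs.times
    return out


def extract_dip_rebound(trace: np.ndarray, times: np.ndarray,
                        config: DipConfig = DipConfig()
                        ) -> HRTrajectoryFeatures:
    """Seven dip/rebound features of one average HR trace.

    Velocity is the gradient of the moving-average-smoothed trace. The dip
    is the global minimum inside the search window (it must be a genuine
    local minimum, otherwise the feature set is flagged invalid). The onset
    is found by walking backward through the contiguous negative-velocity
    run; the rebound is the first local maximum after the dip, or the
    window end if none exists (noted).
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = float(np.mean(np.diff(times)))
    invalid = HRTrajectoryFeatures(*([np.nan] * 7), valid=False)

    def movavg(x: np.ndarray, width_s: float) -> np.ndarray:
        k = max(int(round(width_s / dt)), 1)
        if k % 2 == 0:
            k += 1
        padded = np.pad(x, k // 2, mode="edge")
        return np.convolve(padded, np.ones(k) / k, mode="valid")

    smoothed = movavg(trace, config.smooth_s)
    # velocity for segmentation uses a wider window: averaged HR traces
    # carry beat-interval ripple that would break sign-based run walks
    velocity = np.gradient(movavg(trace, 2.0 * config.smooth_s), dt)

    lo, hi = config.search_window
    win = np.flatnonzero((times >= lo) & (times <= hi))
    if win.size < 3:
        return invalid
    i_dip = int(win[np.argmin(smoothed[win])])
    interior = win[0] < i_dip < win[-1]
    is_local_min = (i_dip > 0 and i_dip < times.size - 1
                    and smoothed[i_dip] <= smoothed[i_dip - 1]
                    and smoothed[i_dip] <= smoothed[i_dip + 1])
    if not (interior and is_local_min):
        invalid.notes = "no local minimum inside search window"
        return invalid

    # onset: from the steepest point of the descent, walk back through the
    # contiguous negative-velocity run, then take the point where the
    # velocity first crossed below -onset_eps (the departure from
    # near-zero change)
    pre_win = np.arange(max(win[0], 1), i_dip + 1)
    if pre_win.size < 2:
        invalid.notes = "dip at search-window edge"
        return invalid
    i_steep = int(pre_win[np.argmin(velocity[pre_win])])
    i = i_steep
    while i > 0 and velocity[i - 1] < 0:
        i -= 1
    run_start = i
    below = np.flatnonzero(velocity[run_start:i_steep + 1]
                           <= -config.onset_eps)
    i_onset = run_start + int(below[0]) if below.size else run_start
    n_plateau = max(int(round(config.plateau_s / dt)), 1)
    notes = ""
    pre = velocity[max(run_start - n_plateau, 0):run_start]
    if pre.size < n_plateau or np.any(np.abs(pre) >= config.plateau_eps):
        notes = "no near-zero plateau before onset; run start used"

    # rebound: first sufficiently prominent local maximum after the dip;
    # fall back to the first occurrence of the post-dip maximum (the window
    # end for monotone recovery)
    post = smoothed[i_dip:]
    peaks, _ = ssig.find_peaks(post, prominence=config.rebound_prominence) \
        if post.size > 2 else (np.empty(0, dtype=int), None)
    if peaks.size:
        i_reb = i_dip + int(peaks[0])
    else:
        i_reb = i_dip + int(np.argmax(post))
        notes = (notes + "; " if notes else "") + \
            "no prominent local maximum after dip; post-dip maximum used"

    return HRTrajectoryFeatures(
        dip_onset_time=float(times[i_onset]),
        dip_time=float(times[i_dip]),
        dip_magnitude=float(smoothed[i_onset] - smoothed[i_dip]),
        dip_duration=float(times[i_dip] - times[i_onset]),
        rebound_magnitude=float(smoothed[i_reb] - smoothed[i_dip]),
        rebound_time=float(times[i_reb]),
        rebound_duration=float(times[i_reb] - times[i_dip]),
        valid=True, notes=notes,
    )


def compute_trajectory_features(epochs: HREpochs,
                                config: DipConfig = DipConfig()
                                ) -> pd.DataFrame:
    """Dip/rebound features per participant x phase average trace."""
    part = participant_traces(epochs, ["phase", "phase_code"])
    rows = []
    for _, row in part.iterrows():
        feats = extract_dip_rebound(np.asarray(row["trace"]), epochs.times,
                                    config)
        rec = {k: row[k] for k in ("participant", "sex", "phase",
                                   "phase_code") if k in row}
        rec.update({k: getattr(feats, k) for k in HR_FEATURES})
        rec["valid"] = feats.valid
        rec["notes"] = feats.notes
        rows.append(rec)
    return pd.DataFrame(rows)


def pointwise_phase_comparison(epochs: HREpochs,
                               pair: tuple[str, str],
                               alpha: float = 0.05) -> pd.DataFrame:
    """Paired per-timepoint comparison of two phases.

    Participant-level mean traces are compared with a two-sided Wilcoxon
    signed-rank test at every timepoint; BH adjustment runs across
    timepoints within the comparison. Returns time, p, p_adj and the
    significance mask.
    """
    phase_a, phase_b = pair
    part = participant_traces(epochs, ["phase"])
    a = part[part["phase"] == phase_a].set_index("participant")["trace"]
    b = part[part["phase"] == phase_b].set_index("participant")["trace"]
    common = a.index.intersection(b.index)
    if common.size < 2:
        raise ValueError("need paired traces for both phases")
    if common.size < 6:
        warnings.warn("fewer than 6 participants: negligible test power")
    mat_a = np.stack(a.loc[common].to_list())
    mat_b = np.stack(b.loc[common].to_list())

    n_t = mat_a.shape[1]
    p = np.ones(n_t)
    for j in range(n_t):
        d = mat_a[:, j] - mat_b[:, j]
        if np.allclose(d, 0):
            continue
        p[j] = sps.wilcoxon(d, alternative="two-sided",
                            zero_method="wilcox").pvalue
    p_adj = bh_adjust(p)
    return pd.DataFrame({
        "time": epochs.times, "p": p, "p_adj": p_adj,
        "significant": p_adj < alpha,
    })
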