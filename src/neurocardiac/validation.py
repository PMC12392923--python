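"""Ground-truth recovery experiments.

Each function runs one self-contained validation of the pipeline against
the synthetic generator's known parameters and returns plain numbers:
R-peak/HR round trips, dip/rebound feature recovery, null calibration and
planted-effect detection of the channel-wise mixed-model t-maps, and
sex-interaction recovery for the HR trajectory features. Used by the
test suite and the acceptance script.

Simulation scales (participant counts, trials, rep counts) are chosen so
each experiment isolates the property under test; statistical recovery
experiments run at the feature level, where the generator's planted
parameters enter the simulated features directly, because waveform-level
replication adds nothing to those hypotheses (the waveform chain is
validated separately by the round-trip experiments).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sig

from . import ecg, eeg_features, hr_dynamics, stats
from .containers import HR_FEATURES
from .montage import CHANNELS
from .synth import (CohortSpec, HRFeatureEffect, dip_template_trace,
                    expected_hr_profile, generate_ecg, generate_eeg,
                    generate_events, session_layout, simulate_hr_features)

__all__ = [
    "ecg_round_trip", "dip_recovery_zero_noise", "dip_recovery_with_noise",
    "tmap_null_calibration", "tmap_planted_detection",
    "sex_interaction_detection", "eeg_planted_sign_recovery",
]


def _noiseless_spec(seed: int, **kw) -> CohortSpec:
    # fixed, widely spaced responses keep successive dip/rebound templates
    # from overlapping, so the instantaneous profile stays within the
    # curvature that beat-interval sampling can represent
    return CohortSpec(n_female=1, n_male=1, runs_per_phase=2,
                      trials_per_run=8, rt_mean_by_phase=(14.0, 14.0, 14.0),
                      rt_sd_by_phase=(0.0, 0.0, 0.0), inter_trial_gap=3.0,
                      hrv_noise_sd=0.0, ecg_noise_sd=0.0,
                      ecg_wander_amp=0.0, seed=seed, **kw)


def ecg_round_trip(seed: int = 0) -> dict[str, float]:
    """Noiseless cohort: R-peak detection and HR reconstruction fidelity.

    Returns sensitivity/precision of Pan-Tompkins R peaks at +/-10 ms
    against the generator's exact R times, and the maximum absolute error
    (bpm) of the reconstructed instantaneous HR against the generative
    profile, excluding 1-s edges.
    """
    spec = _noiseless_spec(seed)
    events = generate_events(spec)
    recordings, truth = generate_ecg(spec, events)
    n_true = n_det = n_hit_true = n_hit_det = 0
    max_err = 0.0
    for pid, rec in recordings.items():
        x = ecg.bandpass_filter(rec.data[0], rec.rate)
        x = ecg.notch_filter(x, rec.rate)
        rr = ecg.detect_r_peaks(x, rec.rate)
        det = rr.r_peak_times
        true = truth.r_peak_times[pid]
        n_true += true.size
        n_det += det.size
        n_hit_true += int(np.sum(np.min(
            np.abs(true[:, None] - det[None, :]), axis=1) <= 0.010))
        n_hit_det += int(np.sum(np.min(
            np.abs(det[:, None] - true[None, :]), axis=1) <= 0.010))
        hr = ecg.rr_to_hr(ecg.clean_rr(rr), 256.0, t_start=0.0,
                          t_end=rec.duration)
        tgrid, profile = expected_hr_profile(spec, events, truth, pid)
        t = hr.times()
        m = (t > 1.0) & (t < rec.duration - 1.0)
        err = np.abs(hr.samples[m] - np.interp(t[m], tgrid, profile))
        max_err = max(max_err, float(err.max()))
    return {"sensitivity": n_hit_true / n_true,
            "precision": n_hit_det / n_det,
            "hr_max_abs_error_bpm": max_err,
            "n_beats": n_true}


def _template_truth(tpl, recovery: float) -> dict[str, float]:
    dip_time = tpl.onset + tpl.duration
    return {"dip_onset_time": tpl.onset, "dip_time": dip_time,
            "dip_magnitude": tpl.magnitude, "dip_duration": tpl.duration,
            "rebound_magnitude": tpl.rebound_magnitude,
            "rebound_time": dip_time + tpl.rebound_duration,
            "rebound_duration": tpl.rebound_duration}


def dip_recovery_zero_noise(rate: float = 256.0) -> dict[str, float]:
    """Extract the seven features from exact template traces.

    Returns the worst absolute timing error (s) and magnitude error (bpm)
    across the female and male default templates.
    """
    spec = CohortSpec()
    times = np.arange(-4.0, 6.0, 1.0 / rate)
    worst_t = worst_m = 0.0
    for tpl in (spec.dip_template_female, spec.dip_template_male):
        trace = dip_template_trace(
            times, tpl.onset, tpl.magnitude, tpl.duration,
            tpl.rebound_magnitude, tpl.rebound_duration,
            spec.recovery_duration)
        feats = hr_dynamics.extract_dip_rebound(trace, times)
        assert feats.valid
        truth = _template_truth(tpl, spec.recovery_duration)
        for key in HR_FEATURES:
            err = abs(getattr(feats, key) - truth[key])
            if "magnitude" in key:
                worst_m = max(worst_m, err)
            else:
                worst_t = max(worst_t, err)
    return {"max_timing_error_s": worst_t,
            "max_magnitude_error_bpm": worst_m}


def dip_recovery_with_noise(n_seeds: int = 50, n_trials: int = 75,
                            noise_sd: float = 1.0, rate: float = 256.0,
                            seed: int = 0) -> dict[str, float]:
    """Bias of dip/rebound recovery from noisy trial-averaged traces.

    Each replicate builds a participant-phase average trace: the default
    female template plus the mean of ``n_trials`` independent HRV-like
    noise realizations (white noise low-passed at 0.4 Hz, SD ``noise_sd``
    bpm per trial). Returns the mean signed errors across replicates.
    """
    spec = CohortSpec()
    tpl = spec.dip_template_female
    times = np.arange(-4.0, 6.0, 1.0 / rate)
    template = dip_template_trace(
        times, tpl.onset, tpl.magnitude, tpl.duration,
        tpl.rebound_magnitude, tpl.rebound_duration, spec.recovery_duration)
    truth = _template_truth(tpl, spec.recovery_duration)
    sos = sig.butter(2, 0.4, btype="low", fs=rate, output="sos")
    rng = np.random.default_rng(seed)
    errs = {"dip_magnitude": [], "rebound_magnitude": [],
            "dip_onset_time": [], "dip_time": []}
    n_valid = 0
    for _ in range(n_seeds):
        white = rng.standard_normal((n_trials, times.size))
        slow = sig.sosfiltfilt(sos, white, axis=-1)
        slow *= noise_sd / slow.std(axis=-1, keepdims=True)
        trace = template + slow.mean(axis=0)
        feats = hr_dynamics.extract_dip_rebound(trace, times)
        if not feats.valid:
            continue
        n_valid += 1
        for key in errs:
            errs[key].append(getattr(feats, key) - truth[key])
    return {f"{k}_bias": float(np.mean(v)) for k, v in errs.items()} | \
        {"n_valid": n_valid, "n_seeds": n_seeds}


# ------------------------------------------------------ t-map simulations ----

def _simulated_run_table(rng, n_participants: int = 25,
                         runs_per_phase: int = 5, intercept_sd: float = 0.02,
                         run_noise_sd: float = 0.01,
                         planted_channel: str | None = None,
                         slope: float = 0.018) -> pd.DataFrame:
    """Run-level relative-power table with optional single-channel plant.

    Emulates the waveform pipeline's run-level output scales: participant
    random intercepts (SD 0.02 on the relative-power scale) and run-level
    estimation noise (SD 0.01, the SE of a 15-trial run mean).
    """
    n_phases = 3
    phase = np.repeat(np.arange(1, n_phases + 1), runs_per_phase)
    n_runs = phase.size
    rows = []
    for i in range(n_participants):
        icpt = rng.normal(0.0, intercept_sd, size=len(CHANNELS))
        noise = rng.normal(0.0, run_noise_sd, size=(len(CHANNELS), n_runs))
        for ci, ch in enumerate(CHANNELS):
            y = 0.22 + icpt[ci] + noise[ci]
            if ch == planted_channel:
                y = y + slope * (phase - 2.0)
            for j in range(n_runs):
                rows.append({"participant": f"P{i:02d}", "sex": 1,
                             "channel": ch, "phase_code": phase[j],
                             "run": j % runs_per_phase + 1, "relT": y[j]})
    return pd.DataFrame(rows)


def tmap_null_calibration(n_sims: int = 200, seed: int = 0,
                          **kw) -> dict[str, float]:
    """Mean fraction of BH-significant channels under the null."""
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_sims):
        table = _simulated_run_table(rng, planted_channel=None, **kw)
        tmap = stats.build_t_map(table, "relT", "phase_code")
        fractions.append(tmap["significant"].mean())
    return {"mean_significant_fraction": float(np.mean(fractions)),
            "n_sims": n_sims}


def tmap_planted_detection(n_seeds: int = 100, seed: int = 1000,
                           channel: str = "P4", slope: float = 0.018,
                           **kw) -> dict[str, float]:
    """Detection rate of a single planted positive channel effect.

    A detection is the planted channel being BH-significant with the
    correct sign; also reports how often its |t| dominates the median of
    the other channels.
    """
    rng = np.random.default_rng(seed)
    detected = dominated = 0
    for _ in range(n_seeds):
        table = _simulated_run_table(rng, planted_channel=channel,
                                     slope=slope, **kw)
        tmap = stats.build_t_map(table, "relT", "phase_code")
        row = tmap.set_index("channel").loc[channel]
        others = tmap[tmap["channel"] != channel]["t"].abs()
        if bool(row["significant"]) and row["t"] > 0:
            detected += 1
        if abs(row["t"]) > others.median():
            dominated += 1
    return {"detection_rate": detected / n_seeds,
            "median_dominance_rate": dominated / n_seeds,
            "n_seeds": n_seeds}


def sex_interaction_detection(n_cohorts: int = 100, seed: int = 2000,
                              onset_slope_male: float = -0.5
                              ) -> dict[str, float]:
    """Recovery of a planted male-only dip-onset x PASA effect.

    Each cohort draws participant x phase dip/rebound features from the
    generator templates with the male dip onset advanced by
    ``onset_slope_male`` seconds per centered PASA unit; the full
    feature x predictor OLS grid is fitted and the sex x PASA interaction
    on dip onset must be BH-significant with the planted (negative) sign.
    """
    base = CohortSpec()
    spec = base.replace(hr_feature_effects=(
        HRFeatureEffect("magnitude", "pasa", 0.3, 0.3),
        HRFeatureEffect("onset", "pasa", 0.0, onset_slope_male)))
    detected = 0
    for i in range(n_cohorts):
        feats = simulate_hr_features(spec, seed=seed + i)
        grid = stats.fit_sex_interaction(feats)
        row = grid[(grid["feature"] == "dip_onset_time")
                   & (grid["term"] == "sex:pasa")]
        if len(row) == 1 and bool(row["significant"].iloc[0]) \
                and float(row["t"].iloc[0]) < 0:
            detected += 1
    return {"detection_rate": detected / n_cohorts, "n_cohorts": n_cohorts}


def eeg_planted_sign_recovery(n_seeds: int = 20, seed: int = 3000,
                              channel: str = "F3", feature: str = "relT"
                              ) -> dict[str, float]:
    """Full waveform chain: sign recovery of a planted band-power slope.

    Small cohorts (1 F + 1 M, 3 runs x 5 trials, short responses) are
    synthesized end to end; the planted negative frontal theta-vs-phase
    slope (generator default) must yield a negative channel-wise LME t at
    the planted channel.
    """
    from .pipeline import PipelineConfig, process_participant_eeg
    config = PipelineConfig()
    correct = 0
    for i in range(n_seeds):
        spec = CohortSpec(n_female=1, n_male=1, runs_per_phase=3,
                          trials_per_run=5,
                          rt_mean_by_phase=(3.0, 2.2, 2.6),
                          rt_sd_by_phase=(0.6, 0.4, 0.5),
                          artifact_rate=0.0, seed=seed + i)
        events = generate_events(spec)
        tables = []
        for pid in spec.participants()["participant"]:
            recs, _ = generate_eeg(spec, events, participants=[pid])
            table, _ = process_participant_eeg(recs[pid], events, config)
            tables.append(table)
        run_table = eeg_features.aggregate_by_run(
            pd.concat(tables, ignore_index=True))
        sub = run_table[run_table["channel"] == channel]
        res = stats.fit_lme_random_intercept(
            sub[feature].to_numpy(), sub["phase_code"].to_numpy(),
            sub["participant"].to_numpy())
        if res.tvalue < 0:
            correct += 1
    return {"sign_match_rate": correct / n_seeds, "n_seeds": n_seeds}
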