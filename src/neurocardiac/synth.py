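"""Synthetic cohort generator with known ground truth.

Emulates a mental-arithmetic stress study: three sequential phases
(control, stress 1, stress 2), five runs of fifteen trials each, 10-s
rest baselines before each phase, time pressure in the stress phases
(the allotted time is 90% of the participant's mean control response
time), phase-dependent error rates and response times with a learning
trend, mood (BMIS) and stress-appraisal (PASA) questionnaires,
single-lead ECG whose instantaneous heart rate carries sex-specific
response-locked dip/rebound templates, and 32-channel EEG whose
band-power composition carries planted covariate effects with
participant-level random intercepts.

Every stochastic quantity derives from one integer seed through fixed
per-participant, per-modality substreams, so identical spec + seed
reproduce every output bit for bit, and every planted parameter is
returned as ground truth for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sig
from scipy import stats as spstats

from . import behavior
from .containers import ContinuousRecording, EVENT_COLUMNS
from .montage import CHANNELS, MIDLINE, pair_of

__all__ = [
    "DipTemplate", "HRFeatureEffect", "PlantedEffect", "CohortSpec",
    "GroundTruth", "generate_events", "generate_questionnaires",
    "generate_ecg", "generate_eeg", "dip_template_trace", "session_layout",
    "simulate_hr_features", "nominal_pasa_by_phase", "expected_hr_profile",
]

# substream domains
_EVENTS, _QUEST, _ECG, _EEG, _FEATURES = 0, 1, 2, 3, 4

BAND_NAMES = ("D", "T", "A", "B", "G")
#: Bandwidth-matched generation bands (identical to the analysis bands).
GEN_BANDS = {"D": (0.5, 3.5), "T": (4.0, 7.5), "A": (8.0, 12.5),
             "B": (13.0, 30.0), "G": (30.0, 60.0)}


def _rng(seed: int, domain: int, participant_index: int = 0):
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(domain, participant_index))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class DipTemplate:
    """Response-locked HR excursion, parameterized by its own features.

    onset: s relative to response (negative = before).
    magnitude: bpm drop from onset level to the minimum.
    duration: s from onset to minimum.
    rebound_magnitude: bpm rise from the minimum to the rebound peak;
        values above ``magnitude`` put the peak above baseline so the
        subsequent return to baseline makes it a genuine local maximum.
    rebound_duration: s from minimum to rebound peak.
    """

    onset: float = -1.2
    magnitude: float = 4.0
    duration: float = 2.8
    rebound_magnitude: float = 5.0
    rebound_duration: float = 3.0


@dataclass(frozen=True)
class HRFeatureEffect:
    """Planted covariate effect on one dip-template parameter.

    ``param`` is a DipTemplate field; slopes are per unit of the centered
    predictor, separately for females and males (sex-specific slopes are
    what the sex x predictor interaction models recover).
    """

    param: str
    predictor: str                      # "pasa" | "phase" | "error_rate"
    slope_female: float
    slope_male: float


@dataclass(frozen=True)
class PlantedEffect:
    """Planted linear effect on one channel's band-power composition.

    ``band`` is one of D/T/A/B/G or "alpha_lat" (opposite-signed alpha
    modulation of the channel and its homologous partner). The slope acts
    on the band's variance-share weight per unit of the centered predictor.
    """

    channel: str
    band: str
    predictor: str                      # "phase" | "pasa" | "error_rate"
    slope: float


@dataclass(frozen=True)
class CohortSpec:
    """All generator parameters. Defaults are the emulated study design."""

    n_female: int = 13
    n_male: int = 12
    phases: tuple[str, ...] = ("control", "stress1", "stress2")
    runs_per_phase: int = 5
    trials_per_run: int = 15
    baseline_duration: float = 10.0     # s rest before each phase
    inter_trial_gap: float = 1.0        # s feedback/fixation between trials
    inter_run_gap: float = 5.0          # s fixation between runs
    post_phase_gap: float = 10.0        # s questionnaire pause after a phase
    eeg_rate: float = 500.0
    ecg_rate: float = 256.0

    # behavior
    rt_mean_by_phase: tuple[float, ...] = (7.0, 3.7, 5.1)
    rt_sd_by_phase: tuple[float, ...] = (2.5, 1.1, 1.6)
    rt_participant_sd: float = 0.12     # lognormal sigma of the RT factor
    control_max_time: float = 30.0      # s cap in the untimed control phase
    error_rate_by_phase: tuple[float, ...] = (0.031, 0.148, 0.378)
    learning_slope_by_phase: tuple[float, ...] = (-0.008, -0.010, 0.0)

    # heart rate; dip/rebound transitions are kept slow enough (>= ~2.8 s)
    # that the beat-interval-sampled HR can represent them faithfully
    hr_base_female: float = 78.0
    hr_base_male: float = 70.0
    hr_participant_sd: float = 2.5
    hr_phase_offsets: tuple[float, ...] = (0.0, -3.0, -5.0)
    dip_template_female: DipTemplate = DipTemplate(
        onset=-1.2, magnitude=4.0, duration=2.8,
        rebound_magnitude=5.0, rebound_duration=3.0)
    dip_template_male: DipTemplate = DipTemplate(
        onset=-1.6, magnitude=3.5, duration=3.0,
        rebound_magnitude=4.3, rebound_duration=3.2)
    recovery_duration: float = 2.5      # s rebound peak back to baseline
    hr_feature_effects: tuple[HRFeatureEffect, ...] = (
        HRFeatureEffect("magnitude", "pasa", 0.3, 0.3),
        HRFeatureEffect("onset", "pasa", 0.0, -0.3),
    )
    hr_feature_noise: tuple[float, float, float] = (0.15, 0.8, 0.2)
    hrv_noise_sd: float = 1.0           # bpm
    ecg_noise_sd: float = 0.02          # mV
    ecg_wander_amp: float = 0.10        # mV at 0.25 Hz

    # EEG
    eeg_band_weights: Mapping[str, float] = field(
        default_factory=lambda: {"D": 0.30, "T": 0.22, "A": 0.25,
                                 "B": 0.15, "G": 0.08})
    planted_effects: tuple[PlantedEffect, ...] = (
        PlantedEffect("F3", "T", "phase", -0.02),
        PlantedEffect("Fz", "T", "phase", -0.02),
        PlantedEffect("F4", "T", "phase", -0.02),
        PlantedEffect("P4", "B", "phase", 0.02),
        PlantedEffect("P8", "B", "phase", 0.02),
        PlantedEffect("P4", "alpha_lat", "phase", 0.015),
    )
    participant_intercept_sd: float = 0.02   # weight scale per channel-band
    eeg_amplitude_uv: float = 15.0           # target rms of clean EEG
    artifact_rate: float = 0.01
    artifact_amp_uv: float = 180.0

    # questionnaires
    pasa_phase_effect: tuple[float, ...] = (0.0, 1.0, 1.5)
    pasa_base_index: float = 0.5
    pasa_participant_sd: float = 0.5
    pasa_item_sd: float = 0.7
    bmis_pre_shift: float = 0.5
    bmis_post_shift: float = -0.5
    bmis_item_sd: float = 0.6

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_female < 0 or self.n_male < 0 or \
                self.n_female + self.n_male == 0:
            raise ValueError("need at least one participant")
        for name in ("runs_per_phase", "trials_per_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eeg_rate <= 0 or self.ecg_rate <= 0:
            raise ValueError("sampling rates must be positive")
        n_ph = len(self.phases)
        for name in ("rt_mean_by_phase", "rt_sd_by_phase",
                     "error_rate_by_phase", "learning_slope_by_phase",
                     "hr_phase_offsets", "pasa_phase_effect"):
            if len(getattr(self, name)) != n_ph:
                raise ValueError(f"{name} must have {n_ph} entries")
        if any(m <= 0 for m in self.rt_mean_by_phase):
            raise ValueError("rt_mean_by_phase entries must be positive")
        if any(not 0 <= e <= 1 for e in self.error_rate_by_phase):
            raise ValueError("error rates must lie in [0, 1]")
        for tpl in (self.dip_template_female, self.dip_template_male):
            if tpl.magnitude < 0 or tpl.rebound_magnitude < 0:
                raise ValueError("dip magnitudes must be non-negative")
            if tpl.duration <= 0 or tpl.rebound_duration <= 0:
                raise ValueError("dip durations must be positive")
        if any(w < 0 for w in self.eeg_band_weights.values()):
            raise ValueError("band weights must be non-negative")
        for eff in self.planted_effects:
            if eff.channel not in CHANNELS:
                raise ValueError(f"unknown channel {eff.channel!r} in "
                                 "planted_effects")
            if eff.band not in BAND_NAMES + ("alpha_lat",):
                raise ValueError(f"unknown band {eff.band!r}")
            if eff.band == "alpha_lat" and eff.channel in MIDLINE:
                raise ValueError("laterality plant needs a lateral channel")

    def replace(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)

    @property
    def n_participants(self) -> int:
        return self.n_female + self.n_male

    def participants(self) -> pd.DataFrame:
        ids = [f"P{i + 1:02d}" for i in range(self.n_participants)]
        sex = [1] * self.n_female + [2] * self.n_male   # 1 = F, 2 = M
        return pd.DataFrame({"participant": ids, "sex": sex})

    def dip_template(self, sex: int) -> DipTemplate:
        return self.dip_template_female if sex == 1 else \
            self.dip_template_male


@dataclass
class GroundTruth:
    """Planted parameters of one generated cohort."""

    hr_params: pd.DataFrame | None = None       # per participant x phase
    r_peak_times: dict = field(default_factory=dict)
    hr_intercepts: dict = field(default_factory=dict)
    eeg_intercepts: pd.DataFrame | None = None  # participant, channel, band
    planted_effects: tuple = ()
    predictor_centers: dict = field(default_factory=dict)
    artifact_trials: pd.DataFrame | None = None


# ------------------------------------------------------------------ events ----

def generate_events(spec: CohortSpec) -> pd.DataFrame:
    """Trial-level event table for the whole cohort.

    Response times follow a truncated lognormal with the phase mean/SD
    (scaled by a per-participant factor); draws beyond the allotted time
    become unanswered trials, coded incorrect with the maximum time as the
    response time. Correctness is Bernoulli with the phase error rate plus
    a learning trend across runs (centered on the middle run). Stress-phase
    allotted time is 90% of the participant's mean control response time.
    """
    spec.validate()
    parts = spec.participants()
    run_center = (spec.runs_per_phase + 1) / 2.0
    records: list[dict] = []

    for pidx, prow in parts.iterrows():
        rng = _rng(spec.seed, _EVENTS, pidx)
        rt_factor = float(np.exp(rng.normal(0.0, spec.rt_participant_sd)))
        t = 0.0
        control_mean_rt: float | None = None
        for ph_idx, phase in enumerate(spec.phases):
            mu = spec.rt_mean_by_phase[ph_idx] * rt_factor
            sd = spec.rt_sd_by_phase[ph_idx] * rt_factor
            if phase == spec.phases[0]:
                max_time = spec.control_max_time
            else:
                assert control_mean_rt is not None
                max_time = 0.9 * control_mean_rt
            # lognormal by moment matching on the untruncated law
            if sd > 0:
                s2 = np.log1p((sd / mu) ** 2)
                mu_ln, sd_ln = np.log(mu) - s2 / 2.0, np.sqrt(s2)
            else:
                mu_ln, sd_ln = np.log(mu), 0.0
            # the phase error rate is the TOTAL error probability
            # (timeouts count as errors); discount the analytic timeout
            # probability from the wrong-answer rate
            if sd_ln > 0:
                z = (np.log(max_time) - mu_ln) / sd_ln
                p_timeout = float(spstats.norm.sf(z))
            else:
                p_timeout = float(mu > max_time)
            denom = max(1.0 - p_timeout, 1e-12)

            t += spec.baseline_duration
            phase_rts = []
            for run in range(1, spec.runs_per_phase + 1):
                target = float(np.clip(
                    spec.error_rate_by_phase[ph_idx]
                    + spec.learning_slope_by_phase[ph_idx]
                    * (run - run_center), 0.0, 1.0))
                p_err = float(np.clip((target - p_timeout) / denom,
                                      0.0, 1.0))
                for trial in range(1, spec.trials_per_run + 1):
                    raw = float(rng.lognormal(mu_ln, sd_ln)) if sd_ln > 0 \
                        else mu
                    answered = raw <= max_time
                    rt = raw if answered else max_time
                    err = bool(rng.random() < p_err)
                    correct = answered and not err
                    records.append({
                        "participant": prow["participant"],
                        "sex": prow["sex"], "phase": phase,
                        "phase_code": ph_idx + 1, "run": run, "trial": trial,
                        "stimulus_onset": t, "response_onset": t + rt,
                        "response_time": rt, "correct": correct,
                        "answered": answered, "max_time": max_time,
                    })
                    phase_rts.append(rt)
                    t += rt + spec.inter_trial_gap
                if run < spec.runs_per_phase:
                    t += spec.inter_run_gap
            if phase == spec.phases[0]:
                control_mean_rt = float(np.mean(phase_rts))
            t += spec.post_phase_gap
    return pd.DataFrame.from_records(records, columns=EVENT_COLUMNS)


def session_layout(spec: CohortSpec, events: pd.DataFrame,
                   participant: str) -> dict:
    """Per-phase baseline/task windows and total duration for one session."""
    ev = events[events["participant"] == participant]
    baselines, spans, tasks = {}, {}, {}
    starts = []
    for phase in spec.phases:
        sub = ev[ev["phase"] == phase]
        start = float(sub["stimulus_onset"].min())
        end = float(sub["response_onset"].max())
        baselines[phase] = (start - spec.baseline_duration, start)
        tasks[phase] = (start, end + spec.inter_trial_gap)
        starts.append(start - spec.baseline_duration)
    duration = float(ev["response_onset"].max()) + spec.post_phase_gap
    # correction regions partition the recording so every sample (incl.
    # the trailing gap after a phase) is corrected against some baseline
    edges = starts[1:] + [duration]
    for phase, s, e in zip(spec.phases, starts, edges):
        spans[phase] = (s, e)
    return {"baseline_windows": baselines, "phase_windows": spans,
            "task_windows": tasks, "duration": duration}


# ---------------------------------------------------------- questionnaires ----

def nominal_pasa_by_phase(spec: CohortSpec) -> dict[str, float]:
    """Expected PASA stress index per phase under the generator."""
    return {ph: spec.pasa_base_index + spec.pasa_phase_effect[i]
            for i, ph in enumerate(spec.phases)}


def _pasa_items_from_index(index: float, rng, item_sd: float) -> dict:
    """Item responses whose mean-scored global index equals ``index``.

    primary = 3.5 + index/2 and secondary = 3.5 - index/2 on the 1-6 item
    scale; reverse-scored items are answered as 7 minus the latent value.
    """
    half = float(np.clip(index / 2.0, -2.5, 2.5))
    target = {"threat": 3.5 + half, "challenge": 3.5 + half,
              "self_efficacy": 3.5 - half, "control_expectancy": 3.5 - half}
    out = {}
    for subscale, defs in behavior.PASA_ITEMS.items():
        if item_sd > 0:
            latents = [target[subscale] + rng.normal(0.0, item_sd)
                       for _ in defs]
        else:
            # noiseless: distribute the subscale total over the four items
            # so the scored mean hits the target to 0.25-point resolution
            # instead of losing the effect to per-item rounding
            total = int(np.clip(np.round(4.0 * target[subscale]), 4, 24))
            base, extra = divmod(total, 4)
            latents = [base + 1 if i < extra else base
                       for i in range(len(defs))]
        for (key, rev), latent in zip(defs, latents):
            resp = 7.0 - latent if rev else latent
            out[key] = int(np.clip(np.round(resp), 1, 6))
    return out


def generate_questionnaires(spec: CohortSpec,
                            seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Item-level BMIS (pre/post) and PASA (per phase) responses.

    Returns ``{"bmis": ..., "pasa": ...}``. PASA responses shift toward
    higher perceived stress across phases by ``pasa_phase_effect`` on the
    global-index scale; BMIS items shift by the pre/post mood offsets.
    """
    spec.validate()
    seed = spec.seed if seed is None else seed
    parts = spec.participants()
    bmis_rows, pasa_rows = [], []
    for pidx, prow in parts.iterrows():
        rng = _rng(seed, _QUEST, pidx)
        for admin, shift in (("pre", spec.bmis_pre_shift),
                             ("post", spec.bmis_post_shift)):
            items = {}
            for adj in behavior.BMIS_POSITIVE:
                v = 2.5 + shift / 2.0 + (rng.normal(0, spec.bmis_item_sd)
                                         if spec.bmis_item_sd > 0 else 0.0)
                items[adj] = int(np.clip(np.round(v), 1, 4))
            for adj in behavior.BMIS_NEGATIVE:
                v = 2.5 - shift / 2.0 + (rng.normal(0, spec.bmis_item_sd)
                                         if spec.bmis_item_sd > 0 else 0.0)
                items[adj] = int(np.clip(np.round(v), 1, 4))
            score = behavior.score_bmis(items)
            bmis_rows.append({"participant": prow["participant"],
                              "sex": prow["sex"], "administration": admin,
                              **items, "score": score,
                              "overall_mood": int(np.clip(
                                  np.round(score / 2.4), -10, 10))})
        part_shift = (rng.normal(0.0, spec.pasa_participant_sd)
                      if spec.pasa_participant_sd > 0 else 0.0)
        for ph_idx, phase in enumerate(spec.phases):
            index = (spec.pasa_base_index + spec.pasa_phase_effect[ph_idx]
                     + part_shift)
            items = _pasa_items_from_index(index, rng, spec.pasa_item_sd)
            pasa_rows.append({"participant": prow["participant"],
                              "sex": prow["sex"], "phase": phase,
                              "phase_code": ph_idx + 1, **items})
    return {"bmis": pd.DataFrame(bmis_rows), "pasa": pd.DataFrame(pasa_rows)}


# ------------------------------------------------------------- HR templates ----

def _smoothstep(t: np.ndarray, t0: float, t1: float,
                v0: float, v1: float) -> np.ndarray:
    """Cubic Hermite step from (t0, v0) to (t1, v1), zero slope at knots."""
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return v0 + (v1 - v0) * u * u * (3.0 - 2.0 * u)


def dip_template_trace(times: np.ndarray, onset: float, magnitude: float,
                       duration: float, rebound_magnitude: float,
                       rebound_duration: float,
                       recovery_duration: float = 1.5) -> np.ndarray:
    """Evaluate the dip/rebound HR template (bpm) on ``times`` (s).

    Piecewise cubic-smoothed excursion: baseline 0 until ``onset``, descent
    to -magnitude over ``duration``, rise to the rebound peak
    (rebound_magnitude - magnitude) over ``rebound_duration``, cubic return
    to baseline over ``recovery_duration``, 0 afterwards.
    """
    t = np.asarray(times, dtype=float)
    t_dip = onset + duration
    t_reb = t_dip + rebound_duration
    t_end = t_reb + recovery_duration
    peak = rebound_magnitude - magnitude
    out = np.zeros_like(t)
    m = (t > onset) & (t <= t_dip)
    out[m] = _smoothstep(t[m], onset, t_dip, 0.0, -magnitude)
    m = (t > t_dip) & (t <= t_reb)
    out[m] = _smoothstep(t[m], t_dip, t_reb, -magnitude, peak)
    m = (t > t_reb) & (t <= t_end)
    out[m] = _smoothstep(t[m], t_reb, t_end, peak, 0.0)
    return out


def _template_params_for(spec: CohortSpec, sex: int, pasa_c: float,
                         phase_c: float, err_c: float) -> dict[str, float]:
    """Template parameters after applying planted covariate effects."""
    tpl = spec.dip_template(sex)
    params = {"onset": tpl.onset, "magnitude": tpl.magnitude,
              "duration": tpl.duration,
              "rebound_magnitude": tpl.rebound_magnitude,
              "rebound_duration": tpl.rebound_duration}
    centered = {"pasa": pasa_c, "phase": phase_c, "error_rate": err_c}
    for eff in spec.hr_feature_effects:
        slope = eff.slope_female if sex == 1 else eff.slope_male
        params[eff.param] += slope * centered.get(eff.predictor, 0.0)
    params["magnitude"] = max(params["magnitude"], 0.0)
    params["rebound_magnitude"] = max(params["rebound_magnitude"], 0.0)
    params["duration"] = max(params["duration"], 0.05)
    params["rebound_duration"] = max(params["rebound_duration"], 0.05)
    return params


def _predictor_centers(spec: CohortSpec) -> dict[str, float]:
    nominal = nominal_pasa_by_phase(spec)
    return {
        "pasa": float(np.mean(list(nominal.values()))),
        "phase": float(np.mean(np.arange(1, len(spec.phases) + 1))),
        "error_rate": float(np.mean(spec.error_rate_by_phase)),
    }


def _pasa_index_lookup(pasa_scores: pd.DataFrame | None, spec: CohortSpec):
    nominal = nominal_pasa_by_phase(spec)
    def lookup(participant: str, phase: str) -> float:
        if pasa_scores is not None:
            hit = pasa_scores[(pasa_scores["participant"] == participant)
                              & (pasa_scores["phase"] == phase)]
            if len(hit):
                return float(hit["index"].iloc[0])
        return nominal[phase]
    return lookup


# ------------------------------------------------------------------- ECG ----

_PROFILE_RATE = 64.0  # Hz grid of the instantaneous-HR profile


def _phase_params(spec: CohortSpec, events: pd.DataFrame, participant: str,
                  sex: int, pasa_lookup, centers: dict) -> list[dict]:
    """Covariate-adjusted template parameters, one dict per phase."""
    out = []
    ev = events[events["participant"] == participant]
    for ph_idx, phase in enumerate(spec.phases):
        pasa_c = pasa_lookup(participant, phase) - centers["pasa"]
        phase_c = (ph_idx + 1) - centers["phase"]
        sub = ev[ev["phase"] == phase]
        err_c = float(1.0 - sub["correct"].mean()) - centers["error_rate"]
        params = _template_params_for(spec, sex, pasa_c, phase_c, err_c)
        out.append({"phase": phase, "phase_code": ph_idx + 1, **params})
    return out


def _hr_profile(spec: CohortSpec, events: pd.DataFrame, participant: str,
                layout: dict, base: float, params_by_phase: list[dict],
                rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous HR (bpm) on the profile grid.

    ``base`` already includes the participant intercept; HRV noise is added
    only when ``rng`` is given.
    """
    n = int(np.ceil(layout["duration"] * _PROFILE_RATE)) + 1
    t = np.arange(n) / _PROFILE_RATE
    hr = np.full(n, base)

    # task-induced phase offsets: smooth 2-s ramps inside the phase span,
    # decaying back to base during the inter-phase rest
    for ph_idx, phase in enumerate(spec.phases):
        off = spec.hr_phase_offsets[ph_idx]
        if off == 0.0:
            continue
        s, e = layout["task_windows"][phase]
        ramp = min(4.0, (e - s) / 4.0)
        m = (t >= s) & (t < e + ramp)
        tt = t[m]
        track = np.where(tt < s + ramp,
                         _smoothstep(tt, s, s + ramp, 0.0, off),
                         np.where(tt < e, off,
                                  _smoothstep(tt, e, e + ramp, off, 0.0)))
        hr[m] += track

    # response-locked dip/rebound templates
    ev = events[events["participant"] == participant]
    for entry in params_by_phase:
        params = {k: entry[k] for k in ("onset", "magnitude", "duration",
                                        "rebound_magnitude",
                                        "rebound_duration")}
        sub = ev[ev["phase"] == entry["phase"]]
        span = (params["onset"], params["onset"] + params["duration"]
                + params["rebound_duration"] + spec.recovery_duration)
        for resp in sub["response_onset"].to_numpy():
            i0 = max(int((resp + span[0]) * _PROFILE_RATE) - 1, 0)
            i1 = min(int(np.ceil((resp + span[1]) * _PROFILE_RATE)) + 1, n)
            hr[i0:i1] += dip_template_trace(
                t[i0:i1] - resp, recovery_duration=spec.recovery_duration,
                **params)

    if rng is not None and spec.hrv_noise_sd > 0:
        white = rng.standard_normal(n)
        sos = sig.butter(2, 0.4, btype="low", fs=_PROFILE_RATE, output="sos")
        slow = sig.sosfiltfilt(sos, white)
        sd = slow.std()
        if sd > 0:
            hr += slow / sd * spec.hrv_noise_sd
    if np.any(hr <= 0):
        raise ValueError("instantaneous HR profile non-positive; "
                         "check spec magnitudes and offsets")
    return t, hr


def expected_hr_profile(spec: CohortSpec, events: pd.DataFrame,
                        truth: "GroundTruth", participant: str
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free instantaneous HR profile implied by stored ground truth."""
    rows = truth.hr_params[truth.hr_params["participant"] == participant]
    if rows.empty:
        raise KeyError(f"no ground truth for {participant}")
    layout = session_layout(spec, events, participant)
    params_by_phase = rows.to_dict("records")
    return _hr_profile(spec, events, participant, layout,
                       float(rows["base_hr"].iloc[0]), params_by_phase)


def _qrs_template(rate: float) -> tuple[np.ndarray, int]:
    """Stereotyped P-QRS-T waveform (mV); returns (samples, apex index)."""
    t = np.arange(int(-0.30 * rate), int(0.45 * rate) + 1) / rate
    def bump(amp, mu, sigma):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    wave = (bump(0.10, -0.18, 0.025)      # P
            + bump(-0.15, -0.035, 0.008)  # Q
            + bump(1.00, 0.0, 0.012)      # R
            + bump(-0.20, 0.035, 0.010)   # S
            + bump(0.25, 0.25, 0.050))    # T
    return wave, int(0.30 * rate)


def generate_ecg(spec: CohortSpec, events: pd.DataFrame,
                 pasa_scores: pd.DataFrame | None = None,
                 participants: Iterable[str] | None = None
                 ) -> tuple[dict[str, ContinuousRecording], GroundTruth]:
    """Synthesize single-lead ECG per participant.

    The instantaneous HR profile (sex base rate + participant intercept +
    task-phase offsets + per-response dip/rebound templates + band-limited
    HRV noise) is integrated to R-peak times; the waveform is a stereotyped
    1-mV QRS template at each R time plus baseline wander and measurement
    noise. Ground truth carries the exact R times and template parameters.
    """
    spec.validate()
    parts = spec.participants()
    if participants is not None:
        wanted = set(participants)
        parts = parts[parts["participant"].isin(wanted)]
    centers = _predictor_centers(spec)
    lookup = _pasa_index_lookup(pasa_scores, spec)
    truth = GroundTruth(planted_effects=spec.hr_feature_effects,
                        predictor_centers=centers)
    recordings: dict[str, ContinuousRecording] = {}
    truth_frames = []
    template, apex = _qrs_template(spec.ecg_rate)

    for pidx, prow in spec.participants().iterrows():
        pid = prow["participant"]
        if pid not in set(parts["participant"]):
            continue
        rng = _rng(spec.seed, _ECG, pidx)
        intercept = float(rng.normal(0.0, spec.hr_participant_sd)) \
            if spec.hr_participant_sd > 0 else 0.0
        layout = session_layout(spec, events, pid)
        base = (spec.hr_base_female if prow["sex"] == 1
                else spec.hr_base_male) + intercept
        params_by_phase = _phase_params(spec, events, pid, prow["sex"],
                                        lookup, centers)
        tgrid, hr = _hr_profile(spec, events, pid, layout, base,
                                params_by_phase, rng)
        truth_frames.append(pd.DataFrame(
            [{"participant": pid, "sex": prow["sex"], "base_hr": base, **p}
             for p in params_by_phase]))
        truth.hr_intercepts[pid] = intercept

        # integrate beats: R peaks where the cumulative beat count crosses
        # successive integers
        beats = np.concatenate([[0.0], np.cumsum(
            (hr[1:] + hr[:-1]) / 2.0 / 60.0 / _PROFILE_RATE)])
        n_beats = int(np.floor(beats[-1]))
        r_times = np.interp(np.arange(1, n_beats + 1), beats, tgrid)
        truth.r_peak_times[pid] = r_times

        n_samp = int(np.ceil(layout["duration"] * spec.ecg_rate))
        wave = np.zeros(n_samp)
        idx = np.round(r_times * spec.ecg_rate).astype(int)
        for i in idx:
            a, b = i - apex, i - apex + template.size
            ta, tb = max(a, 0), min(b, n_samp)
            if ta < tb:
                wave[ta:tb] += template[ta - a:template.size - (b - tb)]
        if spec.ecg_wander_amp > 0:
            phase0 = rng.uniform(0, 2 * np.pi)
            wave += spec.ecg_wander_amp * np.sin(
                2 * np.pi * 0.25 * np.arange(n_samp) / spec.ecg_rate + phase0)
        if spec.ecg_noise_sd > 0:
            wave += rng.normal(0.0, spec.ecg_noise_sd, n_samp)
        recordings[pid] = ContinuousRecording(
            data=wave[np.newaxis, :], rate=spec.ecg_rate,
            channel_names=["ECG"], modality="ecg", participant=pid)
    truth.hr_params = pd.concat(truth_frames, ignore_index=True) \
        if truth_frames else None
    return recordings, truth


# ------------------------------------------------------------------- EEG ----

def _band_gains(weights: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-bin spectral gains producing the requested band variance shares.

    ``weights`` is (n_channels, n_bands); returns (n_channels, n_freqs)
    amplitude gains for a white complex spectrum.
    """
    gains = np.zeros((weights.shape[0], freqs.size))
    for j, name in enumerate(BAND_NAMES):
        lo, hi = GEN_BANDS[name]
        m = (freqs >= lo) & (freqs < hi)
        nbins = max(int(m.sum()), 1)
        w = np.clip(weights[:, j], 0.0, None)
        gains[:, m] = np.sqrt(w / nbins)[:, None]
    return gains


def generate_eeg(spec: CohortSpec, events: pd.DataFrame,
                 pasa_scores: pd.DataFrame | None = None,
                 participants: Iterable[str] | None = None
                 ) -> tuple[dict[str, ContinuousRecording], GroundTruth]:
    """Synthesize 32-channel EEG with planted band-power structure.

    Each channel is a sum of band-limited Gaussian noise whose variance
    shares follow the channel's base profile plus planted linear effects of
    the centered predictors (phase, PASA index, run error rate) and a
    participant-level random intercept; laterality plants modulate the
    alpha share of a homologous pair in opposite directions. Pre-response
    analysis windows are synthesized trial by trial (with a short
    crossfade into the background) so each trial carries its own
    composition; occasional high-amplitude artifact trials are injected at
    ``artifact_rate``. Data are microvolts, float32.
    """
    spec.validate()
    all_parts = spec.participants()
    wanted = set(all_parts["participant"]) if participants is None \
        else set(participants)
    centers = _predictor_centers(spec)
    lookup = _pasa_index_lookup(pasa_scores, spec)
    base_w = np.tile(
        np.array([spec.eeg_band_weights[b] for b in BAND_NAMES]),
        (len(CHANNELS), 1))
    ch_index = {c: i for i, c in enumerate(CHANNELS)}
    band_index = {b: j for j, b in enumerate(BAND_NAMES)}

    recordings: dict[str, ContinuousRecording] = {}
    intercept_rows, artifact_rows = [], []
    fs = spec.eeg_rate
    margin = 0.25              # s of synthesis margin around the window
    fade = int(0.1 * fs)
    window = (-3.0 - margin, -0.5 + margin)
    n_win = int(round((window[1] - window[0]) * fs))
    freqs_win = np.fft.rfftfreq(n_win, 1.0 / fs)
    ramp = np.linspace(0.0, 1.0, fade)

    # run-level error rates (predictor for planted effects)
    err_by_run = (events.assign(err=lambda d: 1.0 - d["correct"])
                  .groupby(["participant", "phase", "run"], observed=True)
                  ["err"].mean())

    for pidx, prow in all_parts.iterrows():
        pid = prow["participant"]
        if pid not in wanted:
            continue
        rng = _rng(spec.seed, _EEG, pidx)
        layout = session_layout(spec, events, pid)
        n_samp = int(np.ceil(layout["duration"] * fs))

        icpt = rng.normal(0.0, spec.participant_intercept_sd,
                          size=base_w.shape) \
            if spec.participant_intercept_sd > 0 else np.zeros_like(base_w)
        for ci, ch in enumerate(CHANNELS):
            for bj, b in enumerate(BAND_NAMES):
                intercept_rows.append({"participant": pid, "channel": ch,
                                       "band": b, "intercept": icpt[ci, bj]})
        part_w = np.clip(base_w + icpt, 0.005, None)

        # full-length background with the participant's base composition
        freqs_full = np.fft.rfftfreq(n_samp, 1.0 / fs)
        gains_full = _band_gains(part_w, freqs_full)
        spectrum = (rng.standard_normal((len(CHANNELS), freqs_full.size))
                    + 1j * rng.standard_normal((len(CHANNELS),
                                                freqs_full.size)))
        data = np.fft.irfft(spectrum * gains_full, n=n_samp, axis=1)
        # complex-white spectrum with amplitude gains g has time-domain
        # variance 4/n^2 * sum(g^2); rescale to unit variance, then to the
        # target rms amplitude
        data *= n_samp / 2.0
        data *= spec.eeg_amplitude_uv

        ev = events[events["participant"] == pid]
        for _, trial in ev.iterrows():
            start = int(round((trial["response_onset"] + window[0]) * fs))
            if start < 0 or start + n_win > n_samp:
                continue
            pasa_c = lookup(pid, trial["phase"]) - centers["pasa"]
            phase_c = trial["phase_code"] - centers["phase"]
            err_c = float(err_by_run.loc[(pid, trial["phase"],
                                          trial["run"])]) \
                - centers["error_rate"]
            centered = {"pasa": pasa_c, "phase": phase_c,
                        "error_rate": err_c}
            w = part_w.copy()
            for eff in spec.planted_effects:
                delta = eff.slope * centered.get(eff.predictor, 0.0)
                if eff.band == "alpha_lat":
                    partner = pair_of(eff.channel)
                    w[ch_index[eff.channel], band_index["A"]] += delta
                    w[ch_index[partner], band_index["A"]] -= delta
                else:
                    w[ch_index[eff.channel], band_index[eff.band]] += delta
            w = np.clip(w, 0.005, None)
            gains = _band_gains(w, freqs_win)
            spec_w = (rng.standard_normal((len(CHANNELS), freqs_win.size))
                      + 1j * rng.standard_normal((len(CHANNELS),
                                                  freqs_win.size)))
            seg = np.fft.irfft(spec_w * gains, n=n_win, axis=1)
            seg *= n_win / 2.0 * spec.eeg_amplitude_uv
            # crossfade the margins into the background
            seg[:, :fade] = (1 - ramp) * data[:, start:start + fade] \
                + ramp * seg[:, :fade]
            seg[:, -fade:] = ramp[::-1] * data[:, start + n_win - fade:
                                               start + n_win] \
                + (1 - ramp[::-1]) * seg[:, -fade:]
            data[:, start:start + n_win] = seg

            if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
                ch = int(rng.integers(len(CHANNELS)))
                center = start + n_win // 2
                tt = (np.arange(n_samp) - center) / fs
                bump = spec.artifact_amp_uv * np.exp(
                    -0.5 * (tt[start:start + n_win] / 0.15) ** 2)
                data[ch, start:start + n_win] += bump
                artifact_rows.append({"participant": pid,
                                      "phase": trial["phase"],
                                      "run": trial["run"],
                                      "trial": trial["trial"],
                                      "channel": CHANNELS[ch]})

        recordings[pid] = ContinuousRecording(
            data=data.astype(np.float32), rate=fs,
            channel_names=list(CHANNELS), modality="eeg", participant=pid)

    truth = GroundTruth(
        eeg_intercepts=pd.DataFrame(intercept_rows),
        planted_effects=spec.planted_effects,
        predictor_centers=centers,
        artifact_trials=pd.DataFrame(
            artifact_rows, columns=["participant", "phase", "run", "trial",
                                    "channel"]))
    return recordings, truth


# ------------------------------------------- feature-level HR simulation ----

def simulate_hr_features(spec: CohortSpec, seed: int | None = None
                         ) -> pd.DataFrame:
    """Participant x phase dip/rebound features drawn from the templates.

    A lightweight stand-in for the full waveform chain used by the
    statistical recovery simulations: template parameters (with the
    planted covariate effects applied) receive extraction-level noise
    (``hr_feature_noise`` = timing, magnitude, duration SDs), and the
    seven features are derived so their ordering invariants hold by
    construction. Includes pasa, error_rate, relative_rt and phase_code
    predictor columns plus the numeric sex code.
    """
    spec.validate()
    seed = spec.seed if seed is None else seed
    centers = _predictor_centers(spec)
    t_sd, m_sd, d_sd = spec.hr_feature_noise
    rows = []
    for pidx, prow in spec.participants().iterrows():
        rng = _rng(seed, _FEATURES, pidx)
        rel_rt = float(np.exp(rng.normal(0.0, spec.rt_participant_sd)))
        part_pasa = rng.normal(0.0, spec.pasa_participant_sd)
        for ph_idx, phase in enumerate(spec.phases):
            pasa = (spec.pasa_base_index + spec.pasa_phase_effect[ph_idx]
                    + part_pasa)
            err = float(np.clip(spec.error_rate_by_phase[ph_idx]
                                + rng.normal(0.0, 0.03), 0.0, 1.0))
            params = _template_params_for(
                spec, prow["sex"], pasa - centers["pasa"],
                (ph_idx + 1) - centers["phase"], err - centers["error_rate"])
            onset = params["onset"] + rng.normal(0.0, t_sd)
            dur = max(params["duration"] + rng.normal(0.0, d_sd), 0.05)
            mag = max(params["magnitude"] + rng.normal(0.0, m_sd), 0.0)
            reb = max(params["rebound_magnitude"] + rng.normal(0.0, m_sd),
                      0.0)
            reb_dur = max(params["rebound_duration"]
                          + rng.normal(0.0, d_sd), 0.05)
            dip_time = onset + dur
            rows.append({
                "participant": prow["participant"], "sex": prow["sex"],
                "phase": phase, "phase_code": ph_idx + 1,
                "pasa": pasa, "error_rate": err, "relative_rt": rel_rt,
                "dip_onset_time": onset, "dip_time": dip_time,
                "dip_magnitude": mag, "dip_duration": dur,
                "rebound_magnitude": reb,
                "rebound_time": dip_time + reb_dur,
                "rebound_duration": reb_dur,
            })
    return pd.DataFrame(rows)
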