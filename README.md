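# neurocardiac

Response-locked neurocardiac analysis of acute mental stress: heart-rate
(HR) dip/rebound dynamics around behavioral responses, EEG relative
band-power features, and channel-wise mixed-model *t*-maps — driven by a
fully synthetic mental-arithmetic stress cohort with known ground truth.

## Who this is for

Psychophysiologists and biosignal engineers who study autonomic and
cortical stress responses in paradigms of the MIST family (mental
arithmetic under time pressure, noise and negative feedback) and want a
tested, reproducible reference implementation of the full analysis
chain — from raw ECG/EEG to effect-size maps — that can be validated
without access to any private recordings.

## What it computes

**Cardiac side.** ECG is band-passed (zero-phase Butterworth, 0.5–60 Hz)
and notch-filtered (50 Hz); R peaks come from the Pan–Tompkins algorithm;
R–R artifacts are repaired by a relative-change screen plus a generalized
extreme studentized deviate (GESD) pass with linear interpolation;
HR = 60/RR is resampled to a uniform 256-Hz grid and baseline-corrected
against the 10-s rest before each phase. Epochs locked to response onset
(−4…+6 s) yield, per participant × phase average trace, seven features:
dip onset time, dip time, dip magnitude, dip duration, rebound magnitude,
rebound time, rebound duration. Sex-moderated associations are tested
with OLS models `Y ~ sex * X` (X ∈ {error rate, PASA stress index, phase,
relative response time}).

**Cortical side.** EEG epochs (−3…−0.5 s before the response, ±100 µV
rejection) yield relative power in delta (0.5–3.5), theta (4–7.5), alpha
(8–12.5), beta (13–30) and gamma (30–60 Hz) bands normalized by the broad
0.5–60 Hz power, the θ/β and γ/θ ratios, and a whole-head alpha
laterality index ln(L) − ln(R) over homologous pairs. Channel-wise
random-intercept linear mixed models

    Y ~ X + (1 | participant),   fitted by maximum likelihood,

give fixed-effect *t*-maps with residual degrees of freedom
(df = n_obs − n_fixed), Benjamini–Hochberg correction across channels,
and Cohen's r = sign(t)·√(t²/(t²+df)). Wilcoxon rank tests (r = Z/√N)
cover the questionnaire and behavioral contrasts; the BMIS mood score and
the PASA stress-appraisal index are scored from item level.

**Synthetic cohort.** `neurocardiac.synth` generates the whole study —
events with phase-dependent response times, error rates, learning trends
and 0.9 × control-mean time limits; item-level BMIS/PASA responses; ECG
with sex-specific dip/rebound templates and exact R-peak ground truth;
32-channel EEG with planted channel × band covariate effects and
participant random intercepts — bit-for-bit reproducible from one seed.

## Worked example

```python
from neurocardiac import CohortSpec, synth, ecg, hr_dynamics

spec = CohortSpec(n_female=2, n_male=2, runs_per_phase=2,
                  trials_per_run=8, seed=42)
events = synth.generate_events(spec)
recordings, truth = synth.generate_ecg(spec, events)

rec = recordings["P01"]
x = ecg.notch_filter(ecg.bandpass_filter(rec.data[0], rec.rate), rec.rate)
rr = ecg.clean_rr(ecg.detect_r_peaks(x, rec.rate))
hr = ecg.rr_to_hr(rr, 256.0, t_start=0.0, t_end=rec.duration)
layout = synth.session_layout(spec, events, "P01")
hr_bc = ecg.baseline_correct_hr(hr, layout["baseline_windows"],
                                layout["phase_windows"])
epochs = hr_dynamics.epoch_hr(hr_bc, events[events.participant == "P01"])
print(hr_dynamics.compute_trajectory_features(epochs)
      [["phase", "dip_onset_time", "dip_time", "dip_magnitude",
        "rebound_magnitude"]].round(2).to_string(index=False))
```

prints

```
  phase  dip_onset_time  dip_time  dip_magnitude  rebound_magnitude
control           -1.07      1.49           3.67               4.55
stress1           -0.74      1.55           2.29               2.46
stress2           -1.12      1.44           3.19               4.03
```

P01 is female, so the generator planted a dip of 4.0 bpm starting 1.2 s
before the response (minimum at +1.6 s) with a 5.0-bpm rebound: the
recovered onsets, dip times and magnitudes track those values, with the
scatter expected from 16-trial averages and beat-interval sampling (HR is
only observable once per heartbeat). The same cohort's `detect_r_peaks`
finds all 458 beats of P01 with zero flagged R–R intervals.

The end-to-end pipeline (simulation → behavior → ECG/HR → EEG features →
t-maps → markdown report) runs from the command line:

```bash
stress-pipeline all --simulate --seed 7 --out results/demo \
    --n-female 2 --n-male 2 --runs-per-phase 2 --trials-per-run 6
```

Every output TSV carries a provenance header (config hash + seed);
re-running with the same config reproduces the directory byte for byte.
`stress-pipeline simulate/behavior/ecg/hr/eeg/stats/report` expose the
individual stages.

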