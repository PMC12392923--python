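"""Synthetic cohort generator: bookkeeping, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from neurocardiac import CohortSpec, ecg, eeg_features, synth
from neurocardiac.behavior import score_pasa_table


class TestEvents:
    def test_trial_bookkeeping(self, tiny_spec, tiny_events):
        per_part = tiny_events.groupby("participant").size()
        expected = len(tiny_spec.phases) * tiny_spec.runs_per_phase \
            * tiny_spec.trials_per_run
        assert (per_part == expected).all()
        assert np.allclose(
            tiny_events["response_onset"],
            tiny_events["stimulus_onset"] + tiny_events["response_time"])
        assert (tiny_events["response_time"]
                <= tiny_events["max_time"] + 1e-9).all()
        # trials are ordered in time without overlap, per participant
        for _, sub in tiny_events.groupby("participant"):
            assert (np.diff(sub["stimulus_onset"]) > 0).all()
            assert (sub["stimulus_onset"].to_numpy()[1:]
                    >= sub["response_onset"].to_numpy()[:-1]).all()

    def test_stress_time_limit_is_90pct_of_control_mean(self, tiny_events):
        for _, sub in tiny_events.groupby("participant"):
            control_mean = sub[sub["phase"] == "control"]["response_time"] \
                .mean()
            for phase in ("stress1", "stress2"):
                limit = sub[sub["phase"] == phase]["max_time"].unique()
                assert limit == pytest.approx(0.9 * control_mean)

    def test_unanswered_trials_coded_incorrect_at_limit(self):
        spec = CohortSpec(n_female=2, n_male=2, seed=3)
        ev = synth.generate_events(spec)
        timeouts = ev[~ev["answered"]]
        assert len(timeouts) > 0
        assert (~timeouts["correct"]).all()
        assert np.allclose(timeouts["response_time"], timeouts["max_time"])

    def test_zero_error_rates_give_all_correct(self):
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=2,
                          trials_per_run=10,
                          error_rate_by_phase=(0.0, 0.0, 0.0),
                          learning_slope_by_phase=(0.0, 0.0, 0.0),
                          rt_sd_by_phase=(0.0, 0.0, 0.0))
        assert synth.generate_events(spec)["correct"].all()

    def test_error_fraction_matches_binomial(self):
        """rt sd 0, flat rate 0.2, ~1e5 trials: within 3 binomial SDs."""
        spec = CohortSpec(n_female=1, n_male=0, phases=("control",),
                          runs_per_phase=40, trials_per_run=2500,
                          rt_mean_by_phase=(2.0,), rt_sd_by_phase=(0.0,),
                          error_rate_by_phase=(0.2,),
                          learning_slope_by_phase=(0.0,),
                          hr_phase_offsets=(0.0,), pasa_phase_effect=(0.0,),
                          seed=7)
        ev = synth.generate_events(spec)
        n = len(ev)
        assert n == 100_000
        frac = 1.0 - ev["correct"].mean()
        assert abs(frac - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / n)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synth.generate_events(
                CohortSpec(rt_mean_by_phase=(0.0, 3.7, 5.1)))

    def test_deterministic_for_seed(self, tiny_spec, tiny_events):
        again = synth.generate_events(tiny_spec)
        pd.testing.assert_frame_equal(tiny_events, again)
        other = synth.generate_events(tiny_spec.replace(seed=99))
        assert not other["response_time"].equals(tiny_events["response_time"])


class TestQuestionnaires:
    def test_item_bounds(self):
        spec = CohortSpec(n_female=4, n_male=4, seed=5,
                          bmis_item_sd=2.0, pasa_item_sd=2.0)
        q = synth.generate_questionnaires(spec)
        from neurocardiac.behavior import (BMIS_NEGATIVE, BMIS_POSITIVE,
                                           PASA_ITEM_KEYS)
        bmis_vals = q["bmis"][list(BMIS_POSITIVE + BMIS_NEGATIVE)]
        assert bmis_vals.min().min() >= 1 and bmis_vals.max().max() <= 4
        pasa_vals = q["pasa"][list(PASA_ITEM_KEYS)]
        assert pasa_vals.min().min() >= 1 and pasa_vals.max().max() <= 6

    def test_noiseless_midpoint_bmis_scores_zero(self):
        spec = CohortSpec(n_female=1, n_male=1, bmis_pre_shift=0.0,
                          bmis_post_shift=0.0, bmis_item_sd=0.0)
        q = synth.generate_questionnaires(spec)
        assert (q["bmis"]["score"] == 0).all()

    def test_planted_pasa_effect_is_monotone(self):
        spec = CohortSpec(n_female=3, n_male=3, pasa_item_sd=0.0,
                          pasa_participant_sd=0.0,
                          pasa_phase_effect=(0.0, 1.0, 2.0))
        scores = score_pasa_table(
            synth.generate_questionnaires(spec)["pasa"])
        means = scores.groupby("phase")["index"].mean()
        assert means["control"] < means["stress1"] < means["stress2"]


class TestECGGeneration:
    def test_constant_rate_without_templates(self):
        flat = synth.DipTemplate(magnitude=0.0, rebound_magnitude=0.0)
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=1,
                          trials_per_run=5, hr_base_female=60.0,
                          hr_participant_sd=0.0,
                          hr_phase_offsets=(0.0, 0.0, 0.0),
                          dip_template_female=flat, dip_template_male=flat,
                          hr_feature_effects=(), hrv_noise_sd=0.0,
                          ecg_noise_sd=0.0, ecg_wander_amp=0.0)
        events = synth.generate_events(spec)
        _, truth = synth.generate_ecg(spec, events)
        rr = np.diff(truth.r_peak_times["P01"])
        assert np.abs(rr - 1.0).max() < 1e-3

    def test_dip_minimum_reaches_template_depth(self):
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=1,
                          trials_per_run=6, hr_participant_sd=0.0,
                          rt_mean_by_phase=(14.0,) * 3,
                          rt_sd_by_phase=(0.0,) * 3, inter_trial_gap=3.0,
                          hrv_noise_sd=0.0, ecg_noise_sd=0.0,
                          ecg_wander_amp=0.0,
                          hr_feature_effects=())
        events = synth.generate_events(spec)
        recs, truth = synth.generate_ecg(spec, events)
        rec = recs["P01"]
        x = ecg.bandpass_filter(rec.data[0], rec.rate)
        rr = ecg.clean_rr(ecg.detect_r_peaks(x, rec.rate))
        hr = ecg.rr_to_hr(rr, 256.0)
        mag = spec.dip_template_female.magnitude
        base_rows = truth.hr_params
        base = float(base_rows["base_hr"].iloc[0])
        offsets = dict(zip(spec.phases, spec.hr_phase_offsets))
        layout = synth.session_layout(spec, events, "P01")
        t = hr.times()
        for phase, off in offsets.items():
            s, e = layout["task_windows"][phase]
            seg = hr.samples[(t >= s + 5) & (t < e)]
            assert seg.min() == pytest.approx(base + off - mag, abs=0.5)

    def test_waveform_determinism(self, tiny_spec, tiny_events):
        a, _ = synth.generate_ecg(tiny_spec, tiny_events,
                                  participants=["P01"])
        b, _ = synth.generate_ecg(tiny_spec, tiny_events,
                                  participants=["P01"])
        assert np.array_equal(a["P01"].data, b["P01"].data)
        c, _ = synth.generate_ecg(tiny_spec.replace(seed=42), tiny_events,
                                  participants=["P01"])
        assert not np.array_equal(a["P01"].data, c["P01"].data)

    def test_nonpositive_profile_rejected(self, tiny_spec, tiny_events):
        bad = tiny_spec.replace(hr_phase_offsets=(0.0, -200.0, -5.0))
        with pytest.raises(ValueError, match="non-positive"):
            synth.generate_ecg(bad, tiny_events, participants=["P01"])


class TestEEGGeneration:
    def test_single_band_weight_concentrates_power(self):
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=1,
                          trials_per_run=5, rt_mean_by_phase=(2.5,) * 3,
                          rt_sd_by_phase=(0.2,) * 3,
                          eeg_band_weights={"D": 0.0, "T": 1.0, "A": 0.0,
                                            "B": 0.0, "G": 0.0},
                          planted_effects=(), participant_intercept_sd=0.0,
                          artifact_rate=0.0, seed=2)
        events = synth.generate_events(spec)
        recs, _ = synth.generate_eeg(spec, events)
        rec = recs["P01"]
        epochs = eeg_features.epoch_eeg(
            rec, events[events["participant"] == "P01"])
        rel = np.stack([eeg_features.relative_band_power(epochs.data[i],
                                                         rec.rate)
                        for i in range(epochs.data.shape[0])])
        assert rel[:, :, 1].mean() >= 0.9          # theta share

    def test_artifact_free_trials_stay_under_threshold(self):
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=2,
                          trials_per_run=8, rt_mean_by_phase=(2.5,) * 3,
                          rt_sd_by_phase=(0.2,) * 3, artifact_rate=0.0,
                          seed=4)
        events = synth.generate_events(spec)
        recs, truth = synth.generate_eeg(spec, events)
        epochs = eeg_features.epoch_eeg(
            recs["P01"], events[events["participant"] == "P01"])
        assert np.abs(epochs.data).max() <= 100.0
        assert len(truth.artifact_trials) == 0

    def test_planted_artifacts_are_rejected_exactly(self):
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=2,
                          trials_per_run=8, rt_mean_by_phase=(2.5,) * 3,
                          rt_sd_by_phase=(0.2,) * 3, artifact_rate=0.3,
                          seed=8)
        events = synth.generate_events(spec)
        recs, truth = synth.generate_eeg(spec, events)
        epochs = eeg_features.epoch_eeg(
            recs["P01"], events[events["participant"] == "P01"])
        kept, log = eeg_features.reject_trials(epochs, 100.0)
        n_planted = len(truth.artifact_trials)
        assert n_planted > 0
        assert int((~log["kept"]).sum()) == n_planted
        rejected = set(map(tuple, log[~log["kept"]]
                           [["phase", "run", "trial"]].to_numpy()))
        planted = set(map(tuple, truth.artifact_trials
                          [["phase", "run", "trial"]].to_numpy()))
        assert rejected == planted

    def test_unknown_planted_channel_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="unknown channel"):
            tiny_spec.replace(planted_effects=(
                synth.PlantedEffect("XX", "T", "phase", 0.01),)).validate()

    def test_waveform_determinism(self):
        spec = CohortSpec(n_female=1, n_male=0, runs_per_phase=1,
                          trials_per_run=3, rt_mean_by_phase=(2.0,) * 3,
                          rt_sd_by_phase=(0.1,) * 3, seed=6)
        events = synth.generate_events(spec)
        a, _ = synth.generate_eeg(spec, events)
        b, _ = synth.generate_eeg(spec, events)
        assert np.array_equal(a["P01"].data, b["P01"].data)


class TestFeatureLevelSimulation:
    def test_ordering_invariants_hold(self):
        feats = synth.simulate_hr_features(CohortSpec(seed=13))
        assert (feats["dip_onset_time"] < feats["dip_time"]).all()
        assert (feats["dip_time"] < feats["rebound_time"]).all()
        assert np.allclose(feats["dip_duration"],
                           feats["dip_time"] - feats["dip_onset_time"])
        assert (feats["dip_magnitude"] >= 0).all()
        assert len(feats) == CohortSpec().n_participants * 3

    def test_planted_sex_slopes_enter_features(self):
        spec = CohortSpec(hr_feature_noise=(0.0, 0.0, 0.0),
                          pasa_participant_sd=0.0,
                          hr_feature_effects=(
                              synth.HRFeatureEffect("onset", "pasa",
                                                    0.0, -0.5),))
        feats = synth.simulate_hr_features(spec, seed=1)
        by_sex = feats.groupby(["sex", "phase"])["dip_onset_time"].mean()
        male_shift = by_sex[2]["stress2"] - by_sex[2]["control"]
        female_shift = by_sex[1]["stress2"] - by_sex[1]["control"]
        # male onset advances with the PASA increase, female tracks the
        # template only
        assert male_shift < -0.4
        assert abs(female_shift) < 0.05
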