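"""Response-locked HR epoching, averaging and dip/rebound extraction."""

import numpy as np
import pandas as pd
import pytest

from neurocardiac import CohortSpec, hr_dynamics, synth
from neurocardiac.containers import HREpochs, HRSignal
from neurocardiac.hr_dynamics import (DipConfig, epoch_hr,
                                      extract_dip_rebound, grand_average,
                                      pointwise_phase_comparison)

RATE = 256.0
TIMES = np.arange(-4.0, 6.0, 1.0 / RATE)


def _events(times, participant="P01", phase="control", sex=1):
    return pd.DataFrame({
        "participant": participant, "sex": sex, "phase": phase,
        "phase_code": 1, "run": 1, "trial": np.arange(1, len(times) + 1),
        "stimulus_onset": np.asarray(times) - 1.0,
        "response_onset": times, "response_time": 1.0,
        "correct": True, "answered": True, "max_time": 30.0})


def _epochs_from_traces(traces_by_cell):
    """traces_by_cell: list of (participant, phase, trace) trial entries."""
    rows, data = [], []
    for pid, phase, trace in traces_by_cell:
        rows.append({"participant": pid, "sex": 1, "phase": phase,
                     "phase_code": 1, "run": 1, "trial": 1})
        data.append(trace)
    return HREpochs(data=np.stack(data), times=TIMES,
                    metadata=pd.DataFrame(rows))


class TestEpochHR:
    def test_constant_signal_gives_constant_epochs(self):
        hr = HRSignal(samples=np.full(int(60 * RATE), 3.0), rate=RATE)
        epochs = epoch_hr(hr, _events([10.0, 30.0]))
        assert np.allclose(epochs.data, 3.0)
        assert epochs.data.shape == (2, TIMES.size)

    def test_planted_dip_minimum_at_expected_sample(self):
        spec = CohortSpec()
        tpl = spec.dip_template_female
        t_abs = np.arange(0, 60, 1 / RATE)
        samples = np.zeros(t_abs.size)
        for resp in (20.0, 40.0):
            samples += synth.dip_template_trace(
                t_abs - resp, tpl.onset, tpl.magnitude, tpl.duration,
                tpl.rebound_magnitude, tpl.rebound_duration,
                spec.recovery_duration)
        hr = HRSignal(samples=samples, rate=RATE)
        epochs = epoch_hr(hr, _events([20.0, 40.0]))
        for i in range(2):
            t_min = epochs.times[int(np.argmin(epochs.data[i]))]
            assert t_min == pytest.approx(tpl.onset + tpl.duration,
                                          abs=2 / RATE)

    def test_edge_trials_dropped_with_warning(self):
        hr = HRSignal(samples=np.zeros(int(30 * RATE)), rate=RATE)
        with pytest.warns(UserWarning, match="dropped"):
            epochs = epoch_hr(hr, _events([2.0, 10.0, 28.0]))
        assert epochs.data.shape[0] == 1 and epochs.n_dropped == 2


class TestGrandAverage:
    def test_identical_participants_zero_se(self):
        trace = np.sin(TIMES)
        epochs = _epochs_from_traces(
            [("A", "control", trace), ("B", "control", trace)])
        ga = grand_average(epochs, by=["phase"])
        assert np.allclose(ga["se"].iloc[0], 0.0)
        assert np.allclose(ga["mean"].iloc[0], trace)

    def test_two_opposite_participants(self):
        ones = np.ones(TIMES.size)
        epochs = _epochs_from_traces(
            [("A", "control", +ones), ("B", "control", -ones)])
        ga = grand_average(epochs, by=["phase"])
        assert np.allclose(ga["mean"].iloc[0], 0.0)
        assert np.allclose(ga["se"].iloc[0], 1.0)

    def test_trials_averaged_within_participant_first(self):
        ones = np.ones(TIMES.size)
        epochs = _epochs_from_traces(
            [("A", "control", 0 * ones), ("A", "control", 2 * ones),
             ("A", "control", 4 * ones), ("B", "control", 4 * ones)])
        ga = grand_average(epochs, by=["phase"])
        # participant means 2 and 4 -> grand mean 3 (not trial mean 2.5)
        assert np.allclose(ga["mean"].iloc[0], 3.0)

    def test_single_participant_cell_omitted(self):
        epochs = _epochs_from_traces([("A", "control", np.zeros(TIMES.size))])
        with pytest.warns(UserWarning, match="fewer than 2"):
            ga = grand_average(epochs, by=["phase"])
        assert len(ga) == 0


class TestExtractDipRebound:
    def test_symmetric_v_closed_form(self):
        trace = np.zeros(TIMES.size)
        falling = (TIMES >= -1.0) & (TIMES < 0.0)
        rising = (TIMES >= 0.0) & (TIMES < 1.0)
        trace[falling] = -6.0 * (TIMES[falling] + 1.0)
        trace[rising] = -6.0 * (1.0 - TIMES[rising])
        cfg = DipConfig(smooth_s=0.02, onset_eps=0.2)
        f = extract_dip_rebound(trace, TIMES, cfg)
        assert f.valid
        assert f.dip_onset_time == pytest.approx(-1.0, abs=0.05)
        assert f.dip_time == pytest.approx(0.0, abs=0.02)
        assert f.dip_magnitude == pytest.approx(6.0, abs=0.1)
        assert f.dip_duration == pytest.approx(1.0, abs=0.06)
        assert f.rebound_magnitude == pytest.approx(6.0, abs=0.1)
        assert f.rebound_time == pytest.approx(1.0, abs=0.05)
        assert f.rebound_duration == pytest.approx(1.0, abs=0.06)

    def test_template_recovery_zero_noise(self):
        spec = CohortSpec()
        for tpl in (spec.dip_template_female, spec.dip_template_male):
            trace = synth.dip_template_trace(
                TIMES, tpl.onset, tpl.magnitude, tpl.duration,
                tpl.rebound_magnitude, tpl.rebound_duration,
                spec.recovery_duration)
            f = extract_dip_rebound(trace, TIMES)
            assert f.valid
            assert f.dip_onset_time == pytest.approx(tpl.onset, abs=0.1)
            assert f.dip_time == pytest.approx(tpl.onset + tpl.duration,
                                               abs=0.1)
            assert f.dip_magnitude == pytest.approx(tpl.magnitude, abs=0.3)
            assert f.rebound_magnitude == pytest.approx(
                tpl.rebound_magnitude, abs=0.3)
            assert f.rebound_time == pytest.approx(
                tpl.onset + tpl.duration + tpl.rebound_duration, abs=0.1)

    def test_constant_trace_invalid(self):
        f = extract_dip_rebound(np.zeros(TIMES.size), TIMES)
        assert not f.valid

    def test_monotone_trace_invalid(self):
        f = extract_dip_rebound(-TIMES, TIMES)   # decreasing through window
        assert not f.valid

    def test_translation_equivariance(self):
        spec = CohortSpec()
        tpl = spec.dip_template_female
        trace = synth.dip_template_trace(
            TIMES, tpl.onset, tpl.magnitude, tpl.duration,
            tpl.rebound_magnitude, tpl.rebound_duration,
            spec.recovery_duration)
        f0 = extract_dip_rebound(trace, TIMES)
        f1 = extract_dip_rebound(trace + 17.3, TIMES)
        for key in ("dip_onset_time", "dip_time", "dip_magnitude",
                    "rebound_magnitude", "rebound_time"):
            assert getattr(f0, key) == pytest.approx(getattr(f1, key),
                                                     abs=1e-9)

    def test_magnitude_scales_linearly(self):
        spec = CohortSpec()
        tpl = spec.dip_template_female
        for k in (0.5, 2.0):
            trace = synth.dip_template_trace(
                TIMES, tpl.onset, k * tpl.magnitude, tpl.duration,
                k * tpl.rebound_magnitude, tpl.rebound_duration,
                spec.recovery_duration)
            f = extract_dip_rebound(trace, TIMES)
            assert f.dip_magnitude == pytest.approx(k * tpl.magnitude,
                                                    rel=0.05)

    def test_feature_ordering_invariant(self, rng):
        """onset < dip < rebound on noisy valid extractions."""
        spec = CohortSpec()
        tpl = spec.dip_template_female
        template = synth.dip_template_trace(
            TIMES, tpl.onset, tpl.magnitude, tpl.duration,
            tpl.rebound_magnitude, tpl.rebound_duration,
            spec.recovery_duration)
        for _ in range(20):
            trace = template + 0.2 * rng.standard_normal(TIMES.size)
            f = extract_dip_rebound(trace, TIMES)
            if not f.valid:
                continue
            assert f.dip_onset_time < f.dip_time < f.rebound_time
            assert f.dip_duration >= 0 and f.rebound_duration >= 0
            assert f.dip_magnitude >= 0 and f.rebound_magnitude >= 0


class TestPointwiseComparison:
    RATE_LOW = 16.0
    T_LOW = np.arange(-4.0, 6.0, 1.0 / RATE_LOW)

    def _epochs(self, rng, n_part=12, offset=0.0, span=(0.0, 2.0),
                noise=1.0):
        rows, data = [], []
        bump = ((self.T_LOW >= span[0]) & (self.T_LOW < span[1])).astype(float)
        for i in range(n_part):
            for phase, delta in (("control", 0.0), ("stress1", offset)):
                rows.append({"participant": f"P{i}", "sex": 1,
                             "phase": phase, "phase_code": 1, "run": 1,
                             "trial": 1})
                data.append(delta * bump
                            + noise * rng.standard_normal(self.T_LOW.size))
        return HREpochs(data=np.stack(data), times=self.T_LOW,
                        metadata=pd.DataFrame(rows))

    def test_identical_phases_nothing_significant(self, rng):
        epochs = self._epochs(rng, offset=0.0, noise=0.0)
        epochs.data += 1.0                       # identical traces
        out = pointwise_phase_comparison(epochs, ("control", "stress1"))
        assert not out["significant"].any()

    def test_planted_offset_detected_in_window(self, rng):
        hits = 0
        for _ in range(10):
            epochs = self._epochs(rng, n_part=25, offset=5.0)
            out = pointwise_phase_comparison(epochs, ("control", "stress1"))
            sig_times = out.loc[out["significant"], "time"]
            inside = sig_times.between(0.0, 2.0)
            hits += int(inside.any() and inside.mean() > 0.5)
        assert hits >= 9

    def test_null_family_error_rate_controlled(self, rng):
        any_sig = sum(
            pointwise_phase_comparison(
                self._epochs(rng, n_part=10, offset=0.0),
                ("control", "stress1"))["significant"].any()
            for _ in range(60))
        assert any_sig / 60 <= 0.10

    def test_requires_pairs(self, rng):
        epochs = self._epochs(rng, n_part=1)
        with pytest.raises(ValueError, match="paired"):
            pointwise_phase_comparison(
                epochs, ("control", "missing_phase"))
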