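import numpy as np
import pytest

from whiskthal.synthetic import SyntheticConfig, generate_whisking_trace
from whiskthal.whisking import (WhiskingTrace, decompose, normalize_angle,
                                phase_at, segment_states, STATE_WHISKING)

FS = 625.0


def times(duration):
    return np.arange(int(duration * FS)) / FS


def bout_angle(duration=4.0, bout=(1.5, 2.5), amp_p2p=10.0, freq=9.0):
    t = times(duration)
    env = ((t >= bout[0]) & (t < bout[1])).astype(float)
    return t, 0.5 * amp_p2p * env * np.cos(2 * np.pi * freq * t)


class TestNormalizeAngle:
    def test_constant_trace_goes_to_zero(self):
        assert np.allclose(normalize_angle(np.full(100, 10.0)), 0.0)

    def test_stationary_median_removed(self):
        t = times(4.0)
        angle = np.where(t < 2.0, 40.0, 40.0 + 10 * np.sin(2 * np.pi * 9 * t))
        out = normalize_angle(angle, stationary_mask=t < 2.0)
        assert np.allclose(out[t < 2.0], 0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        angle = rng.normal(size=500)
        mask = rng.random(500) < 0.5
        assert np.allclose(normalize_angle(angle + 17.3, mask),
                           normalize_angle(angle, mask))


class TestDecompose:
    def test_sinusoid_phase_and_amplitude(self):
        t = times(4.0)
        angle = 5.0 * np.cos(2 * np.pi * 9.0 * t)
        tr = decompose(angle, t)
        mid = slice(int(0.5 * FS), int(3.5 * FS))
        # phase convention: 0 at protraction peaks, +-pi at troughs
        peaks = np.nonzero(np.isclose(angle[mid], 5.0, atol=1e-3))[0]
        assert np.all(np.abs(tr.phase[mid][peaks]) < 0.2)
        # amplitude is peak-to-trough: |difference of consecutive extrema| = 10
        assert np.allclose(tr.amplitude[mid], 10.0, atol=0.5)
        assert np.all(tr.state[mid] == STATE_WHISKING)

    def test_slow_drift_rejected_by_band(self):
        # 5th-order Butterworth, 3 Hz low cutoff: |H(1 Hz)| ~ (1/3)^5, and
        # forward-backward filtering squares it -> ~2e-5 of 20 deg passes
        t = times(8.0)
        angle = 20.0 * np.sin(2 * np.pi * 1.0 * t)
        tr = decompose(angle, t)
        mid = slice(int(FS), int(7 * FS))
        assert np.max(np.abs(tr.angle_band[mid])) < 0.5
        assert np.all(tr.amplitude[mid] < 3.0)
        assert not np.any(tr.state == STATE_WHISKING)

    def test_zero_phase_filtering_preserves_peak_times(self):
        t = times(4.0)
        angle = 5.0 * np.cos(2 * np.pi * 9.0 * t)
        tr = decompose(angle, t)
        mid = slice(int(FS), int(3 * FS))
        raw_peaks = np.nonzero((angle[mid] > np.roll(angle[mid], 1))
                               & (angle[mid] > np.roll(angle[mid], -1)))[0]
        band = tr.angle_band[mid]
        band_peaks = np.nonzero((band > np.roll(band, 1)) & (band > np.roll(band, -1)))[0]
        for p in raw_peaks[1:-1]:
            assert np.min(np.abs(band_peaks - p)) <= 1

    def test_too_short_series_raises(self):
        t = times(0.02)
        with pytest.raises(ValueError, match="short"):
            decompose(np.zeros(t.size), t)

    def test_nonuniform_sampling_raises(self):
        t = times(2.0).copy()
        t[300] += 0.5 / FS
        with pytest.raises(ValueError, match="uniform"):
            decompose(np.zeros(t.size), t)

    def test_amplitude_invariant_under_sign_flip(self):
        t, angle = bout_angle()
        a1 = decompose(angle, t).amplitude
        a2 = decompose(-angle, t).amplitude
        mid = slice(int(1.7 * FS), int(2.3 * FS))
        assert np.allclose(a1[mid], a2[mid], atol=0.5)


class TestSegmentStates:
    def test_flat_trace_single_quiescence(self):
        t = times(2.0)
        tr = decompose(np.zeros(t.size), t)
        segs = segment_states(tr)
        assert len(segs) == 1
        state, on, off = segs[0]
        assert state == "quiescence" and on == 0.0
        assert off == pytest.approx(2.0, abs=2 / FS)

    def test_one_second_bout_detected(self):
        # band-pass ringing smears a rectangular bout edge by ~1 half-cycle
        t, angle = bout_angle(bout=(1.5, 2.5))
        tr = decompose(angle, t)
        whisk = [(a, b) for s, a, b in segment_states(tr) if s == "whisking"]
        assert len(whisk) == 1
        on, off = whisk[0]
        assert on == pytest.approx(1.5, abs=0.2)
        assert off == pytest.approx(2.5, abs=0.2)

    def test_duration_rule_on_amplitude_signal(self):
        # amplitude > 3 deg must last more than 200 ms to count as whisking
        from whiskthal.whisking import label_states
        dt = 1 / FS
        amp = np.zeros(2000)
        amp[100:100 + int(0.15 * FS)] = 10.0   # 150 ms: stays quiescence
        amp[1000:1000 + int(0.5 * FS)] = 10.0  # 500 ms: whisking
        state = label_states(amp, dt)
        assert not state[100:100 + int(0.15 * FS)].any()
        assert state[1000:1000 + int(0.5 * FS)].all()
        # exactly 200 ms is not *more than* 200 ms
        amp2 = np.zeros(2000)
        amp2[100:100 + int(0.2 * FS)] = 10.0
        assert not label_states(amp2, dt).any()

    def test_segmentation_partitions_recording(self):
        cfg = SyntheticConfig(duration=30.0)
        truth = generate_whisking_trace(cfg, np.random.default_rng(3))
        tr = decompose(truth.angle, truth.time)
        segs = segment_states(tr)
        assert segs[0][1] == truth.time[0]
        for (_, _, off1), (_, on2, _) in zip(segs[:-1], segs[1:]):
            assert off1 == on2
        assert segs[-1][2] == pytest.approx(truth.time[-1] + 1 / FS, abs=1e-9)


class TestPhaseAt:
    def make_trace(self, phase, state=None):
        n = len(phase)
        t = np.arange(n) / FS
        ones = np.ones(n)
        return WhiskingTrace(
            time=t, angle_norm=ones, angle_band=ones,
            phase=np.asarray(phase, float), amplitude=10 * ones,
            setpoint=0 * ones,
            state=np.ones(n, np.int8) if state is None else np.asarray(state, np.int8),
        )

    def test_exact_at_sample_times(self):
        tr = self.make_trace([0.1, 0.3, 0.5])
        assert phase_at(tr, tr.time[1]) == pytest.approx(0.3)

    def test_linear_interpolation_midway(self):
        tr = self.make_trace([0.1, 0.3])
        assert phase_at(tr, 0.5 / FS) == pytest.approx(0.2)

    def test_wrap_interpolation_goes_through_pi(self):
        # between 3.1 and -3.1 the path crosses pi, not zero
        tr = self.make_trace([3.1, -3.1])
        val = phase_at(tr, 0.5 / FS)
        assert abs(val) > 3.1

    def test_quiescent_query_flagged_nan(self):
        tr = self.make_trace([0.1, 0.3, 0.5], state=[1, 0, 1])
        out = phase_at(tr, [tr.time[0], tr.time[1]])
        assert not np.isnan(out[0]) and np.isnan(out[1])

    def test_out_of_span_raises(self):
        tr = self.make_trace([0.1, 0.3])
        with pytest.raises(ValueError, match="span"):
            phase_at(tr, 10.0)


class TestGroundTruthRecovery:
    def test_state_agreement_away_from_edges(self):
        cfg = SyntheticConfig(duration=120.0, quiescent_noise_deg=0.0)
        truth = generate_whisking_trace(cfg, np.random.default_rng(11))
        tr = decompose(truth.angle, truth.time)
        # exclude one ramp length around every true bout edge
        edge = np.zeros(truth.time.size, bool)
        pad = int(cfg.ramp_s * FS)
        for i in np.nonzero(np.diff(truth.state.astype(int)) != 0)[0]:
            edge[max(0, i - pad): i + pad] = True
        core = ~edge
        agree = (tr.whisking_mask == truth.state)[core].mean()
        assert agree >= 0.95

    def test_phase_recovery_within_tolerance(self):
        cfg = SyntheticConfig(duration=120.0, quiescent_noise_deg=0.0)
        truth = generate_whisking_trace(cfg, np.random.default_rng(12))
        tr = decompose(truth.angle, truth.time)
        core = truth.state & tr.whisking_mask & (truth.amplitude > 10)
        err = np.angle(np.exp(1j * (tr.phase[core] - truth.phase[core])))
        assert np.percentile(np.abs(err), 90) < 0.2
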