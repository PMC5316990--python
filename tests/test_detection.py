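"""Detector stage contracts, round-trip recovery, and determinism."""

from dataclasses import replace

import numpy as np
import pytest

from sparsegate.detection import (
    DataError,
    DetectionParams,
    ParameterError,
    RoiTrace,
    apply_auc_threshold,
    classify_stimulus_responses,
    compute_dff,
    derivative,
    detect,
    estimate_initial_threshold,
    find_candidate_events,
    smooth,
    robust_sd,
)
from sparsegate.synthetic import AcquisitionConfig, generate_trace, transient_kernel

FRAME = 1.0 / 55.0


def _trace(f, stimulus_times=(), frame_rate=55.0):
    f = np.asarray(f, dtype=float)
    return RoiTrace("r0", np.arange(len(f)) / frame_rate, f,
                    stimulus_times=tuple(stimulus_times))


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        dff = compute_dff(_trace(np.full(100, 100.0)))
        assert np.allclose(dff.dff, 0.0)
        assert dff.f0 == 100.0

    def test_ten_percent_step(self):
        f = np.full(100, 100.0)
        f[60] = 110.0
        dff = compute_dff(_trace(f))
        assert dff.dff[60] == pytest.approx(10.0)

    def test_round_trip_amplitude(self, noise_free_trace):
        trace, events = noise_free_trace
        dff = compute_dff(trace)
        assert dff.dff.max() == pytest.approx(events[0].true_amplitude, abs=0.05)

    def test_short_baseline_raises(self):
        with pytest.raises(DataError):
            compute_dff(_trace(np.full(100, 50.0), stimulus_times=(0.05,)))


class TestSmooth:
    def test_polynomials_pass_through(self):
        """SG reproduces polynomials up to its order on interior frames."""
        t = np.arange(200) / 55.0
        for poly in (np.full_like(t, 3.0), 2.0 * t, 1.0 + t - 4 * t**2):
            dff = compute_dff(_trace(100.0 + poly))
            out = smooth(dff, DetectionParams())
            assert np.allclose(out.dff[10:-10], dff.dff[10:-10], atol=1e-9)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        f = 100.0 + rng.normal(0, 1, 500)
        dff = compute_dff(_trace(f))
        out = smooth(dff, DetectionParams())
        assert out.dff.var() < dff.dff.var()

    def test_window_too_long_raises(self):
        dff = compute_dff(_trace(np.full(30, 100.0)))
        with pytest.raises(ParameterError):
            smooth(dff, DetectionParams(sg_window=31))


class TestDerivative:
    def test_constant_is_zero(self):
        d = derivative(compute_dff(_trace(np.full(50, 100.0))))
        assert np.allclose(d, 0.0)

    def test_ramp_slope(self):
        from sparsegate.detection import DffTrace

        t = np.arange(100) / 55.0
        dff = DffTrace("r0", t, 2.0 * t, f0=100.0)
        assert np.allclose(derivative(dff), 2.0, atol=1e-9)

    def test_sine_max_slope(self):
        """Max derivative of A·sin(ωt) approaches A·ω."""
        fr, amp, freq = 200.0, 5.0, 2.0
        t = np.arange(4000) / fr
        dffv = amp * np.sin(2 * np.pi * freq * t)
        trace = _trace(100.0 * (1 + dffv / 100), frame_rate=fr)
        d = derivative(compute_dff(trace))
        assert d.max() == pytest.approx(amp * 2 * np.pi * freq, rel=0.02)


class TestInitialThreshold:
    def test_zero_derivative_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert estimate_initial_threshold(np.zeros(50)) == 0.0

    def test_mad_consistency_on_gaussian(self):
        """MAD-based scale converges to the true SD: threshold → k·σ."""
        rng = np.random.default_rng(3)
        d = rng.normal(0, 2.5, 200_000)
        assert estimate_initial_threshold(d, k=3.0) == pytest.approx(7.5, rel=0.02)

    def test_robust_to_one_transient(self):
        """One large transient barely moves the whole-trace threshold."""
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 1.0, 2000)
        t = np.arange(2000) / 55.0
        burst = transient_kernel(25.0, 0.02, 0.5, t, onset=10.0)
        thr_clean = estimate_initial_threshold(noise, k=3.0)
        thr_burst = estimate_initial_threshold(noise + np.gradient(burst, t), k=3.0)
        assert abs(thr_burst - thr_clean) / thr_clean < 0.10


class TestCandidates:
    def test_flat_trace_no_candidates(self):
        assert find_candidate_events(np.zeros(100), 1.0) == []

    def test_single_noise_free_transient(self, noise_free_trace, raw_char_params):
        trace, events = noise_free_trace
        detected = detect(trace, raw_char_params)
        assert len(detected) == 1
        assert abs(detected[0].onset_time - events[0].true_onset) <= FRAME

    def test_three_transients_at_1hz(self, clean_profile):
        """Multi-peak support under ~1 Hz stimulation."""
        acq = AcquisitionConfig(n_frames=330, stimulus_times=(1.0, 2.0, 3.0),
                                noise_sd=0.01)
        trace, events = generate_trace(clean_profile, acq, [True] * 3,
                                       np.random.default_rng(7))
        detected = detect(trace)
        assert len(detected) == 3
        assert [e.evoking_stimulus_index for e in detected] == [0, 1, 2]


class TestAucThreshold:
    def test_zero_auc_rejected(self):
        dff = compute_dff(_trace(np.full(300, 100.0)))
        sm = smooth(dff, DetectionParams())
        cands = find_candidate_events(np.zeros(300), 0.0)
        assert apply_auc_threshold(cands, sm, DetectionParams()) == []

    def test_monotone_in_k(self, control_profile):
        """Raising auc_threshold_k never increases the accepted count."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            trace, _ = generate_trace(control_profile, AcquisitionConfig(noise_sd=0.02),
                                      [True], rng)
            counts = [len(detect(trace, DetectionParams(auc_threshold_k=k)))
                      for k in (0.5, 1.0, 2.0, 4.0, 8.0)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_noise_free_transient_accepted(self, noise_free_trace):
        trace, _ = noise_free_trace
        assert len(detect(trace)) == 1


class TestCharacterize:
    def test_analytic_decay90(self, raw_char_params):
        """Single-exponential decay: decay90 − peak = τ·ln 10 (one frame)."""
        tau = 0.5
        t = np.arange(440) / 55.0
        k = transient_kernel(10.0, 1e-4, tau, t, onset=1.5)
        trace = _trace(1000.0 * (1 + k / 100), stimulus_times=(1.4,))
        (event,) = detect(trace, raw_char_params)
        assert event.decay90_time - event.peak_time == pytest.approx(
            tau * np.log(10.0), abs=FRAME)
        assert event.decay_tau == pytest.approx(tau, rel=0.05)

    def test_peak_amplitude_recovery(self, noise_free_trace, raw_char_params):
        """The 5.2% ΔF/F₀ noise-free fixture is measured at 5.2."""
        trace, _ = noise_free_trace
        (event,) = detect(trace, raw_char_params)
        assert event.peak_dff == pytest.approx(5.2, abs=0.05)

    def test_unresolved_decay_flagged(self, clean_profile):
        """A transient cut off by the trace end keeps NaN decay fields."""
        acq = AcquisitionConfig(n_frames=80, stimulus_times=(1.0,), noise_sd=0.0)
        trace, _ = generate_trace(clean_profile, acq, [True], np.random.default_rng(0))
        (event,) = detect(trace, DetectionParams(characterize_on_smoothed=False))
        assert not event.decay_resolved
        assert np.isnan(event.decay90_time)


class TestDetect:
    def test_deterministic(self, control_profile):
        trace, _ = generate_trace(control_profile, AcquisitionConfig(),
                                  [True], np.random.default_rng(12))
        a = detect(trace)
        b = detect(trace)
        assert [(e.onset_time, e.peak_dff, e.auc) for e in a] == \
               [(e.onset_time, e.peak_dff, e.auc) for e in b]

    def test_threshold_monotonicity(self, control_profile):
        """Accepted count is non-increasing in deriv_threshold_k."""
        for seed in range(6):
            trace, _ = generate_trace(control_profile,
                                      AcquisitionConfig(noise_sd=0.02),
                                      [True], np.random.default_rng(100 + seed))
            counts = [len(detect(trace, DetectionParams(deriv_threshold_k=k)))
                      for k in (2.0, 3.0, 4.5, 6.0, 9.0)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClassifyStimulusResponses:
    def _event(self, onset):
        from sparsegate.detection import CalciumEvent
        return CalciumEvent("r", 0, onset, onset + 0.1, 5.0, 1.0, onset + 1, 0.5)

    def test_assigned_within_window(self):
        ev = self._event(1.03)
        flags = classify_stimulus_responses([ev], [1.0], response_window=0.5)
        assert flags.tolist() == [True]
        assert ev.evoking_stimulus_index == 0

    def test_onset_before_first_stimulus_is_spontaneous(self):
        ev = self._event(0.5)
        flags = classify_stimulus_responses([ev], [1.0])
        assert flags.tolist() == [False]
        assert ev.evoking_stimulus_index is None

    def test_matches_brute_force_interval_check(self):
        """Randomized events/stimuli agree with a direct interval scan."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            stims = np.sort(rng.uniform(0, 10, rng.integers(1, 6)))
            onsets = rng.uniform(0, 11, rng.integers(0, 8))
            events = [self._event(o) for o in onsets]
            window = float(rng.uniform(0.1, 2.0))
            flags = classify_stimulus_responses(events, stims, window)
            expect = np.zeros(len(stims), dtype=bool)
            for o in onsets:
                js = [j for j, s in enumerate(stims) if s < o <= s + window]
                if js:
                    expect[max(js)] = True  # nearest preceding stimulus
            assert flags.tolist() == expect.tolist()


def test_robust_sd_matches_gaussian_sd():
    rng = np.random.default_rng(5)
    assert robust_sd(rng.normal(0, 3.0, 100_000)) == pytest.approx(3.0, rel=0.02)
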