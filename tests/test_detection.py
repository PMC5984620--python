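"""Detection chain: decimation, referencing, oscillation and artifact detectors."""

import numpy as np
import pytest

from hfovar.datatypes import ArtifactInterval, HFOEvent, SignalBlock, overlap_length
from hfovar.detection import (ArtifactParams, DetectorParams,
                              common_average_reference, decimate_to_target,
                              detect_artifacts, qhfo, redact_events,
                              staba_detect)
from hfovar.synthetic import EegScenario, generate_synthetic_eeg


def _noise_block(n_ch=2, dur=20.0, fs=5000.0, sd=10.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, sd, (int(dur * fs), n_ch))
    return SignalBlock(x, fs, [f"ch{i:02d}" for i in range(n_ch)])


class TestDecimate:
    def test_integer_factor_length_and_rate(self, rng):
        block = SignalBlock(rng.normal(size=(30000, 2)), 30000.0, ["a", "b"])
        out = decimate_to_target(block, 5000.0)
        assert out.fs == 5000.0
        assert out.n_samples == block.n_samples // 6

    def test_non_integer_multiple_passes_through(self, rng):
        block = SignalBlock(rng.normal(size=(4096, 2)), 4096.0, ["a", "b"])
        out = decimate_to_target(block, 5000.0)
        assert out is block

    def test_rate_below_target_passes_through(self, rng):
        # recordings acquired below the target rate are used as acquired
        block = SignalBlock(rng.normal(size=(1000, 2)), 1000.0, ["a", "b"])
        assert decimate_to_target(block, 2000.0) is block

    def test_passband_amplitude_preserved_within_1pct(self):
        fs = 30000.0
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * 100.0 * t)[:, None]
        out = decimate_to_target(SignalBlock(x, fs, ["a"]), 5000.0)
        # FFT amplitude at 100 Hz before and after (oracle: unit amplitude)
        spec = np.fft.rfft(out.samples[:, 0])
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.fs)
        amp = 2 * np.abs(spec[np.argmin(np.abs(freqs - 100.0))]) / out.n_samples
        assert abs(amp - 1.0) < 0.01


class TestCommonAverageReference:
    def test_two_channel_example(self):
        block = SignalBlock(np.array([[3.0, 1.0]]), 100.0, ["a", "b"])
        out = common_average_reference(block)
        assert np.allclose(out.samples, [[1.0, -1.0]])

    def test_identical_channels_cancel(self, rng):
        x = rng.normal(size=(500, 1))
        block = SignalBlock(np.repeat(x, 4, axis=1), 100.0, list("abcd"))
        assert np.allclose(common_average_reference(block).samples, 0.0)

    def test_channel_mean_is_zero_for_random_input(self, rng):
        block = SignalBlock(rng.normal(size=(200, 5)), 100.0, list("abcde"))
        out = common_average_reference(block)
        assert np.allclose(out.samples.mean(axis=1), 0.0, atol=1e-12)

    def test_single_channel_rejected(self, rng):
        block = SignalBlock(rng.normal(size=(100, 1)), 100.0, ["a"])
        with pytest.raises(ValueError):
            common_average_reference(block)


class TestStabaDetector:
    def test_all_zero_signal_yields_no_events(self):
        assert staba_detect(np.zeros(50000), 5000.0) == []

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            staba_detect(np.zeros(5000), 800.0, DetectorParams())

    @pytest.mark.parametrize("seed", range(20))
    def test_injected_burst_found_once_at_injection(self, seed):
        """150 Hz, 10-cycle burst at 8x background SD in Gaussian noise."""
        scn = EegScenario(n_channels=1, duration_s=20.0,
                          hfo_spec=[(0, 10.0, 150.0, 10, 8.0)], seed=seed)
        block, (truth,), _ = generate_synthetic_eeg(scn)
        events = staba_detect(block.samples[:, 0], block.fs, channel="ch00")
        hits = [e for e in events
                if overlap_length(e.interval, truth.interval) > 0]
        assert len(hits) == 1
        assert len(events) == 1

    def test_mains_sinusoid_adds_no_events(self, rng):
        fs, dur = 5000.0, 20.0
        noise = rng.normal(0, 10.0, int(fs * dur))
        t = np.arange(len(noise)) / fs
        with_mains = noise + 50.0 * np.sin(2 * np.pi * 60.0 * t)
        n0 = len(staba_detect(noise, fs))
        n1 = len(staba_detect(with_mains, fs))
        assert abs(n1 - n0) <= 1

    def test_determinism(self, rng):
        x = rng.normal(0, 10, 50000)
        x[25000:25500] += 80.0 * np.sin(2 * np.pi * 140 * np.arange(500) / 5000)
        e1 = staba_detect(x, 5000.0)
        e2 = staba_detect(x, 5000.0)
        assert e1 == e2 and len(e1) >= 1


class TestArtifactDetectors:
    def test_synchronous_transient_flagged_everywhere(self):
        scn = EegScenario(n_channels=4, duration_s=20.0,
                          artifact_spec=[(10.0, "fast_transient", None)], seed=0)
        block, _, (truth,) = generate_synthetic_eeg(scn)
        arts = detect_artifacts(block)
        fast = [a for a in arts if a.kind == "fast_transient"]
        assert len(fast) >= block.n_channels
        for label in block.channel_labels:
            assert any(a.applies_to(label)
                       and overlap_length(a.interval, truth.interval) > 0
                       for a in fast)

    def test_clean_single_channel_burst_not_flagged(self):
        scn = EegScenario(n_channels=4, duration_s=20.0,
                          hfo_spec=[(2, 10.0, 150.0, 10, 8.0)], seed=1)
        block, (truth,), _ = generate_synthetic_eeg(scn)
        arts = detect_artifacts(block)
        assert not any(overlap_length(a.interval, truth.interval) > 0
                       for a in arts)

    def test_flatline_yields_data_quality_interval(self):
        block = _noise_block(n_ch=2, dur=10.0, seed=2)
        block.samples[10000:20000, 1] = 3.14  # 2-s flatline on one channel
        arts = detect_artifacts(block)
        dq = [a for a in arts if a.kind == "data_quality"]
        assert len(dq) == 1
        assert dq[0].applies_to("ch01") and not dq[0].applies_to("ch00")
        assert dq[0].start_s == pytest.approx(2.0, abs=0.01)
        assert dq[0].end_s == pytest.approx(4.0, abs=0.01)

    def test_non_focal_when_candidates_on_most_channels(self):
        block = _noise_block(n_ch=4, dur=10.0, seed=3)
        ev = lambda ch: HFOEvent(channel=ch, start_s=5.0, end_s=5.1)
        cands = {c: [ev(c)] for c in block.channel_labels[:3]}
        arts = detect_artifacts(block, cands)
        nf = [a for a in arts if a.kind == "non_focal"]
        assert len(nf) == 1
        assert nf[0].interval == (5.0, 5.1)

    def test_low_rate_skips_transient_band_with_warning(self):
        block = SignalBlock(np.random.default_rng(0).normal(size=(2000, 2)),
                            1000.0, ["a", "b"])
        with pytest.warns(RuntimeWarning, match="fast-transient"):
            arts = detect_artifacts(block)
        assert not any(a.kind == "fast_transient" for a in arts)


class TestQhfo:
    def test_overlap_redaction_rule(self):
        events = [HFOEvent("a", 1.0, 1.1), HFOEvent("a", 5.0, 5.1)]
        artifacts = [ArtifactInterval(0.9, 1.2, "non_focal", None)]
        out = redact_events(events, artifacts)
        assert out == [HFOEvent("a", 5.0, 5.1)]

    def test_channel_specific_artifact_redacts_only_its_channel(self):
        events = [HFOEvent("a", 1.0, 1.1), HFOEvent("b", 1.0, 1.1)]
        artifacts = [ArtifactInterval(0.9, 1.2, "fast_transient",
                                      frozenset({"a"}))]
        out = redact_events(events, artifacts)
        assert [e.channel for e in out] == ["b"]

    def test_no_event_overlaps_any_artifact(self):
        scn = EegScenario(
            n_channels=4, duration_s=30.0,
            hfo_spec=[(0, 5.0, 150.0, 10, 8.0), (1, 15.0, 120.0, 10, 8.0),
                      (2, 25.0, 200.0, 10, 8.0)],
            artifact_spec=[(15.0, "fast_transient", None)], seed=4)
        block, _, _ = generate_synthetic_eeg(scn)
        events, artifacts = qhfo(block, return_artifacts=True)
        for ev in events:
            for a in artifacts:
                if a.applies_to(ev.channel):
                    assert overlap_length(ev.interval, a.interval) == 0

    def test_event_lists_sorted_and_non_overlapping_per_channel(self):
        scn = EegScenario(
            n_channels=3, duration_s=30.0,
            hfo_spec=[(0, 5.0, 150.0, 10, 8.0), (0, 10.0, 180.0, 10, 8.0),
                      (1, 20.0, 140.0, 12, 8.0)], seed=5)
        block, _, _ = generate_synthetic_eeg(scn)
        events = qhfo(block)
        starts = [e.start_s for e in events]
        assert starts == sorted(starts)
        by_ch = {}
        for e in events:
            by_ch.setdefault(e.channel, []).append(e)
        for evs in by_ch.values():
            for e1, e2 in zip(evs, evs[1:]):
                assert e1.end_s <= e2.start_s

    def test_fr_band_rejects_120hz_accepts_250hz(self):
        scn = EegScenario(n_channels=4, duration_s=30.0,
                          hfo_spec=[(0, 10.0, 120.0, 10, 8.0),
                                    (1, 20.0, 250.0, 12, 8.0)], seed=6)
        block, _, _ = generate_synthetic_eeg(scn)
        events = qhfo(block, band="fr")
        assert all(e.detector == "qHFO-FR" for e in events)
        channels = {e.channel for e in events}
        assert "ch01" in channels and "ch00" not in channels

    def test_fr_events_dominant_frequency_is_high(self):
        scn = EegScenario(n_channels=8, duration_s=40.0,
                          hfo_spec=[(c, 8.0 + 8 * c, 250.0, 12, 8.0)
                                    for c in range(4)], seed=7)
        block, _, _ = generate_synthetic_eeg(scn)
        car = common_average_reference(block)  # the signal the detector saw
        labels = {c: i for i, c in enumerate(car.channel_labels)}
        events = qhfo(block, band="fr")
        assert len(events) >= 3
        for ev in events:
            i, j = int(ev.start_s * car.fs), int(ev.end_s * car.fs)
            snip = car.samples[i:j, labels[ev.channel]]
            freqs = np.fft.rfftfreq(len(snip), 1 / car.fs)
            dom = freqs[np.argmax(np.abs(np.fft.rfft(snip))[1:]) + 1]
            assert dom >= 150.0
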