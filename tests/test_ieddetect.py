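"""Detection: filtering, thresholding, duration banding, epoch extraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irritmap.errors import EpochError, FilterError
from irritmap.iedsim import NoiseSpec, SimulationConfig, SubtypeSpec, make_ied_template, simulate_recording
from irritmap.ieddetect import (
    SPIKE_BAND,
    EventList,
    bandpass,
    detect_events,
    detect_ieds,
    extract_epochs,
    split_by_kind,
)
from irritmap.ieddetect.detect import Event
from irritmap.recording import Recording

FS = 500.0


def _sine_recording(freq, fs=FS, seconds=10.0, n_ch=4):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data, sampling_rate=fs)


def _noiseless_recording(head, durations=(45.0,), n_events=20, seed=0):
    subtypes = [
        SubtypeSpec(
            make_ied_template("spike" if d < 70 else "sharp_wave", d, FS),
            i * 7, n_events, parcel_id=None,
        )
        for i, d in enumerate(durations)
    ]
    cfg = SimulationConfig(
        n_channels=len(head.montage), sampling_rate=FS, duration_s=40.0,
        subtypes=subtypes, noise=NoiseSpec(sd=0.0), snr=None, seed=seed,
    )
    return simulate_recording(cfg, head.leadfield)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        rec = _sine_recording(30.0)
        out = bandpass(rec, *SPIKE_BAND)
        mid = out.data[0, 1000:-1000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated_20db(self):
        """Out-of-band tone attenuated at least as much as the designed
        squared (forward-backward) Butterworth response predicts."""
        import scipy.signal

        rec = _sine_recording(2.0)
        out = bandpass(rec, *SPIKE_BAND)
        attain = np.abs(out.data[0, 1000:-1000]).max()
        sos = scipy.signal.butter(4, SPIKE_BAND, btype="bandpass", fs=FS, output="sos")
        _, h = scipy.signal.sosfreqz(sos, worN=[2.0], fs=FS)
        designed = np.abs(h[0]) ** 2  # zero-phase filter applies |H|^2
        assert attain < 0.01  # >= 40 dB down in practice
        assert attain == pytest.approx(designed, rel=0.25)

    def test_band_metadata_recorded(self):
        out = bandpass(_sine_recording(30.0), 15.0, 50.0)
        assert out.band == (15.0, 50.0)

    @pytest.mark.parametrize("lo,hi", [(50.0, 15.0), (0.0, 30.0), (10.0, 400.0)])
    def test_invalid_band_rejected(self, lo, hi):
        with pytest.raises(FilterError):
            bandpass(_sine_recording(30.0), lo, hi)


class TestDetectEvents:
    def test_zero_signal_gives_no_events(self):
        rec = Recording(np.zeros((4, 5000)), sampling_rate=FS)
        assert len(detect_events(rec, 5.0)) == 0

    def test_noiseless_events_found_exactly(self, study_head):
        """Every inserted spike is recovered with its peak within one
        sample of the ground truth."""
        rec, truth = _noiseless_recording(study_head, durations=(45.0,))
        events, _ = detect_ieds(rec)
        assert len(events) == truth.n_events
        offsets = np.abs(events.peak_samples - truth.peak_samples)
        assert offsets.max() <= 1

    def test_per_channel_statistic_on_high_snr(self, study_head):
        """The classical per-channel median + k*MAD rule recovers strong
        events (robust statistics degenerate on literally noiseless data,
        so a faint background is included)."""
        cfg = SimulationConfig(
            n_channels=len(study_head.montage), sampling_rate=FS, duration_s=40.0,
            subtypes=[SubtypeSpec(make_ied_template("spike", 45.0, FS), 0, 20)],
            snr=50.0, seed=4,
        )
        rec, truth = simulate_recording(cfg, study_head.leadfield)
        events = detect_events(bandpass(rec, 1.0, 45.0), 5.0, statistic="per_channel")
        assert len(events) == truth.n_events
        assert np.abs(events.peak_samples - truth.peak_samples).max() <= 2

    def test_duration_bands_assign_kind(self, study_head):
        rec, truth = _noiseless_recording(study_head, durations=(45.0, 120.0), n_events=8)
        events, _ = detect_ieds(rec)
        kinds = dict(zip(events.peak_samples, events.kinds))
        for p, lbl in zip(truth.peak_samples, truth.labels):
            matched = min(kinds, key=lambda q: abs(q - p))
            assert kinds[matched] == ("spike" if lbl == 0 else "sharp_wave")

    def test_out_of_range_duration_discarded(self, study_head):
        """A 300 ms hump exceeds the 200 ms IED band and is dropped."""
        rng = np.random.default_rng(9)
        n = int(30 * FS)
        data = rng.normal(0.0, 10.0, size=(len(study_head.montage), n))
        topo = study_head.leadfield.source_gain(0)
        # Gaussian with FWHM 300 ms, well above the detection threshold
        sigma = 300.0 / 2.3548 / 1000.0 * FS
        t = np.arange(-1200, 1201)
        hump = np.exp(-0.5 * (t / sigma) ** 2)
        peaks = (3000, 8000, 13000)
        for peak in peaks:
            data[:, peak - 1200 : peak + 1201] += np.outer(
                topo * 120 / np.abs(topo).max(), hump
            )
        rec = Recording(data, sampling_rate=FS)
        events, _ = detect_ieds(rec)
        for p in events.peak_samples:
            assert min(abs(p - q) for q in peaks) > 0.1 * FS

    def test_raising_threshold_never_adds_events(self, study_head):
        cfg = SimulationConfig(
            n_channels=len(study_head.montage), sampling_rate=FS, duration_s=30.0,
            subtypes=[SubtypeSpec(make_ied_template("spike", 40.0, FS), 0, 10)],
            snr=5.0, seed=3,
        )
        rec, _ = simulate_recording(cfg, study_head.leadfield)
        det = bandpass(rec, 1.0, 45.0)
        counts = [len(detect_events(det, k)) for k in (4.0, 5.0, 6.0, 8.0, 12.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_flat_channel_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 4000))
        data[1] = 0.0
        rec = Recording(data, sampling_rate=FS)
        with caplog.at_level("WARNING"):
            detect_events(rec, 6.0)
        assert any("flat" in r.message for r in caplog.records)


class TestSplitByKind:
    def test_partition_by_band(self):
        durations = [30.0, 90.0, 150.0, 60.0]
        events = EventList(
            [Event(i * 100, 0, 1.0, d, "spike" if d < 70 else "sharp_wave")
             for i, d in enumerate(durations)],
            sampling_rate=FS,
        )
        spikes, sharps = split_by_kind(events)
        assert sorted(e.duration_ms for e in spikes) == [30.0, 60.0]
        assert sorted(e.duration_ms for e in sharps) == [90.0, 150.0]

    def test_boundary_70ms_is_sharp_wave(self, study_head):
        """70 ms sits in the closed-left sharp-wave band."""
        from irritmap.ieddetect.detect import _kind_from_duration

        assert _kind_from_duration(70.0) == "sharp_wave"
        assert _kind_from_duration(69.9) == "spike"
        assert _kind_from_duration(200.0) == "sharp_wave"
        assert _kind_from_duration(210.0) is None

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(20.0, 200.0), max_size=30))
    def test_counts_conserved(self, durations):
        events = EventList(
            [Event(i * 50, 0, 1.0, d, "spike" if d < 70 else "sharp_wave")
             for i, d in enumerate(durations)],
            sampling_rate=FS,
        )
        spikes, sharps = split_by_kind(events)
        assert len(spikes) + len(sharps) == len(events)

    def test_empty_input(self):
        spikes, sharps = split_by_kind(EventList([], sampling_rate=FS))
        assert len(spikes) == 0 and len(sharps) == 0


class TestExtractEpochs:
    def _events(self, peaks):
        return EventList(
            [Event(int(p), 0, 1.0, 45.0, "spike") for p in peaks], sampling_rate=FS
        )

    def test_tensor_shape_bookkeeping(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.normal(size=(32, 20000)), sampling_rate=FS)
        tensor = extract_epochs(rec, self._events(range(1000, 16000, 500)), 300.0)
        assert tensor.values.shape == (32, 150, 30)

    def test_edge_event_dropped(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.normal(size=(4, 2000)), sampling_rate=FS)
        tensor = extract_epochs(rec, self._events([10, 1000]), 300.0)
        assert tensor.n_samples == 1

    def test_constant_channel_zero_after_baseline(self):
        data = np.vstack([np.full(4000, 3.5), np.random.default_rng(3).normal(size=4000)])
        rec = Recording(data, sampling_rate=FS)
        tensor = extract_epochs(rec, self._events([2000]), 300.0)
        assert np.allclose(tensor.values[0, :, 0], 0.0)

    def test_window_longer_than_recording_rejected(self):
        rec = Recording(np.zeros((2, 50)), sampling_rate=FS)
        with pytest.raises(EpochError):
            extract_epochs(rec, self._events([25]), 300.0)
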