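"""Preprocessing chain: re-reference, band-pass, decimation, epoching."""

import numpy as np
import pytest

from avbci.montage import RAW_LABELS_64
from avbci.preprocess import (
    ContinuousRecording,
    PreprocessError,
    bandpass,
    downsample,
    extract_epochs,
    preprocess_pipeline,
    rereference,
)
from avbci.simulate import SessionEvent


def _recording(signal, fs=1000.0, events=()):
    return ContinuousRecording(
        signal=np.asarray(signal, dtype=np.float64),
        fs=fs,
        labels=RAW_LABELS_64[: signal.shape[0]],
        events=list(events),
    )


def _event(sample, stage=1, is_target=True):
    return SessionEvent(sample=sample, stage=stage, char_index=0, index=0,
                        is_target=is_target, character="A", group=0)


class TestRereference:
    def test_mastoid_mean_removed(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((64, 500))
        rec = _recording(sig)
        out = rereference(rec)
        i1, i2 = RAW_LABELS_64.index("M1"), RAW_LABELS_64.index("M2")
        ref = (sig[i1] + sig[i2]) / 2
        keep = [i for i, lab in enumerate(RAW_LABELS_64)
                if lab not in ("M1", "M2")]
        np.testing.assert_allclose(out.signal, sig[keep] - ref)
        assert out.signal.shape[0] == 62
        assert "M1" not in out.labels

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(1)
        sig = rng.standard_normal((64, 200))
        base = rereference(_recording(sig)).signal
        shifted = rereference(_recording(sig + 17.3)).signal
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_signal_equal_to_reference_zeroes_out(self):
        sig = np.ones((64, 100)) * 4.2
        out = rereference(_recording(sig))
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_missing_reference_channel(self):
        sig = np.zeros((10, 100))
        rec = ContinuousRecording(signal=sig, fs=1000.0,
                                  labels=RAW_LABELS_64[:10], events=[])
        with pytest.raises(PreprocessError):
            rereference(rec)


class TestBandpass:
    def _sine(self, freq, fs=1000.0, dur=10.0):
        t = np.arange(int(dur * fs)) / fs
        return np.sin(2 * np.pi * freq * t)

    def test_passband_gain_near_unity(self):
        rec = _recording(self._sine(10.0)[None].repeat(2, 0))
        out = bandpass(rec)
        mid = out.signal[0, 2000:-2000]
        assert abs(mid.max() - 1.0) < 0.05

    def test_stopband_attenuation(self):
        rec = _recording(self._sine(100.0)[None])
        out = bandpass(rec)
        mid = out.signal[0, 2000:-2000]
        assert 20 * np.log10(np.abs(mid).max()) < -20

    def test_zero_phase_preserves_latency(self):
        """A Gaussian burst at 15 Hz keeps its envelope peak position."""
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        env = np.exp(-((t - 2.0) ** 2) / (2 * 0.05**2))
        sig = env * np.sin(2 * np.pi * 15 * t)
        out = bandpass(_recording(sig[None]))
        from scipy.signal import hilbert

        peak_in = np.argmax(np.abs(hilbert(sig)))
        peak_out = np.argmax(np.abs(hilbert(out.signal[0])))
        assert abs(int(peak_in) - int(peak_out)) <= 1

    def test_fs_too_low(self):
        rec = _recording(np.zeros((1, 100)), fs=50.0)
        with pytest.raises(PreprocessError):
            bandpass(rec)


class TestDownsample:
    def test_decimation_arithmetic(self):
        rec = _recording(np.zeros((2, 1000)), events=[_event(1000)])
        # event beyond signal end is fine for the index-remap check
        out = downsample(rec)
        assert out.signal.shape[1] == 200
        assert out.fs == 200.0
        assert out.events[0].sample == 200

    def test_non_integer_factor_rejected(self):
        rec = _recording(np.zeros((1, 100)), fs=300.0)
        with pytest.raises(PreprocessError):
            downsample(rec)

    def test_inband_sine_amplitude_preserved(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        sig = np.sin(2 * np.pi * 10 * t)
        out = downsample(_recording(sig[None]))
        assert abs(out.signal[0, 100:-100].max() - 1.0) < 0.05


class TestExtractEpochs:
    def test_shape_and_count(self):
        rng = np.random.default_rng(2)
        sig = rng.standard_normal((62, 1000))
        rec = ContinuousRecording(
            signal=sig, fs=200.0,
            labels=tuple(l for l in RAW_LABELS_64 if l not in ("M1", "M2")),
            events=[_event(100), _event(400), _event(990)],
        )
        epochs, skipped = extract_epochs(rec)
        assert epochs.data.shape == (2, 62, 100)  # third is out of bounds
        assert skipped == 1

    def test_baseline_removes_constants(self):
        sig = np.full((62, 400), 3.7)
        rec = ContinuousRecording(
            signal=sig, fs=200.0,
            labels=tuple(l for l in RAW_LABELS_64 if l not in ("M1", "M2")),
            events=[_event(100)],
        )
        epochs, _ = extract_epochs(rec)
        np.testing.assert_allclose(epochs.data, 0.0, atol=1e-6)

    def test_baseline_window_mean_is_zero(self):
        """After correction the pre-stimulus segment averages to zero."""
        rng = np.random.default_rng(3)
        sig = rng.standard_normal((62, 600))
        labels = tuple(l for l in RAW_LABELS_64 if l not in ("M1", "M2"))
        rec = ContinuousRecording(signal=sig, fs=200.0, labels=labels,
                                  events=[_event(200)])
        epochs, _ = extract_epochs(rec)
        base = sig[:, 180:200].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(
            epochs.data[0], sig[:, 200:300] - base, atol=1e-5
        )


class TestPipeline:
    def test_epoch_per_marker_with_truth_labels(self, small_session,
                                                small_epochs):
        assert len(small_epochs) == len(small_session.events)
        truth = [e.is_target for e in small_session.events]
        assert small_epochs.info["is_target"].tolist() == truth

    def test_average_peaks_at_template_latencies(self, small_epochs):
        """High-SNR target averages peak at the simulated latencies."""
        from avbci.decode import grand_average

        m = small_epochs.montage
        t_ms = small_epochs.times_ms
        e1 = small_epochs.select((small_epochs.info["stage"] == 1).to_numpy())
        avg = grand_average(e1, label="target")[m.index("P4")]
        for latency, sign in [(90, 1), (130, -1), (195, 1)]:
            window = (t_ms >= latency - 30) & (t_ms <= latency + 30)
            peak = t_ms[window][np.argmax(sign * avg[window])]
            assert abs(peak - latency) <= 10

    def test_pipeline_deterministic(self, small_session):
        a = preprocess_pipeline(small_session)
        b = preprocess_pipeline(small_session)
        np.testing.assert_array_equal(a.data, b.data)
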