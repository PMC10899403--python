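"""Filtering, downsampling, ICA, epoching, rejection, and re-referencing."""

import numpy as np
import pytest
from scipy import signal

from eegmdd import montage, simulate
from eegmdd.preprocess import (EpochSet, Recording, bandpass_filter, downsample,
                               epoch, notch_filter, reject_epochs,
                               remove_ocular_ica, rereference_average)

from conftest import make_tone


def _rms(x, trim=500):
    x = np.atleast_2d(x)[:, trim:-trim]
    return np.sqrt((x**2).mean())


class TestBandpass:
    def test_passband_tone_preserved(self, tone_10hz):
        out = bandpass_filter(tone_10hz)
        assert _rms(out.samples) == pytest.approx(_rms(tone_10hz.samples), rel=0.05)

    def test_drift_removed(self):
        rec = make_tone(0.2, duration_s=40.0)
        out = bandpass_filter(rec)
        # oracle: two-pass Butterworth amplitude response at 0.2 Hz
        sos = signal.butter(12, [1, 40], btype="bandpass", fs=500, output="sos")
        _, h = signal.sosfreqz(sos, worN=[0.2], fs=500)
        assert np.abs(h[0]) ** 2 < 0.10
        assert _rms(out.samples, trim=2000) < 0.10 * _rms(rec.samples, trim=2000)

    def test_dc_offset_stopped(self):
        rec = make_tone(10.0)
        rec.samples = np.full_like(rec.samples, 50.0)
        out = bandpass_filter(rec)
        trim = 1000
        assert np.abs(out.samples[:, trim:-trim]).mean() < 1e-6 * 50.0

    def test_passband_flat_within_half_db(self):
        sos = signal.butter(12, [1, 40], btype="bandpass", fs=500, output="sos")
        f = np.linspace(2, 35, 200)
        _, h = signal.sosfreqz(sos, worN=f, fs=500)
        gain_db = 20 * np.log10(np.abs(h) ** 2)  # forward-backward gain
        assert np.all(np.abs(gain_db) < 0.5)

    def test_zero_phase(self, tone_10hz):
        out = bandpass_filter(tone_10hz)
        x = tone_10hz.samples[0, 1000:-1000]
        y = out.samples[0, 1000:-1000]
        xc = signal.correlate(y, x, mode="full")
        lag = np.argmax(xc) - (len(x) - 1)
        assert lag == 0

    def test_edge_above_nyquist_rejected(self, tone_10hz):
        with pytest.raises(ValueError):
            bandpass_filter(tone_10hz, 1.0, 300.0)

    def test_provenance_appended(self, tone_10hz):
        out = bandpass_filter(tone_10hz)
        assert out.provenance[-1]["op"] == "bandpass"


class TestNotch:
    def test_line_frequency_suppressed(self):
        rec = make_tone(50.0)
        out = notch_filter(rec)
        assert _rms(out.samples) <= 0.10 * _rms(rec.samples)

    def test_attenuation_spec(self):
        sos = signal.butter(2, [49, 51], btype="bandstop", fs=500, output="sos")
        _, h = signal.sosfreqz(sos, worN=[50.0, 45.0], fs=500)
        gain_db = 20 * np.log10(np.abs(h) ** 2 + 1e-300)
        assert gain_db[0] <= -20.0
        assert gain_db[1] >= -3.0

    def test_distant_tone_untouched(self, tone_10hz):
        out = notch_filter(tone_10hz)
        assert _rms(out.samples) == pytest.approx(_rms(tone_10hz.samples), rel=0.02)

    def test_silence_stays_silent(self, tone_10hz):
        tone_10hz.samples[:] = 0.0
        out = notch_filter(tone_10hz)
        assert np.allclose(out.samples, 0.0)

    def test_stopband_outside_nyquist_rejected(self):
        rec = make_tone(10.0, fs=80.0)
        with pytest.raises(ValueError):
            notch_filter(rec)


class TestDownsample:
    def test_sample_count(self):
        rec = make_tone(10.0, fs=1000.0, duration_s=10.0)
        out = downsample(rec, 500.0)
        assert out.samples.shape[1] == 5000
        assert out.sampling_rate_hz == 500.0

    def test_tone_matches_analytic_decimation(self):
        rec = make_tone(10.0, fs=1000.0, duration_s=10.0)
        out = downsample(rec, 500.0)
        t = np.arange(5000) / 500.0
        ideal = 10.0 * np.sin(2 * np.pi * 10.0 * t)
        trim = 200
        c = np.corrcoef(out.samples[0, trim:-trim], ideal[trim:-trim])[0, 1]
        assert c > 0.999

    def test_band_powers_preserved(self, tiny_spec, hc_meta):
        from eegmdd.spectral import band_powers, epoch_psd, relative_powers
        spec1000 = simulate.SimulationSpec(n_mdd=2, n_hc=2, duration_s=20.0,
                                           sampling_rate_hz=1000.0, seed=3)
        rec = simulate.generate_recording(spec1000, hc_meta, "EO", subject_seed=5)
        rec = bandpass_filter(rec)

        def six_band(r):
            es = epoch(r, 2.0)
            f, p = epoch_psd(es.epochs, r.sampling_rate_hz)
            rel = relative_powers(band_powers(f, p))
            return np.array([rel[b].mean() for b in montage.BAND_NAMES])

        before = six_band(rec)
        after = six_band(downsample(rec, 500.0))
        assert np.all(np.abs(after - before) / before < 0.01)

    def test_upsampling_rejected(self, tone_10hz):
        with pytest.raises(ValueError):
            downsample(tone_10hz, 1000.0)


class TestOcularICA:
    def test_clean_recording_mostly_untouched(self, clean_recording):
        out, report = remove_ocular_ica(clean_recording, seed=0)
        assert len(report["removed"]) <= 1
        for i in range(out.n_channels):
            c = np.corrcoef(out.samples[i], clean_recording.samples[i])[0, 1]
            assert c > 0.95

    def test_blink_power_removed(self, tiny_spec, hc_meta):
        from eegmdd.spectral import hilbert_band_power
        spec = simulate.SimulationSpec(n_mdd=2, n_hc=2, duration_s=40.0,
                                       blink_rate_hz=0.25, seed=9)
        rec = simulate.generate_recording(spec, hc_meta, "EO", subject_seed=2)
        dirty, truth = simulate.inject_artifacts(rec, spec, seed=21)
        assert (truth.kind == "blink").sum() > 0
        cleaned, report = remove_ocular_ica(dirty, seed=0)
        assert len(report["removed"]) >= 1
        fs = rec.sampling_rate_hz
        fp1 = list(rec.channel_labels).index("Fp1")
        o1 = list(rec.channel_labels).index("O1")
        p_dirty = hilbert_band_power(dirty.samples[fp1], fs, 1, 4)
        p_clean = hilbert_band_power(cleaned.samples[fp1], fs, 1, 4)
        assert p_clean <= 0.5 * p_dirty
        a_dirty = hilbert_band_power(dirty.samples[o1], fs, 8, 12)
        a_clean = hilbert_band_power(cleaned.samples[o1], fs, 8, 12)
        assert abs(a_clean - a_dirty) / a_dirty < 0.10

    def test_deterministic(self, clean_recording):
        out1, r1 = remove_ocular_ica(clean_recording, seed=5)
        out2, r2 = remove_ocular_ica(clean_recording, seed=5)
        assert r1["removed"] == r2["removed"]
        assert np.array_equal(out1.samples, out2.samples)

    def test_too_short_rejected(self, tone_10hz):
        short = Recording(subject_id="s", eye_state="EO", sampling_rate_hz=500.0,
                          channel_labels=tone_10hz.channel_labels,
                          samples=tone_10hz.samples[:, :5000])
        with pytest.raises(ValueError):
            remove_ocular_ica(short, seed=0)


class TestEpoching:
    def test_trailing_partial_discarded(self):
        rec = make_tone(10.0, fs=500.0, duration_s=61.0)
        es = epoch(rec, 2.0)
        assert es.n_epochs == 30
        assert es.epochs.shape == (30, 19, 1000)
        assert es.retained_mask.all()

    def test_clinical_protocol_epoch_count(self):
        # 10-minute session at 500 Hz -> 300 two-second epochs
        rec = make_tone(10.0, fs=500.0, duration_s=600.0, n_channels=2)
        assert epoch(rec, 2.0).n_epochs == 300

    def test_too_short_recording(self):
        rec = make_tone(10.0, fs=500.0, duration_s=1.9)
        with pytest.raises(ValueError):
            epoch(rec, 2.0)


class TestRejection:
    def _epochset(self, n=3, amp=None):
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 10, size=(n, 19, 1000))
        es = EpochSet(epochs=eps, sampling_rate_hz=500.0,
                      channel_labels=montage.CHANNELS, epoch_length_s=2.0,
                      retained_mask=np.ones(n, dtype=bool))
        return es

    def test_single_excursion_logged(self):
        es = self._epochset()
        t3 = montage.CHANNELS.index("T3")
        es.epochs[1, t3, 137] = 200.0
        out = reject_epochs(es, 150.0)
        assert out.n_retained == 2
        assert not out.retained_mask[1]
        assert out.rejection_log[0]["channel"] == "T3"
        assert out.rejection_log[0]["peak_uv"] == pytest.approx(200.0)
        assert np.array_equal(out.epochs, es.epochs)  # samples untouched

    def test_all_within_threshold_retained(self):
        out = reject_epochs(self._epochset(), 150.0)
        assert out.retained_mask.all()

    def test_boundary_is_strict(self):
        es = self._epochset()
        es.epochs[0, 0, 0] = 150.0
        out = reject_epochs(es, 150.0)
        assert out.retained_mask[0]

    def test_all_rejected_raises(self):
        es = self._epochset()
        es.epochs += 1000.0
        with pytest.raises(ValueError, match="threshold"):
            reject_epochs(es, 150.0)


class TestAverageReference:
    def test_channel_sum_zero(self):
        es = TestRejection()._epochset()
        out = rereference_average(es)
        sums = out.epochs.sum(axis=1)
        assert np.abs(sums).max() < 1e-9 * np.abs(es.epochs).max()
        assert out.reference == "average"

    def test_identical_channels_become_zero(self):
        eps = np.tile(np.random.default_rng(1).normal(size=(1, 1, 100)), (1, 2, 1))
        es = EpochSet(epochs=eps, sampling_rate_hz=500.0,
                      channel_labels=("C3", "C4"), epoch_length_s=0.2,
                      retained_mask=np.ones(1, dtype=bool))
        out = rereference_average(es)
        assert np.allclose(out.epochs, 0.0)

    def test_idempotent(self):
        es = TestRejection()._epochset()
        once = rereference_average(es)
        twice = rereference_average(once)
        assert np.allclose(once.epochs, twice.epochs)

    def test_single_channel_rejected(self):
        es = EpochSet(epochs=np.zeros((1, 1, 100)), sampling_rate_hz=500.0,
                      channel_labels=("Cz",), epoch_length_s=0.2,
                      retained_mask=np.ones(1, dtype=bool))
        with pytest.raises(ValueError):
            rereference_average(es)


def test_label_normalization_aliases():
    assert montage.normalize_label("FP1") == "Fp1"
    assert montage.normalize_label("T7") == "T3"
    assert montage.normalize_label("p8") == "T6"
    with pytest.raises(ValueError):
        montage.normalize_label("XX9")
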