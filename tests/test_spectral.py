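"""PSD, band powers, relative powers, ROI aggregation, asymmetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from eegmdd import montage, simulate
from eegmdd.preprocess import EpochSet, epoch
from eegmdd.spectral import (asymmetry_scores, band_powers, epoch_psd,
                             hilbert_band_power, relative_powers,
                             roi_relative_power, subject_features)

FS = 500.0
SPE = 1000  # samples per 2-s epoch


def sine_epoch(freq, amp=1.0, fs=FS, n=SPE):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestEpochPSD:
    def test_line_spectrum_concentrated(self):
        f, p = epoch_psd(sine_epoch(10.0), FS)
        in_band = (f >= 1) & (f <= 40)
        near = (f >= 9) & (f <= 11)
        assert p[near].sum() / p[in_band].sum() >= 0.95

    def test_parseval_on_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(SPE)
        f, p = epoch_psd(x, FS)
        df = f[1] - f[0]
        w = sps.get_window("hann", SPE)
        var_tapered = np.mean((x * w) ** 2) / np.mean(w**2)
        assert p.sum() * df == pytest.approx(var_tapered, rel=0.05)

    def test_grid_resolution(self):
        f, _ = epoch_psd(sine_epoch(10.0), FS)
        assert f[1] - f[0] == pytest.approx(0.5)

    def test_zero_signal(self):
        _, p = epoch_psd(np.zeros(SPE), FS)
        assert np.all(p == 0)

    def test_nan_rejected(self):
        x = sine_epoch(10.0)
        x[3] = np.nan
        with pytest.raises(ValueError):
            epoch_psd(x, FS)


class TestBandPowers:
    def test_flat_spectrum_bandwidth_ratios(self):
        # analytic flat PSD on the 0.5 Hz grid
        f = np.arange(0, 126, 0.5)
        p = np.ones_like(f)
        bp = band_powers(f, p)
        total = sum(bp.values())
        expected = {"delta": 3, "theta": 4, "alpha": 4, "beta1": 4,
                    "beta2": 8, "beta3": 16.5}  # beta3 closed at 40 Hz
        for b, width in expected.items():
            assert bp[b] == pytest.approx(width)
        assert total == pytest.approx(39.5)

    def test_alpha_tone_dominates(self):
        f, p = epoch_psd(sine_epoch(10.0), FS)
        bp = band_powers(f, p)
        for b in montage.BAND_NAMES:
            if b != "alpha":
                assert bp["alpha"] >= 20 * bp[b]

    def test_fft_vs_hilbert_on_band_limited_noise(self):
        rng = np.random.default_rng(1)
        sos = sps.butter(4, [16, 24], btype="bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(60 * int(FS)))
        es = x.reshape(-1, SPE)
        f, p = epoch_psd(es, FS)
        fft_power = band_powers(f, p)["beta2"].mean()
        hil_power = hilbert_band_power(x, FS, 16, 24)
        assert fft_power == pytest.approx(hil_power, rel=0.10)

    def test_uncovered_band_raises(self):
        f = np.arange(0, 20, 0.5)
        with pytest.raises(ValueError):
            band_powers(f, np.ones_like(f))


class TestRelativePowers:
    def test_equal_powers_sixths(self):
        rel = relative_powers({b: 2.0 for b in montage.BAND_NAMES})
        for b in montage.BAND_NAMES:
            assert rel[b] == pytest.approx(1 / 6)

    def test_pure_alpha(self):
        f, p = epoch_psd(sine_epoch(10.0), FS)
        rel = relative_powers(band_powers(f, p))
        assert rel["alpha"] > 0.95

    def test_scale_invariance(self):
        bp = {b: v for b, v in zip(montage.BAND_NAMES, [1, 2, 3, 4, 5, 6.0])}
        doubled = {b: 2 * v for b, v in bp.items()}
        r1, r2 = relative_powers(bp), relative_powers(doubled)
        for b in bp:
            assert r1[b] == pytest.approx(r2[b])

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            relative_powers({b: 0.0 for b in montage.BAND_NAMES})


class TestROIAggregation:
    def _fractions(self, rows):
        return pd.DataFrame(rows, columns=list(montage.BAND_NAMES))

    def test_mean_of_identical_channels(self):
        v = np.array([0.1, 0.15, 0.3, 0.15, 0.2, 0.1])
        df = pd.DataFrame([v] * 3, index=["Fp1", "Fp2", "Fz"],
                          columns=list(montage.BAND_NAMES))
        out = roi_relative_power(df, montage.ROIS["PFC"])
        assert np.allclose(out.to_numpy(), v)

    def test_arithmetic_mean(self):
        df = pd.DataFrame(0.12, index=["Fp1", "Fp2", "Fz"],
                          columns=list(montage.BAND_NAMES))
        df.loc["Fp1", "alpha"], df.loc["Fp2", "alpha"], df.loc["Fz", "alpha"] = .4, .2, .3
        df = df.div(df.sum(axis=1), axis=0)
        raw = pd.DataFrame(0.12, index=["Fp1", "Fp2", "Fz"],
                           columns=list(montage.BAND_NAMES))
        raw.loc["Fp1", "alpha"], raw.loc["Fp2", "alpha"], raw.loc["Fz", "alpha"] = .4, .2, .3
        out = roi_relative_power(raw, ("Fp1", "Fp2", "Fz"))
        assert out["alpha"] == pytest.approx(0.3 / raw.sum(axis=1).mean(), rel=0.05)

    def test_sum_to_one_preserved(self):
        rng = np.random.default_rng(2)
        m = rng.random((19, 6))
        df = pd.DataFrame(m / m.sum(axis=1, keepdims=True),
                          index=list(montage.CHANNELS),
                          columns=list(montage.BAND_NAMES))
        for roi, chans in montage.ROIS.items():
            assert roi_relative_power(df, chans).sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_channel_named(self):
        df = pd.DataFrame(np.full((2, 6), 1 / 6), index=["Fp1", "Fp2"],
                          columns=list(montage.BAND_NAMES))
        with pytest.raises(ValueError, match="Fz"):
            roi_relative_power(df, ("Fp1", "Fp2", "Fz"))


class TestAsymmetry:
    def _roi_df(self, rng=None):
        rng = rng or np.random.default_rng(3)
        m = rng.random((10, 6))
        return pd.DataFrame(m / m.sum(axis=1, keepdims=True),
                            index=list(montage.ROIS),
                            columns=list(montage.BAND_NAMES))

    def test_identical_hemispheres_zero(self):
        df = self._roi_df()
        for right, left in montage.PAIRS.values():
            df.loc[left] = df.loc[right]
        assert np.allclose(asymmetry_scores(df).to_numpy(), 0.0)

    def test_antisymmetry_under_pair_swap(self):
        df = self._roi_df()
        fwd = asymmetry_scores(df)
        swapped = {name: (l, r) for name, (r, l) in montage.PAIRS.items()}
        rev = asymmetry_scores(df, pairs=swapped)
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_simple_difference(self):
        df = self._roi_df()
        df.loc["RT", "alpha"], df.loc["LT", "alpha"] = 0.30, 0.28
        out = asymmetry_scores(df)
        assert out.loc["RT-LT", "alpha"] == pytest.approx(0.02)

    def test_delta_excluded(self):
        out = asymmetry_scores(self._roi_df())
        assert "delta" not in out.columns
        assert list(out.columns) == list(montage.ASYMMETRY_BANDS)


class TestSubjectFeatures:
    def _epochset(self, epochs):
        return EpochSet(epochs=epochs, sampling_rate_hz=FS,
                        channel_labels=montage.CHANNELS, epoch_length_s=2.0,
                        retained_mask=np.ones(len(epochs), dtype=bool))

    def test_identical_epochs_match_single(self):
        rng = np.random.default_rng(4)
        one = rng.standard_normal((1, 19, SPE))
        few = np.tile(one, (5, 1, 1))
        f1 = subject_features(self._epochset(one), "s", "EO")
        f5 = subject_features(self._epochset(few), "s", "EO")
        assert np.allclose(f1.relative_power.to_numpy(),
                           f5.relative_power.to_numpy())
        assert f5.n_epochs_used == 5

    def test_epoch_order_invariance(self):
        rng = np.random.default_rng(5)
        eps = rng.standard_normal((8, 19, SPE))
        f = subject_features(self._epochset(eps), "s", "EO")
        g = subject_features(self._epochset(eps[::-1].copy()), "s", "EO")
        assert np.allclose(f.relative_power.to_numpy(), g.relative_power.to_numpy())

    def test_long_run_stability(self):
        # stationary white-noise signal: the 300-epoch average converges to
        # the analytic flat-spectrum bandwidth fractions, and the 30-epoch
        # estimate tracks it within periodogram Monte-Carlo error (the
        # smallest band pools ~6 bins/epoch, so ~8% relative SD at 30
        # epochs; 4 sigma bound)
        rng = np.random.default_rng(6)
        eps = rng.standard_normal((300, 19, SPE))
        f300 = subject_features(self._epochset(eps), "s", "EO").relative_power
        f30 = subject_features(self._epochset(eps[:30]), "s", "EO").relative_power
        widths = np.array([3, 4, 4, 4, 8, 16.5])
        expected = widths / widths.sum()
        assert np.abs(f300.to_numpy() - expected).max() < 0.02
        rel_err = np.abs(f30.to_numpy() - f300.to_numpy()) / f300.to_numpy()
        assert rel_err.max() < 0.32

    def test_no_retained_epochs_raises(self):
        es = self._epochset(np.zeros((2, 19, SPE)))
        es.retained_mask[:] = False
        with pytest.raises(ValueError):
            subject_features(es, "s", "EO")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_sum_to_one_and_antisymmetry_properties(seed):
    """Random epochs: ROI fractions sum to 1; asymmetry flips under swap."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((2, 19, 200)) * rng.uniform(0.5, 50)
    es = EpochSet(epochs=eps, sampling_rate_hz=100.0,
                  channel_labels=montage.CHANNELS, epoch_length_s=2.0,
                  retained_mask=np.ones(2, dtype=bool))
    f = subject_features(es, "s", "EO")
    sums = f.relative_power.sum(axis=1).to_numpy()
    assert np.allclose(sums, 1.0, atol=1e-6)
    for pair, (right, left) in montage.PAIRS.items():
        expected = (f.relative_power.loc[right, list(montage.ASYMMETRY_BANDS)]
                    - f.relative_power.loc[left, list(montage.ASYMMETRY_BANDS)])
        assert np.allclose(f.asymmetry.loc[pair].to_numpy(),
                           expected.to_numpy())
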