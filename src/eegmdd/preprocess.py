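"""Preprocessing chain for resting-state EEG recordings.

The fixed pipeline order is: band-pass filter -> notch filter ->
downsample -> ICA ocular removal -> 2-s epoching -> amplitude-based epoch
rejection -> average re-reference.  Epoch rejection runs on the original
(pre-average) reference; re-referencing is applied last.  Every stage
appends a provenance entry so an epoch set's full history is
reconstructible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .montage import CHANNELS, channel_index, normalize_label


@dataclass
class Recording:
    """One subject/eye-state multichannel EEG time series.

    samples are channels x time in microvolts; channel_labels are canonical
    10-20 names; provenance is the ordered list of applied operations.
    """

    subject_id: str
    eye_state: str  # "EO" or "EC"
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    samples: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.channel_labels = tuple(normalize_label(c) for c in self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be channels x time")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain NaN")
        if self.eye_state not in ("EO", "EC"):
            raise ValueError(f"eye_state must be EO or EC, got {self.eye_state!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray, step: dict) -> "Recording":
        """Copy with new samples and one more provenance entry."""
        return replace(
            self, samples=samples, provenance=self.provenance + [step]
        )


@dataclass
class EpochSet:
    """Consecutive fixed-length epochs with a retention mask.

    epochs: n_epochs x channels x samples_per_epoch (microvolts).
    rejection_log: one dict per rejected epoch (epoch index, worst channel,
    peak absolute amplitude).  reference is "original" until average
    re-referencing is applied.
    """

    epochs: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    epoch_length_s: float
    retained_mask: np.ndarray
    rejection_log: list[dict] = field(default_factory=list)
    reference: str = "original"
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def retained(self) -> np.ndarray:
        return self.epochs[self.retained_mask]


def _bandpass_sos(lo_hz: float, hi_hz: float, fs: float, order: int) -> np.ndarray:
    return signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(rec: Recording, lo_hz: float = 1.0, hi_hz: float = 40.0,
                    order: int = 12) -> Recording:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (sosfiltfilt) so the net phase is zero.  The
    default order keeps the two-pass passband gain within +/-0.5 dB over
    2-35 Hz while stopping DC and drift.
    """
    nyq = rec.sampling_rate_hz / 2
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(f"band edges must satisfy 0 < {lo_hz} < {hi_hz} < Nyquist {nyq}")
    sos = _bandpass_sos(lo_hz, hi_hz, rec.sampling_rate_hz, order)
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.with_samples(out, {"op": "bandpass", "lo_hz": lo_hz, "hi_hz": hi_hz,
                                  "order": order, "zero_phase": True})


def notch_filter(rec: Recording, stop_lo_hz: float = 49.0,
                 stop_hi_hz: float = 51.0, order: int = 2) -> Recording:
    """Zero-phase Butterworth band-stop for power-line interference."""
    nyq = rec.sampling_rate_hz / 2
    if not (0 < stop_lo_hz < stop_hi_hz < nyq):
        raise ValueError(f"stopband [{stop_lo_hz}, {stop_hi_hz}] outside (0, Nyquist {nyq})")
    sos = signal.butter(order, [stop_lo_hz, stop_hi_hz], btype="bandstop",
                        fs=rec.sampling_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.with_samples(out, {"op": "notch", "stop_lo_hz": stop_lo_hz,
                                  "stop_hi_hz": stop_hi_hz, "order": order})


def downsample(rec: Recording, target_hz: float = 500.0) -> Recording:
    """Polyphase resampling to a lower rate.

    The signal must already be band-limited below the target Nyquist (the
    band-pass stage guarantees this for the 1-40 Hz analysis band).
    """
    if target_hz >= rec.sampling_rate_hz:
        raise ValueError(
            f"target rate {target_hz} Hz must be below current {rec.sampling_rate_hz} Hz")
    ratio = Fraction(target_hz / rec.sampling_rate_hz).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=1)
    new = rec.with_samples(out, {"op": "downsample", "target_hz": target_hz,
                                 "up": ratio.numerator, "down": ratio.denominator})
    new.sampling_rate_hz = target_hz
    return new


def remove_ocular_ica(rec: Recording, seed: int,
                      corr_threshold: float = 0.7,
                      frontal_ratio: float = 3.0,
                      max_iter: int = 400) -> tuple[Recording, dict]:
    """Remove ocular components with a seeded FastICA decomposition.

    A component is marked ocular if its time course correlates with the
    mean of Fp1/Fp2 beyond ``corr_threshold`` in absolute value, or its
    mixing weights are frontally dominated (mean |weight| at Fp1/Fp2 more
    than ``frontal_ratio`` times the median |weight| across channels).
    Marked components are zeroed and the signal reconstructed.

    FastICA's formal convergence flag is recorded but a non-converged
    decomposition is still used: near-Gaussian background sources make the
    unmixing rotation non-identifiable (so the iteration wanders), while
    the decomposition still reconstructs the data exactly and the
    non-Gaussian ocular components it does isolate are stable.  Only a
    hard decomposition failure falls back to pass-through, with a logged
    warning (never silent).
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if rec.n_channels < 2:
        raise ValueError("ICA requires at least 2 channels")
    if rec.duration_s < 30.0:
        raise ValueError("ICA requires at least 30 s of data")

    idx = channel_index(rec.channel_labels)
    for ch in ("Fp1", "Fp2"):
        if ch not in idx:
            raise ValueError(f"ocular reference channel {ch} missing")
    eog_proxy = rec.samples[[idx["Fp1"], idx["Fp2"]]].mean(axis=0)

    X = rec.samples.T  # time x channels
    mean = X.mean(axis=0)
    ica = FastICA(n_components=rec.n_channels, whiten="unit-variance",
                  random_state=int(seed) % (2**32), max_iter=max_iter, tol=1e-4)
    converged = True
    failed = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            S = ica.fit_transform(X)  # time x components
        except Exception:
            failed = True
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
    if failed:
        report = {"converged": False, "removed": [],
                  "warning": "ICA decomposition failed; pass-through"}
        out = rec.with_samples(rec.samples.copy(),
                               {"op": "ica", "seed": seed, "converged": False,
                                "removed": [], "warning": report["warning"]})
        return out, report

    A = ica.mixing_  # channels x components
    sd_eog = eog_proxy.std()
    removed, corrs, ratios = [], [], []
    med_by_comp = np.median(np.abs(A), axis=0)
    for j in range(S.shape[1]):
        sj = S[:, j]
        r = 0.0
        if sd_eog > 0 and sj.std() > 0:
            r = float(np.corrcoef(sj, eog_proxy)[0, 1])
        frontal = np.abs(A[[idx["Fp1"], idx["Fp2"]], j]).mean()
        ratio = float(frontal / med_by_comp[j]) if med_by_comp[j] > 0 else np.inf
        corrs.append(r)
        ratios.append(ratio)
        if abs(r) > corr_threshold or ratio > frontal_ratio:
            removed.append(j)

    S_clean = S.copy()
    S_clean[:, removed] = 0.0
    X_clean = S_clean @ A.T + mean
    report = {"converged": True, "removed": removed,
              "eog_correlation": corrs, "frontal_ratio": ratios}
    out = rec.with_samples(np.ascontiguousarray(X_clean.T),
                           {"op": "ica", "seed": seed, "converged": True,
                            "removed": removed})
    return out, report


def epoch(rec: Recording, length_s: float = 2.0) -> EpochSet:
    """Cut the recording into consecutive non-overlapping epochs.

    A trailing partial epoch is discarded; all epochs start retained.
    """
    spe = int(round(length_s * rec.sampling_rate_hz))
    n = rec.samples.shape[1] // spe
    if n < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s shorter than epoch length {length_s} s")
    cut = rec.samples[:, : n * spe]
    eps = cut.reshape(rec.n_channels, n, spe).transpose(1, 0, 2).copy()
    return EpochSet(
        epochs=eps,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_labels=rec.channel_labels,
        epoch_length_s=length_s,
        retained_mask=np.ones(n, dtype=bool),
        provenance=rec.provenance + [{"op": "epoch", "length_s": length_s,
                                      "n_epochs": n}],
    )


def reject_epochs(es: EpochSet, threshold_uv: float = 150.0) -> EpochSet:
    """Reject epochs with voltage excursions beyond +/- threshold.

    "Beyond" is strict: a peak of exactly +/-threshold is retained.  Sample
    values are never modified; rejection only clears the retention mask and
    logs the offending channel and peak amplitude.
    """
    if es.reference != "original":
        raise ValueError("rejection must run on the original reference")
    peaks = np.abs(es.epochs).max(axis=2)  # n_epochs x channels
    bad = peaks.max(axis=1) > threshold_uv
    mask = es.retained_mask & ~bad
    log = list(es.rejection_log)
    for i in np.flatnonzero(bad & es.retained_mask):
        ch = int(peaks[i].argmax())
        log.append({"epoch": int(i), "channel": es.channel_labels[ch],
                    "peak_uv": float(peaks[i, ch])})
    if mask.sum() == 0:
        raise ValueError(
            "all epochs rejected; review the amplitude threshold "
            f"({threshold_uv} uV) or artifact contamination")
    return EpochSet(
        epochs=es.epochs, sampling_rate_hz=es.sampling_rate_hz,
        channel_labels=es.channel_labels, epoch_length_s=es.epoch_length_s,
        retained_mask=mask, rejection_log=log, reference=es.reference,
        provenance=es.provenance + [{"op": "reject", "threshold_uv": threshold_uv,
                                     "n_rejected": int(bad.sum())}],
    )


def rereference_average(es: EpochSet) -> EpochSet:
    """Re-reference every epoch to the instantaneous channel average.

    Idempotent: subtracting the channel mean is a projection.
    """
    if es.epochs.shape[1] < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = es.epochs - es.epochs.mean(axis=1, keepdims=True)
    return EpochSet(
        epochs=out, sampling_rate_hz=es.sampling_rate_hz,
        channel_labels=es.channel_labels, epoch_length_s=es.epoch_length_s,
        retained_mask=es.retained_mask.copy(), rejection_log=list(es.rejection_log),
        reference="average",
        provenance=es.provenance + [{"op": "rereference", "scheme": "average"}],
    )


def preprocess_recording(rec: Recording, *, band=(1.0, 40.0), notch=(49.0, 51.0),
                         resample_hz: float | None = 500.0, epoch_s: float = 2.0,
                         reject_uv: float = 150.0, run_ica: bool = True,
                         seed: int = 0) -> EpochSet:
    """Run the full fixed-order preprocessing chain on one recording.

    Downsampling is skipped (and logged) when the recording is already at
    or below the target rate.
    """
    r = bandpass_filter(rec, band[0], band[1])
    r = notch_filter(r, notch[0], notch[1])
    if resample_hz is not None and resample_hz < r.sampling_rate_hz:
        r = downsample(r, resample_hz)
    elif resample_hz is not None:
        r = r.with_samples(r.samples, {"op": "downsample", "skipped": True,
                                       "reason": "rate already <= target"})
    if run_ica:
        r, _ = remove_ocular_ica(r, seed=seed)
    es = epoch(r, epoch_s)
    es = reject_epochs(es, reject_uv)
    return rereference_average(es)
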