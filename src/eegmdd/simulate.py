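"""Synthetic resting-state EEG cohorts for a two-group (MDD vs HC) study.

Each channel is the sum of a 1/f^chi Gaussian background and six
band-limited Gaussian oscillations (the spectral shape of a 4th-order
Butterworth band-pass applied to white noise), synthesized in the
frequency domain.  Group, eye-state, and regional structure enter as
multiplicative amplitude effects on (channel-set, band) cells; hemispheric
asymmetry enters as fractional amplitude shifts applied with opposite
signs to homologous right/left channel sets.  Posterior alpha is enhanced
in the eyes-closed state (alpha blocking on eye opening).

Between-subject variability is log-normal per band, shared across both
eye states of a subject.  The subject's standardized beta2 latent also
drives the simulated HDRS-17 severity score, producing a tunable positive
correlation between frontal beta2 relative power and symptom severity.

The entire cohort is a pure function of the simulation spec, including
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from . import montage
from .preprocess import Recording

FRONTAL = ("Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8")
CENTRAL = ("C3", "Cz", "C4")
OCCIPITAL = ("P3", "P4", "Pz", "O1", "O2")


@dataclass(frozen=True)
class BandEffect:
    """Multiplicative amplitude effect on a (group, eye state, channels, band) cell."""

    group: str       # "MDD" or "HC"
    eye_state: str   # "EO" or "EC"
    channels: tuple[str, ...]
    band: str
    factor: float


@dataclass(frozen=True)
class AsymmetryShift:
    """Fractional amplitude shift: right channels x(1+s), left x(1-s)."""

    group: str
    eye_state: str
    right: tuple[str, ...]
    left: tuple[str, ...]
    band: str
    shift: float


def default_effects() -> tuple[BandEffect, ...]:
    """Group effects mirroring the reported MDD contrasts.

    Eyes open: frontal (and weaker central) beta2 elevation and occipital
    beta3 reduction in MDD.  Eyes closed: right medial-frontal beta2 and
    right temporal alpha elevation, right medial-occipital beta3 reduction.
    Magnitudes were calibrated once against large-cohort runs of this
    generator to land the corresponding relative-power effect sizes in the
    reported d ~ 0.4-0.7 range, with the eyes-open frontal beta2 effect
    the strongest.
    """
    return (
        BandEffect("MDD", "EO", FRONTAL, "beta2", 1.38),
        BandEffect("MDD", "EO", CENTRAL, "beta2", 1.12),
        # medial-occipital beta3 reduction: O1/O2 carry the full factor;
        # Pz, shared with the parietal region, receives the mean of its
        # regions' multipliers
        BandEffect("MDD", "EO", ("O1", "O2"), "beta3", 0.84),
        BandEffect("MDD", "EO", ("Pz",), "beta3", 0.92),
        # eyes-closed beta2: right medial frontal carries the full effect,
        # the left a weaker subthreshold one, so the induced RMFC-LMFC
        # beta2 asymmetry stays small as reported
        BandEffect("MDD", "EC", ("Fz", "F4", "F8"), "beta2", 1.28),
        BandEffect("MDD", "EC", ("F3", "F7"), "beta2", 1.18),
        BandEffect("MDD", "EC", ("F8", "T4", "T6"), "alpha", 1.08),
        BandEffect("MDD", "EC", ("P4", "O2", "Pz"), "beta3", 0.85),
    )


_RT = ("F8", "T4", "T6")
_LT = ("F7", "T3", "T5")


def default_asymmetry_shifts() -> tuple[AsymmetryShift, ...]:
    """Right-temporal asymmetry shifts with the reported group signs.

    Eyes open: MDD shows right-shifted alpha and beta1 (HC slightly
    left-shifted) and loses the HC right-shift in beta2/beta3.  Eyes
    closed: MDD right-shifts alpha; HC carries a small positive theta
    asymmetry that MDD lacks.
    """
    return (
        AsymmetryShift("HC", "EO", _RT, _LT, "beta1", -0.017),
        AsymmetryShift("MDD", "EO", _RT, _LT, "beta1", 0.030),
        AsymmetryShift("HC", "EO", _RT, _LT, "alpha", -0.015),
        AsymmetryShift("MDD", "EO", _RT, _LT, "alpha", 0.015),
        AsymmetryShift("HC", "EO", _RT, _LT, "beta2", 0.014),
        AsymmetryShift("MDD", "EO", _RT, _LT, "beta2", -0.004),
        AsymmetryShift("HC", "EO", _RT, _LT, "beta3", 0.016),
        AsymmetryShift("MDD", "EO", _RT, _LT, "beta3", -0.005),
        AsymmetryShift("HC", "EC", _RT, _LT, "theta", 0.007),
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults use a desk-scale preset (60 s per eye state at 250 Hz, 40
    subjects per group) so the full pipeline runs in minutes; the clinical
    acquisition protocol (600 s at 1000 Hz) is available by configuration.
    Amplitudes are uV RMS within the 1-40 Hz analysis band.
    """

    n_mdd: int = 40
    n_hc: int = 40
    duration_s: float = 60.0
    sampling_rate_hz: float = 250.0
    noise_exponent: float = 1.0
    background_rms_uv: float = 3.5
    base_band_amplitudes: dict = field(default_factory=lambda: {
        "delta": 4.0, "theta": 3.0, "alpha": 4.5,
        "beta1": 1.8, "beta2": 1.5, "beta3": 1.3,
    })
    # Posterior alpha dominance of the resting rhythm.
    alpha_posterior_gain: float = 1.6
    effect_multipliers: tuple[BandEffect, ...] = field(default_factory=default_effects)
    asymmetry_shifts: tuple[AsymmetryShift, ...] = field(
        default_factory=default_asymmetry_shifts)
    alpha_reactivity: float = 2.0          # EC/EO posterior alpha amplitude ratio
    subject_band_sd: float = 0.25          # log-normal sigma of per-band subject factors
    channel_jitter_sd: float = 0.15        # log-normal sigma of per-(channel, band) jitter
    blink_rate_hz: float = 0.0
    excursion_rate_per_min: float = 0.0
    clinical_coupling: float = 1.8         # HDRS points per SD of the beta2 latent
    hdrs_base: float = 6.6                 # mean HDRS excess over the >=17 inclusion floor
    hdrs_noise_sd: float = 4.9
    hama_mean: float = 20.1
    hama_sd: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_mdd < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.alpha_reactivity < 1:
            raise ValueError("alpha_reactivity must be >= 1 (EC alpha >= EO alpha)")
        for r in (self.blink_rate_hz, self.excursion_rate_per_min):
            if r < 0:
                raise ValueError("artifact rates must be >= 0")
        if any(a < 0 for a in self.base_band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        for eff in self.effect_multipliers:
            _check_channels(eff.channels, f"effect on band {eff.band!r}")
        for sh in self.asymmetry_shifts:
            _check_channels(sh.right + sh.left, f"asymmetry shift on band {sh.band!r}")


def _check_channels(channels, context: str):
    unknown = [c for c in channels if c not in montage.CHANNELS]
    if unknown:
        raise ValueError(f"unknown channels {unknown} in {context}")


@dataclass
class SubjectMeta:
    """Demographic and clinical metadata for one simulated subject."""

    subject_id: str
    group: str  # "MDD" or "HC"
    sex: str
    age: float
    hdrs17: float | None
    hama: float | None

    def __post_init__(self):
        if self.group not in ("MDD", "HC"):
            raise ValueError("group must be MDD or HC")
        if self.hdrs17 is not None:
            if self.group != "MDD":
                raise ValueError("HDRS-17 is recorded for MDD subjects only")
            if self.hdrs17 < 17:
                raise ValueError("MDD inclusion requires HDRS-17 >= 17")


# ---------------------------------------------------------------------------
# spectral shapes

_SHAPE_CACHE: dict = {}


def _band_shapes(fs: float, n: int) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Unit-power spectral shapes of the six band oscillations on the rfft grid.

    Each shape is the squared magnitude response of a 4th-order Butterworth
    band-pass, normalized to integrate to 1 over the grid, so multiplying
    by a squared RMS amplitude yields that component's PSD.
    """
    key = (float(fs), int(n))
    if key in _SHAPE_CACHE:
        return _SHAPE_CACHE[key]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = fs / n
    shapes = {}
    for band, (lo, hi) in montage.BANDS.items():
        hi_eff = min(hi, 0.95 * fs / 2)
        sos = signal.butter(4, [lo, hi_eff], btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
        p = np.abs(h) ** 2
        shapes[band] = p / (p.sum() * df)
    _SHAPE_CACHE[key] = (freqs, shapes)
    return freqs, shapes


def _background_psd(freqs: np.ndarray, exponent: float, rms_uv: float) -> np.ndarray:
    """1/f^chi background PSD normalized to rms_uv within 1-40 Hz."""
    df = freqs[1] - freqs[0]
    shape = np.zeros_like(freqs)
    valid = freqs >= 0.5
    shape[valid] = 1.0 / np.maximum(freqs[valid], 0.5) ** exponent
    in_band = (freqs >= 1.0) & (freqs <= 40.0)
    band_power = shape[in_band].sum() * df
    return shape * (rms_uv**2 / band_power)


# ---------------------------------------------------------------------------
# subject profiles and amplitudes


def _subject_profile(subject_seed: int) -> dict:
    """Per-subject latent factors, identical for both eye states.

    z holds standardized normal latents per band; the band amplitude
    factor is exp(sigma * z).  Channel jitter is a log-normal gain per
    channel shared across bands.
    """
    rng = np.random.default_rng([int(subject_seed), 0])
    z = {band: float(rng.standard_normal()) for band in montage.BAND_NAMES}
    # per-(channel, band) jitter: a gain shared across bands would cancel
    # in relative power, leaving asymmetry scores artificially noise-free
    jitter = rng.standard_normal((len(montage.CHANNELS), len(montage.BAND_NAMES)))
    return {"z": z, "jitter": jitter}


def _band_amplitude_matrix(spec: SimulationSpec, group: str, eye_state: str,
                           profile: dict) -> np.ndarray:
    """Per-(channel, band) RMS amplitudes after all modulations."""
    n_ch = len(montage.CHANNELS)
    bands = montage.BAND_NAMES
    amp = np.zeros((n_ch, len(bands)))
    ch_idx = montage.channel_index(list(montage.CHANNELS))
    posterior = [ch_idx[c] for c in montage.POSTERIOR_CHANNELS]
    for j, band in enumerate(bands):
        a = spec.base_band_amplitudes[band] * np.exp(
            spec.subject_band_sd * profile["z"][band])
        col = np.full(n_ch, a)
        if band == "alpha":
            col[posterior] *= spec.alpha_posterior_gain
            if eye_state == "EC":
                col[posterior] *= spec.alpha_reactivity
        amp[:, j] = col
    amp *= np.exp(spec.channel_jitter_sd * profile["jitter"])
    for eff in spec.effect_multipliers:
        if eff.group == group and eff.eye_state == eye_state:
            rows = [ch_idx[c] for c in eff.channels]
            amp[rows, bands.index(eff.band)] *= eff.factor
    for sh in spec.asymmetry_shifts:
        if sh.group == group and sh.eye_state == eye_state:
            j = bands.index(sh.band)
            amp[[ch_idx[c] for c in sh.right], j] *= max(0.0, 1.0 + sh.shift)
            amp[[ch_idx[c] for c in sh.left], j] *= max(0.0, 1.0 - sh.shift)
    return amp


def generate_recording(spec: SimulationSpec, meta: SubjectMeta, eye_state: str,
                       subject_seed: int) -> Recording:
    """Synthesize one artifact-free 19-channel recording.

    The subject's latent profile is derived from subject_seed alone, so
    the same seed yields the same subject across eye states; the noise
    draw additionally depends on the eye state.
    """
    if eye_state not in ("EO", "EC"):
        raise ValueError("eye_state must be EO or EC")
    n = int(round(spec.duration_s * spec.sampling_rate_hz))
    freqs, shapes = _band_shapes(spec.sampling_rate_hz, n)
    df = spec.sampling_rate_hz / n
    profile = _subject_profile(subject_seed)
    amp = _band_amplitude_matrix(spec, meta.group, eye_state, profile)

    psd = np.tile(_background_psd(freqs, spec.noise_exponent,
                                  spec.background_rms_uv), (len(montage.CHANNELS), 1))
    for j, band in enumerate(montage.BAND_NAMES):
        psd += amp[:, j:j + 1] ** 2 * shapes[band][None, :]

    rng = np.random.default_rng([int(subject_seed), 1, 0 if eye_state == "EO" else 1])
    nf = freqs.size
    scale = n * np.sqrt(psd * df / 2.0)
    X = scale * (rng.standard_normal((len(montage.CHANNELS), nf))
                 + 1j * rng.standard_normal((len(montage.CHANNELS), nf))) / np.sqrt(2.0)
    X[:, 0] = 0.0
    if n % 2 == 0:
        X[:, -1] = 0.0
    samples = np.fft.irfft(X, n=n, axis=1)
    return Recording(
        subject_id=meta.subject_id, eye_state=eye_state,
        sampling_rate_hz=spec.sampling_rate_hz,
        channel_labels=montage.CHANNELS, samples=samples,
        provenance=[{"op": "simulate", "group": meta.group,
                     "eye_state": eye_state, "subject_seed": int(subject_seed)}],
    )


# ---------------------------------------------------------------------------
# artifacts

_BLINK_GAINS = {
    "Fp1": 1.0, "Fp2": 1.0, "Fz": 0.45, "F3": 0.35, "F4": 0.35,
    "F7": 0.30, "F8": 0.30, "C3": 0.12, "Cz": 0.12, "C4": 0.12,
    "T3": 0.08, "T4": 0.08, "T5": 0.04, "P3": 0.04, "Pz": 0.04,
    "P4": 0.04, "T6": 0.04, "O1": 0.02, "O2": 0.02,
}


def inject_artifacts(rec: Recording, spec: SimulationSpec,
                     seed: int) -> tuple[Recording, pd.DataFrame]:
    """Add ocular blinks and high-voltage excursion bursts.

    Blinks are 0.3-1 s smooth positive transients peaking 100-300 uV at
    Fp1/Fp2 and decaying posteriorly.  Excursions are 0.15-0.4 s signed
    bursts of 250-450 uV peak on a single random channel.  Returns the
    contaminated recording and a ground-truth table (start_s, end_s, kind,
    channel, peak_uv); for excursions start/end delimit the span where the
    injected waveform alone exceeds 150 uV, which is what an amplitude
    rejection stage should detect.
    """
    rng = np.random.default_rng([int(seed), 7])
    fs = rec.sampling_rate_hz
    n = rec.samples.shape[1]
    out = rec.samples.copy()
    idx = montage.channel_index(rec.channel_labels)
    truth = []

    n_blinks = rng.poisson(spec.blink_rate_hz * rec.duration_s)
    for _ in range(n_blinks):
        dur = rng.uniform(0.3, 1.0)
        peak = rng.uniform(100.0, 300.0)
        start = rng.uniform(0, rec.duration_s - dur)
        i0, i1 = int(start * fs), int((start + dur) * fs)
        t = np.arange(i1 - i0)
        template = peak * np.sin(np.pi * t / max(1, i1 - i0 - 1)) ** 2
        for ch, gain in _BLINK_GAINS.items():
            if ch in idx:
                out[idx[ch], i0:i1] += gain * template
        truth.append({"start_s": start, "end_s": start + dur, "kind": "blink",
                      "channel": "Fp1", "peak_uv": peak})

    n_exc = rng.poisson(spec.excursion_rate_per_min * rec.duration_s / 60.0)
    for _ in range(n_exc):
        dur = rng.uniform(0.15, 0.4)
        peak = rng.uniform(250.0, 450.0) * rng.choice([-1.0, 1.0])
        start = rng.uniform(0, rec.duration_s - dur)
        ch = rng.choice(len(rec.channel_labels))
        i0, i1 = int(start * fs), int((start + dur) * fs)
        t = np.arange(i1 - i0)
        template = peak * np.sin(np.pi * t / max(1, i1 - i0 - 1)) ** 2
        out[ch, i0:i1] += template
        over = np.flatnonzero(np.abs(template) > 150.0)
        if over.size:
            truth.append({"start_s": (i0 + over[0]) / fs,
                          "end_s": (i0 + over[-1] + 1) / fs, "kind": "excursion",
                          "channel": rec.channel_labels[ch], "peak_uv": float(peak)})

    truth_df = pd.DataFrame(truth, columns=["start_s", "end_s", "kind",
                                            "channel", "peak_uv"])
    step = {"op": "inject_artifacts", "seed": int(seed),
            "n_blinks": int(n_blinks), "n_excursions": int(n_exc)}
    epoch_s = 2.0
    n_epochs = max(1, int(rec.duration_s // epoch_s))
    contaminated = len({int(r["start_s"] // epoch_s) for r in truth})
    if n_epochs and (n_epochs - contaminated) / n_epochs < 0.10:
        step["warning"] = ("artifact rates leave fewer than 10% of epochs clean")
    return rec.with_samples(out, step), truth_df


# ---------------------------------------------------------------------------
# cohort


def subject_seed_for(spec_seed: int, index: int) -> int:
    """Stable per-subject seed derived from the cohort seed."""
    return int(np.random.SeedSequence([int(spec_seed), int(index)]).generate_state(1)[0])


def generate_cohort(spec: SimulationSpec) -> tuple[list[dict], pd.DataFrame]:
    """Generate all subjects of a two-group cohort.

    Returns (subjects, meta_table).  Each subject dict holds the meta, the
    EO and EC recordings, and any ground-truth artifact table.  The MDD
    HDRS-17 score couples positively to the subject's beta2 latent, so
    frontal beta2 relative power and severity correlate at roughly the
    configured strength.
    """
    groups = ["MDD"] * spec.n_mdd + ["HC"] * spec.n_hc
    meta_rng = np.random.default_rng([int(spec.seed), 99])
    subjects = []
    rows = []
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        sseed = subject_seed_for(spec.seed, i)
        profile = _subject_profile(sseed)
        p_male = 31 / 86 if group == "MDD" else 37 / 83
        sex = "M" if meta_rng.random() < p_male else "F"
        age_mu, age_sd = (26.2, 6.3) if group == "MDD" else (26.4, 8.2)
        age = float(np.clip(meta_rng.normal(age_mu, age_sd), 18, 65))
        hdrs = hama = None
        if group == "MDD":
            z = profile["z"]["beta2"]
            raw = (spec.hdrs_base + spec.clinical_coupling * z
                   + meta_rng.normal(0.0, spec.hdrs_noise_sd))
            hdrs = 17.0 + max(0.0, round(raw))
            hama = float(max(0.0, round(meta_rng.normal(spec.hama_mean, spec.hama_sd))))
        meta = SubjectMeta(subject_id=sid, group=group, sex=sex, age=round(age, 1),
                           hdrs17=hdrs, hama=hama)
        recs = {}
        truths = []
        for state in ("EO", "EC"):
            rec = generate_recording(spec, meta, state, sseed)
            if spec.blink_rate_hz > 0 or spec.excursion_rate_per_min > 0:
                rec, truth = inject_artifacts(
                    rec, spec, seed=subject_seed_for(spec.seed, 10_000 + 2 * i
                                                     + (state == "EC")))
                truth.insert(0, "eye_state", state)
                truth.insert(0, "subject_id", sid)
                truths.append(truth)
            recs[state] = rec
        subjects.append({"meta": meta, "recordings": recs,
                         "artifacts": (pd.concat(truths, ignore_index=True)
                                       if truths else None)})
        rows.append({"subject_id": sid, "group": group, "sex": sex,
                     "age": meta.age, "hdrs17": hdrs, "hama": hama})
    meta_df = pd.DataFrame(rows)
    return subjects, meta_df


def null_spec(**overrides) -> SimulationSpec:
    """Spec with all group effects and asymmetry shifts switched off."""
    base = SimulationSpec(effect_multipliers=(), asymmetry_shifts=(), **overrides)
    return base


def scale_effects(spec: SimulationSpec, gain: float) -> SimulationSpec:
    """Scale every multiplicative effect toward/away from 1 and every shift by gain."""
    effs = tuple(replace(e, factor=1.0 + gain * (e.factor - 1.0))
                 for e in spec.effect_multipliers)
    shifts = tuple(replace(s, shift=gain * s.shift) for s in spec.asymmetry_shifts)
    return replace(spec, effect_multipliers=effs, asymmetry_shifts=shifts)
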