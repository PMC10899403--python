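"""Electrode montage, frequency bands, and regions of interest.

The analysis uses the 19-channel international 10-20 montage and six
frequency bands spanning the 1-40 Hz broadband range.  Electrodes are
grouped into ten partially overlapping regions of interest (ROIs); three
homologous left/right ROI pairs define hemispheric asymmetry scores.
"""

from __future__ import annotations

# Canonical 10-20 channel order (old nomenclature: T3/T4 temporal, T5/T6
# posterior-temporal).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Modern 10-10 names accepted as aliases of the classic temporal labels.
_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_CANONICAL_BY_UPPER = {c.upper(): c for c in CHANNELS}


def normalize_label(label: str) -> str:
    """Map a channel label to its canonical 10-20 name.

    Matching is case-insensitive ("FP1" -> "Fp1") and accepts the modern
    temporal aliases T7/T8/P7/P8 for T3/T4/T5/T6.  Unknown labels raise
    ``ValueError``.
    """
    key = label.strip().upper()
    key = {a.upper(): c for a, c in _ALIASES.items()}.get(key, key)
    try:
        return _CANONICAL_BY_UPPER[key]
    except KeyError:
        raise ValueError(f"unknown 10-20 channel label: {label!r}") from None


# Six analysis bands as (low, high) in Hz.  Ranges are half-open [lo, hi)
# so shared edges are counted once; the final band is closed at 40 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta1": (12.0, 16.0),
    "beta2": (16.0, 24.0),
    "beta3": (24.0, 40.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

BROADBAND: tuple[float, float] = (1.0, 40.0)

# Ten regions of interest.  Fz and Pz are shared between neighbouring
# regions, so ROIs overlap by construction.
ROIS: dict[str, tuple[str, ...]] = {
    "PFC": ("Fp1", "Fp2", "Fz"),
    "RMFC": ("Fz", "F4", "F8"),
    "LMFC": ("Fz", "F3", "F7"),
    "CC": ("C3", "C4", "Cz"),
    "PP": ("P3", "P4", "Pz"),
    "LT": ("F7", "T3", "T5"),
    "RT": ("F8", "T4", "T6"),
    "MOC": ("O1", "Pz", "O2"),
    "RMOC": ("P4", "O2", "Pz"),
    "LMOC": ("P3", "O1", "Pz"),
}

# Homologous (right, left) ROI pairs for asymmetry scores.
PAIRS: dict[str, tuple[str, str]] = {
    "RMFC-LMFC": ("RMFC", "LMFC"),
    "RMOC-LMOC": ("RMOC", "LMOC"),
    "RT-LT": ("RT", "LT"),
}

# Asymmetry is reported for theta..beta3 only (delta excluded).
ASYMMETRY_BANDS: tuple[str, ...] = ("theta", "alpha", "beta1", "beta2", "beta3")

# Posterior channels showing eyes-closed alpha enhancement (alpha blocking
# on eye opening is strongest over parieto-occipital cortex).
POSTERIOR_CHANNELS: tuple[str, ...] = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")


def channel_index(labels: list[str] | tuple[str, ...]) -> dict[str, int]:
    """Return a name -> row index map for a channel label sequence."""
    return {lab: i for i, lab in enumerate(labels)}
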