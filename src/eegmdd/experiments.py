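"""Reusable study procedures: printed-statistic checks and simulation studies.

This module packages the repeatable experiments the analysis scripts and
the acceptance layer both run:

* recomputation of the reference clinical cohort's printed demographic
  chi-squares and the temporal beta1 asymmetry effect size from its
  published group summaries;
* spectral calibration of the band-power stack on white noise;
* ground-truth recovery of injected excursion artifacts by the rejection
  stage;
* repeated-cohort parameter recovery (is the strongest FDR-corrected
  group contrast a frontal beta2 feature? does the diagnostic model
  discriminate?) and null calibration (type-I error and chance-level AUC
  with all effects off).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import model as model_mod
from . import montage, simulate, stats
from .io import PipelineConfig
from .pipeline import analyze_cohort
from .preprocess import epoch, reject_epochs
from .spectral import band_powers, epoch_psd

# Demographics of the reference clinical cohort (86 MDD / 83 HC):
# counts by group for sex (male/female) and marital status
# (married/unmarried), and the group summaries of the eyes-open RT-LT
# beta1 asymmetry (mean, SD, n) for HC and MDD.
REFERENCE_SEX_COUNTS = [[31, 55], [37, 46]]        # rows: MDD, HC; cols: M, F
REFERENCE_MARITAL_COUNTS = [[57, 28], [54, 28]]    # rows: MDD, HC
REFERENCE_RTLT_BETA1_EO = {"hc": (-0.003, 0.018, 83), "mdd": (0.008, 0.022, 86)}

FRONTAL_ROIS = ("PFC", "RMFC", "LMFC")

# Bandwidths of the six bands on the analysis grid (Hz); white noise
# should split its relative power proportionally.
BANDWIDTH_FRACTIONS = {
    band: (hi - lo) / (montage.BROADBAND[1] - montage.BROADBAND[0])
    for band, (lo, hi) in montage.BANDS.items()
}


def demographic_chi_squares() -> dict:
    """Recompute the reference cohort's sex and marital chi-squares."""
    chi_sex, p_sex = stats.chi_square_2x2(REFERENCE_SEX_COUNTS)
    chi_mar, p_mar = stats.chi_square_2x2(REFERENCE_MARITAL_COUNTS)
    return {"chi2_sex": chi_sex, "p_sex": p_sex,
            "chi2_marital": chi_mar, "p_marital": p_mar}


def reference_asymmetry_effect_size() -> float:
    """Cohen's d (HC minus MDD) of the reference RT-LT beta1 EO asymmetry."""
    hc = REFERENCE_RTLT_BETA1_EO["hc"]
    mdd = REFERENCE_RTLT_BETA1_EO["mdd"]
    return stats.d_from_summaries(*hc, *mdd)


def flat_spectrum_calibration(n_epochs: int = 120, seed: int = 0,
                              fs: float = 250.0) -> dict:
    """Mean six-band relative powers of white-noise epochs.

    White noise has a flat PSD, so relative powers should match the
    bandwidth fractions (3, 4, 4, 4, 8, 16)/39.  Returns the measured
    fractions and the maximum absolute deviation from those ratios.
    """
    rng = np.random.default_rng(seed)
    spe = int(2 * fs)
    x = rng.standard_normal((n_epochs, spe))
    freqs, psd = epoch_psd(x, fs)
    bp = band_powers(freqs, psd)
    total = sum(bp.values())
    measured = {b: float((bp[b] / total).mean()) for b in montage.BAND_NAMES}
    dev = {b: abs(measured[b] - BANDWIDTH_FRACTIONS[b]) for b in measured}
    return {"measured": measured, "expected": dict(BANDWIDTH_FRACTIONS),
            "max_abs_deviation": max(dev.values()), "n_epochs": n_epochs}


def excursion_recovery(seed: int = 0, duration_s: float = 60.0,
                       excursion_rate_per_min: float = 4.0) -> dict:
    """Inject excursion bursts and check the rejection stage recovers them.

    Returns the ground-truth and detected epoch-index sets plus
    sensitivity/specificity of the rejection against the injection truth.
    """
    spec = simulate.null_spec(duration_s=duration_s, seed=seed,
                              excursion_rate_per_min=excursion_rate_per_min)
    meta = simulate.SubjectMeta(subject_id="sub-art", group="HC", sex="F",
                                age=30.0, hdrs17=None, hama=None)
    rec = simulate.generate_recording(spec, meta, "EO", subject_seed=seed)
    dirty, truth = simulate.inject_artifacts(rec, spec, seed=seed)
    es = epoch(dirty, 2.0)
    rejected = set()
    try:
        es2 = reject_epochs(es, 150.0)
        rejected = set(np.flatnonzero(~es2.retained_mask))
    except ValueError:
        rejected = set(range(es.n_epochs))
    exc = truth[truth.kind == "excursion"]
    true_epochs = set()
    for _, row in exc.iterrows():
        first = int(row.start_s // 2.0)
        last = int(np.nextafter(row.end_s, row.start_s) // 2.0)
        true_epochs.update(range(first, min(last, es.n_epochs - 1) + 1))
    tp = len(true_epochs & rejected)
    sens = tp / len(true_epochs) if true_epochs else 1.0
    clean = set(range(es.n_epochs)) - true_epochs
    spec_ = len(clean - rejected) / len(clean) if clean else 1.0
    return {"true_epochs": sorted(true_epochs), "rejected_epochs": sorted(rejected),
            "sensitivity": sens, "specificity": spec_, "n_epochs": es.n_epochs}


def _cohort_config(seed: int) -> PipelineConfig:
    # Simulated calibration cohorts are artifact-free, so the ocular-ICA
    # stage has nothing to remove and is skipped for speed.
    return PipelineConfig(ica=False, seed=seed, n_boot=200)


def effect_recovery_study(n_cohorts: int = 25, seed: int = 0,
                          spec: simulate.SimulationSpec | None = None) -> pd.DataFrame:
    """Repeated default cohorts with effects on: per-cohort recovery metrics.

    For each cohort records whether the smallest FDR-adjusted power p-value
    is a frontal beta2 feature, and the stratified 10-fold CV mean AUC of
    the diagnostic model.
    """
    rows = []
    for c in range(n_cohorts):
        cseed = seed * 100_000 + c
        sp = spec if spec is not None else simulate.SimulationSpec(seed=cseed)
        if spec is not None:
            sp = dataclasses.replace(sp, seed=cseed)
        subs, meta = simulate.generate_cohort(sp)
        cfg = _cohort_config(cseed)
        feats, st, _, _ = analyze_cohort(subs, meta, cfg, with_model=False,
                                         with_correlations=False)
        X, y, _ = model_mod.design_matrix(feats, meta)
        cv = model_mod.cross_validated_performance(X, y, k=cfg.cv_folds, seed=cseed)
        pw = st[st.feature_type == "power"]
        best = pw.loc[pw.p_fdr.idxmin()]
        rows.append({
            "cohort": c,
            "top_feature": f"{best.eye_state}:{best.region_or_pair}:{best.band}",
            "top_is_frontal_beta2": bool(best.region_or_pair in FRONTAL_ROIS
                                         and best.band == "beta2"),
            "cv_mean_auc": cv["mean_auc"],
            "cv_sensitivity": cv["mean_sensitivity"],
            "cv_specificity": cv["mean_specificity"],
        })
    return pd.DataFrame(rows)


def null_calibration_study(n_cohorts: int = 50, seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Repeated cohorts with all effects off: type-I error and chance AUC.

    Returns the across-cohort mean CV AUC, the pooled fraction of raw
    p-values below alpha across all 150 features per cohort, and the
    per-cohort AUC list.
    """
    aucs, p_below = [], []
    n_tests = 0
    for c in range(n_cohorts):
        cseed = seed * 100_000 + 50_000 + c
        sp = simulate.null_spec(seed=cseed)
        subs, meta = simulate.generate_cohort(sp)
        cfg = _cohort_config(cseed)
        feats, st, _, _ = analyze_cohort(subs, meta, cfg, with_model=False,
                                         with_correlations=False)
        X, y, _ = model_mod.design_matrix(feats, meta)
        cv = model_mod.cross_validated_performance(X, y, k=cfg.cv_folds, seed=cseed)
        aucs.append(cv["mean_auc"])
        p_below.append(int((st.p_raw < alpha).sum()))
        n_tests += len(st)
    return {"mean_cv_auc": float(np.mean(aucs)), "cv_aucs": aucs,
            "type1_rate": sum(p_below) / n_tests, "n_cohorts": n_cohorts,
            "n_tests": n_tests}


def clinical_correlation_study(seed: int = 0, n_mdd: int = 86, n_hc: int = 83) -> dict:
    """One cohort at the reference sample size: r(HDRS-17, PFC beta2 EO)."""
    sp = simulate.SimulationSpec(n_mdd=n_mdd, n_hc=n_hc, seed=seed)
    subs, meta = simulate.generate_cohort(sp)
    feats, _, corr, _ = analyze_cohort(subs, meta, _cohort_config(seed),
                                       with_model=False)
    row = corr[(corr.eye_state == "EO") & (corr.feature_type == "power")
               & (corr.region_or_pair == "PFC") & (corr.band == "beta2")
               & (corr.scale == "hdrs17")]
    return {"r": float(row.r.iloc[0]), "p": float(row.p.iloc[0]),
            "n": int(row.n.iloc[0])}
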