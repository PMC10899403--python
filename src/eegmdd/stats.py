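"""Group-level inference: t-tests, Cohen's d, chi-square, BH-FDR, correlations.

The group contrast table compares MDD and HC on every (eye state, feature)
cell: 10 ROIs x 6 bands of relative power plus 3 ROI pairs x 5 bands of
asymmetry, per eye state (150 rows).  FDR correction is applied within
four families: power and asymmetry features separately per eye state.
Cohen's d uses the HC-minus-MDD difference over the n-1-weighted pooled
SD, so a band elevated in MDD carries a negative d.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def two_sample_t(x, y, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default, pooled available).

    Two zero-variance samples with equal means return (0, 1) by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Standardized mean difference with the n-1-weighted pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    return d_from_summaries(x.mean(), x.std(ddof=1), x.size,
                            y.mean(), y.std(ddof=1), y.size)


def d_from_summaries(m1: float, s1: float, n1: int,
                     m2: float, s2: float, n2: int) -> float:
    """Cohen's d from printed group summaries (mean, SD, n)."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled SD is zero: d undefined")
    return (m1 - m2) / math.sqrt(sp2)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be a 2x2 nonnegative integer table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def group_contrast_table(features: pd.DataFrame, meta: pd.DataFrame,
                         variant: str = "welch") -> pd.DataFrame:
    """MDD vs HC contrast for every (eye state, feature) cell.

    features is the tidy table (subject_id, eye_state, feature_type,
    region_or_pair, band, value); meta supplies the group labels.  Returns
    one row per feature with group means/SDs, t, raw p, FDR-adjusted p
    (within eye-state x feature-type families), and Cohen's d
    (HC minus MDD).  Features missing for more than half of either group
    are skipped with a warning.
    """
    df = features.drop(columns=["group"], errors="ignore").merge(
        meta[["subject_id", "group"]], on="subject_id")
    n_by_group = meta.groupby("group")["subject_id"].nunique()
    for g in ("MDD", "HC"):
        if n_by_group.get(g, 0) < 2:
            raise ValueError(f"group {g} needs n >= 2")
    rows = []
    keys = ["eye_state", "feature_type", "region_or_pair", "band"]
    for key, sub in df.groupby(keys, sort=False):
        x = sub.loc[sub.group == "HC", "value"].to_numpy()
        y = sub.loc[sub.group == "MDD", "value"].to_numpy()
        if (x.size < n_by_group["HC"] / 2) or (y.size < n_by_group["MDD"] / 2):
            warnings.warn(f"feature {key} missing for >50% of a group; skipped")
            continue
        t, p = two_sample_t(x, y, variant=variant)
        rows.append(dict(zip(keys, key)) | {
            "mean_hc": x.mean(), "sd_hc": x.std(ddof=1), "n_hc": x.size,
            "mean_mdd": y.mean(), "sd_mdd": y.std(ddof=1), "n_mdd": y.size,
            "t": t, "p_raw": p, "cohen_d": cohens_d(x, y),
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for (_, _), idx in out.groupby(["eye_state", "feature_type"]).groups.items():
        out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p_raw"].to_numpy())
    return out


def clinical_correlations(features: pd.DataFrame, meta: pd.DataFrame,
                          scales: tuple[str, ...] = ("hdrs17", "hama"),
                          group: str = "MDD") -> pd.DataFrame:
    """Pearson correlation of every feature with clinical scores within a group."""
    sub_meta = meta[meta.group == group].set_index("subject_id")
    df = features[features.subject_id.isin(sub_meta.index)]
    keys = ["eye_state", "feature_type", "region_or_pair", "band"]
    wide = df.pivot_table(index="subject_id", columns=keys, values="value")
    rows = []
    for scale in scales:
        score = sub_meta.loc[wide.index, scale]
        ok = score.notna()
        if ok.sum() < 3:
            continue
        s = score[ok].to_numpy(dtype=float)
        for key in wide.columns:
            r, p = pearson_r(wide.loc[ok, key].to_numpy(dtype=float), s)
            rows.append(dict(zip(keys, key)) | {"scale": scale, "r": r, "p": p,
                                                "n": int(ok.sum())})
    return pd.DataFrame(rows)
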