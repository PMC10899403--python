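"""Diagnostic layer: logistic regression, ROC/Youden analysis, cross-validation.

The diagnostic model is an unpenalized binary logistic regression on raw
(unstandardized) EEG features — relative powers are fractions, so
coefficients on the order of tens are expected.  Performance is assessed
by stratified 10-fold cross-validation: per fold the model is fit on the
training split, test subjects are scored, fold AUC is the trapezoidal
area under the ROC, and fold sensitivity/specificity are measured at the
Youden-optimal cut-off derived from the training scores (deriving the
cut-off on the test fold would leak).  A percentile bootstrap over
subjects, stratified by class, gives the AUC confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

# Feature set of the published diagnostic model: every (eye state,
# feature) whose group t-test was significant at raw p < 0.05.
DEFAULT_FEATURE_SET: tuple[tuple[str, str, str, str], ...] = (
    ("EO", "power", "PFC", "beta2"),
    ("EO", "power", "RMFC", "beta2"),
    ("EO", "power", "LMFC", "beta2"),
    ("EO", "power", "CC", "beta2"),
    ("EO", "power", "MOC", "beta3"),
    ("EO", "asymmetry", "RT-LT", "alpha"),
    ("EO", "asymmetry", "RT-LT", "beta1"),
    ("EO", "asymmetry", "RT-LT", "beta2"),
    ("EO", "asymmetry", "RT-LT", "beta3"),
    ("EC", "power", "PFC", "beta3"),
    ("EC", "power", "RMFC", "beta2"),
    ("EC", "power", "RT", "alpha"),
    ("EC", "power", "RT", "beta3"),
    ("EC", "power", "MOC", "beta3"),
    ("EC", "power", "RMOC", "beta3"),
    ("EC", "power", "LMOC", "beta3"),
    ("EC", "asymmetry", "RT-LT", "theta"),
    ("EC", "asymmetry", "RT-LT", "alpha"),
)


def design_matrix(features: pd.DataFrame, meta: pd.DataFrame,
                  feature_set=DEFAULT_FEATURE_SET) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot the tidy feature table into (X, y, names) for the model.

    y is 1 for MDD, 0 for HC.  Raises if any requested feature is absent.
    """
    df = features.drop(columns=["group"], errors="ignore")
    key = df.eye_state + ":" + df.feature_type + ":" + df.region_or_pair + ":" + df.band
    wide = df.assign(key=key).pivot_table(index="subject_id", columns="key",
                                          values="value")
    names = [f"{s}:{t}:{r}:{b}" for s, t, r, b in feature_set]
    missing = [n for n in names if n not in wide.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    wide = wide[names].loc[meta.subject_id]
    y = (meta.group == "MDD").to_numpy(dtype=int)
    return wide.to_numpy(), y, names


def _sigmoid(z):
    return 0.5 * (1 + np.tanh(z / 2))


def fit_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 200) -> dict:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Returns coefficients B (intercept first), standard errors from the
    inverse observed information, and two-sided Wald p-values.  If the
    coefficients diverge (complete or quasi-separation) the model is refit
    with a small ridge (lambda = 1e-4) and the report is flagged.
    Constant features and singular designs raise with the offending
    columns named.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    const = [j for j in range(p) if np.ptp(X[:, j]) == 0]
    if const:
        raise ValueError(f"constant feature columns: {const}")
    Xd = np.column_stack([np.ones(n), X])

    def irls(ridge: float):
        beta = np.zeros(p + 1)
        ll_old = -np.inf
        for _ in range(max_iter):
            eta = Xd @ beta
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (y - mu) / w
            XtW = Xd.T * w
            H = XtW @ Xd + ridge * np.eye(p + 1)
            try:
                beta = np.linalg.solve(H, XtW @ z)
            except np.linalg.LinAlgError:
                raise ValueError("singular design matrix; check for collinear columns")
            mu = np.clip(_sigmoid(Xd @ beta), 1e-12, 1 - 1e-12)
            ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu)) \
                - 0.5 * ridge * float(beta @ beta)
            if abs(ll - ll_old) < tol:
                ll_old = ll
                break
            ll_old = ll
        return beta, ll_old

    beta, ll = irls(0.0)
    # diverging standardized slopes signal complete/quasi-separation
    scaled = np.abs(beta[1:]) * X.std(axis=0)
    separated = bool(scaled.max(initial=0.0) > 12.0 or abs(beta[0]) > 30.0)
    if separated or not np.isfinite(beta).all():
        beta, ll = irls(1e-4)
    mu = np.clip(_sigmoid(Xd @ beta), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    info = (Xd.T * w) @ Xd + (1e-4 if separated else 0.0) * np.eye(p + 1)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ValueError("singular information matrix; check for collinear columns")
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * sps.norm.sf(np.abs(zstat))
    return {"B": beta, "SE": se, "p": pvals, "log_likelihood": ll,
            "ridged": separated, "n_iter_converged": True}


def predict_proba(fit: dict, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return _sigmoid(np.column_stack([np.ones(len(X)), X]) @ fit["B"])


@dataclass
class ROCResult:
    """ROC curve with the Youden-optimal operating point."""

    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float = field(default=np.nan)
    youden_sens: float = field(default=np.nan)
    youden_spec: float = field(default=np.nan)


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all unique score thresholds, rule: score >= threshold => positive.

    AUC is the trapezoidal integral of sensitivity against 1-specificity;
    it equals the Mann-Whitney U statistic divided by n+ * n-.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    npos, nneg = int(y.sum()), int((1 - y).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    ss, ys = s[order], y[order]
    cum_pos = np.cumsum(ys)
    cum_neg = np.cumsum(1 - ys)
    # last occurrence of each unique score in descending order
    last = np.flatnonzero(np.diff(ss, append=-np.inf) != 0)
    thr = np.concatenate([[np.inf], ss[last]])
    sens = np.concatenate([[0.0], cum_pos[last] / npos])
    spec = np.concatenate([[1.0], 1.0 - cum_neg[last] / nneg])
    auc = float(np.trapezoid(sens, 1 - spec))
    roc = ROCResult(thresholds=thr, sensitivity=sens, specificity=spec, auc=auc)
    roc.youden_cutoff, roc.youden_sens, roc.youden_spec = youden_cutoff(roc)
    return roc


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the lowest threshold, favoring sensitivity.
    The +inf sentinel is never returned when a finite threshold ties it.
    """
    j = roc.sensitivity + roc.specificity - 1
    best = np.flatnonzero(j >= j.max() - 1e-12)
    finite = best[np.isfinite(roc.thresholds[best])]
    k = int((finite if finite.size else best)[-1])  # thresholds descending
    return (float(roc.thresholds[k]), float(roc.sensitivity[k]),
            float(roc.specificity[k]))


def cross_validated_performance(X, y, k: int = 10, seed: int = 0,
                                feature_names=None) -> dict:
    """Stratified k-fold CV of the logistic model.

    Returns fold-mean AUC and fold-mean sensitivity/specificity at
    training-derived Youden cut-offs (and, secondarily, at the fixed 0.5
    probability cut-off), plus the pooled out-of-fold scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= k={k} members for stratified CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    aucs, sens_y, spec_y, sens_5, spec_5 = [], [], [], [], []
    oof_scores = np.full(len(y), np.nan)
    for train, test in skf.split(X, y):
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValueError("fold with a single class: stratification violated")
        fit = fit_logistic(X[train], y[train])
        p_train = predict_proba(fit, X[train])
        p_test = predict_proba(fit, X[test])
        oof_scores[test] = p_test
        cut, _, _ = youden_cutoff(roc_curve(p_train, y[train]))
        fold_roc = roc_curve(p_test, y[test])
        aucs.append(fold_roc.auc)
        for cutoff, sl, pl in ((cut, sens_y, spec_y), (0.5, sens_5, spec_5)):
            pred = p_test >= cutoff
            sl.append((pred & (y[test] == 1)).sum() / max(1, (y[test] == 1).sum()))
            pl.append((~pred & (y[test] == 0)).sum() / max(1, (y[test] == 0).sum()))
    return {
        "mean_auc": float(np.mean(aucs)),
        "mean_sensitivity": float(np.mean(sens_y)),
        "mean_specificity": float(np.mean(spec_y)),
        "mean_sensitivity_at_0.5": float(np.mean(sens_5)),
        "mean_specificity_at_0.5": float(np.mean(spec_5)),
        "fold_aucs": [float(a) for a in aucs],
        "oof_scores": oof_scores,
        "k": k, "seed": int(seed),
    }


def auc_confidence_interval(scores, labels, n_boot: int = 2000,
                            seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap 95% CI for the AUC, resampling within classes."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size < 5 or neg.size < 5:
        raise ValueError("need >= 5 subjects per class for the bootstrap")
    rng = np.random.default_rng(int(seed) % (2**32))
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size, replace=True),
                              rng.choice(neg, neg.size, replace=True)])
        aucs[b] = roc_curve(s[idx], y[idx]).auc
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class ModelReport:
    """Coefficients and cross-validated performance of the diagnostic model."""

    feature_names: list[str]
    B: np.ndarray
    SE: np.ndarray
    p: np.ndarray
    ridged: bool
    cv_mean_auc: float
    cv_sensitivity: float
    cv_specificity: float
    auc_ci_95: tuple[float, float]
    k: int
    seed: int

    def to_dict(self) -> dict:
        rows = [{"feature": n, "B": float(b), "SE": float(s), "p": float(pv)}
                for n, b, s, pv in zip(["intercept"] + self.feature_names,
                                       self.B, self.SE, self.p)]
        return {"coefficients": rows, "ridged": self.ridged,
                "cv_mean_auc": self.cv_mean_auc,
                "cv_sensitivity": self.cv_sensitivity,
                "cv_specificity": self.cv_specificity,
                "auc_ci_95": list(self.auc_ci_95), "k": self.k, "seed": self.seed}


def diagnostic_report(features: pd.DataFrame, meta: pd.DataFrame,
                      feature_set=DEFAULT_FEATURE_SET, k: int = 10,
                      seed: int = 0, n_boot: int = 2000) -> ModelReport:
    """Fit the full-sample model and cross-validate it; pure in (data, seed).

    The confidence interval bootstraps the AUC of the pooled out-of-fold
    scores, so it describes the cross-validated discrimination (it need
    not bracket the fold-mean AUC).
    """
    X, y, names = design_matrix(features, meta, feature_set)
    fit = fit_logistic(X, y)
    cv = cross_validated_performance(X, y, k=k, seed=seed)
    ci = auc_confidence_interval(cv["oof_scores"], y, n_boot=n_boot, seed=seed + 1)
    return ModelReport(feature_names=names, B=fit["B"], SE=fit["SE"], p=fit["p"],
                       ridged=fit["ridged"], cv_mean_auc=cv["mean_auc"],
                       cv_sensitivity=cv["mean_sensitivity"],
                       cv_specificity=cv["mean_specificity"],
                       auc_ci_95=ci, k=k, seed=seed)
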