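"""Utility (signal-retention) comparisons between original and synthetic data.

Three evaluations mirror the standard audit of an anonymized dataset:
a factor-space overlay (both tables projected into the space fitted on
the originals only), a two-arm survival comparison (Kaplan-Meier
curves, log-rank test, Cox proportional-hazards HR with Wald p), and a
classification comparison (per-feature F-score ranking feeding a
radial-kernel SVM, AUC over repeated stratified 70/30 splits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import TabularDataset, validate_against
from .projection import fit_famd, transform

__all__ = [
    "UtilityError",
    "overlay_coordinates",
    "survival_comparison",
    "f_scores",
    "classification_comparison",
]


class UtilityError(ValueError):
    """Invalid input to a utility evaluation."""


def overlay_coordinates(
    original: TabularDataset, synthetic: TabularDataset
) -> dict:
    """Project both tables into the space fitted on the originals only.

    Returns full component scores for distance work plus the first two
    components of each cloud for plotting.
    """
    ok, issues = validate_against(synthetic, original.schema)
    if not ok:
        raise UtilityError(f"synthetic data does not match original schema: {issues}")
    model = fit_famd(original)
    co = transform(model, original)
    cs = transform(model, synthetic)
    return {
        "model": model,
        "original": co,
        "synthetic": cs,
        "original_2d": co[:, : min(2, model.ncomp)],
        "synthetic_2d": cs[:, : min(2, model.ncomp)],
    }


def _binary_numeric(data: TabularDataset, col: str) -> np.ndarray:
    spec = data.spec(col)
    if spec.is_numeric:
        v = data.numeric_view(col)
    else:
        levels = sorted(set(data.frame[col]))
        v = data.frame[col].map({l: i for i, l in enumerate(levels)}).to_numpy(float)
    uniq = np.unique(v)
    if uniq.size != 2:
        raise UtilityError(f"column {col!r} is not binary (levels {uniq})")
    return (v == uniq.max()).astype(int)


def survival_comparison(
    data: TabularDataset, time_col: str, event_col: str, arm_col: str
) -> dict:
    """Two-arm survival analysis on one dataset.

    Fits a single-covariate Cox model (Efron ties), reporting the hazard
    ratio of arm 1 vs arm 0 with its 95% CI and Wald p, Kaplan-Meier
    estimates per arm, and the log-rank test.
    """
    time = data.numeric_view(time_col)
    if np.any(time <= 0):
        raise UtilityError("event times must be positive")
    event = _binary_numeric(data, event_col)
    arm = _binary_numeric(data, arm_col)
    for a in (0, 1):
        if event[arm == a].sum() == 0:
            raise UtilityError(f"arm {a} has no events; Cox fit is degenerate")
    df = pd.DataFrame({"time": time, "event": event, "arm": arm})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["arm"])
    lo, hi = cph.confidence_intervals_.loc["arm"].to_numpy(float)
    km = {}
    for a in (0, 1):
        fitter = KaplanMeierFitter()
        fitter.fit(time[arm == a], event[arm == a], label=f"arm{a}")
        sf = fitter.survival_function_
        km[f"arm{a}"] = {
            "time": sf.index.to_numpy(float),
            "survival": sf.iloc[:, 0].to_numpy(float),
        }
    lr = logrank_test(time[arm == 0], time[arm == 1], event[arm == 0], event[arm == 1])
    return {
        "hr": float(np.exp(coef)),
        "hr_ci": (float(np.exp(lo)), float(np.exp(hi))),
        "log_hr": coef,
        "wald_p": float(cph.summary.loc["arm", "p"]),
        "km": km,
        "logrank_stat": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "ties_method": "efron",
    }


def f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher-style discrimination score per feature.

    F(i) = [(mean_i(+) - mean_i)^2 + (mean_i(-) - mean_i)^2]
           / [var_i(+) + var_i(-)]

    with sample variances (ddof=1); the numerator is the squared
    deviation of each class mean from the overall mean.  Invariant to
    row permutation; zero when a feature is identical in both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise UtilityError("each class needs >= 2 rows for variances")
    num = (pos.mean(0) - X.mean(0)) ** 2 + (neg.mean(0) - X.mean(0)) ** 2
    den = pos.var(0, ddof=1) + neg.var(0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return f


def classification_comparison(
    data: TabularDataset,
    outcome_col: str,
    n_repeats: int = 100,
    n_features: int = 5,
    pos_label: str | None = None,
    seed: int = 0,
) -> dict:
    """F-score feature ranking + radial-SVM AUC over repeated 70/30 splits.

    Each repeat draws a stratified 70/30 train/test split; F-scores are
    computed on the training part only, the top ``n_features`` features
    feed an RBF-kernel SVM (default regularization, features standardized
    on the training split) and the AUC is measured on the test part.
    AUC is reported on the percent scale.  ``pos_label`` defaults to the
    minority outcome class.
    """
    spec = data.spec(outcome_col)
    labels = data.frame[outcome_col] if not spec.is_numeric else pd.Series(
        data.numeric_view(outcome_col).astype(int).astype(str)
    )
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise UtilityError(f"outcome {outcome_col!r} must have exactly 2 classes")
    if pos_label is None:
        counts = labels.value_counts()
        pos_label = counts.idxmin()
    y = (labels == pos_label).to_numpy(int)
    feat_names = [v.name for v in data.schema if v.name != outcome_col]
    bad = [n for n in feat_names if not data.spec(n).is_numeric]
    if bad:
        raise UtilityError(f"non-numeric features not supported: {bad}")
    X = np.column_stack([data.numeric_view(n) for n in feat_names])

    n_features = min(n_features, X.shape[1])
    aucs = []
    f_all = []
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=0.30, stratify=y, random_state=split_seed
        )
        f = f_scores(Xtr, ytr)
        f_all.append(f)
        top = np.argsort(-f, kind="stable")[:n_features]
        scaler = StandardScaler().fit(Xtr[:, top])
        clf = SVC(kernel="rbf")
        clf.fit(scaler.transform(Xtr[:, top]), ytr)
        scores = clf.decision_function(scaler.transform(Xte[:, top]))
        aucs.append(100.0 * roc_auc_score(yte, scores))
    f_all = np.asarray(f_all)
    aucs = np.asarray(aucs)
    lo, hi = np.quantile(f_all, [0.025, 0.975], axis=0)
    return {
        "pos_label": pos_label,
        "features": feat_names,
        "f_score_mean": f_all.mean(axis=0),
        "f_score_ci": np.stack([lo, hi], axis=1),
        "selected_rank": [feat_names[i] for i in np.argsort(-f_all.mean(axis=0), kind="stable")],
        "auc_mean": float(aucs.mean()),
        "auc_sd": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        "auc_values": aucs,
        "n_repeats": n_repeats,
        "n_features": n_features,
    }
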