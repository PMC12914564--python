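"""Fisher linear discriminant analysis of per-animal injury features.

Each animal contributes a feature vector (injury volume, IBA1⁺ volume,
IBA1 integrated density).  The Fisher discriminant direction

    w ∝ S_w⁻¹ (μ_case − μ_control)

maximizes between-group over within-group variance; each animal's LDA
score is its projection onto w, centered so the grand mean maps to 0 and
signed so the case (KO) group mean is positive.  Group separation on the
scores is assessed with a two-tailed Welch t-test, and classification
performance with leave-one-out cross-validation (per-fold refit, equal
class priors, midpoint decision threshold).

Features are z-scored before fitting by default — the raw features mix
mm³ and arbitrary-unit scales — which changes the scores only by an
affine reparametrization and leaves LOO accuracy invariant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import LdaResult

__all__ = ["fit_lda", "welch_test", "loo_cv", "lda_analysis"]

DEFAULT_FEATURES = ("injury_volume_mm3", "iba1_volume_mm3",
                    "iba1_integrated_density")


def _extract(table: pd.DataFrame, feature_names, group_col: str):
    X = table.loc[:, list(feature_names)].to_numpy(dtype=float)
    groups = table[group_col].to_numpy()
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    counts = [(groups == g).sum() for g in labels]
    if min(counts) < 2:
        raise ValueError("need at least 2 animals per group")
    if np.any(~np.isfinite(X)):
        raise ValueError("feature table contains missing values")
    return X, groups, labels


def _fisher_direction(X: np.ndarray, y: np.ndarray,
                      pseudo_inverse: bool = True) -> np.ndarray:
    """w ∝ S_w⁻¹ (μ₁ − μ₀) with pooled within-group scatter S_w."""
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for k, mu in ((0, mu0), (1, mu1)):
        d = X[y == k] - mu
        Sw += d.T @ d
    try:
        w = np.linalg.solve(Sw, mu1 - mu0)
    except np.linalg.LinAlgError:
        if not pseudo_inverse:
            raise
        warnings.warn("singular within-group scatter; using pseudo-inverse")
        w = np.linalg.pinv(Sw) @ (mu1 - mu0)
    return w


def fit_lda(
    table: pd.DataFrame,
    feature_names=DEFAULT_FEATURES,
    group_col: str = "group",
    case_label: str | None = None,
    z_score: bool = True,
) -> LdaResult:
    """Fisher LDA with per-animal scores.

    Scores are projections onto the discriminant axis, centered at the
    grand mean; the sign convention makes the case group's mean score
    positive.  ``case_label`` defaults to the second group encountered.
    """
    X, groups, labels = _extract(table, feature_names, group_col)
    if case_label is None:
        case_label = labels[1]
    elif case_label not in labels:
        raise ValueError(f"case_label {case_label!r} not among {list(labels)}")
    y = (groups == case_label).astype(int)
    if z_score:
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs = (X - mean) / sd
    else:
        Xs = X
    w = _fisher_direction(Xs, y)
    raw = Xs @ w
    if raw[y == 1].mean() < raw[y == 0].mean():
        w, raw = -w, -raw
    intercept = -float(raw.mean())
    scores = raw + intercept
    return LdaResult(weight_vector=w, intercept=intercept,
                     scores=scores, groups=list(groups),
                     feature_names=list(feature_names))


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch t-test:
    t = (m₁ − m₂) / √(s₁²/n₁ + s₂²/n₂), Welch–Satterthwaite df.

    Zero variance in both samples with equal means returns (0, 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 observations per group")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # Welch–Satterthwaite df on normalized variance fractions: the df
    # depends only on (v1/n1)/(v2/n2), and normalizing avoids underflow
    # when the variances are extreme
    f1 = (v1 / n1) / se2
    f2 = (v2 / n2) / se2
    df = 1.0 / (f1 ** 2 / (n1 - 1) + f2 ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _classify_fold(X_train, y_train, x_test, z_score: bool) -> int:
    """Fit Fisher LDA on the training fold and classify one held-out
    animal by the midpoint threshold between projected class means."""
    if z_score:
        mean, sd = X_train.mean(axis=0), X_train.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X_train = (X_train - mean) / sd
        x_test = (x_test - mean) / sd
    w = _fisher_direction(X_train, y_train)
    proj = X_train @ w
    m0, m1 = proj[y_train == 0].mean(), proj[y_train == 1].mean()
    s = float(x_test @ w)
    if m1 >= m0:
        return int(s > (m0 + m1) / 2.0)
    return int(s <= (m0 + m1) / 2.0)


def loo_cv(
    table: pd.DataFrame,
    feature_names=DEFAULT_FEATURES,
    group_col: str = "group",
    case_label: str | None = None,
    z_score: bool = True,
) -> float:
    """Leave-one-out accuracy: refit without each animal, classify it."""
    X, groups, labels = _extract(table, feature_names, group_col)
    if case_label is None:
        case_label = labels[1]
    y = (groups == case_label).astype(int)
    correct = 0
    evaluated = 0
    for i in range(len(y)):
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if min((y_tr == 0).sum(), (y_tr == 1).sum()) < 2:
            warnings.warn(f"fold {i}: fewer than 2 per group after holdout; "
                          "fold skipped")
            continue
        pred = _classify_fold(X[keep], y_tr, X[i], z_score)
        correct += int(pred == y[i])
        evaluated += 1
    if evaluated == 0:
        warnings.warn("no evaluable leave-one-out folds; accuracy undefined")
        return float("nan")
    return correct / evaluated


def lda_analysis(
    table: pd.DataFrame,
    feature_names=DEFAULT_FEATURES,
    group_col: str = "group",
    case_label: str | None = None,
    z_score: bool = True,
) -> LdaResult:
    """Full multivariate stage: fit, Welch test on scores, LOO accuracy."""
    res = fit_lda(table, feature_names, group_col, case_label, z_score)
    groups = np.asarray(res.groups)
    labels = pd.unique(groups)
    case = case_label if case_label is not None else labels[1]
    scores = np.asarray(res.scores)
    t, p = welch_test(scores[groups == case], scores[groups != case])
    res.welch_t, res.welch_p = t, p
    res.loo_accuracy = loo_cv(table, feature_names, group_col, case_label,
                              z_score)
    return res
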