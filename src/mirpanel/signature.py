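"""Signature refinement by cross-validated multinomial elastic net.

The differentially expressed features act as predictors of a multiclass
outcome (disease/healthy crossed with age stratum, or the strata as
outcome levels); the refined signature is the set of features whose
coefficients survive the penalty at the CV-minimum lambda. Also provides
the multiclass AUC summaries and the two-sample t-test power/sample-size
calculation used to size a follow-on validation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .meta import rank_auc


@dataclass
class SignatureModel:
    feature_ids: list[str]
    retained_features: list[str]
    coefficients: pd.DataFrame  # classes x features, original feature scale
    intercepts: pd.Series
    alpha: float  # elastic-net mixing parameter, 1 = lasso
    lambda_: float  # selected penalty strength
    cv_folds: int
    seed: int
    cv_curve: pd.DataFrame  # lambda, mean_deviance, sd_deviance
    classes: list[str]
    scaler_mean: pd.Series
    scaler_scale: pd.Series


def make_class_labels(meta: pd.DataFrame, coding: str = "group_by_stratum") -> pd.Series:
    """Class coding for the signature model.

    ``group_by_stratum``: six classes, disease/healthy crossed with the
    three age strata. ``stratum_outcome``: four levels, the three disease
    strata plus one pooled healthy class.
    """
    if coding == "group_by_stratum":
        return meta["group"] + ":" + meta["age_stratum"].astype(str)
    if coding == "stratum_outcome":
        return meta.apply(
            lambda r: f"disease:{r['age_stratum']}"
            if r["group"] == "disease"
            else "healthy",
            axis=1,
        )
    raise ValueError(f"unknown coding {coding!r}")


def _multinomial_deviance(y_codes: np.ndarray, proba: np.ndarray) -> float:
    eps = 1e-12
    return float(-2.0 * np.mean(np.log(proba[np.arange(len(y_codes)), y_codes] + eps)))


def _lambda_grid(xs: np.ndarray, y_onehot: np.ndarray, alpha: float, n_lambda: int) -> np.ndarray:
    n = xs.shape[0]
    resid = y_onehot - y_onehot.mean(axis=0)
    lam_max = np.abs(xs.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def fit_multinomial_elasticnet(
    x: pd.DataFrame,
    y,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 25,
) -> SignatureModel:
    """Cross-validated multinomial elastic-net fit over a lambda grid.

    Features are standardized internally; coefficients are reported on
    the original scale. The penalty at the CV-minimum multinomial
    deviance is selected and the model refit on all samples; retained
    features are those with any non-zero coefficient. Deterministic given
    ``seed`` (fold assignment is seeded).
    """
    y = pd.Series(list(y), index=x.index, dtype=str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = y.value_counts()
    if (counts < max(folds / 2, 2)).any():
        small = list(counts[counts < max(folds / 2, 2)].index)
        raise ValueError(f"class too small for {folds}-fold CV: {small}")
    arr = x.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in feature matrix")

    mean = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (arr - mean) / scale
    code = {c: i for i, c in enumerate(classes)}
    y_codes = y.map(code).to_numpy()
    onehot = np.eye(len(classes))[y_codes]
    lambdas = _lambda_grid(xs, onehot, alpha, n_lambda)
    n = xs.shape[0]

    def make_clf():
        # float l1_ratio implies the elastic-net penalty
        return LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            max_iter=2000,
            tol=1e-4,
            warm_start=True,
            random_state=seed,
        )

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xs))
    dev = np.zeros((len(lambdas), folds))
    # warm-start each fold's estimator along the decreasing-penalty path
    for fi, (tr, te) in enumerate(splits):
        clf = make_clf()
        for li, lam in enumerate(lambdas):
            clf.C = 1.0 / (len(tr) * lam)
            clf.fit(xs[tr], y_codes[tr])
            proba = np.zeros((len(te), len(classes)))
            proba[:, clf.classes_] = clf.predict_proba(xs[te])
            dev[li, fi] = _multinomial_deviance(y_codes[te], proba)
    mean_dev = dev.mean(axis=1)
    best = int(np.argmin(mean_dev))
    lam_star = float(lambdas[best])

    path = make_clf()
    for lam in lambdas[: best + 1]:
        path.C = 1.0 / (n * lam)
        path.fit(xs, y_codes)
    final = path
    coef_std = np.zeros((len(classes), xs.shape[1]))
    coef_std[final.classes_, :] = final.coef_
    coef = coef_std / scale  # back to the original feature scale
    coef_df = pd.DataFrame(coef, index=classes, columns=x.columns)
    retained = [f for f in x.columns if (coef_df[f].abs() > 0).any()]
    intercepts = pd.Series(0.0, index=classes)
    intercepts.iloc[final.classes_] = final.intercept_ - coef_std[
        final.classes_, :
    ] @ (mean / scale)
    curve = pd.DataFrame(
        {
            "lambda": lambdas,
            "mean_deviance": mean_dev,
            "sd_deviance": dev.std(axis=1, ddof=1),
        }
    )
    model = SignatureModel(
        feature_ids=list(x.columns),
        retained_features=retained,
        coefficients=coef_df,
        intercepts=intercepts,
        alpha=alpha,
        lambda_=lam_star,
        cv_folds=folds,
        seed=seed,
        cv_curve=curve,
        classes=classes,
        scaler_mean=pd.Series(mean, index=x.columns),
        scaler_scale=pd.Series(scale, index=x.columns),
    )
    return model


def predict_class_probabilities(model: SignatureModel, x: pd.DataFrame) -> pd.DataFrame:
    """Softmax class probabilities from the fitted coefficients."""
    eta = (
        x[model.feature_ids].to_numpy(dtype=float) @ model.coefficients.to_numpy().T
        + model.intercepts.to_numpy()
    )
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, index=x.index, columns=model.classes)


def multiclass_auc(model: SignatureModel, x: pd.DataFrame, y) -> dict:
    """AUC summaries for a fitted multiclass signature.

    ``binary``: class probabilities collapsed to a disease-vs-healthy
    score (sum of disease-class probabilities) and scored with the
    mid-rank Mann-Whitney AUC. ``macro``: unweighted mean of one-vs-rest
    AUCs.
    """
    y = pd.Series(list(y), index=x.index, dtype=str)
    if y.nunique() < 2:
        raise ValueError("need >= 2 classes in y")
    proba = predict_class_probabilities(model, x)
    disease_classes = [c for c in model.classes if c.startswith("disease")]
    disease_score = proba[disease_classes].sum(axis=1)
    is_disease = y.str.startswith("disease")
    binary = rank_auc(disease_score, is_disease)
    macro_parts = []
    for c in model.classes:
        mask = y == c
        if mask.any() and (~mask).any():
            macro_parts.append(rank_auc(proba[c], mask))
    return {"binary": binary, "macro": float(np.mean(macro_parts))}


@dataclass
class PowerCalculation:
    effect_size: float
    alpha: float
    power: float
    n_per_group: int


def _t_power(n: int, d: float, alpha: float) -> float:
    """Power of a two-sided two-sample t-test with n per group."""
    df = 2 * n - 2
    if df < 1:
        return 0.0
    tcrit = stats.t.isf(alpha / 2, df)
    ncp = d * np.sqrt(n / 2.0)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_for_power(
    d: float, alpha: float = 0.05, power: float = 0.95
) -> PowerCalculation:
    """Smallest n per group so a two-sided two-sample t-test at level
    ``alpha`` reaches the requested power for standardized effect ``d``.

    Initialized at the normal approximation 2 (z_{1-a/2} + z_{power})^2 / d^2
    and refined by exact noncentral-t evaluation.
    """
    if d <= 0:
        raise ValueError("undetectable effect (d must be > 0)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = stats.norm.isf(alpha / 2)
    zb = stats.norm.isf(1 - power)
    n = max(int(np.ceil(2 * (za + zb) ** 2 / d**2)), 2)
    while n > 2 and _t_power(n - 1, d, alpha) >= power:
        n -= 1
    while _t_power(n, d, alpha) < power:
        n += 1
    return PowerCalculation(d, alpha, power, n)
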