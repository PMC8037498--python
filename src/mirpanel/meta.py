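"""Cross-platform meta-analysis, panel selection, ROC and longitudinal tools.

Per-feature p-values from two quantification platforms (e.g. serum
sequencing and plasma qPCR) are combined with Fisher's method; features
below a combined-p threshold form the biomarker panel. Each panel member
is evaluated with a univariate binary logistic model and a mid-rank
Mann-Whitney AUC with DeLong 95% confidence intervals; the combined panel
gets a multivariate logistic model. Treatment response is tracked as the
fold change of each panel feature against the patient's own pre-therapy
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


def rank_auc(scores, labels) -> float:
    """Mid-rank Mann-Whitney AUC: P(score_positive > score_negative),
    ties counting one half. ``labels`` is boolean (True = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(scores)
    u = r[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong asymptotic variance from placement values."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa (ties = 1/2)
    v10 = np.array([(x > neg).mean() + 0.5 * (x == neg).mean() for x in pos])
    v01 = np.array([(pos > y).mean() + 0.5 * (pos == y).mean() for y in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def combine_pvalues(p_list, method: str = "fisher") -> float:
    """Combine per-platform p-values into one evidence measure.

    Fisher: X = -2 sum(ln p) ~ chi-square with 2k df. A single input is
    returned unchanged; zeros are clamped to 1e-300 with a warning.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("zero p-value clamped to floor 1e-300")
        p = np.maximum(p, P_FLOOR)
    if p.size == 1:
        return float(p[0])
    if method == "fisher":
        x = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(x, 2 * p.size))
    if method == "stouffer":
        z = stats.norm.isf(p).sum() / np.sqrt(p.size)
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown method {method!r}")


def meta_rank(
    de_a: pd.DataFrame, de_b: pd.DataFrame, method: str = "fisher"
) -> pd.DataFrame:
    """Per-feature combined p over two platform DE tables (inner join).

    Raw two-group p-values (column ``p_raw``) enter the combination; the
    output is sorted ascending by combined p (ties broken by feature id)
    with ranks 1..n. Features present in only one table are recorded in
    ``result.attrs['excluded']``.
    """
    a = de_a.loc[de_a["p_raw"].notna(), ["feature", "p_raw"]].rename(
        columns={"p_raw": "p_a"}
    )
    b = de_b.loc[de_b["p_raw"].notna(), ["feature", "p_raw"]].rename(
        columns={"p_raw": "p_b"}
    )
    merged = a.merge(b, on="feature", how="inner")
    if merged.empty:
        raise ValueError("no shared features between platforms")
    merged["combined_p"] = [
        combine_pvalues([pa, pb], method=method)
        for pa, pb in zip(merged["p_a"], merged["p_b"])
    ]
    merged = merged.sort_values(
        ["combined_p", "feature"], kind="mergesort"
    ).reset_index(drop=True)
    merged["rank"] = np.arange(1, len(merged) + 1)
    excluded = sorted(
        set(a["feature"]).symmetric_difference(set(b["feature"]))
    )
    merged.attrs["excluded"] = excluded
    return merged


def select_panel(meta_table: pd.DataFrame, threshold: float = 1e-4) -> list[str]:
    """Features with combined p below ``threshold``, in rank order."""
    sel = meta_table[meta_table["combined_p"] < threshold]
    return list(sel.sort_values("rank")["feature"])


@dataclass
class RocResult:
    id: str
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficients: dict
    converged: bool


def _fit_logistic(x: np.ndarray, y: np.ndarray):
    """Binary logistic fit (MLE via IRLS); returns (params, fitted, converged).

    Falls back to a ridge-stabilized fit on separation or collinearity.
    """
    import statsmodels.api as sm

    design = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y.astype(float), design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        converged = bool(res.mle_retvals.get("converged", True)) and np.all(
            np.isfinite(params)
        ) and np.all(np.abs(params) < 1e3)
        if converged:
            return params, np.asarray(res.predict(design)), True
    except Exception:
        pass
    # ridge-stabilized fallback (separation / collinearity)
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1e4, max_iter=5000)  # default ridge penalty
    clf.fit(x, y.astype(int))
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    fitted = clf.predict_proba(x)[:, 1]
    return params, fitted, False


def _roc_from_scores(scores, labels, rid: str, coefficients, converged) -> RocResult:
    auc, var = delong_variance(scores, labels)
    if var > 0:
        se = np.sqrt(var)
        lo, hi = max(auc - 1.959964 * se, 0.0), min(auc + 1.959964 * se, 1.0)
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        lo = hi = auc
        p = 0.0 if auc != 0.5 else 1.0
    return RocResult(rid, auc, lo, hi, p, coefficients, converged)


def logistic_roc(values, labels, feature_id: str = "feature") -> RocResult:
    """Univariate binary logistic regression + Mann-Whitney AUC with
    DeLong CI and a z-test of AUC != 0.5.

    ``labels`` is boolean/binary with True (1) = disease. The AUC is
    computed on the fitted disease probability; for a monotone univariate
    link this equals the AUC of the raw values (possibly flipped for a
    negative slope).
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).any() is False:
        raise ValueError("both labels must be present")
    params, fitted, converged = _fit_logistic(v, y)
    coef = {"intercept": float(params[0]), feature_id: float(params[1])}
    return _roc_from_scores(fitted, y, feature_id, coef, converged)


def combined_panel_roc(x: pd.DataFrame, labels, panel_id: str = "panel") -> RocResult:
    """Multivariate logistic model on a panel feature matrix (samples x
    features); AUC with DeLong CI on the fitted probabilities."""
    if x.shape[1] == 0:
        raise ValueError("panel is empty")
    y = np.asarray(labels).astype(bool)
    params, fitted, converged = _fit_logistic(x.to_numpy(dtype=float), y)
    coef = {"intercept": float(params[0])}
    coef.update({c: float(p) for c, p in zip(x.columns, params[1:])})
    return _roc_from_scores(fitted, y, panel_id, coef, converged)


def longitudinal_fold_change(
    expr, meta: pd.DataFrame, panel: list[str]
) -> pd.DataFrame:
    """Panel-feature fold changes against each patient's pre-therapy baseline.

    fold change = 2^(norm_t - norm_baseline) on the higher-is-more-abundant
    normalized scale; the baseline row (timepoint 0) is exactly 1. Patients
    without a baseline sample are skipped with a reason in
    ``result.attrs['skipped']``.
    """
    values = expr.values if hasattr(expr, "values") else expr
    rows, skipped = [], []
    pmeta = meta.dropna(subset=["patient_id", "timepoint_months"])
    for patient, grp in pmeta.groupby("patient_id"):
        grp = grp.sort_values("timepoint_months")
        base = grp[grp["timepoint_months"] == 0]
        if base.empty:
            skipped.append({"patient_id": patient, "reason": "missing_baseline"})
            continue
        base_sample = base["sample_id"].iloc[0]
        for feat in panel:
            if feat not in values.index:
                continue
            b = values.at[feat, base_sample]
            for _, r in grp.iterrows():
                v = values.at[feat, r["sample_id"]]
                rows.append(
                    {
                        "patient_id": patient,
                        "feature": feat,
                        "timepoint_months": float(r["timepoint_months"]),
                        "fold_change_vs_baseline": float(2.0 ** (v - b)),
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["patient_id", "feature", "timepoint_months", "fold_change_vs_baseline"],
    )
    out.attrs["skipped"] = skipped
    return out
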