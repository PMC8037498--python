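"""Differential expression: qPCR ddCq fold changes and count-based NB tests.

qPCR route: per-feature group difference of normalized Cq values (ddCq).
Because normalized Cq is oriented so higher = more abundant, upregulation
in the disease group gives ddCq > 0 and fold change 2^ddCq > 1. Signed
fold changes below 1 are displayed as -1/FC (so a halving prints -2).

Count route: a two-group negative-binomial test in the style of exact
small-sample count tests: library sizes are equalized via TMM-scaled
mean adjustment, dispersion is a 50/50 blend of a per-feature moment
estimate and a common profile-likelihood estimate, and the p-value comes
from the exact conditional distribution of the group-A sum given the
total (falling back to a normal approximation for large totals).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .containers import CountMatrix
from .normalize import NormalizedExpression, NormFactors


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1; ties share the
    value of their maximal rank by construction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _signed_fold(log2_fc: float) -> float:
    fc = 2.0 ** log2_fc
    return fc if fc >= 1 else -1.0 / fc


def _direction(log2_fc: float) -> str:
    if log2_fc > 0:
        return "up"
    if log2_fc < 0:
        return "down"
    return "none"


def ddcq_differential(
    expr: NormalizedExpression, meta: pd.DataFrame
) -> pd.DataFrame:
    """Two-group ddCq differential expression on normalized qPCR values.

    Per feature: ddCq = disease mean - healthy mean of normalized Cq,
    log2 fold change = ddCq, pooled-variance two-sided t-test, BH
    adjustment across the tested features. Features with fewer than two
    detected values in either group are skipped with a reason.
    """
    groups = meta.loc[expr.sample_ids, "group"]
    d_cols = [s for s in expr.sample_ids if groups[s] == "disease"]
    h_cols = [s for s in expr.sample_ids if groups[s] == "healthy"]
    if not d_cols or not h_cols:
        raise ValueError("both disease and healthy samples are required")

    rows = []
    for feat in expr.feature_ids:
        dv = expr.values.loc[feat, d_cols].dropna()
        hv = expr.values.loc[feat, h_cols].dropna()
        if len(dv) < 2 or len(hv) < 2:
            rows.append(
                {
                    "feature": feat,
                    "delta_delta_cq": np.nan,
                    "log2_fc": np.nan,
                    "fold_change": np.nan,
                    "mean_disease": np.nan,
                    "mean_healthy": np.nan,
                    "p_raw": np.nan,
                    "n_disease": len(dv),
                    "n_healthy": len(hv),
                    "direction": "none",
                    "reason": "insufficient_detection",
                }
            )
            continue
        ddcq = float(dv.mean() - hv.mean())
        t = stats.ttest_ind(dv, hv, equal_var=True)
        rows.append(
            {
                "feature": feat,
                "delta_delta_cq": ddcq,
                "log2_fc": ddcq,
                "fold_change": _signed_fold(ddcq),
                "mean_disease": float(dv.mean()),
                "mean_healthy": float(hv.mean()),
                "p_raw": float(t.pvalue),
                "n_disease": len(dv),
                "n_healthy": len(hv),
                "direction": _direction(ddcq),
                "reason": "",
            }
        )
    table = pd.DataFrame(rows)
    tested = table["reason"] == ""
    table["p_adjusted"] = np.nan
    if tested.any():
        table.loc[tested, "p_adjusted"] = bh_adjust(table.loc[tested, "p_raw"])
    return table


def filter_de(
    table: pd.DataFrame,
    p_max: float = 0.05,
    abs_fc_min: float | None = 2.0,
    abs_log2fc_min: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Subset of DE rows passing the adjusted-p and effect-size thresholds.

    Thresholds are inclusive (p <= p_max, |FC| >= abs_fc_min or
    |log2FC| >= abs_log2fc_min). Returns (subset, counts) with counts
    n_total / n_up / n_down.
    """
    if p_max <= 0:
        keep = pd.Series(False, index=table.index)
    else:
        keep = table["p_adjusted"] <= p_max
    if abs_log2fc_min is not None:
        keep &= table["log2_fc"].abs() >= abs_log2fc_min
    elif abs_fc_min is not None:
        keep &= table["fold_change"].abs() >= abs_fc_min
    sub = table.loc[keep.fillna(False)].copy()
    n_up = int((sub["direction"] == "up").sum())
    n_down = int((sub["direction"] == "down").sum())
    return sub, {"n_total": len(sub), "n_up": n_up, "n_down": n_down}


def unique_de_union(tables: list[pd.DataFrame]) -> tuple[pd.DataFrame, dict]:
    """Union of features significant in any stratum comparison.

    Input tables are already-thresholded DE tables sharing a feature
    universe. A feature significant in several strata is counted once;
    features with conflicting directions across strata are flagged and
    counted in the total only.
    """
    seen: dict[str, set] = {}
    for t in tables:
        for _, row in t.iterrows():
            seen.setdefault(row["feature"], set()).add(row["direction"])
    rows = []
    for feat in seen:
        dirs = seen[feat] - {"none"}
        if len(dirs) == 1:
            d = next(iter(dirs))
            conflict = False
        elif len(dirs) == 0:
            d, conflict = "none", False
        else:
            d, conflict = "conflict", True
        rows.append({"feature": feat, "direction": d, "conflict": conflict})
    out = pd.DataFrame(rows, columns=["feature", "direction", "conflict"])
    counts = {
        "n_total": len(out),
        "n_up": int((out["direction"] == "up").sum()),
        "n_down": int((out["direction"] == "down").sum()),
    }
    return out, counts


# ---------------------------------------------------------------------------
# Negative-binomial count test
# ---------------------------------------------------------------------------

_EXACT_TOTAL_CAP = 20_000


def _nb_loglik_common(phi: float, pseudo: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Profile log-likelihood of a common dispersion given group means."""
    r = 1.0 / max(phi, 1e-8)
    ll = 0.0
    for cols in group_idx:
        block = pseudo[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        mu = np.maximum(mu, 1e-8)
        p = r / (r + mu)
        y = np.round(block)
        ll += np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(p)
            + y * np.log1p(-p)
        )
    return ll


def estimate_common_dispersion(
    pseudo: np.ndarray, group_idx: list[np.ndarray]
) -> float:
    res = optimize.minimize_scalar(
        lambda lp: -_nb_loglik_common(np.exp(lp), pseudo, group_idx),
        bounds=(np.log(1e-6), np.log(10.0)),
        method="bounded",
    )
    return float(np.exp(res.x))


def _moment_dispersion(pseudo_row: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Pooled within-group method-of-moments dispersion for one feature."""
    num, den_df = 0.0, 0
    mus = []
    for cols in group_idx:
        y = pseudo_row[cols]
        mus.append(y.mean())
        num += ((y - y.mean()) ** 2).sum()
        den_df += len(y) - 1
    s2 = num / max(den_df, 1)
    mu = float(np.mean(mus))
    if mu <= 0:
        return 0.0
    return max((s2 - mu) / mu**2, 0.0)


def _exact_conditional_p(sa: int, s: int, r_a: float, r_b: float) -> float:
    """Two-sided exact conditional NB test.

    Given independent NB sums with a shared success probability, the
    conditional law of the group-A sum a given total s is
    P(a) proportional to C(a + r_a - 1, a) C(s - a + r_b - 1, s - a).
    The p-value sums all outcomes no more probable than the observed one.
    """
    a = np.arange(s + 1)
    logw = (
        special.gammaln(a + r_a)
        - special.gammaln(a + 1)
        + special.gammaln(s - a + r_b)
        - special.gammaln(s - a + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    obs = w[sa]
    return float(min(w[w <= obs * (1 + 1e-12)].sum(), 1.0))


def nb_differential(
    c: CountMatrix,
    factors: NormFactors,
    meta: pd.DataFrame,
    stratum: str | None = None,
) -> pd.DataFrame:
    """Negative-binomial two-group differential expression for counts.

    Counts are scaled to a common effective library size (mapped total x
    TMM factor); per-feature dispersions blend moment estimates 50/50
    with a common profile-likelihood estimate; the group comparison uses
    the exact conditional NB test on the rounded equalized counts, with
    BH adjustment across tested features. ``stratum`` restricts the
    comparison to one age stratum (metadata filtering).
    """
    sub_meta = meta.loc[[s for s in c.sample_ids if s in meta.index]]
    if stratum is not None:
        sub_meta = sub_meta[sub_meta["age_stratum"] == stratum]
    cols = list(sub_meta.index)
    groups = sub_meta["group"]
    a_cols = [s for s in cols if groups[s] == "disease"]
    b_cols = [s for s in cols if groups[s] == "healthy"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    counts = c.counts[cols].to_numpy(dtype=float)
    lib = (c.mapped_totals[cols] * factors.tmm_factor[cols]).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("group with all-zero effective library")
    common_lib = float(np.exp(np.mean(np.log(lib))))
    pseudo = counts * (common_lib / lib)

    col_pos = {s: i for i, s in enumerate(cols)}
    idx_a = np.array([col_pos[s] for s in a_cols])
    idx_b = np.array([col_pos[s] for s in b_cols])
    nonzero = pseudo.sum(axis=1) > 0
    phi_common = estimate_common_dispersion(pseudo[nonzero], [idx_a, idx_b])

    n_a, n_b = len(idx_a), len(idx_b)
    rows = []
    for i, feat in enumerate(c.feature_ids):
        row = pseudo[i]
        sa = float(row[idx_a].sum())
        sb = float(row[idx_b].sum())
        if sa + sb == 0:
            rows.append(
                {
                    "feature": feat,
                    "log2_fc": np.nan,
                    "fold_change": np.nan,
                    "mean_disease": 0.0,
                    "mean_healthy": 0.0,
                    "p_raw": np.nan,
                    "direction": "none",
                    "reason": "all_zero",
                }
            )
            continue
        phi = max(0.5 * _moment_dispersion(row, [idx_a, idx_b]) + 0.5 * phi_common, 1e-6)
        log2fc = float(np.log2((sa / n_a + 0.5) / (sb / n_b + 0.5)))
        sa_i, sb_i = int(round(sa)), int(round(sb))
        s = sa_i + sb_i
        r_a, r_b = n_a / phi, n_b / phi
        if s <= _EXACT_TOTAL_CAP:
            p = _exact_conditional_p(sa_i, s, r_a, r_b)
        else:
            mu = s / (n_a + n_b)
            va = n_a * mu * (1 + phi * mu)
            vb = n_b * mu * (1 + phi * mu)
            var_c = va * vb / (va + vb)
            z = (sa_i - s * n_a / (n_a + n_b)) / np.sqrt(var_c)
            p = float(min(2 * stats.norm.sf(abs(z)), 1.0))
        rows.append(
            {
                "feature": feat,
                "log2_fc": log2fc,
                "fold_change": _signed_fold(log2fc),
                "mean_disease": sa / n_a,
                "mean_healthy": sb / n_b,
                "p_raw": p,
                "direction": _direction(log2fc),
                "reason": "",
            }
        )
    table = pd.DataFrame(rows)
    tested = table["reason"] == ""
    table["p_adjusted"] = np.nan
    if tested.any():
        table.loc[tested, "p_adjusted"] = bh_adjust(table.loc[tested, "p_raw"])
    return table
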