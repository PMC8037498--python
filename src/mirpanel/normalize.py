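"""Normalization for qPCR Cq data and small-RNA-seq counts.

qPCR side: global-mean normalization (normalized Cq = per-sample mean Cq
of the assays detected everywhere minus the assay Cq, so HIGHER normalized
values mean MORE abundant), reference-gene normalization against a chosen
normalizer set, and the model-based reference-gene stability estimator
(Andersen's variance-decomposition approach) with normalizer-pair search.

Count side: tags-per-million (TPM), expression floors, and trimmed mean of
M-values (TMM) scaling factors (Robinson-Oshlack), plus the exploratory
transforms: Z-scaling, hierarchical clustering and PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .containers import CountMatrix, CqMatrix

LOG2 = np.log(2.0)


@dataclass
class NormalizedExpression:
    """Normalized Cq values; higher = more abundant."""

    values: pd.DataFrame  # features x samples, cycles
    normalizer_spec: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def global_mean_normalize(m: CqMatrix) -> NormalizedExpression:
    """Normalize each assay against the per-sample mean Cq of the assays
    detected in every sample (the reference assay set).

    norm(f, s) = mean over reference set of Cq(., s) - Cq(f, s).
    Undetected cells stay missing. The per-sample mean of the normalized
    values over the reference set is 0 by construction.
    """
    all_detected = m.detected.all(axis=1)
    ref_set = list(m.values.index[all_detected])
    if not ref_set:
        raise ValueError(
            "no assay is detected in all samples; use reference_normalize "
            "with an explicit normalizer list"
        )
    ref_mean = m.values.loc[ref_set].mean(axis=0)  # per sample
    norm = ref_mean - m.values.where(m.detected)
    return NormalizedExpression(
        norm, {"method": "global_mean", "reference_assays": ref_set}
    )


def reference_normalize(m: CqMatrix, refs: list[str]) -> NormalizedExpression:
    """Normalize against the mean Cq of explicit reference assays.

    norm(f, s) = mean of refs' Cq in s - Cq(f, s).
    """
    if not refs:
        raise ValueError("refs list empty")
    missing = [r for r in refs if r not in m.values.index]
    if missing:
        raise ValueError(f"reference assays absent from matrix: {missing}")
    for r in refs:
        und = [s for s in m.sample_ids if not m.detected.at[r, s]]
        if und:
            raise ValueError(f"reference {r} undetected in sample(s) {und}")
    ref_mean = m.values.loc[refs].mean(axis=0)
    norm = ref_mean - m.values.where(m.detected)
    return NormalizedExpression(
        norm, {"method": "reference_genes", "reference_assays": list(refs)}
    )


# ---------------------------------------------------------------------------
# Reference-gene stability (model-based variance decomposition)
# ---------------------------------------------------------------------------

def _log_expression(expr, candidate_features) -> pd.DataFrame:
    """Extract log-scale expression (natural log of 2^-Cq equivalents).

    Works directly on -Cq * ln 2 (or +normalized Cq * ln 2), which equals
    the log of the exponentially transformed values and avoids underflow.
    """
    if isinstance(expr, CqMatrix):
        df = -expr.values.where(expr.detected) * LOG2
    elif isinstance(expr, NormalizedExpression):
        df = expr.values * LOG2
    else:
        df = pd.DataFrame(expr)
    if candidate_features is not None:
        missing = [f for f in candidate_features if f not in df.index]
        if missing:
            raise ValueError(f"candidate features absent: {missing}")
        df = df.loc[list(candidate_features)]
    keep = df.notna().all(axis=1)
    if not keep.all():
        dropped = list(df.index[~keep])
        warnings.warn(f"candidates dropped (not detected in all samples): {dropped}")
        df = df.loc[keep]
    return df


@dataclass
class _StabilityModel:
    """Fitted components of the stability model, reused for pair scoring."""

    features: list[str]
    groups: list[str]
    group_sizes: np.ndarray  # per group
    centered: pd.DataFrame  # sample-centered log expression
    group_means: np.ndarray  # features x groups (z_ig)
    sigma2: np.ndarray  # features x groups, bias-corrected intragroup var
    gamma2: float  # between-gene variance of intergroup effects

    def stability_of(self, rows: list[int]) -> tuple[float, float, float]:
        """Stability of the average of the given candidate rows.

        Returns (stability, mean intragroup variance, intergroup spread).
        Averaging p genes divides the residual variance by p^2 under
        independence; intergroup deviations average linearly.
        """
        p = len(rows)
        z_g = self.group_means[rows].mean(axis=0)
        d_g = z_g - np.average(z_g, weights=self.group_sizes)
        sig2_g = self.sigma2[rows].sum(axis=0) / p**2
        v_g = sig2_g / self.group_sizes
        g2 = self.gamma2
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = np.where(g2 + v_g > 0, g2 / (g2 + v_g), 0.0)
            post_var = np.where(g2 + v_g > 0, g2 * v_g / (g2 + v_g), 0.0)
        d_tilde = d_g * shrink
        rho = float(np.mean(np.abs(d_tilde) + np.sqrt(v_g + post_var)))
        return rho, float(sig2_g.mean()), float(np.mean(np.abs(d_g)))


def _fit_stability_model(df: pd.DataFrame, meta: pd.DataFrame) -> _StabilityModel:
    groups = sorted(meta.loc[df.columns, "group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.array(
        [int((meta.loc[df.columns, "group"] == g).sum()) for g in groups]
    )
    if (sizes < 2).any():
        raise ValueError("each group needs >= 2 samples")
    n_feat = df.shape[0]
    if n_feat < 3:
        raise ValueError("need >= 3 candidate features")

    centered = df - df.mean(axis=0)  # remove per-sample RNA-amount effect
    k = len(groups)
    z = np.empty((n_feat, k))
    s2 = np.empty((n_feat, k))
    for gi, g in enumerate(groups):
        cols = meta.index[
            (meta["group"] == g) & meta.index.isin(df.columns)
        ]
        block = centered[cols].to_numpy()
        z[:, gi] = block.mean(axis=1)
        s2[:, gi] = block.var(axis=1, ddof=1)
    # Bias correction: subtracting per-sample means over I genes inflates each
    # raw variance by the average gene variance / I and deflates the own-gene
    # term; E[s2_ig] = sigma2_ig (1 - 2/I) + mean_i sigma2_ig / I.
    I = n_feat
    sbar = s2.mean(axis=0) / (1.0 - 1.0 / I)
    sigma2 = np.maximum((s2 - sbar / I) / (1.0 - 2.0 / I), 0.0)

    w = sizes / sizes.sum()
    d = z - (z @ w)[:, None]
    v = sigma2 / sizes
    gamma2 = max(0.0, (d**2).sum() / ((I - 1) * (k - 1)) - v.mean())
    return _StabilityModel(
        list(df.index), groups, sizes, centered, z, sigma2, gamma2
    )


def normfinder_stability(
    expr, meta: pd.DataFrame, candidate_features: list[str] | None = None
) -> pd.DataFrame:
    """Rank candidate reference genes by the model-based stability value.

    The log-scale expression is decomposed into gene, sample and group
    effects; each gene's stability combines its shrunken intergroup
    deviation with its intragroup standard error, averaged over groups.
    Lower is more stable. Returns a table sorted ascending with columns
    (feature, stability, intragroup_var, intergroup_dev).
    """
    df = _log_expression(expr, candidate_features)
    model = _fit_stability_model(df, meta)
    rows = []
    for i, feat in enumerate(model.features):
        rho, s2, dd = model.stability_of([i])
        rows.append(
            {
                "feature": feat,
                "stability": rho,
                "intragroup_var": s2,
                "intergroup_dev": dd,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["stability", "feature"], kind="mergesort"
    )
    return table.reset_index(drop=True)


def best_normalizer_pair(
    st: pd.DataFrame,
    expr,
    meta: pd.DataFrame,
    top_k: int = 10,
) -> tuple[tuple[str, str], float, bool]:
    """Search all pairs among the ``top_k`` most stable singles for the pair
    whose averaged signal has the lowest combined stability.

    Returns ((feature_a, feature_b), combined_stability, beats_best_single).
    """
    singles = list(st["feature"].head(top_k))
    if len(singles) < 2:
        raise ValueError("need >= 2 candidates")
    df = _log_expression(expr, None)
    df = df.loc[[f for f in df.index if f in set(singles)]]
    model = _fit_stability_model(df, meta)
    idx = {f: i for i, f in enumerate(model.features)}
    best_pair, best_rho = None, np.inf
    for a in range(len(model.features)):
        for b in range(a + 1, len(model.features)):
            rho, _, _ = model.stability_of([a, b])
            if rho < best_rho:
                best_rho = rho
                best_pair = (model.features[a], model.features[b])
    best_single = float(st["stability"].iloc[0])
    return best_pair, float(best_rho), bool(best_rho <= best_single)


# ---------------------------------------------------------------------------
# Count normalization
# ---------------------------------------------------------------------------

def tpm(c: CountMatrix) -> pd.DataFrame:
    """Reads per million mapped reads: counts / mapped_total * 1e6."""
    if (c.mapped_totals <= 0).any():
        raise ValueError("mapped totals must be > 0")
    return c.counts.div(c.mapped_totals, axis=1) * 1e6


def expression_filter(t: pd.DataFrame, floor: float, scope: str = "all_samples") -> list[str]:
    """Features at or above ``floor`` TPM in every sample (inclusive)."""
    if scope != "all_samples":
        raise ValueError(f"unknown scope {scope!r}")
    keep = (t >= floor).all(axis=1)
    return list(t.index[keep])


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Doubly trimmed, precision-weighted mean of M-values for one sample
    against the reference; returns the scaling factor on the linear scale."""
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weight = inverse
    w = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = pd.Series(m).rank(method="first").to_numpy()
    ra = pd.Series(a).rank(method="first").to_numpy()
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if kept.sum() == 0 or w[kept].sum() == 0:
        return 1.0
    f = np.sum(w[kept] * m[kept]) / np.sum(w[kept])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


@dataclass
class NormFactors:
    sample_ids: list[str]
    tmm_factor: pd.Series  # geometric mean 1

    @property
    def effective_library_size(self) -> pd.Series:
        return self._lib * self.tmm_factor

    def __init__(self, sample_ids, tmm_factor, lib):
        self.sample_ids = list(sample_ids)
        self.tmm_factor = tmm_factor
        self._lib = lib


def tmm_factors(
    c: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Per-sample TMM scaling factors (trimmed mean of M-values).

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions. Factors are rescaled to have
    geometric mean 1. Trims default to 30% of M-values and 5% of A-values
    from each tail, with precision weights.
    """
    if c.counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (c.counts.sum(axis=0) == 0).any():
        raise ValueError("sample with all-zero counts")
    lib = c.mapped_totals.astype(float)
    arr = c.counts.to_numpy()
    uq = np.array(
        [
            np.quantile(arr[:, j][arr[:, j] > 0], 0.75) / lib.iloc[j]
            for j in range(arr.shape[1])
        ]
    )
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(arr.shape[1]):
        if j == ref_j:
            factors.append(1.0)
        else:
            factors.append(
                _tmm_pair_factor(
                    arr[:, j], arr[:, ref_j], lib.iloc[j], lib.iloc[ref_j],
                    trim_m, trim_a,
                )
            )
    f = np.asarray(factors)
    f = f / np.exp(np.mean(np.log(f)))
    series = pd.Series(f, index=c.counts.columns, name="tmm_factor")
    return NormFactors(c.sample_ids, series, lib)


# ---------------------------------------------------------------------------
# Exploratory transforms
# ---------------------------------------------------------------------------

@dataclass
class ClusterPCAResult:
    linkage: np.ndarray  # scipy linkage matrix over samples
    scores: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x PCs
    dropped_features: list[str]


def zscore_cluster_pca(
    x: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "ward",
    zscale: bool = False,
    top_variance: int | None = None,
) -> ClusterPCAResult:
    """Hierarchical sample clustering plus PCA of an expression matrix.

    ``x`` is features x samples. ``distance`` is ``euclidean`` or
    ``one_minus_pearson`` (applied after optional Z-scaling of features);
    linkage is Ward's. Optionally restrict to the ``top_variance`` features
    with the largest variance before the transforms. PCA centers features
    and unit-scales them only on the Z-scale path; explained-variance
    fractions are non-increasing and sum to <= 1.
    """
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    dropped: list[str] = []
    if top_variance is not None:
        order = x.var(axis=1).sort_values(ascending=False)
        x = x.loc[order.index[:top_variance]]
    if distance == "one_minus_pearson" or zscale:
        sd = x.std(axis=1, ddof=1)
        const = sd == 0
        if const.any():
            dropped = list(x.index[const])
            warnings.warn(f"constant features dropped: {dropped}")
            x = x.loc[~const]
            sd = sd[~const]
    work = x.copy()
    if zscale:
        work = work.sub(work.mean(axis=1), axis=0).div(
            work.std(axis=1, ddof=1), axis=0
        )
    samples = work.T  # samples x features
    if distance == "euclidean":
        dvec = ssd.pdist(samples.to_numpy(), metric="euclidean")
    elif distance == "one_minus_pearson":
        dvec = ssd.pdist(samples.to_numpy(), metric="correlation")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = sch.linkage(dvec, method=linkage)

    centered = samples - samples.mean(axis=0)
    if zscale:
        scale = samples.std(axis=0, ddof=1).replace(0, 1.0)
        centered = centered / scale
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    n = samples.shape[0]
    var = s**2 / (n - 1)
    total_var = centered.to_numpy().var(axis=0, ddof=1).sum()
    evr = var / total_var if total_var > 0 else np.zeros_like(var)
    k = len(s)
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=samples.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=work.index, columns=pcs)
    return ClusterPCAResult(Z, scores, evr, loadings, dropped)
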