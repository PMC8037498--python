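"""Shared domain containers for the miRNA biomarker pipeline.

Two quantification platforms are modelled: RT-qPCR panels, whose raw
measurement is the quantification cycle Cq (lower = more abundant), and
small-RNA sequencing, whose raw measurement is a non-negative read count
per miRNA together with the per-sample total of mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("disease", "healthy")
AGE_STRATA = ("le19", "20_29", "ge30")
BIOFLUIDS = ("serum", "plasma")

#: accepted aliases for group labels on disk (case-insensitive)
GROUP_ALIASES = {
    "disease": "disease",
    "mngie": "disease",
    "patient": "disease",
    "case": "disease",
    "healthy": "healthy",
    "control": "healthy",
    "hc": "healthy",
}


class FormatError(ValueError):
    """Raised when an input table violates the expected tabular format."""


def age_to_stratum(age_years: float) -> str:
    """Map an age in years to the study's stratum labels (<=19, 20-29, >=30)."""
    if age_years <= 19:
        return "le19"
    if age_years <= 29:
        return "20_29"
    return "ge30"


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise FormatError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CqMatrix:
    """Feature x sample matrix of qPCR quantification cycles.

    Parameters
    ----------
    values
        DataFrame of Cq values (cycles), index = miRNA identifiers,
        columns = sample identifiers. Cells may be NaN where undetected.
    detected
        Boolean mask, same shape; False marks undetected reactions.
    spike_channels
        Optional map of spike-in name (UniSp2/UniSp4/UniSp6/UniSp3) to a
        per-sample Cq Series.
    negative_control
        Optional per-assay Cq Series of the no-template control; NaN where
        the control gave no signal.
    """

    values: pd.DataFrame
    detected: pd.DataFrame | None = None
    spike_channels: dict[str, pd.Series] = field(default_factory=dict)
    negative_control: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.values.notna()
        if self.detected.shape != self.values.shape:
            raise FormatError("values/detected shape mismatch")
        self.detected = self.detected.astype(bool)
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        bad = self.detected.to_numpy() & ~np.isfinite(
            self.values.to_numpy(dtype=float)
        )
        if bad.any():
            raise FormatError("non-finite Cq in cells flagged detected")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "CqMatrix":
        return CqMatrix(
            self.values.copy(),
            self.detected.copy(),
            {k: v.copy() for k, v in self.spike_channels.items()},
            None if self.negative_control is None else self.negative_control.copy(),
        )

    def subset_samples(self, keep: list[str]) -> "CqMatrix":
        return CqMatrix(
            self.values[keep],
            self.detected[keep],
            {k: v[v.index.isin(keep)] for k, v in self.spike_channels.items()},
            self.negative_control,
        )


@dataclass
class CountMatrix:
    """Feature x sample matrix of mapped small-RNA read counts."""

    counts: pd.DataFrame
    mapped_totals: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("non-integral counts")
        self.counts = self.counts.astype(np.int64)
        _check_unique(self.counts.index, "feature ids")
        _check_unique(self.counts.columns, "sample ids")
        if self.mapped_totals is None:
            # totals default to column sums; they may legitimately exceed them
            # when upstream filtering removed features from the matrix
            self.mapped_totals = self.counts.sum(axis=0).astype(float)
        else:
            self.mapped_totals = self.mapped_totals.reindex(self.counts.columns)
            if self.mapped_totals.isna().any():
                raise FormatError("mapped totals missing for some samples")
        if (self.mapped_totals <= 0).any():
            raise FormatError("mapped totals must be > 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample metadata table.

    Required columns: ``sample_id``, ``group``, ``biofluid``. Optional:
    ``age`` (years; mapped to ``age_stratum``), ``age_stratum``,
    ``patient_id``, ``timepoint_months``, ``sex``.
    """
    required = {"sample_id", "group", "biofluid"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing required columns: {sorted(missing)}")
    meta = meta.copy()
    _check_unique(meta["sample_id"], "sample ids in metadata")

    def norm_group(g):
        key = str(g).strip().lower()
        if key not in GROUP_ALIASES:
            raise FormatError(f"unknown group label: {g!r}")
        return GROUP_ALIASES[key]

    meta["group"] = meta["group"].map(norm_group)
    meta["biofluid"] = meta["biofluid"].astype(str).str.lower()
    bad_fluid = set(meta["biofluid"]) - set(BIOFLUIDS)
    if bad_fluid:
        raise FormatError(f"unknown biofluid labels: {sorted(bad_fluid)}")
    if "age" in meta.columns and "age_stratum" not in meta.columns:
        meta["age_stratum"] = meta["age"].map(
            lambda a: age_to_stratum(float(a)) if pd.notna(a) else pd.NA
        )
    if "age_stratum" in meta.columns:
        known = set(AGE_STRATA)
        bad = {s for s in meta["age_stratum"].dropna() if s not in known}
        if bad:
            raise FormatError(f"unknown age strata: {sorted(bad)}")
    if "timepoint_months" in meta.columns:
        tp = pd.to_numeric(meta["timepoint_months"], errors="coerce")
        if (tp.dropna() < 0).any():
            raise FormatError("timepoint_months must be >= 0")
        meta["timepoint_months"] = tp
    return meta.set_index("sample_id", drop=False)


def check_samples_covered(sample_ids, meta: pd.DataFrame) -> None:
    """Every sample referenced by a matrix must have exactly one metadata row."""
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise FormatError(f"samples without metadata: {missing}")


@dataclass
class PipelineConfig:
    """Run configuration: thresholds and model settings with study defaults.

    Threshold defaults follow the study rules: hemolysis warn above a
    Cq(miR-23a)-Cq(miR-451) difference of 5 cycles and exclusion above 7;
    upper limit of detection Cq = 37; assays must sit at least 5 cycles
    below the no-template control; differential expression at BH-adjusted
    p <= 0.05 with |fold change| >= 2 (qPCR) or |log2 FC| >= 1 (counts);
    meta-analysis panel threshold combined p < 1e-4.
    """

    hemolysis_warn_dcq: float = 5.0
    hemolysis_exclude_dcq: float = 7.0
    lod_cq: float = 37.0
    nc_margin_cq: float = 5.0
    spike_tolerance_cq: float = 2.0
    de_p_max: float = 0.05
    de_abs_fc_min: float = 2.0
    de_abs_log2fc_min: float = 1.0
    tpm_floor: float = 1.0
    meta_p_threshold: float = 1e-4
    elasticnet_alpha: float = 0.5
    elasticnet_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        positives = [
            self.hemolysis_warn_dcq,
            self.hemolysis_exclude_dcq,
            self.lod_cq,
            self.nc_margin_cq,
            self.spike_tolerance_cq,
            self.de_p_max,
            self.de_abs_fc_min,
            self.de_abs_log2fc_min,
            self.meta_p_threshold,
        ]
        if any(t <= 0 for t in positives):
            raise ValueError("all thresholds must be positive")
        if not 0 < self.elasticnet_alpha <= 1:
            raise ValueError("elastic-net mixing parameter must be in (0, 1]")
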