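"""Sample- and assay-level quality control for qPCR panels.

Implements the pre-analytical checks used for circulating-miRNA panels:

* hemolysis scoring from the Cq difference miR-23a minus miR-451 (miR-451
  is abundant in erythrocytes, miR-23a is stable in plasma/serum, so a
  large positive difference flags red-cell contamination);
* an upper limit of detection (default Cq 37);
* the no-template-control rule (assays must amplify at least 5 cycles
  earlier than their negative control);
* advisory spike-in consistency flags (extraction / RT / PCR monitoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CqMatrix, PipelineConfig

HEMOLYSIS_MARKER_HIGH = "hsa-miR-23a-3p"
HEMOLYSIS_MARKER_RBC = "hsa-miR-451a"

#: aliases accepted when locating the hemolysis marker rows
_MARKER_ALIASES = {
    HEMOLYSIS_MARKER_HIGH: ("hsa-miR-23a-3p", "miR-23a-3p", "miR-23a", "hsa-miR-23a"),
    HEMOLYSIS_MARKER_RBC: ("hsa-miR-451a", "miR-451a", "miR-451", "hsa-miR-451"),
}


@dataclass
class HemolysisResult:
    sample_id: str
    dcq: float  # Cq(miR-23a) - Cq(miR-451), cycles
    verdict: str  # clean | warn | hemolysed | indeterminate


@dataclass
class QCReport:
    hemolysis: pd.DataFrame  # sample_id, dcq, verdict
    spike_flags: pd.DataFrame  # sample_id, channel, deviation_cq
    assay_included: pd.Series  # per-feature bool (negative-control rule)
    excluded_samples: pd.DataFrame  # sample_id, reason
    notes: list[str] = field(default_factory=list)

    @property
    def kept_samples(self) -> list[str]:
        excl = set(self.excluded_samples["sample_id"])
        return [s for s in self.hemolysis["sample_id"] if s not in excl]


def hemolysis_score(
    cq_mir23a: float,
    cq_mir451: float,
    warn_at: float = 5.0,
    exclude_at: float = 7.0,
    sample_id: str = "",
) -> HemolysisResult:
    """Score one sample for hemolysis from its two marker Cq values.

    Verdict is ``clean`` for dCq <= ``warn_at``, ``warn`` in
    (``warn_at``, ``exclude_at``], ``hemolysed`` above ``exclude_at`` and
    ``indeterminate`` when either marker is undetected (flag, never
    auto-exclude).
    """
    if not (np.isfinite(cq_mir23a) and np.isfinite(cq_mir451)):
        return HemolysisResult(sample_id, np.nan, "indeterminate")
    dcq = cq_mir23a - cq_mir451
    if dcq <= warn_at:
        verdict = "clean"
    elif dcq <= exclude_at:
        verdict = "warn"
    else:
        verdict = "hemolysed"
    return HemolysisResult(sample_id, dcq, verdict)


def apply_detection_limits(
    m: CqMatrix, lod_cq: float = 37.0, nc_margin: float = 5.0
) -> tuple[CqMatrix, pd.Series]:
    """Apply the upper limit of detection and the negative-control rule.

    Cells with Cq above ``lod_cq`` become undetected. An assay (feature) is
    flagged excluded unless every detected sample Cq sits at least
    ``nc_margin`` cycles below the negative control; assays whose control
    gave no signal use ``lod_cq`` as the control value. Idempotent.
    """
    out = m.copy()
    over = out.values > lod_cq
    out.detected = out.detected & ~over.fillna(False)
    out.values = out.values.where(out.detected)

    if m.negative_control is not None:
        nc = m.negative_control.fillna(lod_cq)
    else:
        nc = pd.Series(lod_cq, index=m.values.index)
    masked = out.values.where(out.detected)
    worst = masked.max(axis=1)  # highest (latest) detected Cq per assay
    included = worst.isna() | (worst <= nc - nc_margin)
    included.name = "included"
    return out, included


def spike_in_check(
    spike_channels: dict[str, pd.Series], tolerance_cq: float = 2.0
) -> tuple[pd.DataFrame, list[str]]:
    """Flag samples whose spike-in Cq deviates from the channel median.

    Flags are advisory (extraction/RT/PCR monitoring), never exclusions.
    Channels with fewer than 3 samples are skipped with a note.
    """
    rows, notes = [], []
    for channel, series in spike_channels.items():
        vals = series.dropna()
        if len(vals) < 3:
            notes.append(f"spike channel {channel} skipped (<3 samples)")
            continue
        med = float(vals.median())
        dev = vals - med
        for sample, d in dev.items():
            if abs(d) > tolerance_cq:
                rows.append(
                    {"sample_id": sample, "channel": channel, "deviation_cq": float(d)}
                )
    return (
        pd.DataFrame(rows, columns=["sample_id", "channel", "deviation_cq"]),
        notes,
    )


def _find_marker(m: CqMatrix, canonical: str) -> str | None:
    lower = {f.lower(): f for f in m.feature_ids}
    for alias in _MARKER_ALIASES[canonical]:
        if alias.lower() in lower:
            return lower[alias.lower()]
    return None


def build_qc_report(
    m: CqMatrix,
    meta: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> tuple[QCReport, CqMatrix]:
    """Consolidated QC: detection limits, hemolysis verdicts, spike flags.

    Samples with verdict ``hemolysed`` are removed from the returned
    matrix; the report partitions the input sample set into kept/excluded
    with machine-readable reasons.
    """
    if config is None:
        config = PipelineConfig()
    if m.values.shape[0] == 0:
        raise ValueError("no features")

    filtered, included = apply_detection_limits(m, config.lod_cq, config.nc_margin_cq)

    notes: list[str] = []
    f23 = _find_marker(m, HEMOLYSIS_MARKER_HIGH)
    f451 = _find_marker(m, HEMOLYSIS_MARKER_RBC)
    hem_rows = []
    if f23 is None or f451 is None:
        warnings.warn("hemolysis markers absent; hemolysis scoring skipped")
        notes.append("hemolysis scoring skipped: marker rows absent")
        for s in m.sample_ids:
            hem_rows.append({"sample_id": s, "dcq": np.nan, "verdict": "indeterminate"})
    else:
        for s in m.sample_ids:
            cq23 = m.values.at[f23, s] if m.detected.at[f23, s] else np.nan
            cq451 = m.values.at[f451, s] if m.detected.at[f451, s] else np.nan
            r = hemolysis_score(
                cq23,
                cq451,
                config.hemolysis_warn_dcq,
                config.hemolysis_exclude_dcq,
                s,
            )
            hem_rows.append({"sample_id": s, "dcq": r.dcq, "verdict": r.verdict})
    hemolysis = pd.DataFrame(hem_rows)

    spike_flags, spike_notes = spike_in_check(
        m.spike_channels, config.spike_tolerance_cq
    )
    notes.extend(spike_notes)

    excluded = hemolysis.loc[hemolysis["verdict"] == "hemolysed", ["sample_id"]].copy()
    excluded["reason"] = "hemolysis"
    kept = [s for s in m.sample_ids if s not in set(excluded["sample_id"])]
    report = QCReport(
        hemolysis=hemolysis,
        spike_flags=spike_flags,
        assay_included=included,
        excluded_samples=excluded.reset_index(drop=True),
        notes=notes,
    )
    return report, filtered.subset_samples(kept)
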