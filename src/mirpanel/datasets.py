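"""Bundled reference tables from the published MNGIE circulating-miRNA study.

Four small TSV tables ship with the package and serve as inputs for the
filtering, union and panel-selection operations:

* discovery-phase serum qPCR differential expression (adjusted p and
  signed fold change);
* candidate-screening serum sequencing differential expression per age
  stratum (TMM means, log2 FC, raw and adjusted p);
* validation-phase plasma/serum qPCR differential expression (log2 FC,
  adjusted p, membership in the sequencing-refined signature);
* cross-platform meta-analysis combined p-values (top 10 per biofluid).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("mirpanel.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_discovery_de() -> pd.DataFrame:
    """Discovery serum qPCR DE table with derived log2_fc and direction."""
    df = _load("discovery_qpcr_de.tsv")
    fc = df["fold_change"].astype(float)
    df["log2_fc"] = np.sign(fc) * np.log2(fc.abs())
    df["direction"] = np.where(fc > 0, "up", "down")
    return df


def load_screening_de() -> pd.DataFrame:
    """Screening-phase sequencing DE rows per age stratum with direction."""
    df = _load("screening_ngs_de.tsv")
    df["direction"] = np.where(df["log2_fc"] > 0, "up", "down")
    df["fold_change"] = np.where(
        df["log2_fc"] >= 0, 2.0 ** df["log2_fc"], -(2.0 ** (-df["log2_fc"]))
    )
    return df


def load_validation_de() -> pd.DataFrame:
    """Validation qPCR DE table (plasma and serum) with signed fold change."""
    df = _load("validation_qpcr_de.tsv")
    df["fold_change"] = np.where(
        df["log2_fc"] >= 0, 2.0 ** df["log2_fc"], -(2.0 ** (-df["log2_fc"]))
    )
    df["in_refined_signature"] = df["in_refined_signature"].astype(bool)
    return df


def load_meta_combined() -> pd.DataFrame:
    """Cross-platform combined p-values, top 10 per biofluid."""
    return _load("meta_combined.tsv")
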