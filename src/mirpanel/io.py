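"""TSV readers and writers for Cq matrices, count matrices and metadata.

The canonical on-disk dialect is UTF-8 TSV, wide orientation: features as
rows, samples as columns. Undetected qPCR reactions are stored as empty
cells or ``NA`` and written back as ``NA``. A long dialect with columns
(feature, sample, cq) is accepted on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, CqMatrix, FormatError, validate_sample_metadata

NA_TOKENS = {"", "na", "nan", "nd", "undetected"}

_SPIKE_PREFIX = "#spike:"
_NC_PREFIX = "#negative_control"
_TOTALS_PREFIX = "#mapped_total"


def _parse_cq_cell(raw, where: str) -> float:
    s = str(raw).strip()
    if s.lower() in NA_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError as exc:
        raise FormatError(f"non-numeric Cq {raw!r} at {where}") from exc


def read_cq_matrix(path, dialect: str = "wide") -> CqMatrix:
    """Read a Cq matrix from a TSV file.

    ``wide``: header of sample IDs, first column feature IDs. Comment rows
    starting ``#spike:<name>`` carry spike-in channels and ``#negative_control``
    a per-assay no-template-control column appended as the last column.
    ``long``: columns (feature, sample, cq).
    """
    if dialect == "long":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 3:
            raise FormatError("long dialect needs columns (feature, sample, cq)")
        df.columns = ["feature", "sample", "cq"] + list(df.columns[3:])
        dup = df.duplicated(subset=["feature", "sample"])
        if dup.any():
            pairs = df.loc[dup, ["feature", "sample"]].to_records(index=False)
            raise FormatError(f"duplicate (feature, sample) pairs: {list(pairs)[:5]}")
        df["cq"] = [
            _parse_cq_cell(v, f"({f}, {s})")
            for v, f, s in zip(df["cq"], df["feature"], df["sample"])
        ]
        wide = df.pivot(index="feature", columns="sample", values="cq")
        wide = wide.loc[pd.unique(df["feature"]), pd.unique(df["sample"])]
        wide.index.name = None
        wide.columns.name = None
        return CqMatrix(wide)
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")

    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    sample_ids = header[1:]
    has_nc = sample_ids and sample_ids[-1] == "negative_control"
    if has_nc:
        sample_ids = sample_ids[:-1]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise FormatError(f"duplicate sample columns: {dups}")

    features, rows, nc_vals = [], [], []
    spikes: dict[str, pd.Series] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        name, cells = parts[0], parts[1:]
        if name.startswith(_SPIKE_PREFIX):
            sname = name[len(_SPIKE_PREFIX):]
            vals = [_parse_cq_cell(c, f"spike {sname}") for c in cells[: len(sample_ids)]]
            spikes[sname] = pd.Series(vals, index=sample_ids)
            continue
        if name in features:
            raise FormatError(f"duplicate feature row: {name!r}")
        features.append(name)
        vals = [
            _parse_cq_cell(c, f"({name}, {s})") for c, s in zip(cells, sample_ids)
        ]
        if len(vals) != len(sample_ids):
            raise FormatError(f"row {name!r} has {len(vals)} cells, expected {len(sample_ids)}")
        rows.append(vals)
        if has_nc:
            nc_vals.append(
                _parse_cq_cell(parts[1 + len(sample_ids)], f"({name}, negative_control)")
                if len(parts) > 1 + len(sample_ids)
                else np.nan
            )
    values = pd.DataFrame(rows, index=features, columns=sample_ids, dtype=float)
    nc = pd.Series(nc_vals, index=features) if has_nc else None
    return CqMatrix(values, spike_channels=spikes, negative_control=nc)


def write_cq_matrix(m: CqMatrix, path) -> None:
    """Write a CqMatrix in the wide dialect; undetected cells emit ``NA``."""
    out = m.values.where(m.detected)
    df = out.copy()
    if m.negative_control is not None:
        df["negative_control"] = m.negative_control
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(df.columns) + "\n")
        for feat, row in df.iterrows():
            cells = ["NA" if pd.isna(v) else format(v, ".10g") for v in row]
            fh.write(str(feat) + "\t" + "\t".join(cells) + "\n")
        for sname, series in m.spike_channels.items():
            cells = [
                "NA" if pd.isna(series.get(s, np.nan)) else format(series[s], ".10g")
                for s in m.sample_ids
            ]
            if m.negative_control is not None:
                cells.append("NA")
            fh.write(f"{_SPIKE_PREFIX}{sname}\t" + "\t".join(cells) + "\n")


def read_count_matrix(path) -> CountMatrix:
    """Read an integer count TSV; an optional ``#mapped_total`` row overrides
    the default (column sums)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    sample_ids = header[1:]
    features, rows = [], []
    totals = None
    for ln in lines[1:]:
        parts = ln.split("\t")
        name, cells = parts[0], parts[1:]
        if name.startswith(_TOTALS_PREFIX):
            totals = pd.Series(
                [float(c) for c in cells], index=sample_ids, dtype=float
            )
            continue
        vals = []
        for c, s in zip(cells, sample_ids):
            try:
                v = float(c)
            except ValueError as exc:
                raise FormatError(f"non-numeric count {c!r} at ({name}, {s})") from exc
            if v < 0 or v != int(v):
                raise FormatError(f"invalid count {c!r} at ({name}, {s})")
            vals.append(int(v))
        features.append(name)
        rows.append(vals)
    counts = pd.DataFrame(rows, index=features, columns=sample_ids)
    return CountMatrix(counts, totals)


def write_count_matrix(c: CountMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(c.sample_ids) + "\n")
        fh.write(
            _TOTALS_PREFIX
            + "\t"
            + "\t".join(format(t, ".10g") for t in c.mapped_totals)
            + "\n"
        )
        for feat, row in c.counts.iterrows():
            fh.write(str(feat) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV (sample_id, group, biofluid,
    optional age/age_stratum/patient_id/timepoint_months/sex)."""
    df = pd.read_csv(path, sep="\t")
    return validate_sample_metadata(df)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)
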