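"""Synthetic study generators with planted, recoverable truth.

Every generator is a pure function of its parameters and a seed, and
returns the generated data together with a :class:`SimulationTruth`
recording exactly what was planted. Defaults mirror the study conditions
the pipeline targets: two-group qPCR Cq data with miRNA-specific
baselines and group effects on the published discovery-phase fold-change
scale, technical noise of 0.8 cycles, negative-binomial sequencing
counts around 1.5 million mapped reads per sample, hemolysis injection
through the erythrocyte miRNAs, and declining treatment trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AGE_STRATA, CountMatrix, CqMatrix
from .datasets import load_discovery_de, load_screening_de
from .qc import HEMOLYSIS_MARKER_HIGH, HEMOLYSIS_MARKER_RBC

#: erythrocyte-associated miRNAs co-perturbed by hemolysis injection
ERYTHROCYTE_FEATURES = (HEMOLYSIS_MARKER_RBC, "hsa-miR-16-5p", "hsa-miR-486-5p")

PANEL_FEATURES = (
    "hsa-miR-192-5p",
    "hsa-miR-193a-5p",
    "hsa-miR-194-5p",
    "hsa-miR-215-5p",
    "hsa-miR-34a-5p",
)

PREDICTION_SOURCES = ("diana", "pictar", "targetscan", "miranda")


@dataclass
class SimulationTruth:
    """What a generator planted; fully determines expectations given the seed."""

    seed: int
    effects: dict = field(default_factory=dict)  # feature -> log2 effect (or per stratum)
    stable_features: list = field(default_factory=list)
    hemolysed_samples: list = field(default_factory=list)
    panel_features: list = field(default_factory=list)
    trajectories: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def default_qpcr_effects(feature_names: list[str]) -> dict[str, float]:
    """Assign the published discovery-phase log2 fold changes (2.1- to
    7.1-fold up, 2.1- to 6.1-fold down) to the first features in order."""
    ref = load_discovery_de()
    effects = {}
    for name, l2 in zip(feature_names, ref["log2_fc"]):
        effects[name] = float(l2)
    return effects


def simulate_qpcr_study(
    n_per_group: int = 10,
    n_features: int = 100,
    effect_profile: dict[str, float] | None = None,
    noise_sd: float = 0.8,
    n_stable: int = 4,
    seed: int = 0,
):
    """Two-group qPCR panel study with planted group effects.

    Per feature, baseline Cq ~ U(22, 34); disease samples are shifted by
    -effect (log2 units; more abundant = lower Cq) with Gaussian
    technical noise. ``n_stable`` designed normalizer features get zero
    effect and a quarter of the noise. The hemolysis marker pair and the
    spike-in channels are always included; cells above Cq 37 are
    undetected. Returns (CqMatrix, metadata, SimulationTruth).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    markers = [HEMOLYSIS_MARKER_HIGH, HEMOLYSIS_MARKER_RBC]
    erythro_extra = [f for f in ERYTHROCYTE_FEATURES if f not in markers]
    stable = [f"sim-ref-{i + 1:02d}" for i in range(n_stable)]
    n_regular = n_features - len(markers) - len(erythro_extra) - n_stable
    if n_regular < 1:
        raise ValueError("n_features too small for markers and stable set")
    regular = [f"sim-miR-{i + 1:03d}" for i in range(n_regular)]
    features = markers + erythro_extra + stable + regular

    if effect_profile is None:
        effect_profile = default_qpcr_effects(regular)
    protected = set(markers) | set(erythro_extra) | set(stable)
    bad = protected & set(effect_profile)
    if bad:
        raise ValueError(f"effect assigned to stable/marker feature: {sorted(bad)}")
    unknown = set(effect_profile) - set(features)
    if unknown:
        raise ValueError(f"effect assigned to unknown feature: {sorted(unknown)}")

    d_ids = [f"SP{i + 1:02d}" for i in range(n_per_group)]
    h_ids = [f"SC{i + 1:02d}" for i in range(n_per_group)]
    samples = d_ids + h_ids
    is_disease = np.array([1] * n_per_group + [0] * n_per_group, dtype=bool)

    baseline = rng.uniform(22.0, 34.0, size=len(features))
    baseline[features.index(HEMOLYSIS_MARKER_HIGH)] = 22.0
    baseline[features.index(HEMOLYSIS_MARKER_RBC)] = 19.0
    for f in erythro_extra:
        baseline[features.index(f)] = rng.uniform(22.0, 25.0)
    for f in stable:
        baseline[features.index(f)] = rng.uniform(23.0, 29.0)

    sd = np.full(len(features), float(noise_sd))
    for f in stable:
        sd[features.index(f)] = noise_sd / 4.0
    for f in markers:  # keep the marker pair tight so planted dCq is crisp
        sd[features.index(f)] = noise_sd / 2.0
    effect = np.array([effect_profile.get(f, 0.0) for f in features])

    noise = rng.normal(0.0, 1.0, size=(len(features), len(samples))) * sd[:, None]
    cq = baseline[:, None] - effect[:, None] * is_disease[None, :] + noise
    values = pd.DataFrame(cq, index=features, columns=samples)
    detected = values <= 37.0
    values = values.where(detected)

    spike_base = {"UniSp2": 19.0, "UniSp4": 26.0, "UniSp6": 21.0, "UniSp3": 18.0}
    spikes = {
        name: pd.Series(
            base + rng.normal(0.0, 0.15, size=len(samples)), index=samples
        )
        for name, base in spike_base.items()
    }
    nc = pd.Series(rng.uniform(38.0, 42.0, size=len(features)), index=features)

    ages = {"disease": [], "healthy": []}
    age_cycle = [15, 25, 35]
    rows = []
    for i, s in enumerate(samples):
        rows.append(
            {
                "sample_id": s,
                "group": "disease" if is_disease[i] else "healthy",
                "biofluid": "serum",
                "age": age_cycle[i % 3],
            }
        )
    from .containers import validate_sample_metadata

    meta = validate_sample_metadata(pd.DataFrame(rows))
    truth = SimulationTruth(
        seed=seed,
        effects=dict(effect_profile),
        stable_features=stable,
    )
    return CqMatrix(values, detected, spikes, nc), meta, truth


def inject_hemolysis(
    m: CqMatrix,
    sample_ids: list[str],
    severity_dcq: float,
    erythrocyte_features: tuple[str, ...] = ERYTHROCYTE_FEATURES,
) -> CqMatrix:
    """Lower the erythrocyte miRNAs' Cq in chosen samples so that
    Cq(miR-23a) - Cq(miR-451) equals ``severity_dcq`` there."""
    if HEMOLYSIS_MARKER_RBC not in m.values.index:
        raise ValueError("miR-451 row absent")
    unknown = [s for s in sample_ids if s not in m.values.columns]
    if unknown:
        raise ValueError(f"unknown sample(s): {unknown}")
    out = m.copy()
    for s in sample_ids:
        cq23 = out.values.at[HEMOLYSIS_MARKER_HIGH, s]
        target_451 = cq23 - severity_dcq
        shift = target_451 - out.values.at[HEMOLYSIS_MARKER_RBC, s]
        for f in erythrocyte_features:
            if f in out.values.index:
                out.values.at[f, s] = out.values.at[f, s] + shift
    out.detected = out.values <= 37.0
    out.values = out.values.where(out.detected)
    return out


def default_ngs_effects(feature_names: list[str]) -> dict[str, dict[str, float]]:
    """Per-stratum log2 effects on the published screening-phase scale."""
    ref = load_screening_de()
    effects: dict[str, dict[str, float]] = {s: {} for s in AGE_STRATA}
    pool = {s: list(ref.loc[ref["stratum"] == s, "log2_fc"]) for s in AGE_STRATA}
    for stratum in AGE_STRATA:
        for name, l2 in zip(feature_names, pool[stratum]):
            effects[stratum][name] = float(l2)
    return effects


def simulate_ngs_counts(
    n_per_group: int = 8,
    n_features: int = 500,
    mean_library: float = 1.5e6,
    dispersion: float = 0.15,
    effect_profile: dict | None = None,
    strata: tuple[str, ...] | None = None,
    seed: int = 0,
):
    """Negative-binomial small-RNA-seq counts with library-size variation.

    Feature abundances are log-normal proportions; counts are
    gamma-Poisson (NB) with the given dispersion around
    proportion x library x 2^effect for disease samples. With ``strata``,
    ``n_per_group`` applies per group within each stratum and
    ``effect_profile`` may map stratum -> {feature -> log2 effect};
    otherwise a flat {feature -> log2 effect} map applies to all disease
    samples. Returns (CountMatrix, metadata, SimulationTruth).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    features = [f"sim-miR-{i + 1:03d}" for i in range(n_features)]

    if effect_profile is None:
        effect_profile = {}
    per_stratum = strata is not None and effect_profile and all(
        isinstance(v, dict) for v in effect_profile.values()
    )

    groups = ["disease", "healthy"]
    stratum_list = list(strata) if strata is not None else [None]
    sample_rows = []
    idx = 0
    for st in stratum_list:
        for g in groups:
            for _ in range(n_per_group):
                idx += 1
                sample_rows.append(
                    {
                        "sample_id": f"N{'P' if g == 'disease' else 'C'}{idx:03d}",
                        "group": g,
                        "biofluid": "serum",
                        "age_stratum": st if st is not None else "20_29",
                    }
                )
    meta_df = pd.DataFrame(sample_rows)
    samples = list(meta_df["sample_id"])

    weights = rng.lognormal(mean=0.0, sigma=1.5, size=n_features)
    prop = weights / weights.sum()
    lib = rng.lognormal(
        mean=np.log(mean_library) - 0.3**2 / 2, sigma=0.3, size=len(samples)
    )

    counts = np.zeros((n_features, len(samples)), dtype=np.int64)
    for j, row in meta_df.iterrows():
        mu = prop * lib[j]
        if row["group"] == "disease":
            if per_stratum:
                eff = effect_profile.get(row["age_stratum"], {})
            else:
                eff = effect_profile
            if eff:
                mult = np.array([2.0 ** eff.get(f, 0.0) for f in features])
                mu = mu * mult
        lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=features, columns=samples))
    from .containers import validate_sample_metadata

    meta = validate_sample_metadata(meta_df)
    truth = SimulationTruth(
        seed=seed,
        effects=dict(effect_profile),
        extras={"dispersion": dispersion, "mean_library": mean_library,
                "proportions": dict(zip(features, prop))},
    )
    return cm, meta, truth


def simulate_treatment_response(
    panel_features: tuple[str, ...] = PANEL_FEATURES,
    n_patients: int = 4,
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 11.0),
    decline_log2_per_step: float = 0.75,
    relapse_spec: dict[str, list[float]] | None = None,
    noise_sd: float = 0.15,
    seed: int = 0,
):
    """Longitudinal qPCR samples for treated patients.

    Panel features decline by ``decline_log2_per_step`` log2 units per
    successive timepoint (Cq rises as abundance falls); a relapse entry
    {patient: [timepoints]} reverses the step at those timepoints. Two
    constant reference assays are included for normalization. Returns
    (CqMatrix, metadata, SimulationTruth).
    """
    if 0.0 not in timepoints:
        raise ValueError("baseline timepoint 0 is required")
    rng = np.random.default_rng(seed)
    relapse_spec = relapse_spec or {}
    refs = ["sim-ref-A", "sim-ref-B"]
    features = list(panel_features) + refs
    patients = [chr(ord("A") + i) for i in range(n_patients)]
    sample_rows, columns = [], {}
    traj: dict[str, dict[str, list[float]]] = {}
    for p in patients:
        base_cq = {f: rng.uniform(24.0, 30.0) for f in panel_features}
        ref_cq = {f: rng.uniform(22.0, 26.0) for f in refs}
        level = {f: 0.0 for f in panel_features}  # cumulative log2 decline
        traj[p] = {f: [] for f in panel_features}
        for ti, tp in enumerate(sorted(timepoints)):
            if ti > 0:
                step = decline_log2_per_step
                if tp in relapse_spec.get(p, []):
                    step = -decline_log2_per_step
                for f in panel_features:
                    level[f] -= step
            sid = f"{p}_t{tp:g}"
            col = {}
            for f in panel_features:
                col[f] = base_cq[f] - level[f] + rng.normal(0.0, noise_sd)
                traj[p][f].append(level[f])
            for f in refs:
                col[f] = ref_cq[f] + rng.normal(0.0, noise_sd / 3.0)
            columns[sid] = col
            sample_rows.append(
                {
                    "sample_id": sid,
                    "group": "disease",
                    "biofluid": "plasma",
                    "patient_id": p,
                    "timepoint_months": tp,
                }
            )
    values = pd.DataFrame(
        {sid: [col[f] for f in features] for sid, col in columns.items()},
        index=features,
    )
    from .containers import validate_sample_metadata

    meta = validate_sample_metadata(pd.DataFrame(sample_rows))
    truth = SimulationTruth(
        seed=seed,
        panel_features=list(panel_features),
        stable_features=refs,
        trajectories=traj,
        extras={"relapse_spec": relapse_spec},
    )
    return CqMatrix(values), meta, truth


def make_annotation_fixtures(
    n_mirnas: int = 5,
    n_genes: int = 600,
    n_sources: int = 4,
    n_terms: int = 9,
    n_pathways: int = 8,
    consensus_spec: dict[int, int] | None = None,
    enriched_spec: dict[str, float] | None = None,
    pathway_size: int = 12,
    term_size: int = 15,
    seed: int = 0,
):
    """Offline prediction-source and annotation fixtures with known
    consensus composition.

    ``consensus_spec`` maps target in-degree -> number of genes (default
    {2: 52, 3: 2}, the published network geometry); those genes are
    predicted by the required number of panel miRNAs in exactly two
    sources each, all other genes by at most one source. ``enriched_spec``
    maps a term/pathway id to the fraction of its genes drawn from the
    consensus target set. Returns (prediction tables, annotation table,
    pathway dict, SimulationTruth).
    """
    from .targets import PredictionTable

    rng = np.random.default_rng(seed)
    consensus_spec = consensus_spec or {2: 52, 3: 2}
    enriched_spec = enriched_spec or {}
    mirnas = list(PANEL_FEATURES[:n_mirnas])
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    sources = list(PREDICTION_SOURCES[:n_sources])

    pool = list(genes)
    rng.shuffle(pool)
    rows_by_source: dict[str, list] = {s: [] for s in sources}
    consensus_truth: dict[str, int] = {}
    cursor = 0
    for degree, count in sorted(consensus_spec.items()):
        for _ in range(count):
            gene = pool[cursor]
            cursor += 1
            consensus_truth[gene] = degree
            chosen_mirnas = rng.choice(mirnas, size=degree, replace=False)
            for mir in chosen_mirnas:
                chosen_sources = rng.choice(sources, size=2, replace=False)
                for src in chosen_sources:
                    rows_by_source[src].append(
                        {"mirna": mir, "gene": gene, "score": rng.uniform(0.5, 1.0)}
                    )
    for gene in pool[cursor:]:
        src = sources[int(rng.integers(len(sources)))]
        mir = mirnas[int(rng.integers(len(mirnas)))]
        rows_by_source[src].append(
            {"mirna": mir, "gene": gene, "score": rng.uniform(0.0, 1.0)}
        )
    tables = [
        PredictionTable(s, pd.DataFrame(rows_by_source[s])) for s in sources
    ]

    consensus_genes = list(consensus_truth)
    categories = ["MF", "BP", "CC"]
    ann_rows = []
    for t in range(n_terms):
        term = f"TERM{t + 1:03d}"
        frac = enriched_spec.get(term, 0.0)
        n_from_consensus = int(round(frac * term_size))
        chosen = list(
            rng.choice(consensus_genes, size=min(n_from_consensus, len(consensus_genes)), replace=False)
        )
        others = [g for g in genes if g not in chosen]
        chosen += list(rng.choice(others, size=term_size - len(chosen), replace=False))
        for g in chosen:
            ann_rows.append(
                {
                    "term_id": term,
                    "term_name": f"synthetic term {t + 1}",
                    "category": categories[t % 3],
                    "gene": g,
                }
            )
    annotation = pd.DataFrame(ann_rows)

    pathways: dict[str, set] = {}
    for t in range(n_pathways):
        name = f"PATH{t + 1:03d}"
        frac = enriched_spec.get(name, 0.0)
        n_from_consensus = int(round(frac * pathway_size))
        chosen = list(
            rng.choice(consensus_genes, size=min(n_from_consensus, len(consensus_genes)), replace=False)
        )
        others = [g for g in genes if g not in chosen]
        chosen += list(rng.choice(others, size=pathway_size - len(chosen), replace=False))
        pathways[name] = set(chosen)

    truth = SimulationTruth(
        seed=seed,
        panel_features=mirnas,
        extras={
            "consensus_degrees": consensus_truth,
            "enriched_spec": dict(enriched_spec),
            "universe": genes,
        },
    )
    return tables, annotation, pathways, truth
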