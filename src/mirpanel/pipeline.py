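"""End-to-end orchestration of the biomarker discovery workflow.

One call runs the four study phases on synthetic cohorts sharing a
planted truth: qPCR QC -> normalizer selection and normalization ->
differential expression on both platforms -> elastic-net signature ->
cross-platform meta-analysis and panel selection -> panel ROC ->
longitudinal treatment response -> target/enrichment annotation. Every
stage writes one TSV and the run ends with a machine-readable summary;
the whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import meta as meta_mod
from . import normalize as norm_mod
from . import qc as qc_mod
from . import signature as sig_mod
from . import simulate as sim_mod
from . import targets as tgt_mod
from .containers import PipelineConfig


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    n_per_group: int = 17,
    n_features: int = 100,
    ngs_n_per_group: int = 5,
    n_lambda: int = 15,
) -> dict:
    """Run the full synthetic-study pipeline and write per-stage TSVs plus
    ``summary.json`` to ``out_dir``. Deterministic given ``config.seed``."""
    if n_per_group <= 0 or ngs_n_per_group <= 0:
        raise ValueError("no samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    summary: dict = {"seed": seed, "stages": {}, "counts": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - report stage and re-raise
                summary["stages"][name] = "failed"
                raise StageError(name, exc) from exc

        return deco

    # --- simulate -----------------------------------------------------------
    @stage("simulate")
    def _sim():
        cq, qmeta, qtruth = sim_mod.simulate_qpcr_study(
            n_per_group=n_per_group, n_features=n_features, seed=seed
        )
        flat_effects = dict(qtruth.effects)
        counts, nmeta, ntruth = sim_mod.simulate_ngs_counts(
            n_per_group=ngs_n_per_group,
            n_features=n_features,
            effect_profile=flat_effects,
            strata=("le19", "20_29", "ge30"),
            seed=seed + 1,
        )
        return cq, qmeta, qtruth, counts, nmeta

    cq, qmeta, qtruth, counts, nmeta = _sim
    summary["stages"]["simulate"] = "ok"

    # --- qc -----------------------------------------------------------------
    @stage("qc")
    def _qc():
        report, filtered = qc_mod.build_qc_report(cq, qmeta, config)
        _write(report.hemolysis, out / "qc_report.tsv")
        return report, filtered

    qc_report, cq_f = _qc
    summary["stages"]["qc"] = "qc_report.tsv"
    summary["counts"]["excluded_samples"] = len(qc_report.excluded_samples)

    # --- normalization ------------------------------------------------------
    @stage("normalize")
    def _norm():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = norm_mod.normfinder_stability(cq_f, qmeta)
            pair, pair_stab, beats = norm_mod.best_normalizer_pair(
                st, cq_f, qmeta, top_k=10
            )
        expr = norm_mod.reference_normalize(cq_f, list(pair))
        _write(st, out / "stability.tsv")
        norm_out = expr.values.reset_index().rename(columns={"index": "feature"})
        _write(norm_out, out / "normalized_cq.tsv")
        factors = norm_mod.tmm_factors(counts)
        fac_df = factors.tmm_factor.reset_index()
        fac_df.columns = ["sample_id", "tmm_factor"]
        _write(fac_df, out / "tmm_factors.tsv")
        return st, pair, pair_stab, expr, factors

    stability, pair, pair_stab, expr, factors = _norm
    summary["stages"]["normalize"] = "stability.tsv,normalized_cq.tsv,tmm_factors.tsv"
    summary["counts"]["normalizer_pair"] = list(pair)

    # --- differential expression -------------------------------------------
    @stage("de")
    def _de():
        de_q = de_mod.ddcq_differential(expr, qmeta)
        de_n = de_mod.nb_differential(counts, factors, nmeta)
        _write(de_q, out / "de_qpcr.tsv")
        _write(de_n, out / "de_ngs.tsv")
        return de_q, de_n

    de_q, de_n = _de
    sig_q, cnt_q = de_mod.filter_de(
        de_q, config.de_p_max, abs_fc_min=config.de_abs_fc_min
    )
    sig_n, cnt_n = de_mod.filter_de(
        de_n, config.de_p_max, abs_fc_min=None,
        abs_log2fc_min=config.de_abs_log2fc_min,
    )
    summary["stages"]["de"] = "de_qpcr.tsv,de_ngs.tsv"
    summary["counts"]["de_qpcr"] = cnt_q
    summary["counts"]["de_ngs"] = cnt_n

    # --- signature ----------------------------------------------------------
    @stage("signature")
    def _sig():
        tpm_df = norm_mod.tpm(counts)
        x = np.log2(tpm_df + 1.0).T  # samples x features
        predictors = sorted(set(sig_n["feature"]) | set(sig_q["feature"]))
        predictors = [f for f in predictors if f in x.columns]
        if len(predictors) < 2:
            predictors = list(x.columns)
        y = sig_mod.make_class_labels(nmeta.loc[x.index])
        min_class = int(y.value_counts().min())
        folds = max(2, min(config.elasticnet_folds, 2 * min_class))
        model = sig_mod.fit_multinomial_elasticnet(
            x[predictors], y,
            alpha=config.elasticnet_alpha,
            folds=folds,
            seed=seed + 4,
            n_lambda=n_lambda,
        )
        aucs = sig_mod.multiclass_auc(model, x[predictors], y)
        coef_long = (
            model.coefficients.T.reset_index()
            .rename(columns={"index": "feature"})
        )
        coef_long["retained"] = coef_long["feature"].isin(model.retained_features)
        _write(coef_long, out / "signature.tsv")
        return model, aucs

    model, aucs = _sig
    summary["stages"]["signature"] = "signature.tsv"
    summary["counts"]["signature_retained"] = len(model.retained_features)
    summary["counts"]["signature_auc_binary"] = round(aucs["binary"], 6)

    # --- meta-analysis and panel -------------------------------------------
    @stage("meta")
    def _meta():
        mr = meta_mod.meta_rank(de_n, de_q)
        _write(mr, out / "meta.tsv")
        panel = meta_mod.select_panel(mr, config.meta_p_threshold)
        pd.DataFrame({"feature": panel}).to_csv(
            out / "panel.tsv", sep="\t", index=False
        )
        return mr, panel

    meta_table, panel = _meta
    summary["stages"]["meta"] = "meta.tsv,panel.tsv"
    summary["counts"]["panel_size"] = len(panel)

    # --- panel ROC ----------------------------------------------------------
    @stage("panel_roc")
    def _roc():
        labels = (qmeta.loc[expr.sample_ids, "group"] == "disease").to_numpy()
        rows = []
        for feat in panel:
            if feat not in expr.values.index:
                continue
            vals = expr.values.loc[feat]
            if vals.isna().any():
                continue
            r = meta_mod.logistic_roc(vals.to_numpy(), labels, feat)
            rows.append(
                {
                    "id": r.id, "auc": r.auc, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p_value": r.p_value,
                }
            )
        usable = [f for f in panel if f in expr.values.index
                  and not expr.values.loc[f].isna().any()]
        if usable:
            xmat = expr.values.loc[usable].T
            rc = meta_mod.combined_panel_roc(xmat, labels)
            rows.append(
                {
                    "id": "panel", "auc": rc.auc, "ci_low": rc.ci_low,
                    "ci_high": rc.ci_high, "p_value": rc.p_value,
                }
            )
        roc_df = pd.DataFrame(rows)
        _write(roc_df, out / "roc.tsv")
        return roc_df

    roc_df = _roc
    summary["stages"]["panel_roc"] = "roc.tsv"
    if len(roc_df):
        summary["counts"]["panel_auc"] = round(
            float(roc_df.loc[roc_df["id"] == "panel", "auc"].iloc[0]), 6
        ) if (roc_df["id"] == "panel").any() else None

    # --- longitudinal performance ------------------------------------------
    @stage("performance")
    def _perf():
        cqt, tmeta, ttruth = sim_mod.simulate_treatment_response(seed=seed + 2)
        texpr = norm_mod.reference_normalize(cqt, ttruth.stable_features)
        prof = meta_mod.longitudinal_fold_change(
            texpr, tmeta, ttruth.panel_features
        )
        _write(prof, out / "longitudinal.tsv")
        return prof

    _perf
    summary["stages"]["performance"] = "longitudinal.tsv"

    # --- enrichment ---------------------------------------------------------
    @stage("enrich")
    def _enrich():
        tables, annotation, pathways, atruth = sim_mod.make_annotation_fixtures(
            enriched_spec={"PATH001": 0.8, "TERM001": 0.6}, seed=seed + 3
        )
        consensus = tgt_mod.aggregate_targets(tables)
        net = tgt_mod.build_network(consensus, atruth.panel_features)
        ranking = list(
            consensus.sort_values(
                ["aggregate_score", "gene"], ascending=[False, True]
            )["gene"].drop_duplicates()
        )
        go = tgt_mod.go_enrichment_ks(ranking, annotation)
        pw = tgt_mod.pathway_enrichment(
            set(consensus["gene"]), pathways, set(atruth.extras["universe"])
        )
        enr = pd.concat([go, pw], ignore_index=True)
        _write(enr, out / "enrichment.tsv")
        edges = pd.DataFrame(
            [(u, v) for u, v in net.graph.edges], columns=["mirna", "gene"]
        )
        _write(edges, out / "network_edges.tsv")
        return net

    net = _enrich
    summary["stages"]["enrich"] = "enrichment.tsv,network_edges.tsv"
    summary["counts"]["network_degree_histogram"] = {
        str(k): v for k, v in sorted(net.degree_histogram.items())
    }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
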