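"""Consensus target prediction, miRNA-target networks and enrichment.

Predicted miRNA-gene interactions from several offline prediction sources
are aggregated by requiring support from at least two sources and ranking
genes by the geometric mean of within-source rank-normalized scores. The
panel's consensus targets form a bipartite miRNA-gene network; gene
rankings feed a rank-based Kolmogorov-Smirnov GO term test, and target
gene sets feed a hypergeometric pathway over-representation test with BH
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass
class PredictionTable:
    """One prediction source: rows of (mirna, gene, score), higher = stronger."""

    source_name: str
    table: pd.DataFrame  # columns: mirna, gene, score

    def __post_init__(self) -> None:
        if self.table.duplicated(subset=["mirna", "gene"]).any():
            raise ValueError(
                f"duplicate (mirna, gene) pairs in source {self.source_name}"
            )


def aggregate_targets(
    tables: list[PredictionTable], min_sources: int = 2
) -> pd.DataFrame:
    """Consensus targets supported by at least ``min_sources`` sources.

    Within each source, the scores of a miRNA's predicted genes are
    mapped to (0, 1] by rank/n (average rank for ties, best score -> 1);
    the aggregate is the geometric mean of the normalized scores over the
    sources that predict the pair. Output columns: mirna, gene,
    n_sources, aggregate_score, sorted per miRNA by aggregate descending.
    """
    if not tables:
        raise ValueError("no prediction tables supplied")
    frames = []
    for t in tables:
        df = t.table.copy()
        df["norm_score"] = df.groupby("mirna")["score"].transform(
            lambda s: s.rank(method="average") / len(s)
        )
        df["source"] = t.source_name
        frames.append(df[["mirna", "gene", "norm_score", "source"]])
    allp = pd.concat(frames, ignore_index=True)
    agg = allp.groupby(["mirna", "gene"]).agg(
        n_sources=("source", "nunique"),
        aggregate_score=("norm_score", lambda v: float(np.exp(np.mean(np.log(v))))),
    )
    agg = agg[agg["n_sources"] >= min_sources].reset_index()
    agg = agg.sort_values(
        ["mirna", "aggregate_score", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return agg


@dataclass
class TargetNetwork:
    graph: nx.DiGraph  # mirna -> gene edges
    gene_degree: pd.Series  # number of panel miRNAs targeting each kept gene
    degree_histogram: dict[int, int]


def build_network(
    consensus: pd.DataFrame, panel: list[str], min_degree: int = 2
) -> TargetNetwork:
    """Bipartite network of panel miRNAs and genes targeted by at least
    ``min_degree`` of them."""
    if not panel:
        raise ValueError("panel is empty")
    sub = consensus[consensus["mirna"].isin(panel)]
    deg = sub.groupby("gene")["mirna"].nunique()
    kept = deg[deg >= min_degree]
    g = nx.DiGraph()
    g.add_nodes_from(panel, kind="mirna")
    g.add_nodes_from(kept.index, kind="gene")
    for _, row in sub[sub["gene"].isin(kept.index)].iterrows():
        g.add_edge(row["mirna"], row["gene"], weight=row["aggregate_score"])
    hist: dict[int, int] = {}
    for d in kept:
        hist[int(d)] = hist.get(int(d), 0) + 1
    return TargetNetwork(g, kept.sort_values(ascending=False), hist)


def go_enrichment_ks(
    gene_ranking: list[str], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Rank-based K-S enrichment of annotation terms in a gene ranking.

    ``gene_ranking`` is ordered best-first (e.g. by consensus aggregate
    score descending); ``annotation`` has columns (term_id, term_name,
    category, gene). Each term's member ranks are compared with the
    non-member ranks by a two-sample Kolmogorov-Smirnov test (exact where
    feasible). Terms with fewer than 2 annotated ranked genes, or no
    complement, are skipped.
    """
    ranks = {g: i + 1 for i, g in enumerate(gene_ranking)}
    n = len(ranks)
    rows = []
    for (term_id, term_name, category), grp in annotation.groupby(
        ["term_id", "term_name", "category"]
    ):
        member_ranks = np.array(
            sorted({ranks[g] for g in grp["gene"] if g in ranks})
        )
        if len(member_ranks) < 2 or len(member_ranks) >= n:
            continue
        bg = np.setdiff1d(np.arange(1, n + 1), member_ranks)
        ks = stats.ks_2samp(member_ranks, bg)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "category": category,
                "statistic": float(ks.statistic),
                "p_raw": float(ks.pvalue),
            }
        )
    return pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "statistic", "p_raw"]
    )


def pathway_enrichment(
    target_genes: set, pathways: dict[str, set], universe: set
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in a target gene set.

    p = P(X >= overlap) with X hypergeometric(universe, pathway-in-universe,
    selected); BH adjustment across tested pathways. Pathways disjoint
    from the universe are skipped.
    """
    target_genes = set(target_genes) & set(universe)
    if not set(target_genes) <= set(universe):
        raise ValueError("universe must contain the target genes")
    big_m = len(universe)
    n_sel = len(target_genes)
    rows = []
    for name, genes in pathways.items():
        in_universe = set(genes) & set(universe)
        if not in_universe:
            continue
        overlap = len(in_universe & target_genes)
        p = float(stats.hypergeom.sf(overlap - 1, big_m, len(in_universe), n_sel))
        rows.append(
            {
                "term_id": name,
                "term_name": name,
                "category": "pathway",
                "statistic": overlap,
                "p_raw": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "category", "statistic", "p_raw"]
    )
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p_raw"])
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
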