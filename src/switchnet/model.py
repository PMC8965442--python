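"""Model-style front end: a fitted switch-gene analysis of one dataset.

``SwitchGeneModel`` holds the expression matrix plus every tunable of the
pipeline; ``fit()`` runs preprocessing, the differential filter, network
construction, community detection and cartography, and returns a
``SwitchGeneResults`` carrying the per-stage tables, the switch-gene calls
and a ``summary()``.  Robustness curves, biclustering and the downstream
enrichment / regulator analyses hang off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import cartography as carto
from . import communities as comm
from . import diffexp, downstream, network
from .cartography import Thresholds
from .io import ExpressionMatrix, GeneSetCollection, InteractionTable, \
    read_expression, write_gene_list
from .robustness import RobustnessCurve, compare_strategies, removal_curve

logger = logging.getLogger(__name__)

__all__ = ["SwitchGeneModel", "SwitchGeneResults"]


class SwitchGeneModel:
    """Switch-gene analysis of a case/control expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Log2 expression with case/control sample groups.
    fold_change : float
        Linear fold-change threshold of the differential filter (the filter
        keeps |log2fc| >= log2(fold_change)).
    alpha : float
        BH FDR cut-off of the filter; ``alpha=1`` disables the significance
        test and leaves a pure fold-change filter.
    correlation_threshold : float or "auto"
        |r| cut-off of the co-expression graph; "auto" picks the smallest
        grid value whose graph density is <= 10%.
    k : int or None
        Number of communities; None selects k at the SSE scree elbow over
        ``k_range``.
    min_mean, min_fraction_expressed : float
        Low-expression preprocessing thresholds.
    thresholds : Thresholds
        Cartography cut-offs (zg 2.5, kpi 0.8, apcc 0, hub 5).
    """

    def __init__(self, expr: ExpressionMatrix, *, fold_change: float = 2.0,
                 alpha: float = 0.05, correlation_threshold="auto",
                 k: int | None = None, k_range=range(2, 11),
                 replicates: int = 10, min_mean: float = 1.0,
                 min_fraction_expressed: float = 0.5,
                 thresholds: Thresholds = Thresholds()):
        self.expr = expr
        self.fold_change = float(fold_change)
        self.alpha = float(alpha)
        self.correlation_threshold = correlation_threshold
        self.k = k
        self.k_range = list(k_range)
        self.replicates = int(replicates)
        self.min_mean = float(min_mean)
        self.min_fraction_expressed = float(min_fraction_expressed)
        self.thresholds = thresholds

    @classmethod
    def from_files(cls, matrix_path, annotation_path, **kwargs) -> "SwitchGeneModel":
        return cls(read_expression(matrix_path, annotation_path), **kwargs)

    def config(self) -> dict:
        return {
            "fold_change": self.fold_change,
            "alpha": self.alpha,
            "correlation_threshold": self.correlation_threshold,
            "k": self.k,
            "k_range": self.k_range,
            "replicates": self.replicates,
            "min_mean": self.min_mean,
            "min_fraction_expressed": self.min_fraction_expressed,
            "thresholds": asdict(self.thresholds),
        }

    def fit(self, seed: int = 0) -> "SwitchGeneResults":
        """Run the full pipeline; deterministic given (inputs, config, seed).

        One seed feeds named substreams, so community detection and any
        later robustness run are individually reproducible.
        """
        ss = np.random.SeedSequence(int(seed))
        seed_kmeans, seed_robust = (int(c.generate_state(1)[0] % (2 ** 31))
                                    for c in ss.spawn(2))

        filtered = diffexp.preprocess(self.expr, self.min_mean,
                                      self.min_fraction_expressed)
        diff = diffexp.differential_analysis(filtered, self.fold_change, self.alpha)
        retained = list(diff.index[diff["retained"]])
        logger.info("filter: %d of %d genes retained", len(retained), len(diff))
        if len(retained) < 3:
            raise ValueError(f"only {len(retained)} genes pass the filter; "
                             "lower fold_change or raise alpha")

        corr = network.pearson_matrix(filtered.subset_genes(retained))
        if self.correlation_threshold == "auto":
            threshold = network.auto_threshold(corr)
        else:
            threshold = float(self.correlation_threshold)
        graph = network.build_graph(corr, threshold)

        assignment = comm.detect_communities(
            filtered, list(graph.nodes), k=self.k, k_range=self.k_range,
            replicates=self.replicates, seed=seed_kmeans)

        zg = carto.within_module_degree_z(graph, assignment.cluster_of)
        kpi = carto.clusterphobic_coefficient(graph, assignment.cluster_of)
        apcc_values = carto.apcc(filtered, graph, corr=corr)
        cart = carto.classify_nodes(zg, kpi, apcc_values, assignment.cluster_of,
                                    self.thresholds)
        switch = carto.call_switch_genes(cart)
        logger.info("called %d switch genes in %d communities", len(switch),
                    assignment.k)
        return SwitchGeneResults(
            model=self, expr_filtered=filtered, differential=diff,
            correlation=corr, threshold=threshold, graph=graph,
            communities=assignment, cartography=cart, switch_genes=switch,
            seed=int(seed), _seed_robust=seed_robust)


@dataclass
class SwitchGeneResults:
    """Everything the fitted pipeline produced for one dataset."""

    model: SwitchGeneModel
    expr_filtered: ExpressionMatrix
    differential: pd.DataFrame
    correlation: pd.DataFrame
    threshold: float
    graph: nx.Graph
    communities: comm.CommunityAssignment
    cartography: pd.DataFrame
    switch_genes: list[str]
    seed: int
    _seed_robust: int = field(repr=False, default=0)

    # -- headline numbers --------------------------------------------------
    def counts(self) -> dict[str, int | float]:
        hub = self.cartography["hub_class"].value_counts()
        return {
            "genes_input": len(self.model.expr.gene_ids),
            "genes_after_preprocess": len(self.differential),
            "genes_retained": int(self.differential["retained"].sum()),
            "graph_nodes": self.graph.number_of_nodes(),
            "graph_edges": self.graph.number_of_edges(),
            "correlation_threshold": float(self.threshold),
            "communities": self.communities.k,
            "party_hubs": int(hub.get("party", 0)),
            "date_hubs": int(hub.get("date", 0)),
            "fight_club_hubs": int(hub.get("fight_club", 0)),
            "switch_genes": len(self.switch_genes),
        }

    def summary(self) -> str:
        c = self.counts()
        lines = ["Switch-gene co-expression analysis", "=" * 36]
        labels = {
            "genes_input": "Genes in input matrix",
            "genes_after_preprocess": "Genes after low-expression filter",
            "genes_retained": "Genes passing |log2FC|/FDR filter",
            "graph_nodes": "Network nodes",
            "graph_edges": "Network edges",
            "correlation_threshold": "Correlation threshold |r|",
            "communities": "Communities (k)",
            "party_hubs": "Party nodes (APCC >= 0.5)",
            "date_hubs": "Date nodes (0 <= APCC < 0.5)",
            "fight_club_hubs": "Fight-club nodes (APCC < 0)",
            "switch_genes": "Switch genes (Zg<2.5, Kpi>0.8, APCC<0)",
        }
        for key, label in labels.items():
            value = c[key]
            shown = f"{value:.2f}" if isinstance(value, float) else str(value)
            lines.append(f"{label:<40s} {shown:>8s}")
        if self.switch_genes:
            lines.append("Switch genes: " + ", ".join(self.switch_genes))
        return "\n".join(lines)

    # -- follow-on analyses ------------------------------------------------
    def robustness(self, strategies=("random", "fight_club"), *,
                   fractions=None, n_points: int = 5,
                   seed: int | None = None) -> dict[str, RobustnessCurve]:
        """Removal curves on the largest component, one shared fraction grid."""
        G = network.largest_component(self.graph)
        return compare_strategies(G, self.cartography, strategies,
                                  fractions=fractions, n_points=n_points,
                                  seed=self._seed_robust if seed is None else seed)

    def removal_curve(self, strategy: str, fractions,
                      seed: int | None = None) -> RobustnessCurve:
        G = network.largest_component(self.graph)
        return removal_curve(G, self.cartography, strategy, fractions,
                             seed=self._seed_robust if seed is None else seed)

    def bicluster(self) -> carto.Bicluster:
        return carto.bicluster_switch(self.expr_filtered, self.switch_genes)

    def enrich(self, collection: GeneSetCollection,
               background=None) -> pd.DataFrame:
        """ORA of the switch genes; background defaults to the preprocessed genes."""
        bg = background if background is not None else self.differential.index
        return downstream.enrich(self.switch_genes, bg, collection)

    def rank_regulators(self, table: InteractionTable,
                        min_sources: int = 1) -> pd.DataFrame:
        return downstream.rank_regulators(table, self.switch_genes, min_sources)

    # -- persistence -------------------------------------------------------
    def save(self, out_dir) -> Path:
        """Write every stage artifact plus the resolved config to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config = dict(self.model.config(), seed=self.seed,
                      resolved_threshold=float(self.threshold))
        (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
        self.differential.to_csv(out / "differential.tsv", sep="\t",
                                 index_label="gene")
        network.write_edge_list(self.graph, out / "edges.tsv")
        self.communities.cluster_of.rename("cluster").to_csv(
            out / "communities.tsv", sep="\t", index_label="node")
        sse = [(k, i + 1, s) for k, reps in self.communities.sse_table.items()
               for i, s in enumerate(reps)]
        pd.DataFrame(sse, columns=["k", "replicate", "sse"]).to_csv(
            out / "sse.tsv", sep="\t", index=False)
        self.cartography.to_csv(out / "cartography.tsv", sep="\t",
                                index_label="node")
        write_gene_list(self.switch_genes, out / "switch_genes.txt")
        if len(self.switch_genes) >= 2:
            bic = self.bicluster()
            bic.matrix.to_csv(out / "bicluster_matrix.tsv", sep="\t",
                              index_label="gene")
            (out / "bicluster_rows.nwk").write_text(
                carto.linkage_to_newick(bic.linkage_rows, self.switch_genes))
        return out
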