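"""Downstream analyses of a switch-gene list.

* ``enrich`` -- hypergeometric over-representation of the switch genes
  against a user-supplied gene-set collection (e.g. a pathway GMT), BH
  corrected.  The background defaults to the genes that survived
  preprocessing, not the genome.
* ``rank_regulators`` -- degree / betweenness ranking of transcription
  factors, miRNAs or chemicals over a bipartite regulator-target graph
  restricted to switch-gene targets, with an optional multi-database
  consensus (keep regulators present in >= min_sources sources).
* ``shared_between`` -- exact multi-list membership table (the Venn logic
  used to compare switch-gene or regulator lists across datasets).
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_fdr
from .io import GeneSetCollection, InteractionTable

logger = logging.getLogger(__name__)

__all__ = ["enrich", "rank_regulators", "shared_between"]


def enrich(query, background, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation, BH corrected.

    For each set: population = background size, successes = set members in
    the background, draws = query size, p = P(X >= overlap).  Zero overlap
    reports p = 1; sets with no member in the background are skipped.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query gene set")
    stray = query - background
    if stray:
        raise ValueError(f"query not contained in background; e.g. {sorted(stray)[:3]}")
    rows = []
    for name in collection.names():
        members = set(collection.members(name)) & background
        if not members:
            logger.info("set %r has no member in the background; skipped", name)
            continue
        overlap = len(query & members)
        if overlap == 0:
            p = 1.0
        else:
            p = float(hypergeom.sf(overlap - 1, len(background), len(members), len(query)))
        rows.append((name, overlap, len(members), len(query), len(background), p))
    if not rows:
        raise ValueError("no gene set overlaps the background")
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "query_size", "background_size", "p_value"])
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "set_name"], ignore_index=True)


def rank_regulators(table: InteractionTable, switch_genes,
                    min_sources: int = 1) -> pd.DataFrame:
    """Rank regulators hitting switch genes by degree, then betweenness.

    Edges are restricted to switch-gene targets; a regulator survives only
    if it appears in at least ``min_sources`` distinct source databases
    (the multi-database Venn consensus).  Betweenness is unnormalized and
    computed on the undirected bipartite regulator+gene graph.
    """
    if len(table) == 0:
        raise ValueError("empty interaction table")
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    switch_genes = set(switch_genes)
    edges = table.edges[table.edges["gene"].isin(switch_genes)]
    if edges.empty:
        logger.warning("no regulator targets any switch gene")
        return pd.DataFrame(columns=["regulator", "kind", "degree", "betweenness",
                                     "n_sources", "sources"])
    sources = edges.groupby("regulator")["source"].agg(lambda s: frozenset(s))
    kept = sources[sources.map(len) >= min_sources]
    edges = edges[edges["regulator"].isin(kept.index)]
    if edges.empty:
        logger.warning("no regulator meets the %d-source consensus", min_sources)
        return pd.DataFrame(columns=["regulator", "kind", "degree", "betweenness",
                                     "n_sources", "sources"])

    G = nx.Graph()
    pairs = edges[["regulator", "gene"]].drop_duplicates()
    G.add_edges_from((f"reg::{r}", f"gene::{g}")
                     for r, g in pairs.itertuples(index=False))
    bc = nx.betweenness_centrality(G, normalized=False)
    degree = pairs.groupby("regulator").size()
    out = pd.DataFrame({
        "regulator": degree.index,
        "kind": table.kind,
        "degree": degree.to_numpy(),
        "betweenness": [bc[f"reg::{r}"] for r in degree.index],
        "n_sources": [len(kept[r]) for r in degree.index],
        "sources": [",".join(sorted(kept[r])) for r in degree.index],
    })
    return out.sort_values(["degree", "betweenness", "regulator"],
                           ascending=[False, False, True], ignore_index=True)


def shared_between(lists: dict[str, set]) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Exact multi-list membership and shared-by-exactly-n summary.

    Returns (table, summary): the table has one row per item in the union
    with the names of the lists containing it; ``summary[n]`` holds the
    items found in exactly n lists.  The summary partitions the union.
    """
    if len(lists) < 2:
        raise ValueError("need >= 2 named lists")
    sets = {name: set(v) for name, v in lists.items()}
    union = sorted(set().union(*sets.values()))
    rows = []
    summary: dict[int, list[str]] = {}
    for item in union:
        where = sorted(name for name, s in sets.items() if item in s)
        rows.append((item, len(where), ",".join(where)))
        summary.setdefault(len(where), []).append(item)
    table = pd.DataFrame(rows, columns=["item", "n_lists", "list_names"])
    return table, summary
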