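"""Heat cartography: Zg, Kpi, APCC, node roles and switch-gene calls.

Every node of the co-expression graph gets three coordinates:

* ``zg`` -- within-module degree z-score: how hub-like the node is inside
  its own community (population sd; a zero-spread community maps to 0);
* ``kpi`` -- clusterphobic coefficient ``1 - (k_in / k_tot)**2``: near 1
  when most links leave the community;
* ``apcc`` -- average Pearson correlation between the node's expression
  profile and its graph neighbours' profiles.

Hubs split by APCC into party (high positive), date (low positive) and
fight-club (negative) classes; the (kpi, zg) plane splits into seven role
regions R1-R7.  Switch genes are the fight-club nodes of region R4:
zg < 2.5, kpi > 0.8, apcc < 0 (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["Thresholds", "within_module_degree_z", "clusterphobic_coefficient",
           "apcc", "classify_nodes", "call_switch_genes", "Bicluster",
           "bicluster_switch", "linkage_to_newick"]


@dataclass(frozen=True)
class Thresholds:
    """Cartography cut-offs; defaults are the standard switch-gene triple."""

    zg: float = 2.5           # local-hub boundary
    kpi: float = 0.8          # mostly-external boundary
    apcc: float = 0.0         # fight-club boundary
    hub_zg: float = 5.0       # network-hub flag
    party_apcc: float = 0.5   # date/party split
    # region boundaries on the kpi axis (Guimera-Amaral style, R4 pinned
    # to the switch cell kpi > 0.8)
    nonhub_kpi: tuple[float, float, float] = (0.05, 0.62, 0.8)
    hub_kpi: tuple[float, float] = (0.30, 0.75)


def within_module_degree_z(G: nx.Graph, cluster_of: pd.Series) -> pd.Series:
    """Zg: z-score of the intra-community degree within each community."""
    _require_assigned(G, cluster_of)
    kappa = pd.Series(
        {n: sum(1 for nb in G.neighbors(n) if cluster_of[nb] == cluster_of[n])
         for n in G.nodes}, dtype=float)
    zg = pd.Series(0.0, index=kappa.index)
    for _, members in kappa.groupby(cluster_of.loc[kappa.index]):
        sd = members.std(ddof=0)
        if sd > 0:
            zg.loc[members.index] = (members - members.mean()) / sd
        # zero-spread community: zg stays 0 by convention
    return zg.rename("zg")


def clusterphobic_coefficient(G: nx.Graph, cluster_of: pd.Series) -> pd.Series:
    """Kpi = 1 - (k_in / k_tot)^2; isolated nodes map to 0 by convention."""
    _require_assigned(G, cluster_of)
    out = {}
    for n in G.nodes:
        k_tot = G.degree(n)
        if k_tot == 0:
            out[n] = 0.0
            continue
        k_in = sum(1 for nb in G.neighbors(n) if cluster_of[nb] == cluster_of[n])
        out[n] = 1.0 - (k_in / k_tot) ** 2
    return pd.Series(out, name="kpi")


def apcc(expr: ExpressionMatrix, G: nx.Graph, *,
         corr: pd.DataFrame | None = None) -> pd.Series:
    """Average Pearson correlation between each node and its neighbours.

    Isolated nodes have no neighbours and get NaN (they are excluded from
    the hub taxonomy).  A precomputed correlation matrix can be passed to
    avoid recomputation.
    """
    if corr is None:
        X = expr.values.loc[list(G.nodes)]
        r = pd.DataFrame(np.corrcoef(X.to_numpy()), index=X.index, columns=X.index)
    else:
        r = corr
    out = {}
    for n in G.nodes:
        nbrs = list(G.neighbors(n))
        out[n] = float(r.loc[n, nbrs].mean()) if nbrs else np.nan
    return pd.Series(out, name="apcc")


def classify_nodes(zg: pd.Series, kpi: pd.Series, apcc_values: pd.Series,
                   cluster_of: pd.Series,
                   thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Assemble the cartography table: coordinates, region, hub class, switch flag."""
    t = thresholds
    nodes = list(zg.index)
    if set(nodes) != set(kpi.index) or set(nodes) != set(apcc_values.index):
        raise ValueError("zg, kpi and apcc must cover the same node set")
    cart = pd.DataFrame({
        "community": cluster_of.loc[nodes],
        "zg": zg.loc[nodes],
        "kpi": kpi.loc[nodes],
        "apcc": apcc_values.loc[nodes],
    })

    def region(row) -> str:
        if row.zg < t.zg:
            lo, mid, hi = t.nonhub_kpi
            if row.kpi < lo:
                return "R1"
            if row.kpi < mid:
                return "R2"
            if row.kpi <= hi:
                return "R3"
            return "R4"
        lo, hi = t.hub_kpi
        if row.kpi < lo:
            return "R5"
        if row.kpi < hi:
            return "R6"
        return "R7"

    def hub_class(a) -> str:
        if np.isnan(a):
            return "none"
        if a < t.apcc:
            return "fight_club"
        if a >= t.party_apcc:
            return "party"
        return "date"

    cart["region"] = cart.apply(region, axis=1)
    cart["hub_class"] = cart["apcc"].map(hub_class)
    cart["is_network_hub"] = cart["zg"] > t.hub_zg
    cart["is_switch"] = ((cart["zg"] < t.zg) & (cart["kpi"] > t.kpi)
                         & (cart["apcc"] < t.apcc))
    boundary = (((cart["zg"] == t.zg) | (cart["kpi"] == t.kpi)
                 | (cart["apcc"] == t.apcc)) & ~cart["is_switch"])
    if boundary.any():
        logger.info("%d node(s) sit exactly on a switch threshold and are excluded",
                    int(boundary.sum()))
    return cart


def call_switch_genes(cartography: pd.DataFrame) -> list[str]:
    """Sorted switch-gene ids; empty is allowed (with a warning)."""
    called = sorted(cartography.index[cartography["is_switch"]])
    if not called:
        logger.warning("no switch genes called")
    return called


def _require_assigned(G: nx.Graph, cluster_of: pd.Series) -> None:
    missing = [n for n in G.nodes if n not in cluster_of.index]
    if missing:
        raise ValueError(f"{len(missing)} node(s) lack a community assignment, "
                         f"e.g. {missing[:3]}")


# ---------------------------------------------------------------------------
# biclustering of switch-gene expression
# ---------------------------------------------------------------------------

@dataclass
class Bicluster:
    """Row/column dendrograms and the doubly reordered expression block."""

    row_order: list[str]
    col_order: list[str]
    linkage_rows: np.ndarray
    linkage_cols: np.ndarray
    matrix: pd.DataFrame


def bicluster_switch(expr: ExpressionMatrix, switch_genes) -> Bicluster:
    """Average-linkage biclustering of the switch-gene expression block.

    Rows (switch genes) use correlation distance 1 - r; columns (samples)
    use Euclidean distance on per-gene z-scored values.  Leaf orders follow
    scipy's left-before-right traversal.
    """
    switch_genes = list(switch_genes)
    if len(switch_genes) < 2:
        raise ValueError("biclustering needs >= 2 switch genes")
    X = expr.values.loc[switch_genes]
    Zrow = linkage(pdist(X.to_numpy(), metric="correlation"), method="average")
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0).replace(0, 1.0)
    Xz = X.sub(mu, axis=0).div(sd, axis=0)
    Zcol = linkage(pdist(Xz.to_numpy().T, metric="euclidean"), method="average")
    rows = [switch_genes[i] for i in leaves_list(Zrow)]
    cols = [X.columns[i] for i in leaves_list(Zcol)]
    return Bicluster(rows, cols, Zrow, Zcol, X.loc[rows, cols])


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick-style nested string."""
    labels = list(labels)
    n = len(labels)

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, height, _ = Z[i - n]
        return f"({node(int(a))},{node(int(b))}):{height:.6g}"

    return node(2 * n - 2) + ";"
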