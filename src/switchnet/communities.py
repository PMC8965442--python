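"""Community detection: k-means on z-scored expression profiles.

Communities are expression-driven, not topology-driven: the nodes of the
co-expression graph are clustered by Lloyd's algorithm on their per-gene
standardized profiles, replicated from distinct seeded initializations, and
the replicate with minimal within-cluster sum of squared errors (SSE) wins.
The number of communities comes from the elbow of the SSE scree curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["CommunityAssignment", "kmeans_profiles", "scree", "choose_k",
           "detect_communities", "zscore_profiles"]


@dataclass
class CommunityAssignment:
    cluster_of: pd.Series            # node -> cluster index in 1..k
    k: int
    sse_table: dict[int, list[float]] = field(default_factory=dict)
    chosen_k_rule: str = "fixed"

    def __post_init__(self) -> None:
        labels = set(self.cluster_of)
        if labels != set(range(1, self.k + 1)):
            raise ValueError(f"clusters must be exactly 1..{self.k}, got {sorted(labels)}")


def zscore_profiles(expr: ExpressionMatrix, nodes) -> pd.DataFrame:
    """Per-gene standardized (population sd) profiles for the given nodes."""
    X = expr.values.loc[list(nodes)]
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.warning("%d flat profile(s) z-scored to zero", int(flat.sum()))
        sd = sd.where(~flat, 1.0)
    return X.sub(mu, axis=0).div(sd, axis=0)


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    # prefix property: the first r seeds are identical for any replicates >= r,
    # so adding replicates can only improve the best-of-replicates SSE
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(replicates)]


def kmeans_profiles(expr: ExpressionMatrix, nodes, k: int, replicates: int = 10,
                    seed: int = 0) -> tuple[pd.Series, list[float]]:
    """Best-of-replicates Lloyd k-means on z-scored profiles.

    Returns the minimal-SSE assignment (labels 1..k) and the per-replicate
    SSE list.  Deterministic given ``seed``; replicate r uses the r-th child
    seed so results are reproducible under partial reruns.
    """
    nodes = list(nodes)
    if not 1 <= k <= len(nodes):
        raise ValueError(f"k must be in [1, {len(nodes)}]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    Z = zscore_profiles(expr, nodes).to_numpy()
    sses: list[float] = []
    best_labels, best_sse = None, np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatters about duplicate points
        for rs in _replicate_seeds(seed, replicates):
            km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                        algorithm="lloyd", random_state=rs).fit(Z)
            sses.append(float(km.inertia_))
            if km.inertia_ < best_sse:
                best_sse, best_labels = float(km.inertia_), km.labels_
    # relabel to 1..k in order of first appearance so output is stable
    order = {old: new for new, old in enumerate(dict.fromkeys(best_labels), start=1)}
    labels = pd.Series([order[l] for l in best_labels], index=nodes, name="cluster")
    return labels, sses


def scree(expr: ExpressionMatrix, nodes, k_range, replicates: int = 10,
          seed: int = 0) -> dict[int, list[float]]:
    """Replicate SSE lists over candidate community counts."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    table: dict[int, list[float]] = {}
    for k in ks:
        _, sses = kmeans_profiles(expr, nodes, k, replicates=replicates, seed=seed)
        table[k] = sses
    return table


def choose_k(sse_table: dict[int, list[float]]) -> int:
    """Elbow of the best-of-replicates SSE curve.

    Returns the interior candidate k maximizing the perpendicular distance to
    the chord joining the curve's endpoints (ties broken toward smaller k).
    A flat curve returns the smallest k with a warning; a perfectly linear
    decline returns the smallest interior k with a warning.
    """
    ks = sorted(sse_table)
    if len(ks) < 3:
        raise ValueError("choose_k needs >= 3 candidate k values")
    best = np.array([min(sse_table[k]) for k in ks], dtype=float)
    if np.allclose(best, best[0]):
        logger.warning("flat SSE curve; returning smallest k=%d", ks[0])
        return ks[0]
    p0 = np.array([ks[0], best[0]])
    p1 = np.array([ks[-1], best[-1]])
    chord = p1 - p0
    chord_len = float(np.hypot(*chord))
    dists = []
    for k, s in zip(ks[1:-1], best[1:-1]):
        v = np.array([k, s]) - p0
        dists.append(abs(chord[0] * v[1] - chord[1] * v[0]) / chord_len)
    dists = np.asarray(dists)
    if np.allclose(dists, 0.0):
        logger.warning("SSE declines linearly; returning smallest interior k=%d", ks[1])
        return ks[1]
    return ks[1:-1][int(np.argmax(dists))]  # argmax takes the first (smallest k) tie


def detect_communities(expr: ExpressionMatrix, nodes, *, k: int | None = None,
                       k_range=range(2, 11), replicates: int = 10,
                       seed: int = 0) -> CommunityAssignment:
    """Scree + elbow (or fixed k) followed by the final best-of-replicates fit."""
    nodes = list(nodes)
    if k is not None:
        labels, sses = kmeans_profiles(expr, nodes, k, replicates=replicates, seed=seed)
        return CommunityAssignment(labels, k, {k: sses}, chosen_k_rule="fixed")
    ks = [kk for kk in k_range if 1 <= kk <= len(nodes)]
    table = scree(expr, nodes, ks, replicates=replicates, seed=seed)
    k_star = choose_k(table)
    labels, _ = kmeans_profiles(expr, nodes, k_star, replicates=replicates, seed=seed)
    return CommunityAssignment(labels, k_star, table, chosen_k_rule="elbow")
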