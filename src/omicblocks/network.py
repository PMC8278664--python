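"""Weighted gene association network and SPICi clustering.

The network combines a protein-protein interaction (PPI) edge list with
co-expression: an edge is kept only when the pair interacts in the PPI list
*and* the absolute Pearson correlation of the two expression profiles
exceeds 0.2 (weaker correlations indicate essentially no linear
association). The edge weight is |r|, so weights lie in (0.2, 1].

Clusters are found with SPICi, a greedy seed-and-expand heuristic for large
weighted biological networks. Two quantities govern it:

* ``support(u, S)``  = sum of edge weights from vertex u into the set S,
* ``density(S)``     = sum of edge weights inside S divided by the number of
  possible edges |S|(|S|-1)/2.

Expansion adds the unclustered neighbour with maximal support, provided the
support stays above a fraction (the minimum support threshold) of the best
within-cluster support and the density stays above the minimum cluster
density. Clusters smaller than the minimum cluster size are discarded;
their vertices stay unassigned. Ties (seed degree, candidate support) break
by lexicographic gene id so a run is fully deterministic.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

#: minimum |Pearson r| for an edge to enter the network
MIN_EDGE_WEIGHT = 0.2


@dataclass(frozen=True)
class SpiciParams:
    """SPICi hyperparameters.

    Defaults are the settings used for the lung adenocarcinoma cohort
    (density 0.1, support 0.4, size 5); the admissible intervals are
    density in [0.1, 0.6], support in [0.4, 0.7], size >= 2.
    """

    min_cluster_density: float = 0.1
    min_support_threshold: float = 0.4
    min_cluster_size: int = 5

    def __post_init__(self) -> None:
        if not 0.1 <= self.min_cluster_density <= 0.6:
            raise ValueError("min_cluster_density must be in [0.1, 0.6]")
        if not 0.4 <= self.min_support_threshold <= 0.7:
            raise ValueError("min_support_threshold must be in [0.4, 0.7]")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


@dataclass(frozen=True)
class GeneCluster:
    """A disjoint gene set emitted by SPICi, with its recorded density."""

    cluster_id: str
    genes: frozenset
    density: float

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


def build_network(
    e: ExpressionMatrix, ppi_edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Build the weighted gene graph from PPI pairs and expression.

    Keeps a PPI pair (u, v) as an edge with weight |pearson r(u, v)| when
    both genes are measured and |r| > 0.2. Pairs with a constant expression
    profile (undefined correlation) are skipped and counted in the log.
    """
    X = e.data
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    genes = set(e.genes)
    pairs = []
    seen = set()
    for u, v in ppi_edges:
        if u == v or u not in genes or v not in genes:
            continue
        key = (u, v) if u <= v else (v, u)
        if key not in seen:
            seen.add(key)
            pairs.append(key)

    # centred, norm-1 columns: pearson r reduces to a dot product
    vals = X.to_numpy(dtype=float)
    vals = vals - vals.mean(axis=0)
    norms = np.linalg.norm(vals, axis=0)
    col = {gname: i for i, gname in enumerate(e.genes)}

    net = nx.Graph()
    n_constant = 0
    for u, v in pairs:
        iu, iv = col[u], col[v]
        if norms[iu] == 0.0 or norms[iv] == 0.0:
            n_constant += 1
            continue
        net.add_node(u)
        net.add_node(v)
        r = float(vals[:, iu] @ vals[:, iv] / (norms[iu] * norms[iv]))
        w = abs(r)
        if w > MIN_EDGE_WEIGHT:
            net.add_edge(u, v, weight=min(w, 1.0))
    if n_constant:
        logger.info("build_network: skipped %d pairs with a constant profile", n_constant)
    logger.info(
        "build_network: %d genes, %d edges from %d PPI pairs",
        net.number_of_nodes(), net.number_of_edges(), len(pairs),
    )
    return net


def support(u: str, S: Iterable[str], net: nx.Graph) -> float:
    """Sum of edge weights from vertex ``u`` into the set ``S``."""
    adj = net.adj.get(u, {})
    return float(sum(adj[v]["weight"] for v in S if v in adj))


def density(S: Iterable[str], net: nx.Graph) -> float:
    """Sum of edge weights inside ``S`` over the |S|(|S|-1)/2 possible edges."""
    members = list(S)
    k = len(members)
    if k < 2:
        raise ValueError("density needs at least 2 vertices")
    total = 0.0
    for a, b in itertools.combinations(members, 2):
        if net.has_edge(a, b):
            total += net.edges[a, b]["weight"]
    return total / (k * (k - 1) / 2.0)


_WEIGHT_BINS = (0.8, 0.6, 0.4, 0.2, 0.0)


def spici_cluster(net: nx.Graph, params: SpiciParams | None = None) -> list[GeneCluster]:
    """Greedy seed-and-expand clustering of a weighted gene graph.

    Repeatedly seeds from the unclustered vertex with the highest weighted
    degree, picks a second seed among its neighbours (highest weight bin,
    then highest weighted degree), then grows the cluster by the neighbour
    with maximal support, requiring

    ``support(t, S) >= threshold * max_{v in S} support(v, S \\ {v})``

    and density(S + t) >= minimum cluster density. Emitted clusters are
    disjoint; vertices in rejected (too small) groups stay unassigned.
    """
    if params is None:
        params = SpiciParams()
    if net.number_of_nodes() == 0:
        return []

    wdeg: dict[str, float] = {
        v: float(sum(d["weight"] for d in net.adj[v].values())) for v in net.nodes
    }
    unclustered = set(net.nodes)
    clusters: list[GeneCluster] = []

    def _remove(members: Iterable[str]) -> None:
        for v in members:
            unclustered.discard(v)
        for v in members:
            for u, d in net.adj[v].items():
                if u in unclustered:
                    wdeg[u] -= d["weight"]

    while unclustered:
        seed = min(unclustered, key=lambda v: (-wdeg[v], v))
        nbrs = [v for v in net.adj[seed] if v in unclustered]
        if not nbrs:
            _remove([seed])
            continue

        def bin_of(v: str) -> int:
            w = net.edges[seed, v]["weight"]
            for i, lo in enumerate(_WEIGHT_BINS):
                if w > lo:
                    return i
            return len(_WEIGHT_BINS) - 1

        second = min(nbrs, key=lambda v: (bin_of(v), -wdeg[v], v))
        members = [seed, second]
        member_set = {seed, second}
        w0 = net.edges[seed, second]["weight"]
        internal = {seed: w0, second: w0}  # support(v, S \ {v})
        weight_sum = w0
        # support of each outside candidate into the growing cluster
        cand: dict[str, float] = {}
        for v in members:
            for u, d in net.adj[v].items():
                if u in unclustered and u not in member_set:
                    cand[u] = cand.get(u, 0.0) + d["weight"]

        while cand:
            best = min(cand, key=lambda v: (-cand[v], v))
            s_best = cand[best]
            scale = max(internal.values())
            k = len(members)
            new_density = (weight_sum + s_best) / ((k + 1) * k / 2.0)
            if s_best < params.min_support_threshold * scale:
                break
            if new_density < params.min_cluster_density:
                break
            # accept
            members.append(best)
            member_set.add(best)
            weight_sum += s_best
            internal[best] = s_best
            del cand[best]
            for u, d in net.adj[best].items():
                if u in member_set:
                    internal[u] += d["weight"]
                elif u in unclustered:
                    cand[u] = cand.get(u, 0.0) + d["weight"]

        _remove(members)
        k = len(members)
        dens = weight_sum / (k * (k - 1) / 2.0)
        if k >= params.min_cluster_size and dens >= params.min_cluster_density:
            clusters.append(
                GeneCluster(f"C{len(clusters) + 1:03d}", frozenset(members), dens)
            )
    logger.info("spici_cluster: %d clusters", len(clusters))
    return clusters


def tune_clustering(
    net: nx.Graph,
    densities: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
    supports: Sequence[float] = (0.4, 0.5, 0.6, 0.7),
    sizes: Sequence[int] = (5,),
    target_n_clusters: tuple[int, int] = (100, 200),
    target_cluster_size: tuple[int, int] = (5, 100),
) -> tuple[SpiciParams, list[GeneCluster]]:
    """Scan the hyperparameter grid (density-major order) and return the first
    combination whose clustering yields ``target_n_clusters`` clusters, each
    within ``target_cluster_size`` genes.

    If no combination qualifies, the one minimizing a distance to the target
    ranges (relative deviation of the cluster count plus the fraction of
    clusters outside the size range) is returned with a warning.
    """
    grid = [
        SpiciParams(d, s, m) for d in densities for s in supports for m in sizes
    ]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    lo_n, hi_n = target_n_clusters
    lo_k, hi_k = target_cluster_size
    best: tuple[float, SpiciParams, list[GeneCluster]] | None = None
    for params in grid:
        clusters = spici_cluster(net, params)
        nc = len(clusters)
        sizes_ok = all(lo_k <= len(c) <= hi_k for c in clusters)
        if lo_n <= nc <= hi_n and sizes_ok and nc > 0:
            return params, clusters
        count_dev = max(0.0, (lo_n - nc) / lo_n, (nc - hi_n) / hi_n)
        frac_bad = (
            sum(1 for c in clusters if not lo_k <= len(c) <= hi_k) / nc if nc else 1.0
        )
        score = count_dev + frac_bad
        if best is None or score < best[0]:
            best = (score, params, clusters)
    assert best is not None
    warnings.warn(
        "tune_clustering: no hyperparameter combination met the target ranges; "
        f"returning the closest (score {best[0]:.3f})",
        stacklevel=2,
    )
    return best[1], best[2]
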