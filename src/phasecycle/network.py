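"""Cluster-membership network across the two transitions.

Every gene belongs to exactly one cluster per transition, so clusters form a
bipartite graph whose edges carry the genes shared between an RB cluster and
a BR cluster: edge weights sum to the size of the gene universe, and no two
clusters of the same transition are ever connected. Edge similarity is the
Jaccard index of the two member sets; the *conserved* sub-network keeps the
edges whose Jaccard index strictly exceeds the 95th percentile of a
size-preserving permutation null (R random reassignments of genes to
clusters of the original sizes, all cluster pairs pooled, zero-overlap pairs
included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # GraphML export convenience
    import networkx as nx
except ImportError:  # pragma: no cover
    nx = None


@dataclass
class Edge:
    a: object                   # cluster label, transition A
    b: object                   # cluster label, transition B
    shared: set
    jaccard: float
    conserved: bool = False
    direction_class: str | None = None   # "same" / "opposite"

    @property
    def weight(self) -> int:
        return len(self.shared)


@dataclass
class ClusterNetwork:
    nodes_a: dict               # label -> gene set
    nodes_b: dict
    edges: list[Edge] = field(default_factory=list)

    @property
    def universe(self) -> set:
        out = set()
        for s in self.nodes_a.values():
            out |= s
        return out

    def total_edge_weight(self) -> int:
        return sum(e.weight for e in self.edges)

    def conserved_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.conserved]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.a, e.b, e.weight, e.jaccard, e.conserved, e.direction_class)
             for e in self.edges],
            columns=["cluster_a", "cluster_b", "weight", "jaccard",
                     "conserved", "direction_class"],
        )

    def to_networkx(self):
        if nx is None:  # pragma: no cover
            raise ImportError("networkx unavailable")
        g = nx.Graph()
        for lab, genes in self.nodes_a.items():
            g.add_node(("A", lab), transition="A", size=len(genes))
        for lab, genes in self.nodes_b.items():
            g.add_node(("B", lab), transition="B", size=len(genes))
        for e in self.edges:
            g.add_edge(("A", e.a), ("B", e.b), weight=e.weight,
                       jaccard=e.jaccard, conserved=e.conserved)
        return g


@dataclass
class NullJaccardDistribution:
    scores: np.ndarray
    n_replicates: int
    threshold: float            # empirical 95th percentile
    seed: int


def jaccard(set_x: set, set_y: set) -> float:
    """|X n Y| / |X u Y|; zero when both sets are empty."""
    union = len(set_x | set_y)
    if union == 0:
        return 0.0
    return len(set_x & set_y) / union


def build_complete_network(partition_a: dict, partition_b: dict) -> ClusterNetwork:
    """Bipartite network of all cluster pairs sharing at least one gene.

    ``partition_a`` / ``partition_b`` map cluster labels to gene sets; both
    must cover the same gene universe.
    """
    ua = set().union(*partition_a.values()) if partition_a else set()
    ub = set().union(*partition_b.values()) if partition_b else set()
    if ua != ub:
        raise ValueError(
            f"partitions cover different universes "
            f"({len(ua)} vs {len(ub)} genes, {len(ua ^ ub)} mismatched)"
        )
    net = ClusterNetwork(dict(partition_a), dict(partition_b))
    for la, ga in partition_a.items():
        for lb, gb in partition_b.items():
            shared = ga & gb
            if shared:
                net.edges.append(Edge(la, lb, shared, jaccard(ga, gb)))
    return net


def null_distribution(sizes_a, sizes_b, universe, n_replicates: int = 1000,
                      seed: int = 0) -> NullJaccardDistribution:
    """Jaccard scores of all cluster pairs under random gene-to-cluster
    assignment with the original cluster sizes, pooled over replicates."""
    sizes_a = np.asarray(sizes_a, int)
    sizes_b = np.asarray(sizes_b, int)
    n = len(set(universe))
    if sizes_a.sum() != n or sizes_b.sum() != n:
        raise ValueError(
            f"cluster sizes must partition the universe "
            f"(sums {sizes_a.sum()}, {sizes_b.sum()} vs {n} genes)"
        )
    rng = np.random.default_rng(seed)
    la = np.repeat(np.arange(len(sizes_a)), sizes_a)
    lb = np.repeat(np.arange(len(sizes_b)), sizes_b)
    ka, kb = len(sizes_a), len(sizes_b)
    denom_base = sizes_a[:, None] + sizes_b[None, :]
    pools = np.empty((n_replicates, ka * kb))
    for r in range(n_replicates):
        pa = la[rng.permutation(n)]
        pb = lb[rng.permutation(n)]
        inter = np.bincount(pa * kb + pb, minlength=ka * kb).reshape(ka, kb)
        pools[r] = (inter / (denom_base - inter)).ravel()
    scores = pools.ravel()
    return NullJaccardDistribution(scores, n_replicates,
                                   float(np.quantile(scores, 0.95)), seed)


def conserved_network(net: ClusterNetwork,
                      null: NullJaccardDistribution) -> ClusterNetwork:
    """Flag as conserved the edges whose Jaccard index strictly exceeds the
    null threshold."""
    for e in net.edges:
        e.conserved = e.jaccard > null.threshold
    return net


def edge_direction_classes(net: ClusterNetwork, mcv_a: dict, mcv_b: dict) -> ClusterNetwork:
    """Classify every edge as linking clusters with the same or opposite MCV
    direction of expression change."""
    for e in net.edges:
        if e.a not in mcv_a or e.b not in mcv_b:
            raise ValueError(f"missing MCV for edge ({e.a!r}, {e.b!r})")
        e.direction_class = ("opposite"
                             if mcv_a[e.a].direction != mcv_b[e.b].direction
                             else "same")
    return net


def compare_direction_proportions(net: ClusterNetwork) -> dict:
    """Opposite-direction edge proportions in the conserved sub-network vs
    the rest of the complete network, with a 2 x 2 Pearson chi-square test
    (no continuity correction; disjoint edge sets keep the table independent)."""
    cons = [e for e in net.edges if e.conserved]
    rest = [e for e in net.edges if not e.conserved]
    if not net.edges:
        raise ValueError("empty network")
    if not cons or not rest:
        raise ValueError("need both conserved and non-conserved edges to compare")

    def split(edges):
        opp = sum(e.direction_class == "opposite" for e in edges)
        return opp, len(edges) - opp

    o1, s1 = split(cons)
    o2, s2 = split(rest)
    table = np.array([[o1, s1], [o2, s2]], float)
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (exp == 0).any():
        stat, p = 0.0, 1.0
    else:
        from scipy.stats import chi2 as chi2_dist
        stat = float(((table - exp) ** 2 / exp).sum())
        p = float(chi2_dist.sf(stat, 1))
    prop_cons = 100.0 * o1 / len(cons)
    prop_all = 100.0 * (o1 + o2) / len(net.edges)
    return {
        "prop_opposite_conserved": round(prop_cons, 1),
        "prop_opposite_complete": round(prop_all, 1),
        "table": table,
        "chi2": stat,
        "df": 1,
        "pvalue": p,
    }
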