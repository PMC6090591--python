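"""High-level drivers composing the pipeline stages: DE testing on a
synthetic or supplied experiment, per-transition trajectory clustering with
DEG-enrichment, interval timing comparison, and the conserved cluster
network. These are the entry points the analysis scripts call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from . import de
from .clustering import (
    ClusterAssignment,
    bic_scan,
    choose_lambda,
    cluster_mcvs,
    fit_pspline_mixture,
    interval_gene_counts,
    select_k,
)
from .enrichment import enrich_all_clusters
from .io import CountMatrix, SampleMetadata
from .network import (
    build_complete_network,
    conserved_network,
    edge_direction_classes,
    null_distribution,
)


@dataclass
class TransitionClustering:
    transition: str
    assignment: ClusterAssignment
    mcvs: dict
    enriched_clusters: set
    interval_counts: pd.Series
    k_selected: int
    bic_table: pd.DataFrame


def interaction_degs(counts: CountMatrix, meta: SampleMetadata,
                     alpha: float = 0.05) -> tuple[set, pd.DataFrame]:
    """Genes with a significant time-by-transition interaction (BH < alpha)."""
    res = de.lrt_contrast(counts, meta, "interaction")
    return set(res.loc[res["padj"] < alpha, "gene_id"]), res


def cluster_transition(vst_matrix: pd.DataFrame, meta: SampleMetadata,
                       transition: str, degs: set, k_values=None,
                       seed: int = 0, alpha: float = 0.05) -> TransitionClustering:
    """Cluster one transition's trajectories (BIC-selected K), flag clusters
    enriched for DEGs, and count genes per maximal-change interval."""
    traj = de.transition_trajectories(vst_matrix, meta, transition)
    if k_values is None:
        k_values = range(2, min(21, len(traj)), 2)
    lam = choose_lambda(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # overparameterized K may fail; scan continues
        tab = bic_scan(traj, k_values, lam=lam, seed=seed)
    k_star = select_k(tab)
    fit = fit_pspline_mixture(traj, k_star, lam=lam, seed=seed)
    assignment = ClusterAssignment.from_mixture(fit, traj.index)
    enr = enrich_all_clusters(assignment.partition(), degs, set(traj.index),
                              alpha=alpha)
    enriched = set(enr.loc[enr["enriched"], "cluster"])
    mcvs = cluster_mcvs(assignment)
    counts = interval_gene_counts(assignment, mcvs, enriched)
    return TransitionClustering(transition, assignment, mcvs, enriched,
                                counts, k_star, tab)


def conserved_cluster_network(rb: TransitionClustering, br: TransitionClustering,
                              n_permutations: int = 1000, seed: int = 0):
    """Complete bipartite cluster network, permutation null, conserved flags
    and direction classes."""
    pa = rb.assignment.partition()
    pb = br.assignment.partition()
    net = build_complete_network(pa, pb)
    null = null_distribution([len(s) for s in pa.values()],
                             [len(s) for s in pb.values()],
                             net.universe, n_permutations, seed)
    net = conserved_network(net, null)
    net = edge_direction_classes(net, rb.mcvs, br.mcvs)
    return net, null
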