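"""Sample-level structure: the twofold-change outlier screen with its
sensitivity/specificity accounting, and ordination (PCA, k-means, Euclidean
distances with average-linkage dendrogram) of time-point mean profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import SampleMetadata


@dataclass
class FoldChangeScreen:
    """Genes whose max/min group-mean ratio (linear scale) reaches a threshold."""

    ratios: pd.Series          # per-gene max/min group-mean ratio
    threshold: float

    @property
    def gene_set(self) -> set[str]:
        return set(self.ratios.index[self.ratios >= self.threshold])


@dataclass
class OutlierImpact:
    n_lost_overall: int
    n_candidate_early_genes: int
    n_candidates_lost: int
    percent_lost: float


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame      # group x principal axes
    percent_variance: np.ndarray
    kmeans_labels: pd.Series
    distances: pd.DataFrame        # symmetric, zero diagonal
    linkage: np.ndarray            # scipy average-linkage matrix

    def nearest(self, group: str) -> str:
        d = self.distances.loc[group].drop(group)
        return d.idxmin()

    def newick(self) -> str:
        names = list(self.distances.index)
        tree = to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return names[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(tree).rsplit(":", 1)[0] + ";"


def group_means(vst_matrix: pd.DataFrame, meta: SampleMetadata,
                samples=None) -> pd.DataFrame:
    """Mean VST expression per (transition, time) group; genes x groups."""
    ids = list(samples) if samples is not None else list(vst_matrix.columns)
    t = meta.table.loc[ids]
    out = {}
    for (tr, tp), sub in t.groupby(["transition", "time_h"], sort=True):
        out[f"{tr}_{int(tp)}h"] = vst_matrix[list(sub.index)].mean(axis=1)
    return pd.DataFrame(out)


def fold_change_screen(vst_matrix: pd.DataFrame, meta: SampleMetadata,
                       threshold: float = 2.0, samples=None) -> FoldChangeScreen:
    """Flag genes with >= ``threshold``-fold change between any two
    (transition, time) group means, ratios taken on the de-transformed scale
    (2**VST, which carries the +1 offset of the transform)."""
    if threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    gm = group_means(vst_matrix, meta, samples)
    ratios = np.exp2(gm.max(axis=1) - gm.min(axis=1))
    return FoldChangeScreen(ratios, threshold)


def outlier_impact(screen_all: FoldChangeScreen, screen_no6h: FoldChangeScreen,
                   early_candidates: set) -> OutlierImpact:
    """Cost of dropping the 6-h samples: how many of the candidate
    early-responding genes are no longer flagged by the screen without 6 h."""
    kept = screen_no6h.gene_set
    lost_overall = len(screen_all.gene_set - kept)
    candidates = set(early_candidates)
    lost = candidates - kept
    if not candidates:
        warnings.warn("empty early-candidate set; percent lost reported as 0")
        percent = 0.0
    else:
        percent = round(100.0 * len(lost) / len(candidates), 1)
    return OutlierImpact(lost_overall, len(candidates), len(lost), percent)


def ordinate(vst_matrix: pd.DataFrame, meta: SampleMetadata, k: int = 3,
             gene_set=None, seed: int = 0, n_restarts: int = 50) -> OrdinationResult:
    """PCA, k-means and Euclidean-distance summaries of the centered
    time-point mean profiles (one profile per transition x time group)."""
    if gene_set is not None:
        vst_matrix = vst_matrix.loc[sorted(set(gene_set) & set(vst_matrix.index))]
    gm = group_means(vst_matrix, meta)          # genes x groups
    profiles = gm.T                             # groups x genes
    if k > profiles.shape[0]:
        raise ValueError(f"k = {k} exceeds the {profiles.shape[0]} groups")

    X = profiles.to_numpy() - profiles.to_numpy().mean(axis=0, keepdims=True)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    pct = 100.0 * pca.explained_variance_ratio_

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)

    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    dist = pd.DataFrame(D, index=profiles.index, columns=profiles.index)
    Z = average(squareform(D, checks=False))
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=profiles.index,
                                 columns=[f"PC{i+1}" for i in range(coords.shape[1])]),
        percent_variance=pct,
        kmeans_labels=pd.Series(labels, index=profiles.index, name="kmeans"),
        distances=dist,
        linkage=Z,
    )
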