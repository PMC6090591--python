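"""Cluster enrichment for gene sets (DEGs, GO terms, TFBS-bearing genes) by
one-sided Fisher's exact test with Benjamini-Hochberg adjustment, and
log-odds PWM scanning of promoter sequences at a relative-score threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import AnnotationTable, PositionWeightMatrix


@dataclass
class EnrichmentResult:
    cluster: object
    gene_set: str
    table: tuple                # (in&set, in-not-set, out&set, out-not-set)
    odds_ratio: float
    pvalue: float
    padj: float | None = None


@dataclass(frozen=True)
class TFBSHit:
    gene_id: str
    motif: str
    position: int               # forward-strand coordinate of window start
    strand: str                 # "+" or "-"
    relative_score: float


def fisher_enrichment(cluster: set, target: set, universe: set,
                      cluster_id="cluster", set_id="set") -> EnrichmentResult:
    """One-sided (enrichment) Fisher test of a cluster against a gene set.

    The p-value is the hypergeometric upper tail P(X >= overlap). The odds
    ratio gets a 0.5 continuity correction for reporting when a cell is zero
    (the p-value is unaffected).
    """
    universe = set(universe)
    cluster = set(cluster)
    target = set(target)
    if not cluster <= universe or not target <= universe:
        raise ValueError("cluster and target must be subsets of the universe")
    N, n, K = len(universe), len(cluster), len(target)
    k = len(cluster & target)
    p = float(hypergeom.sf(k - 1, N, K, n))
    a, b_, c, d = k, n - k, K - k, N - n - K + k
    if min(a, b_, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b_, c, d
    return EnrichmentResult(cluster_id, set_id, (a, b_, c, d),
                            float(oa * od / (ob * oc)), p)


def enrich_all_clusters(partition: dict, gene_sets, universe: set,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Test every (cluster, gene set) pair; BH adjustment within the family
    of all tests for this annotation source; enriched iff padj < alpha.

    ``gene_sets`` is a mapping name -> gene set, an :class:`AnnotationTable`
    (one set per term), or a single gene set (treated as a one-member family,
    e.g. the DEG list).
    """
    if isinstance(gene_sets, AnnotationTable):
        sets = {t: gene_sets.genes_with_term(t) for t in sorted(gene_sets.all_terms())}
    elif isinstance(gene_sets, (set, frozenset, list)):
        sets = {"set": set(gene_sets)}
    else:
        sets = dict(gene_sets)
    results = []
    for name, genes in sets.items():
        genes = set(genes) & set(universe)
        if not genes:
            warnings.warn(f"gene set {name!r} empty in universe; skipped")
            continue
        for lab, members in partition.items():
            results.append(fisher_enrichment(members, genes, universe, lab, name))
    df = pd.DataFrame(
        [(r.cluster, r.gene_set, *r.table, r.odds_ratio, r.pvalue) for r in results],
        columns=["cluster", "gene_set", "k", "cluster_only", "set_only",
                 "neither", "odds_ratio", "pvalue"],
    )
    df["padj"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    df["enriched"] = df["padj"] < alpha if len(df) else []
    return df


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid DNA character {exc.args[0]!r}") from None


def _window_scores(code: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Sum of per-position log-odds over each window; N contributes 0."""
    L = logodds.shape[1]
    n_win = len(code) - L + 1
    scores = np.zeros(n_win)
    padded = np.vstack([logodds, np.zeros(L)])  # row 4 = N, background score
    for j in range(L):
        scores += padded[code[j:j + n_win], j]
    return scores


def scan_pwm(sequence: str, pwm: PositionWeightMatrix, threshold: float = 0.95,
             gene_id: str = "seq", background: float = 0.25) -> list[TFBSHit]:
    """Scan both strands with log-odds scores against a uniform background.

    The relative score of a window is (score - min) / (max - min), where min
    and max are the extreme achievable log-odds sums of the motif; windows at
    or above ``threshold`` are reported. Positions are forward-strand
    coordinates of the window start; 'N' bases score as background.
    """
    code = _encode(sequence)
    L = pwm.length
    if len(code) < L:
        raise ValueError(f"sequence shorter ({len(code)}) than motif ({L})")
    logodds = np.log(pwm.probabilities / background)
    smin = logodds.min(axis=0).sum()
    smax = logodds.max(axis=0).sum()
    span = smax - smin if smax > smin else 1.0
    # reverse strand == forward scan with the reverse-complemented motif
    rc_logodds = logodds[_COMPLEMENT[:4]][:, ::-1]
    hits = []
    for strand, lo in (("+", logodds), ("-", rc_logodds)):
        rel = (_window_scores(code, lo) - smin) / span
        for pos in np.flatnonzero(rel >= threshold):
            hits.append(TFBSHit(gene_id, pwm.name, int(pos), strand,
                                float(rel[pos])))
    return sorted(hits, key=lambda h: (h.position, h.strand))


def genes_with_site(promoters: dict, pwm: PositionWeightMatrix,
                    threshold: float = 0.95) -> set:
    """Genes whose promoter has at least one PWM hit at the threshold."""
    return {g for g, seq in promoters.items()
            if scan_pwm(seq, pwm, threshold, gene_id=g)}
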