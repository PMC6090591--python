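"""Cluster-membership network across the two transitions: complete bipartite
network, 1000-permutation Jaccard null, conserved sub-network, and the
comparison of opposite-direction edge proportions."""

import pandas as pd

from _common import RESULTS, SEED, ensure_dirs, load_experiment
from phasecycle.de import estimate_size_factors, vst
from phasecycle.network import compare_direction_proportions
from phasecycle.pipeline import cluster_transition, conserved_cluster_network


def main():
    ensure_dirs()
    cm, meta = load_experiment()
    degs = set(pd.read_csv(RESULTS / "interaction_degs.txt", header=None)[0])
    v = vst(cm, estimate_size_factors(cm))

    rb = cluster_transition(v, meta, "RB", degs, seed=SEED)
    br = cluster_transition(v, meta, "BR", degs, seed=SEED)
    net, null = conserved_cluster_network(rb, br, n_permutations=1000, seed=SEED)

    edges = net.to_frame()
    edges.to_csv(RESULTS / "cluster_network_edges.tsv", sep="\t", index=False)
    n_cons = int(edges["conserved"].sum())
    print(f"complete network: {len(edges)} edges over "
          f"{rb.k_selected} RB x {br.k_selected} BR clusters; "
          f"null 95th percentile Jaccard = {null.threshold:.3f}; "
          f"{n_cons} conserved edges")

    try:
        out = compare_direction_proportions(net)
        print(f"opposite-direction edges: {out['prop_opposite_conserved']}% of "
              f"conserved vs {out['prop_opposite_complete']}% of all edges "
              f"(chi2 = {out['chi2']:.1f}, p = {out['pvalue']:.3g})")
        pd.Series({k: v for k, v in out.items() if k != "table"}).to_csv(
            RESULTS / "network_direction_summary.tsv", sep="\t", header=False)
    except ValueError as exc:
        print(f"direction comparison unavailable: {exc}")


if __name__ == "__main__":
    main()
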