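"""Ordination of time-point mean expression over the interaction DEGs:
PCA with k-means groups, Euclidean distances, and the average-linkage
dendrogram — the sample-structure view of the two transitions."""

import pandas as pd

from _common import RESULTS, ensure_dirs, load_experiment
from phasecycle.de import estimate_size_factors, vst
from phasecycle.samples import ordinate


def main():
    ensure_dirs()
    cm, meta = load_experiment()
    degs = set(pd.read_csv(RESULTS / "interaction_degs.txt", header=None)[0])
    v = vst(cm, estimate_size_factors(cm))
    o = ordinate(v, meta, k=3, gene_set=degs, seed=1)

    o.coordinates.round(4).to_csv(RESULTS / "ordination_coords.tsv", sep="\t")
    o.distances.round(4).to_csv(RESULTS / "ordination_distances.tsv", sep="\t")
    (RESULTS / "ordination_dendrogram.nwk").write_text(o.newick() + "\n")

    print("variance explained (%):",
          [round(x, 1) for x in o.percent_variance[:3]])
    print("k-means groups:")
    print(o.kmeans_labels.to_string())
    print("\nnearest control per time-point group:")
    for g in o.distances.index:
        if g.endswith("_0h"):
            continue
        d_rb = o.distances.loc[g, "RB_0h"]
        d_br = o.distances.loc[g, "BR_0h"]
        nearer = "RB_0h (reproductive)" if d_rb < d_br else "BR_0h (brood care)"
        print(f"  {g}: {nearer}  (RB_0h {d_rb:.2f} vs BR_0h {d_br:.2f})")


if __name__ == "__main__":
    main()
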