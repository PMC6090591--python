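"""Generate the synthetic brood-swap experiment used by the later drivers.

Emulates the study design: two transitions (RB and BR), controls coded time
0 with 4 replicates, 8 replicates at 12/24/48/96 h, colony batch effects,
negative binomial counts with planted interaction DEGs (10% of genes, 4-fold
phase effect) and a shared manipulation response, plus ovary scores.
Writes counts, metadata and ground truth under results/data/.
"""

import json

import numpy as np

from _common import DATA, SEED, ensure_dirs
from phasecycle.io import RunLog, write_count_matrix, write_metadata
from phasecycle.simulate import (
    SimulationSpec,
    simulate_experiment,
    simulate_ovary_scores,
)


def main():
    ensure_dirs()
    spec = SimulationSpec(n_genes=2000, seed=SEED)
    cm, meta, truth = simulate_experiment(spec)
    meta.table["ovary_score"] = simulate_ovary_scores(truth, noise_sd=0.3,
                                                      seed=SEED).round(2)
    write_count_matrix(cm, DATA / "counts.tsv")
    write_metadata(meta, DATA / "metadata.tsv")
    truth_out = {
        "interaction_degs": [g for g, f in zip(truth.gene_ids,
                                               truth.interaction_deg) if f],
        "cluster_rb": {g: str(c) for g, c in zip(truth.gene_ids, truth.cluster_rb)},
        "cluster_br": {g: str(c) for g, c in zip(truth.gene_ids, truth.cluster_br)},
        "phase_position": truth.phase_position.round(4).to_dict(),
    }
    (DATA / "ground_truth.json").write_text(json.dumps(truth_out, indent=1))
    RunLog(DATA).record("simulate", seed=SEED, n_genes=spec.n_genes,
                        n_samples=cm.shape[1])
    n_deg = int(truth.interaction_deg.sum())
    print(f"wrote {cm.shape[0]} genes x {cm.shape[1]} samples "
          f"({n_deg} planted interaction DEGs) to {DATA}")
    print(f"median library size: {np.median(cm.counts.sum(axis=0)):.0f} counts")


if __name__ == "__main__":
    main()
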