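"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

import numpy as np

from phasecycle.io import read_count_matrix, read_metadata

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

SEED = 1


def ensure_dirs():
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def load_experiment():
    counts_path = DATA / "counts.tsv"
    if not counts_path.exists():
        raise SystemExit("run analysis/01_simulate_experiment.py first")
    cm = read_count_matrix(counts_path)
    meta = read_metadata(DATA / "metadata.tsv", cm)
    return cm, meta


def forkhead_like_pfm() -> np.ndarray:
    """Synthetic forkhead-family PFM (consensus TGTTTAC); stands in for a
    database motif so the promoter-scanning stage runs offline."""
    consensus = "TGTTTAC"
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 17.0
    return counts
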