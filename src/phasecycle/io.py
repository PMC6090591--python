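"""Readers, writers and validated containers for the pipeline's external formats.

Counts and sample metadata travel as TSV, motifs as JASPAR PFM text,
promoter sequences as FASTA, gene annotations as a two-column TSV.
Every reader validates on entry so that downstream modules can assume
well-formed objects.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED_TIMES = (0, 6, 12, 24, 48, 96)
TRANSITIONS = ("RB", "BR")


class FormatError(ValueError):
    """Malformed input file or inconsistent identifiers."""


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with opaque string identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {name} ids: {dupes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        keep = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in keep]
        return CountMatrix(list(self.gene_ids), keep, self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample design information bound to a :class:`CountMatrix`.

    ``transition`` is RB (reproduction -> brood care) or BR (brood care ->
    reproduction); controls are coded ``time_h = 0`` within their own
    transition. ``ovary_score`` is the mean ovary-activation score on the
    ordinal 0-4 scale (0 = no activation, 4 = fully developed eggs).
    """

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("transition", "time_h", "colony_id")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing_cols = [c for c in self.REQUIRED if c not in t.columns]
        if missing_cols:
            raise FormatError(f"metadata missing required columns: {missing_cols}")
        bad_tr = set(t["transition"]) - set(TRANSITIONS)
        if bad_tr:
            raise FormatError(f"unknown transition labels: {sorted(bad_tr)}")
        bad_t = set(t["time_h"]) - set(ALLOWED_TIMES)
        if bad_t:
            raise FormatError(
                f"time_h values {sorted(bad_t)} outside allowed set {ALLOWED_TIMES}"
            )
        if "ovary_score" in t.columns:
            s = t["ovary_score"].dropna()
            if ((s < 0) | (s > 4)).any():
                raise FormatError("ovary_score outside [0, 4]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def validate_against(self, counts: CountMatrix) -> None:
        missing = [s for s in counts.sample_ids if s not in self.table.index]
        if missing:
            raise FormatError(f"samples in counts missing from metadata: {missing}")

    def samples_for(self, transition: str) -> list[str]:
        """Samples of one transition, controls (time 0) included."""
        t = self.table
        return list(t.index[t["transition"] == transition])


@dataclass
class PositionWeightMatrix:
    """Column-stochastic 4 x L motif model over the DNA alphabet A, C, G, T."""

    name: str
    probabilities: np.ndarray  # (4, L)
    pseudocount: float = 0.8

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4 or p.shape[1] < 1:
            raise FormatError(f"PWM must be 4 x L with L >= 1, got {p.shape}")
        if (p <= 0).any():
            raise FormatError(
                f"PWM {self.name!r} has zero/negative probabilities; "
                "use a positive pseudocount"
            )
        sums = p.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise FormatError(f"PWM {self.name!r} columns do not sum to 1: {sums}")
        self.probabilities = p

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.probabilities.argmax(axis=0))


@dataclass
class AnnotationTable:
    """gene_id -> set of term ids (GO or any other gene-set labels)."""

    terms: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.universe:
            unknown = set(self.terms) - self.universe
            if unknown:
                raise FormatError(
                    f"annotated genes absent from universe: {sorted(unknown)[:5]}..."
                )

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.terms.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out


# ---------------------------------------------------------------------------
# count matrix / metadata TSV
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a genes-in-rows TSV count table (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {raw!r} at gene {genes[i]!r}, sample {samples[j]!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"negative count {v} at gene {genes[i]!r}, sample {samples[j]!r}"
                )
            counts[i, j] = v
    return CountMatrix(genes, samples, counts)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path, counts: CountMatrix | None = None) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "colony_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata must have a sample_id column")
    df = df.set_index("sample_id")
    meta = SampleMetadata(df)
    if counts is not None:
        meta.validate_against(counts)
    return meta


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

def read_jaspar_pwm(path: str | Path, pseudocount: float = 0.8) -> PositionWeightMatrix:
    """Read a JASPAR-style PFM (``>name`` header then A/C/G/T count rows).

    Counts get a uniform ``pseudocount`` before column-wise normalisation;
    a pseudocount of 0 with a zero count column entry is rejected because the
    log-odds scanner needs strictly positive probabilities.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    name = "motif"
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].split()[0]
        lines = lines[1:]
    rows = {}
    for ln in lines:
        base = ln[0].upper()
        if base not in "ACGT":
            raise FormatError(f"unexpected PFM row start: {ln[:10]!r}")
        body = ln[1:].strip().strip("[]").replace("[", " ").replace("]", " ")
        rows[base] = [float(x) for x in body.split()]
    if set(rows) != set("ACGT"):
        raise FormatError(f"PFM must have A, C, G, T rows; got {sorted(rows)}")
    lens = {len(v) for v in rows.values()}
    if len(lens) != 1:
        raise FormatError(f"PFM rows of unequal length: {sorted(lens)}")
    counts = np.array([rows[b] for b in "ACGT"], dtype=float)
    if (counts < 0).any():
        raise FormatError("negative PFM counts")
    counts = counts + pseudocount
    colsum = counts.sum(axis=0)
    if (colsum <= 0).any():
        raise FormatError("PFM column with zero total and zero pseudocount")
    probs = counts / colsum
    return PositionWeightMatrix(name, probs, pseudocount)


def write_jaspar(counts: np.ndarray, name: str, path: str | Path) -> None:
    """Write raw PFM counts in JASPAR bracketed text form."""
    counts = np.asarray(counts)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate("ACGT"):
            vals = " ".join(f"{v:g}" for v in counts[i])
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA / annotations / config / run log
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_annotations(path: str | Path, universe: set[str] | None = None) -> AnnotationTable:
    """Two-column TSV (gene_id, term_id), one association per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    terms: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        terms.setdefault(g, set()).add(t)
    return AnnotationTable(terms, universe or set())


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


class RunLog:
    """Append-only JSON-lines log of parameters and seeds for a run directory."""

    def __init__(self, run_dir: str | Path):
        self.path = Path(run_dir) / "run_log.jsonl"
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, event: str, **params) -> None:
        entry = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event, **params}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")
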