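"""Synthetic brood-swap time courses with known ground truth.

The generator emulates the brood-swap design: two induced transitions
(RB: reproduction -> brood care, after larvae are added; BR: brood care ->
reproduction, after larvae are removed), each with its own control colonies
coded as time 0 and eight replicate colonies at 12, 24, 48 and 96 h
(four replicates for controls), with colony batch effects and negative
binomial counts.

Genes respond through a latent *phase position* p(t) in [0, 1]
(1 = reproductive state, 0 = brood-care state). The RB transition starts at
p = 1 and decays to 0 with most of its movement in the first intervals; the
BR transition starts at p = 0 and rises to 1 with most of its movement in
the 48 -> 96 h interval (``timing_asymmetry``). Phase-responsive genes carry
a log2 phase effect rho, so their trajectories differ between transitions
(planted time-by-transition interaction DEGs), while shared-response genes
follow one disturbance bump in both transitions (time effects without
interaction). Trajectories are piecewise linear between the design times,
so maximum-change-vector logic recovers them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, PositionWeightMatrix, SampleMetadata

DESIGN_TIMES = (0, 12, 24, 48, 96)

# Base phase paths evaluated at the design times. Interior values are scaled
# per cluster (factor in [0.7, 1.3]), which preserves the early/late location
# of the largest change.
_RB_PATH_ASYM = np.array([1.0, 0.70, 0.30, 0.15, 0.0])
_BR_PATH_ASYM = np.array([0.0, 0.02, 0.05, 0.20, 1.0])
_RB_PATH_SYM = np.array([1.0, 0.75, 0.50, 0.25, 0.0])
_BR_PATH_SYM = np.array([0.0, 0.25, 0.50, 0.75, 1.0])

# Shared (manipulation-response) bump, identical in both transitions.
_SHARED_BUMP = np.array([0.0, 1.0, 0.6, 0.2, 0.0])


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic experiment."""

    n_genes: int = 2000
    n_clusters_per_transition: int = 10
    time_points: tuple = DESIGN_TIMES
    n_control_reps: int = 4
    n_reps_per_timepoint: int = 8
    n_colonies: int = 8
    nb_dispersion: tuple = (0.05, 0.5)
    colony_effect_sd: float = 0.2   # natural-log scale, multiplicative mean 1
    libsize_sd: float = 0.15        # natural-log scale sample depth variation
    frac_interaction_degs: float = 0.1
    frac_shared_response: float = 0.1
    effect_size_log2: float = 2.0
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    timing_asymmetry: bool = True
    include_6h: bool = False
    frac_disturbance_genes: float = 0.05
    disturbance_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(self.time_points)
        if tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing from 0")
        for name in ("n_genes", "n_clusters_per_transition", "n_control_reps",
                     "n_reps_per_timepoint", "n_colonies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_interaction_degs", "frac_shared_response",
                     "frac_disturbance_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.nb_dispersion
        if lo <= 0 or hi < lo:
            raise ValueError("nb_dispersion must be a positive (low, high) range")


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages against the truth."""

    gene_ids: list[str]
    cluster_rb: np.ndarray          # per-gene label, RB transition
    cluster_br: np.ndarray          # per-gene label, BR transition
    interaction_deg: np.ndarray     # bool per gene
    time_deg: np.ndarray            # bool per gene: any time effect in either transition
    trajectories: dict              # transition -> genes x times log2 mean (sf = 1)
    phase_position: pd.Series       # per sample, in [0, 1]; 1 = reproductive
    times: tuple = DESIGN_TIMES
    site_genes: set = field(default_factory=set)

    def labels_for(self, transition: str) -> np.ndarray:
        return self.cluster_rb if transition == "RB" else self.cluster_br


def _interp_path(path_at_design: np.ndarray, times) -> np.ndarray:
    return np.interp(np.asarray(times, float), np.asarray(DESIGN_TIMES, float),
                     path_at_design)


def _variant_scales(n_variants: int) -> np.ndarray:
    """Interior-path scale factors for the timing variants of one transition."""
    return np.linspace(0.7, 1.3, n_variants) if n_variants > 1 else np.array([1.0])


def _phase_paths(spec: SimulationSpec):
    if spec.timing_asymmetry:
        return _RB_PATH_ASYM, _BR_PATH_ASYM
    return _RB_PATH_SYM, _BR_PATH_SYM


def simulate_experiment(spec: SimulationSpec) -> tuple[CountMatrix, SampleMetadata, GroundTruth]:
    """Draw counts, metadata and ground truth for one synthetic brood swap."""
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]

    times = list(spec.time_points)
    if spec.include_6h and 6 not in times:
        times = sorted(times + [6])
    nonzero = [t for t in times if t > 0]

    # ---- samples ---------------------------------------------------------
    sample_ids, rows = [], []
    for transition in ("RB", "BR"):
        groups = [(0, spec.n_control_reps)] + [(t, spec.n_reps_per_timepoint)
                                               for t in nonzero]
        counter = 0
        for t, nrep in groups:
            for r in range(nrep):
                sid = f"{transition}_t{t:02d}_r{r}"
                colony = f"c{counter % spec.n_colonies}"
                counter += 1
                sample_ids.append(sid)
                rows.append((sid, transition, t, colony))
    meta = pd.DataFrame(rows, columns=["sample_id", "transition", "time_h",
                                       "colony_id"]).set_index("sample_id")

    # ---- gene roles ------------------------------------------------------
    n_int = int(round(spec.frac_interaction_degs * G))
    n_shared = int(round(spec.frac_shared_response * G))
    roles = np.array(["flat"] * G, dtype=object)
    perm = rng.permutation(G)
    roles[perm[:n_int]] = "phase"
    roles[perm[n_int:n_int + n_shared]] = "shared"

    base2 = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, G)
    base2 = np.clip(base2, 1.0, None)
    alpha = rng.uniform(*spec.nb_dispersion, G)

    # phase clusters: timing variant x sign of the gene-level phase effect
    n_var = max(1, spec.n_clusters_per_transition // 2)
    scale = _variant_scales(n_var)
    rb_base, br_base = _phase_paths(spec)

    def variant_paths(base_path):
        paths = np.tile(base_path, (n_var, 1))
        paths[:, 1:-1] = np.clip(base_path[1:-1][None, :] * scale[:, None], 0.0, 1.0)
        return paths  # n_var x 5 at DESIGN_TIMES

    rb_paths, br_paths = variant_paths(rb_base), variant_paths(br_base)

    # gene-level phase effect: the reproductive state differs from the
    # brood-care state by exactly +-effect_size_log2 for phase genes
    is_phase = roles == "phase"
    is_shared = roles == "shared"
    rho = np.zeros(G)
    gene_sign = np.where(rng.random(G) < 0.5, 1.0, -1.0)
    rho[is_phase] = gene_sign[is_phase] * spec.effect_size_log2

    # timing variant drawn independently per transition
    k_rb = rng.integers(0, n_var, is_phase.sum())
    k_br = rng.integers(0, n_var, is_phase.sum())
    cluster_rb = np.full(G, "flat", dtype=object)
    cluster_br = np.full(G, "flat", dtype=object)
    sign_tag = np.where(gene_sign > 0, "+", "-")
    cluster_rb[is_phase] = [f"rb{k}{s}" for k, s in zip(k_rb, sign_tag[is_phase])]
    cluster_br[is_phase] = [f"br{k}{s}" for k, s in zip(k_br, sign_tag[is_phase])]
    cluster_rb[is_shared] = "shared"
    cluster_br[is_shared] = "shared"

    # ---- true log2 trajectories at the sampled times ---------------------
    t_arr = np.array(times, float)
    dev = {"RB": np.zeros((G, len(times))), "BR": np.zeros((G, len(times)))}
    shared_bump = _interp_path(_SHARED_BUMP, t_arr)
    for transition, paths in (("RB", rb_paths), ("BR", br_paths)):
        ks = k_rb if transition == "RB" else k_br
        p_at = np.vstack([_interp_path(paths[k], t_arr) for k in range(n_var)])
        idx = np.flatnonzero(is_phase)
        for j, g in enumerate(idx):
            # absolute phase-state expression: the reproductive state sits
            # rho log2 units above the brood-care state, so the two phase
            # controls differ for phase genes
            dev[transition][g] = rho[g] * p_at[ks[j]]
        dev[transition][is_shared] = (
            gene_sign[is_shared, None] * 0.5 * spec.effect_size_log2
            * shared_bump[None, :]
        )

    # experimental-disturbance shock confined to the 6-h samples
    disturbance = np.zeros(G, dtype=bool)
    if spec.include_6h:
        n_dist = int(round(spec.frac_disturbance_genes * G))
        disturbance[rng.permutation(G)[:n_dist]] = True
        j6 = times.index(6)
        for transition in ("RB", "BR"):
            dev[transition][disturbance, j6] += spec.disturbance_log2

    # ---- nuisance structure and counts -----------------------------------
    colony_ids = sorted(meta["colony_id"].unique())
    colony_ln = rng.normal(-spec.colony_effect_sd ** 2 / 2, spec.colony_effect_sd,
                           (G, len(colony_ids)))
    libsize = np.exp(rng.normal(-spec.libsize_sd ** 2 / 2, spec.libsize_sd,
                                len(sample_ids)))

    counts = np.empty((G, len(sample_ids)), dtype=np.int64)
    LN2 = np.log(2.0)
    time_index = {t: j for j, t in enumerate(times)}
    for sj, sid in enumerate(sample_ids):
        transition = meta.loc[sid, "transition"]
        tj = time_index[meta.loc[sid, "time_h"]]
        cj = colony_ids.index(meta.loc[sid, "colony_id"])
        log_mu = LN2 * (base2 + dev[transition][:, tj]) + colony_ln[:, cj] + np.log(libsize[sj])
        mu = np.exp(log_mu)
        r = 1.0 / alpha
        counts[:, sj] = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(gene_ids, sample_ids, counts)
    rb_phase = _interp_path(rb_base, t_arr)
    br_phase = _interp_path(br_base, t_arr)
    phase = pd.Series(
        [rb_phase[time_index[meta.loc[s, "time_h"]]] if meta.loc[s, "transition"] == "RB"
         else br_phase[time_index[meta.loc[s, "time_h"]]] for s in sample_ids],
        index=sample_ids,
    )
    truth = GroundTruth(
        gene_ids=gene_ids,
        cluster_rb=cluster_rb,
        cluster_br=cluster_br,
        interaction_deg=is_phase.copy(),
        time_deg=is_phase | (is_shared & (spec.effect_size_log2 != 0)),
        trajectories={tr: base2[:, None] + dev[tr] for tr in ("RB", "BR")},
        phase_position=phase,
        times=tuple(times),
    )
    return cm, SampleMetadata(meta), truth


def simulate_ovary_scores(truth: GroundTruth, noise_sd: float = 0.3,
                          seed: int = 0) -> pd.Series:
    """Mean ovary-activation scores (0-4): a monotone map of the latent phase
    position (4 = fully reproductive) plus clipped Gaussian noise."""
    rng = np.random.default_rng(seed)
    scores = 4.0 * truth.phase_position.to_numpy()
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, len(scores))
    return pd.Series(np.clip(scores, 0.0, 4.0), index=truth.phase_position.index,
                     name="ovary_score")


def simulate_promoters(gene_ids, pwm: PositionWeightMatrix, site_genes,
                       length: int = 500, seed: int = 0) -> dict[str, str]:
    """Uniform-background promoter sequences; genes in ``site_genes`` carry one
    embedded consensus motif word at a random position."""
    if length < pwm.length:
        raise ValueError(
            f"promoter length {length} shorter than motif length {pwm.length}"
        )
    rng = np.random.default_rng(seed)
    site_genes = set(site_genes)
    word = pwm.consensus()
    alphabet = np.array(list("ACGT"))
    out = {}
    for g in gene_ids:
        seq = alphabet[rng.integers(0, 4, length)]
        if g in site_genes:
            pos = int(rng.integers(0, length - pwm.length + 1))
            seq[pos:pos + pwm.length] = list(word)
        out[g] = "".join(seq)
    return out


def simulate_trajectories(n_genes: int = 400, n_clusters: int = 4,
                          separation: float = 4.0, noise_sd: float = 0.5,
                          intercept_sd: float = 0.0, seed: int = 0,
                          times=DESIGN_TIMES) -> tuple[pd.DataFrame, np.ndarray]:
    """Directly simulated VST-scale mean trajectories with planted clusters,
    for exercising the trajectory-clustering stage in isolation.

    Cluster means are distinct trajectory shapes (flat, rising, falling,
    transient) scaled so that every pair differs by ``separation`` VST units
    at some time point; clusters beyond four also shift in level. Per-gene
    noise is iid Gaussian plus an optional random intercept.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    u = (t - t[0]) / (t[-1] - t[0])
    shapes = [np.zeros_like(u), u, 1.0 - u, np.sin(np.pi * u)]
    means = np.vstack([
        (k // len(shapes)) * separation + separation * shapes[k % len(shapes)]
        for k in range(n_clusters)
    ])
    labels = rng.integers(0, n_clusters, n_genes)
    Y = means[labels]
    if intercept_sd > 0:
        Y = Y + rng.normal(0.0, intercept_sd, (n_genes, 1))
    Y = Y + rng.normal(0.0, noise_sd, Y.shape)
    df = pd.DataFrame(Y, index=[f"g{i:05d}" for i in range(n_genes)], columns=list(times))
    return df, labels
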