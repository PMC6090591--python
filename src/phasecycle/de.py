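"""Differential expression over the time course: normalization, negative
binomial GLM fits, and spline likelihood-ratio contrasts.

The model for gene g in sample j is

    K_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha * mu^2
    log mu_gj = log s_j + x_j' beta_g

with s_j the median-of-ratios size factor and x_j a design row of colony
indicators plus a cubic spline in time (df = 3, controls coded time 0).
Three contrasts are tested by likelihood ratio against chi^2 with 3 df:

* ``RB_time`` / ``BR_time``: within one transition,
  full  = colony + spline(time), reduced = colony;
* ``interaction``: across both transitions,
  full  = colony + transition + spline + transition:spline,
  reduced = colony + transition + spline.

Per-gene dispersion is estimated once under the full model by Cox-Reid
adjusted profile likelihood and shared with the reduced fit, so the LRT
compares nested mean models at a common variance function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2

from .io import CountMatrix, SampleMetadata
from .splines import build_spline_basis

CONTRASTS = ("RB_time", "BR_time", "interaction")

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 10.0
_ETA_CLIP = 30.0


@dataclass
class SizeFactors:
    factors: pd.Series  # sample_id -> positive real

    def values_for(self, sample_ids) -> np.ndarray:
        return self.factors.loc[list(sample_ids)].to_numpy(dtype=float)


@dataclass
class GeneFit:
    gene_id: str
    beta: np.ndarray
    alpha: float
    loglik: float
    converged: bool
    n_iter: int


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors over genes with positive geometric mean."""
    K = counts.counts.astype(float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene with nonzero counts in every sample; filter the matrix first"
        )
    logK = np.log(K[all_pos])
    log_geo = logK.mean(axis=1)
    ratios = np.exp(logK - log_geo[:, None])
    sf = np.median(ratios, axis=0)
    return SizeFactors(pd.Series(sf, index=counts.sample_ids))


def vst(counts: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    """log2(count / size_factor + 1): a variance-stabilizing transform that
    approximates log2 counts and is exactly log2(count + 1) at unit factors."""
    s = sf.values_for(counts.sample_ids)
    return pd.DataFrame(
        np.log2(counts.counts / s[None, :] + 1.0),
        index=counts.gene_ids,
        columns=counts.sample_ids,
    )


# ---------------------------------------------------------------------------
# NB GLM
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / max(alpha, _MIN_ALPHA)
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu) + (y == 0))  # y log(mu/..) with 0*log0 = 0
        )
    )


def _irls(y, X, offset, alpha, beta0=None, max_iter=100, tol=1e-8):
    """Fisher-scoring IRLS with step-halving for the NB log-link GLM."""
    n, p = X.shape
    if beta0 is None:
        z0 = np.log(np.maximum(y, 0.5)) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    else:
        beta = beta0.copy()
    eta = np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = nb_loglik(y, mu, alpha)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        ll_new = -np.inf
        for _ in range(30):
            cand = beta + step
            eta_c = np.clip(X @ cand + offset, -_ETA_CLIP, _ETA_CLIP)
            mu_c = np.exp(eta_c)
            ll_new = nb_loglik(y, mu_c, alpha)
            if ll_new >= ll - 1e-12:
                beta, eta, mu = cand, eta_c, mu_c
                break
            step *= 0.5
        else:
            break
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return beta, ll, converged, it


def _cr_adjusted_profile(y, X, offset, alpha, beta0=None):
    """Cox-Reid adjusted profile log-likelihood of the dispersion."""
    beta, ll, _, _ = _irls(y, X, offset, alpha, beta0=beta0, tol=1e-6, max_iter=50)
    mu = np.exp(np.clip(X @ beta + offset, -_ETA_CLIP, _ETA_CLIP))
    w = mu / (1.0 + alpha * mu)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    if sign <= 0:
        return -np.inf, beta
    return ll - 0.5 * logdet, beta


def estimate_dispersion(y, X, offset) -> float:
    """Per-gene dispersion by maximizing the CR-adjusted profile likelihood
    over log(alpha) in [1e-8, 10]."""
    y = np.asarray(y, dtype=float)
    state = {"beta": None}

    def neg(la):
        apl, beta = _cr_adjusted_profile(y, X, offset, np.exp(la), beta0=state["beta"])
        state["beta"] = beta
        return -apl

    res = minimize_scalar(
        neg,
        bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
        method="bounded",
        options={"xatol": 1e-3, "maxiter": 40},
    )
    return float(np.exp(res.x))


def fit_nb_glm(y, X, sf=None, offset=None, alpha=None, gene_id="gene",
               max_iter=100, tol=1e-8) -> GeneFit:
    """Fit one gene's NB GLM; estimates dispersion when ``alpha`` is None."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if offset is None:
        s = np.ones(len(y)) if sf is None else np.asarray(sf, dtype=float)
        offset = np.log(s)
    if alpha is None:
        alpha = estimate_dispersion(y, X, offset)
    beta, ll, converged, it = _irls(y, X, offset, alpha, max_iter=max_iter, tol=tol)
    return GeneFit(gene_id, beta, float(alpha), ll, converged, it)


# ---------------------------------------------------------------------------
# designs and contrasts
# ---------------------------------------------------------------------------

def _colony_dummies(colony: pd.Series) -> np.ndarray:
    """Intercept plus treatment-coded colony indicators."""
    levels = sorted(colony.unique())
    cols = [np.ones(len(colony))]
    cols += [(colony == lv).to_numpy(float) for lv in levels[1:]]
    return np.column_stack(cols)


def _drop_dependent_columns(X: np.ndarray) -> np.ndarray:
    """Drop trailing columns until the design has full column rank."""
    keep = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return X[:, keep]


def build_designs(meta: SampleMetadata, contrast: str,
                  sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Full and reduced design matrices and the LRT degrees of freedom."""
    t = meta.table.loc[sample_ids]
    spline = build_spline_basis(t["time_h"].to_numpy(float)).basis
    colony = _colony_dummies(t["colony_id"])
    if contrast in ("RB_time", "BR_time"):
        X_full = np.column_stack([colony, spline])
        X_red = colony
    elif contrast == "interaction":
        tr = (t["transition"] == "RB").to_numpy(float)
        X_red = np.column_stack([colony, tr, spline])
        X_full = np.column_stack([X_red, spline * tr[:, None]])
    else:
        raise ValueError(f"unknown contrast {contrast!r}; expected {CONTRASTS}")
    X_full = _drop_dependent_columns(X_full)
    X_red = _drop_dependent_columns(X_red)
    return X_full, X_red, X_full.shape[1] - X_red.shape[1]


def lrt_contrast(counts: CountMatrix, meta: SampleMetadata, contrast: str,
                 sf: SizeFactors | None = None, min_total: int = 10,
                 log=None) -> pd.DataFrame:
    """Likelihood-ratio test of one contrast for every sufficiently expressed
    gene; returns gene, statistic, df, p and BH-adjusted p."""
    meta.validate_against(counts)
    if contrast in ("RB_time", "BR_time"):
        transition = contrast[:2]
        sample_ids = [s for s in counts.sample_ids
                      if s in set(meta.samples_for(transition))]
        if not sample_ids:
            raise ValueError(f"no samples for transition {transition}")
    else:
        sample_ids = list(counts.sample_ids)
    sub = counts.subset_samples(sample_ids)
    tsub = meta.table.loc[sample_ids]
    for transition in (set(tsub["transition"])):
        times = set(tsub.loc[tsub["transition"] == transition, "time_h"])
        if len(times) < 2:
            raise ValueError(
                f"transition {transition} has a single time level {sorted(times)}; "
                "cannot fit a time effect"
            )
    if sf is None:
        sf = estimate_size_factors(sub)
    offset = np.log(sf.values_for(sample_ids))
    X_full, X_red, df = build_designs(meta, contrast, sample_ids)

    rows = []
    for gi, gene in enumerate(sub.gene_ids):
        y = sub.counts[gi].astype(float)
        if y.sum() < min_total:
            continue
        alpha = estimate_dispersion(y, X_full, offset)
        _, ll_full, conv_f, _ = _irls(y, X_full, offset, alpha)
        _, ll_red, conv_r, _ = _irls(y, X_red, offset, alpha)
        if not (conv_f and conv_r):
            if log is not None:
                log.record("nb_glm_nonconvergence", gene=gene, contrast=contrast)
            continue
        stat = max(0.0, 2.0 * (ll_full - ll_red))
        rows.append((gene, stat, df, chi2.sf(stat, df)))
    out = pd.DataFrame(rows, columns=["gene_id", "statistic", "df", "pvalue"])
    out["padj"] = bh_adjust(out["pvalue"].to_numpy()) if len(out) else []
    out["contrast"] = contrast
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def deg_overlap(set_a: set, set_b: set) -> dict:
    """Overlap bookkeeping between two DEG sets: sizes, union, intersection,
    and the percent of the union shared (1 decimal)."""
    a, b = set(set_a), set(set_b)
    inter, union = a & b, a | b
    percent = round(100.0 * len(inter) / len(union), 1) if union else 0.0
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "percent_shared": percent,
    }


def transition_trajectories(vst_matrix: pd.DataFrame, meta: SampleMetadata,
                            transition: str) -> pd.DataFrame:
    """Per-gene mean VST expression at each design time of one transition
    (controls contribute the time-0 column); genes x times."""
    sample_ids = [s for s in vst_matrix.columns
                  if s in set(meta.samples_for(transition))]
    t = meta.table.loc[sample_ids]
    times = sorted(t["time_h"].unique())
    cols = {}
    for tp in times:
        sel = [s for s in sample_ids if t.loc[s, "time_h"] == tp]
        cols[tp] = vst_matrix[sel].mean(axis=1)
    return pd.DataFrame(cols)
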