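"""P-spline mixture clustering of expression time courses, BIC-based choice
of the cluster count, maximum change vectors (MCV), and the cross-transition
comparison of per-interval gene counts.

Each gene's trajectory (mean VST expression at the design times of one
transition) is modeled as a K-component Gaussian mixture whose component
means are penalized splines: a rich cubic B-spline basis with equally spaced
interior knots and a second-order difference penalty on adjacent
coefficients (smoothing parameter lambda, chosen once by GCV on the
one-component fit and held fixed across K so BIC values are comparable).
A gene-level random intercept absorbs baseline shifts; EM treats both the
component label and the intercept as latent, so the penalized marginal
log-likelihood is non-decreasing across iterations.

The MCV of a trajectory is the interval, magnitude and direction of its
largest change between consecutive time points (earliest interval on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist
from sklearn.cluster import KMeans

from .splines import pspline_basis, second_difference_penalty

_RIDGE = 1e-8
_MIN_SIGMA2 = 1e-8


@dataclass
class PSplineMixture:
    K: int
    theta: np.ndarray            # K x M spline coefficients
    pi: np.ndarray               # K mixing proportions
    sigma2: float                # noise variance
    sigma2_b: float              # gene random-intercept variance
    lam: float
    responsibilities: np.ndarray  # G x K
    loglik: float                # marginal, unpenalized
    bic: float
    converged: bool
    n_iter: int
    basis: np.ndarray            # T x M
    times: np.ndarray
    loglik_path: np.ndarray = field(default=None, repr=False)  # penalized objective

    def cluster_means(self) -> np.ndarray:
        """Fitted component mean trajectories at the design times; K x T."""
        return self.theta @ self.basis.T

    def labels(self) -> np.ndarray:
        """Hard assignment (argmax responsibility), labels 1..K."""
        return self.responsibilities.argmax(axis=1) + 1


@dataclass
class ClusterAssignment:
    labels: pd.Series            # gene_id -> cluster label (1..K)
    cluster_means: pd.DataFrame  # cluster label x time
    times: np.ndarray

    @classmethod
    def from_mixture(cls, mix: PSplineMixture, gene_ids) -> "ClusterAssignment":
        labels = pd.Series(mix.labels(), index=list(gene_ids), name="cluster")
        means = pd.DataFrame(mix.cluster_means(), index=np.arange(1, mix.K + 1),
                             columns=list(mix.times))
        return cls(labels, means, np.asarray(mix.times, float))

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def genes_in(self, label) -> set:
        return set(self.labels.index[self.labels == label])

    def partition(self) -> dict:
        return {lab: self.genes_in(lab) for lab in sorted(self.labels.unique())}


@dataclass(frozen=True)
class MCV:
    """Maximum change vector: interval, magnitude (VST units), direction."""

    interval: tuple              # (t_from, t_to)
    magnitude: float
    direction: str               # "+" or "-"

    @property
    def interval_label(self) -> str:
        return f"{int(self.interval[0])}-{int(self.interval[1])}"

    def same_as(self, other: "MCV") -> bool:
        """Categorical identity: same interval and direction (magnitude ignored)."""
        return self.interval == other.interval and self.direction == other.direction


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def choose_lambda(traj: pd.DataFrame, grid=None, n_interior: int = 5) -> float:
    """Pick the P-spline smoothing parameter by GCV of the single-smoother
    (one-component) fit pooled over all gene trajectories."""
    times = np.asarray(traj.columns, float)
    Y = traj.to_numpy(float)
    B = pspline_basis(times, n_interior)
    P = second_difference_penalty(B.shape[1])
    if grid is None:
        grid = np.logspace(-2, 4, 25)
    G, T = Y.shape
    best_lam, best_gcv = grid[0], np.inf
    for lam in grid:
        H = B @ np.linalg.solve(B.T @ B + lam * P + _RIDGE * np.eye(B.shape[1]), B.T)
        edf = np.trace(H)
        if edf > T - 0.5:
            continue
        resid = Y - Y @ H.T
        rss = float((resid ** 2).sum())
        gcv = G * T * rss / (G * (T - edf)) ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    return float(best_lam)


def _log_densities(Y, means, sigma2, sigma2_b):
    """Marginal Gaussian log densities N(y; m_k, sigma2*I + sigma2_b*J); G x K."""
    G, T = Y.shape
    tau = sigma2 + T * sigma2_b
    logdet = (T - 1) * np.log(sigma2) + np.log(tau)
    yss = (Y ** 2).sum(axis=1)[:, None]
    mss = (means ** 2).sum(axis=1)[None, :]
    cross = Y @ means.T
    ss = yss - 2 * cross + mss                      # ||e||^2, G x K
    se = Y.sum(axis=1)[:, None] - means.sum(axis=1)[None, :]   # sum(e), G x K
    quad = ss / sigma2 - (sigma2_b / (sigma2 * tau)) * se ** 2
    return -0.5 * (T * np.log(2 * np.pi) + logdet + quad), se


def fit_pspline_mixture(traj: pd.DataFrame, K: int, lam: float | None = None,
                        seed: int = 0, max_iter: int = 300, tol: float = 1e-6,
                        random_intercept: bool = True,
                        n_interior: int = 5) -> PSplineMixture:
    """EM fit of the K-component penalized-spline mixture.

    ``traj`` is genes x times (columns are hours). Initialization is k-means
    on the raw trajectories with the given seed, so fits are deterministic.
    """
    times = np.asarray(traj.columns, float)
    Y = traj.to_numpy(float)
    G, T = Y.shape
    if K < 1 or K > G:
        raise ValueError(f"K = {K} outside [1, {G}]")
    if lam is None:
        lam = choose_lambda(traj, n_interior=n_interior)
    B = pspline_basis(times, n_interior)
    M = B.shape[1]
    P = second_difference_penalty(M)
    BtB = B.T @ B

    # k-means++ initialization on trajectories
    if K == 1:
        init_labels = np.zeros(G, dtype=int)
    else:
        init_labels = KMeans(n_clusters=K, n_init=10, random_state=seed).fit_predict(Y)
    R = np.zeros((G, K))
    R[np.arange(G), init_labels] = 1.0

    centers = np.vstack([Y[init_labels == k].mean(axis=0) if (init_labels == k).any()
                         else Y[k % G] for k in range(K)])
    theta = np.linalg.solve(BtB + (lam + _RIDGE) * np.eye(M) + lam * P, B.T @ centers.T).T
    resid0 = Y - centers[init_labels]
    sigma2 = max(float(resid0.var()), 1e-3)
    sigma2_b = 0.1 * sigma2 if random_intercept else 0.0
    pi = np.full(K, 1.0 / K)

    rng = np.random.default_rng(seed)
    reinit_used = np.zeros(K, dtype=bool)
    pen_path = []
    converged = False
    it = 0
    pen_prev = -np.inf
    for it in range(1, max_iter + 1):
        means = theta @ B.T                                    # K x T
        logd, se = _log_densities(Y, means, sigma2, sigma2_b)
        logw = logd + np.log(np.maximum(pi, 1e-300))[None, :]
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        pen = ll - 0.5 * lam * float(np.einsum("km,mn,kn->", theta, P, theta))
        pen_path.append(pen)
        R = np.exp(logw - norm[:, None])

        # components may carry arbitrarily small mixing weight (BIC penalizes
        # overparameterization); only numerically dead components are revived
        Rk = R.sum(axis=0)
        empty = Rk < 1e-10
        if empty.any():
            for k in np.flatnonzero(empty):
                if reinit_used[k]:
                    raise RuntimeError(
                        f"component {k} emptied twice during EM (K = {K}); "
                        "reduce K or the separation demanded"
                    )
                reinit_used[k] = True
                # seize the currently worst-explained gene for the component
                g = int(np.argmin(norm))
                R[:, k] = 0.0
                R[g] = 0.0
                R[g, k] = 1.0
                norm = norm.copy()
                norm[g] = np.inf
            Rk = R.sum(axis=0)

        # E-quantities for the latent intercept (current parameters)
        tau = sigma2 + T * sigma2_b
        shrink = sigma2_b / tau
        bhat = shrink * se                                     # G x K
        v_b = sigma2_b * sigma2 / tau if sigma2_b > 0 else 0.0

        # CM steps (single E-step; penalized objective is non-decreasing)
        pi = Rk / G
        theta_new = np.empty_like(theta)
        for k in range(K):
            wk = R[:, k]
            target = (wk[:, None] * (Y - bhat[:, [k]])).sum(axis=0)
            A = Rk[k] * BtB + lam * sigma2 * P + _RIDGE * np.eye(M)
            theta_new[k] = np.linalg.solve(A, B.T @ target)
        theta = theta_new
        means = theta @ B.T
        # residual moments with updated means, same E-step intercepts
        yss = (Y ** 2).sum(axis=1)[:, None]
        mss = (means ** 2).sum(axis=1)[None, :]
        ss = yss - 2 * (Y @ means.T) + mss
        se_new = Y.sum(axis=1)[:, None] - means.sum(axis=1)[None, :]
        # ||y - m - b 1||^2 = ss - 2 b se + T b^2 (b estimated from old means)
        quad = ss - 2 * bhat * se_new + T * bhat ** 2
        sigma2 = max(float((R * (quad + T * v_b)).sum() / (G * T)), _MIN_SIGMA2)
        if random_intercept:
            sigma2_b = max(float((R * (bhat ** 2 + v_b)).sum() / G), 0.0)

        if it > 1 and abs(pen - pen_prev) < tol * (abs(pen_prev) + 1.0):
            converged = True
            break
        pen_prev = pen

    means = theta @ B.T
    logd, _ = _log_densities(Y, means, sigma2, sigma2_b)
    logw = logd + np.log(np.maximum(pi, 1e-300))[None, :]
    norm = logsumexp(logw, axis=1)
    ll = float(norm.sum())
    R = np.exp(logw - norm[:, None])
    n_params = K * M + (K - 1) + 2
    bic = -2.0 * ll + n_params * np.log(G)
    return PSplineMixture(K, theta, pi, sigma2, sigma2_b, lam, R, ll, bic,
                          converged, it, B, times, np.asarray(pen_path))


def bic_scan(traj: pd.DataFrame, k_values=None, lam: float | None = None,
             seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Fit the mixture at each K and tabulate BIC (failures become NaN rows)."""
    if k_values is None:
        k_values = range(2, min(120, len(traj)) + 1, 2)
    k_values = list(k_values)
    if max(k_values) > len(traj):
        raise ValueError("K_max exceeds the number of genes")
    if lam is None:
        lam = choose_lambda(traj)
    rows = []
    for K in k_values:
        try:
            fit = fit_pspline_mixture(traj, K, lam=lam, seed=seed, **fit_kwargs)
            rows.append((K, fit.bic, fit.loglik, fit.converged))
        except RuntimeError as exc:
            warnings.warn(f"K = {K} failed: {exc}")
            rows.append((K, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["K", "bic", "loglik", "converged"])


def select_k(bic_table: pd.DataFrame, tau_frac: float = 0.005) -> int:
    """Plateau rule for the cluster count: the smallest scanned K whose BIC is
    within tau of the global minimum and is never exceeded by more than tau at
    any later K (tau = ``tau_frac`` of the BIC range). Falls back to the
    first global minimizer when no K satisfies both conditions."""
    tab = bic_table.dropna(subset=["bic"]).sort_values("K")
    if tab.empty:
        raise ValueError("empty BIC table")
    ks = tab["K"].to_numpy()
    bics = tab["bic"].to_numpy(float)
    tau = tau_frac * (bics.max() - bics.min())
    best = bics.min()
    for i, (k, b) in enumerate(zip(ks, bics)):
        if b <= best + tau and (bics[i + 1:] <= b + tau).all():
            return int(k)
    return int(ks[np.argmin(bics)])


# ---------------------------------------------------------------------------
# maximum change vectors
# ---------------------------------------------------------------------------

def compute_mcv(trajectory, times=None) -> MCV:
    """MCV of one trajectory: largest |change| between consecutive time
    points; earliest interval on exact ties; zero changes count as '+'."""
    if isinstance(trajectory, pd.Series) and times is None:
        times = np.asarray(trajectory.index, float)
    y = np.asarray(trajectory, float)
    if times is None:
        raise ValueError("times required when trajectory has no index")
    times = np.asarray(times, float)
    if len(y) < 2:
        raise ValueError("need at least 2 time points for an MCV")
    diffs = np.diff(y)
    i = int(np.argmax(np.abs(diffs)))          # first maximum = earliest interval
    d = diffs[i]
    return MCV((float(times[i]), float(times[i + 1])), float(abs(d)),
               "+" if d >= 0 else "-")


def cluster_mcvs(assignment: ClusterAssignment) -> dict:
    """MCV of each cluster's fitted mean trajectory."""
    return {lab: compute_mcv(assignment.cluster_means.loc[lab].to_numpy(),
                             assignment.times)
            for lab in assignment.cluster_means.index}


def gene_mcvs(traj: pd.DataFrame) -> dict:
    times = np.asarray(traj.columns, float)
    return {g: compute_mcv(traj.loc[g].to_numpy(), times) for g in traj.index}


def same_mcv_percent(mcv_a: dict, mcv_b: dict, genes) -> float:
    """Percent of ``genes`` whose MCV (interval and direction) is identical
    in both transitions, 1 decimal."""
    genes = list(genes)
    if not genes:
        return 0.0
    same = sum(mcv_a[g].same_as(mcv_b[g]) for g in genes)
    return round(100.0 * same / len(genes), 1)


def interval_gene_counts(assignment: ClusterAssignment, mcvs: dict,
                         deg_enriched, intervals=None) -> pd.Series:
    """Number of genes whose (DEG-enriched) cluster has its maximal change in
    each time interval; genes contribute through their cluster's MCV."""
    times = assignment.times
    if intervals is None:
        intervals = [f"{int(a)}-{int(b)}" for a, b in zip(times, times[1:])]
    counts = pd.Series(0, index=intervals, dtype=int)
    sizes = assignment.sizes()
    for lab in deg_enriched:
        if lab not in mcvs:
            raise ValueError(f"cluster {lab!r} has no MCV")
        counts[mcvs[lab].interval_label] += int(sizes.get(lab, 0))
    return counts


def chi2_homogeneity(counts_a, counts_b) -> tuple[float, int, float]:
    """Pearson chi-square test that two per-interval count vectors share one
    distribution; zero-total columns are dropped with a warning."""
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a row of the table is all zeros")
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-total interval(s)")
        a, b = a[keep], b[keep]
    table = np.vstack([a, b])
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(((table - exp) ** 2 / exp).sum())
    df = table.shape[1] - 1
    return stat, df, float(chi2_dist.sf(stat, df))
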