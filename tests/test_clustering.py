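import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency
from sklearn.metrics import adjusted_rand_score

from phasecycle.clustering import (
    MCV,
    ClusterAssignment,
    bic_scan,
    chi2_homogeneity,
    choose_lambda,
    cluster_mcvs,
    compute_mcv,
    fit_pspline_mixture,
    gene_mcvs,
    interval_gene_counts,
    same_mcv_percent,
    select_k,
)
from phasecycle.simulate import simulate_trajectories

TIMES = (0, 12, 24, 48, 96)


class TestMixtureFit:
    def test_single_component_recovers_grand_mean(self):
        traj, _ = simulate_trajectories(n_genes=150, n_clusters=1, noise_sd=0.4,
                                        seed=2)
        fit = fit_pspline_mixture(traj, 1, seed=0, random_intercept=False)
        np.testing.assert_allclose(fit.cluster_means()[0],
                                   traj.mean(axis=0), atol=0.15)

    def test_penalized_objective_monotone(self):
        traj, _ = simulate_trajectories(n_genes=200, n_clusters=3, seed=4)
        fit = fit_pspline_mixture(traj, 3, seed=0)
        d = np.diff(fit.loglik_path)
        tol = 1e-8 * (np.abs(fit.loglik_path[:-1]) + 1.0)
        assert (d >= -tol).all()

    def test_two_separated_groups_recovered(self):
        traj, labels = simulate_trajectories(n_genes=200, n_clusters=2,
                                             separation=4.0, noise_sd=0.5, seed=7)
        fit = fit_pspline_mixture(traj, 2, seed=0)
        assert adjusted_rand_score(labels, fit.labels()) >= 0.95

    def test_labels_stable_across_seeds(self):
        traj, _ = simulate_trajectories(n_genes=200, n_clusters=3, seed=9)
        a = fit_pspline_mixture(traj, 3, seed=0).labels()
        b = fit_pspline_mixture(traj, 3, seed=5).labels()
        assert adjusted_rand_score(a, b) >= 0.95

    def test_responsibilities_are_simplex_rows(self):
        traj, _ = simulate_trajectories(n_genes=100, n_clusters=2, seed=1)
        fit = fit_pspline_mixture(traj, 2, seed=0)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        assert (fit.responsibilities >= 0).all()
        assert fit.pi.sum() == pytest.approx(1.0)

    def test_k_larger_than_genes_rejected(self):
        traj, _ = simulate_trajectories(n_genes=10, n_clusters=1, seed=0)
        with pytest.raises(ValueError):
            fit_pspline_mixture(traj, 11)


class TestBicScan:
    def test_planted_four_clusters_beat_two(self):
        traj, _ = simulate_trajectories(n_genes=300, n_clusters=4, seed=3)
        tab = bic_scan(traj, [2, 4], seed=0)
        bics = tab.set_index("K")["bic"]
        assert bics[4] < bics[2]

    def test_scan_length_and_determinism(self):
        traj, _ = simulate_trajectories(n_genes=120, n_clusters=2, seed=5)
        ks = [2, 4, 6]
        a = bic_scan(traj, ks, seed=1)
        b = bic_scan(traj, ks, seed=1)
        assert len(a) == len(ks)
        pd.testing.assert_frame_equal(a, b)

    def test_kmax_above_gene_count_rejected(self):
        traj, _ = simulate_trajectories(n_genes=10, n_clusters=1, seed=0)
        with pytest.raises(ValueError, match="K_max"):
            bic_scan(traj, [2, 20], seed=0)


class TestSelectK:
    def _table(self, bics):
        return pd.DataFrame({"K": 2 * np.arange(1, len(bics) + 1), "bic": bics})

    def test_decreasing_then_flat_picks_plateau_start(self):
        assert select_k(self._table([100, 50, 10, 10.01, 10.02])) == 6

    def test_strictly_increasing_picks_first(self):
        assert select_k(self._table([10, 20, 30])) == 2

    def test_near_minimum_before_a_rise_is_skipped(self):
        # hand-evaluated: 49.9 precedes the 60 spike, so the rule moves past it
        tab = self._table([100, 50, 49.9, 60, 49.8, 49.8])
        assert select_k(tab, tau_frac=0.005) == 10

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_k(pd.DataFrame({"K": [2], "bic": [np.nan]}))


class TestMcv:
    def test_forced_arithmetic(self):
        m = compute_mcv([10, 12, 20, 19, 18], TIMES)
        assert m.interval == (12.0, 24.0)
        assert m.magnitude == pytest.approx(8.0)
        assert m.direction == "+"

    def test_constant_trajectory_tie_rule(self):
        m = compute_mcv([3, 3, 3, 3, 3], TIMES)
        assert m.interval == (0.0, 12.0)
        assert m.magnitude == 0.0
        assert m.direction == "+"

    def test_exhaustive_argmax_oracle(self):
        """Brute-force check over 1000 random trajectories, ties included."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            y = rng.integers(-3, 4, 5).astype(float)  # small ints force ties
            m = compute_mcv(y, TIMES)
            diffs = [y[i + 1] - y[i] for i in range(4)]
            best = max(range(4), key=lambda i: (abs(diffs[i]), -i))
            assert m.interval == (float(TIMES[best]), float(TIMES[best + 1]))
            assert m.magnitude == pytest.approx(abs(diffs[best]))
            assert m.direction == ("+" if diffs[best] >= 0 else "-")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compute_mcv([1.0], [0.0])

    def test_mcv_linear_in_member_average(self):
        """The MCV of a cluster mean equals the MCV of the member average."""
        rng = np.random.default_rng(5)
        members = rng.normal(0, 1, (20, 5))
        a = compute_mcv(members.mean(axis=0), TIMES)
        b = compute_mcv(sum(members[i] for i in range(20)) / 20.0, TIMES)
        assert a == b


class TestSameMcvPercent:
    def test_reported_concordance_arithmetic(self):
        """103 of 185 overlapping DEGs share interval and direction: 55.7%."""
        genes = [f"g{i}" for i in range(185)]
        up_early = MCV((0.0, 12.0), 1.0, "+")
        down_late = MCV((48.0, 96.0), 2.0, "-")
        a = {g: up_early for g in genes}
        b = {g: (up_early if i < 103 else down_late)
             for i, g in enumerate(genes)}
        assert same_mcv_percent(a, b, genes) == 55.7

    def test_magnitude_ignored(self):
        a = {"g": MCV((0.0, 12.0), 1.0, "+")}
        b = {"g": MCV((0.0, 12.0), 9.0, "+")}
        assert same_mcv_percent(a, b, ["g"]) == 100.0

    def test_empty_gene_list(self):
        assert same_mcv_percent({}, {}, []) == 0.0


def _assignment(labels, means):
    lab = pd.Series(labels, index=[f"g{i}" for i in range(len(labels))])
    mm = pd.DataFrame(means, index=sorted(set(labels)), columns=list(TIMES))
    return ClusterAssignment(lab, mm, np.array(TIMES, float))


class TestIntervalCounts:
    def test_single_enriched_cluster(self):
        asg = _assignment([1] * 50 + [2] * 10,
                          [[0, 0, 0, 0, 5], [0, 5, 0, 0, 0]])
        mcvs = cluster_mcvs(asg)
        counts = interval_gene_counts(asg, mcvs, deg_enriched=[1])
        assert counts.tolist() == [0, 0, 0, 50]

    def test_no_enriched_clusters(self):
        asg = _assignment([1] * 5, [[0, 1, 0, 0, 0]])
        counts = interval_gene_counts(asg, cluster_mcvs(asg), deg_enriched=[])
        assert counts.sum() == 0

    def test_counts_conserve_cluster_sizes(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_clusters = int(rng.integers(2, 6))
            labels = rng.integers(1, n_clusters + 1, 80)
            labels[:n_clusters] = np.arange(1, n_clusters + 1)  # none empty
            means = rng.normal(0, 1, (n_clusters, 5))
            asg = _assignment(labels, means)
            enriched = list(rng.choice(np.arange(1, n_clusters + 1),
                                       size=rng.integers(1, n_clusters + 1),
                                       replace=False))
            counts = interval_gene_counts(asg, cluster_mcvs(asg), enriched)
            expected = sum((labels == k).sum() for k in enriched)
            assert counts.sum() == expected

    def test_missing_mcv_rejected(self):
        asg = _assignment([1] * 5, [[0, 1, 0, 0, 0]])
        with pytest.raises(ValueError, match="MCV"):
            interval_gene_counts(asg, {}, deg_enriched=[1])


class TestChi2Homogeneity:
    def test_identical_counts_give_zero(self):
        stat, df, p = chi2_homogeneity([5, 10, 15], [5, 10, 15])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_evaluated_table(self):
        stat, df, p = chi2_homogeneity([30, 10], [10, 30])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a = rng.integers(1, 200, 4)
            b = rng.integers(1, 200, 4)
            stat, df, p = chi2_homogeneity(a, b)
            ref = chi2_contingency(np.vstack([a, b]), correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert df == ref.dof
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            chi2_homogeneity([0, 0], [1, 2])

    def test_zero_total_column_dropped(self):
        with pytest.warns(UserWarning, match="zero-total"):
            stat, df, _ = chi2_homogeneity([5, 0, 10], [7, 0, 3])
        assert df == 1


def test_gene_mcvs_agree_with_per_row_computation():
    traj, _ = simulate_trajectories(n_genes=20, n_clusters=2, seed=6)
    out = gene_mcvs(traj)
    g = traj.index[7]
    assert out[g] == compute_mcv(traj.loc[g].to_numpy(), np.asarray(traj.columns, float))


def test_choose_lambda_returns_positive_scalar():
    traj, _ = simulate_trajectories(n_genes=80, n_clusters=2, seed=8)
    lam = choose_lambda(traj)
    assert lam > 0
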