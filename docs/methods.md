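# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## Count model and differential expression

Counts are negative binomial with the NB2 variance function,
`Var = mu + alpha mu^2`, log link, and an offset of log size factor.
Size factors are the median-of-ratios convention: per sample, the median
over all-positive genes of the ratio of the count to that gene's geometric
mean. They are defined up to a common scale; the likelihood-ratio statistics
are invariant to that scale (tested).

The time effect is a cubic B-spline with df = 3, boundary knots at 0 and
96 h and no interior knots, evaluated by the Cox–de Boor recursion with the
intercept column excluded (so the basis vanishes at t = 0, where the
controls sit). Three contrasts are tested, each with 3 degrees of freedom:

* per transition — full `colony + spline(t)` vs reduced `colony`, on that
  transition's samples with its controls as t = 0;
* interaction — full
  `colony + transition + spline(t) + transition:spline(t)` vs the same
  without the interaction block, on all samples.

Fitting is iteratively reweighted least squares (Fisher scoring) with
step-halving, tolerance 1e-8 on the log-likelihood, at most 100 iterations;
non-converged genes are excluded from testing with a logged warning. Genes
with fewer than 10 total counts are not tested (configurable); degenerate
fits at very low counts are not informative.

**Dispersion.** Each gene's `alpha` is estimated under the full model by
maximizing the Cox–Reid adjusted profile likelihood
(`loglik - 0.5 logdet(X'WX)`) over `log alpha` in `[1e-8, 10]`, and shared
between the full and reduced fits so the LRT compares mean models at a
common variance function. The CR adjustment is used instead of the raw
profile likelihood because at this design's parameter-to-sample ratio
(11–15 coefficients on 36–72 samples) the unadjusted maximum-likelihood
dispersion is biased low and visibly inflates the type-I error of the LRT;
with the adjustment the null rejection rate at 0.05 is ~0.05–0.06 and the
p-value distribution is uniform by KS test (measured in the acceptance
suite). No empirical-Bayes shrinkage or dispersion trend is applied — each
gene stands alone — which is the main respect in which this implementation
is simpler than production DE packages.

Multiple testing is Benjamini–Hochberg step-up, implemented directly and
verified against an independent implementation.

## Variance-stabilizing transform and screens

The VST is `log2(count/sf + 1)`: monotone, approximately log2 at high
counts, and exactly `log2(count+1)` at unit size factors. Fold-change
screening compares de-transformed group means (`2^mean-VST`, which inherits
the +1 offset), so a "twofold change" is a difference of 1 on the VST
scale. Ordination (PCA, k-means with 50 restarts and a fixed seed,
Euclidean distances, average linkage) operates on centered time-point mean
profiles, not individual samples: group means are the unit of interest when
comparing phase positions, and replicate noise is averaged out first.

## P-spline mixture clustering

Trajectories are per-gene mean VST values at the five design times of one
transition; replicate variation is absorbed before clustering. The
K-component mixture has:

* component means `B theta_k` on a rich cubic B-spline basis (5 equally
  spaced interior knots, 9 basis functions, intercept kept) with a
  second-order difference penalty `lambda * ||D2 theta||^2`;
* a per-gene Gaussian random intercept (variance `sigma_b^2`) shared across
  components, absorbing baseline offsets;
* iid Gaussian noise (variance `sigma^2`) around the component mean.

`lambda` is chosen once by GCV of the one-component smoother pooled over all
genes and held fixed across the whole BIC scan, so BIC values at different K
are comparable. EM treats the component label and the intercept as latent;
the theta update solves penalized weighted least squares with the penalty
scaled by the current `sigma^2` (the exact conditional maximizer when the
penalty is read as a Gaussian prior on theta), which makes the penalized
marginal log-likelihood non-decreasing across iterations (tested).
Initialization is k-means on the raw trajectories with a fixed seed, so fits
are deterministic. Components may shrink to arbitrarily small mixing weight;
only a numerically dead component (responsibility mass < 1e-10) is revived
once, by seizing the worst-explained gene, before the fit fails with a
diagnostic. Overparameterized K therefore sometimes fail; the BIC scan
records the failure and continues, which is the intended behaviour of a
scan whose upper range deliberately exceeds the plausible cluster count.

BIC is `-2 loglik + p log(G)` with `p = K*9 + (K-1) + 2` (spline
coefficients, free mixing proportions, two variances) and G the number of
genes. The selection rule is a plateau rule: the smallest scanned K whose
BIC is within tau of the global minimum and is never exceeded by more than
tau at any later K, with tau = 0.5% of the scanned BIC range; if no K
satisfies both clauses (e.g. monotonically rising BIC), the first global
minimizer is taken.

Random intercepts are intercept-only: no random spline coefficients. A
consequence worth knowing is that clusters differing *only* in baseline
level are absorbed by the intercept; the clustering resolves trajectory
shapes, which is the quantity of interest here.

## Maximum change vectors and timing

The MCV of a trajectory is `(interval, |delta|, sign)` of the largest
change between consecutive design times, with the earliest interval on
exact ties and "+" for a zero change. Cluster-level MCVs (of the fitted
cluster means) drive the per-interval gene counts restricted to
DEG-enriched clusters; gene-level MCVs (of per-gene trajectories) drive the
cross-transition "same MCV" concordance, where *same* means identical
interval and direction, magnitude ignored (the MCV is used as a categorical
label there). Timing distributions are compared by a Pearson chi-square
homogeneity test on the 2 × intervals table; zero-total intervals are
dropped with a warning.

## Cluster network

Because each gene has exactly one cluster per transition, the cluster
network is bipartite and the edge weights (shared gene counts) sum to the
universe size — both enforced and fuzz-tested. The permutation null
reassigns genes to clusters of the original sizes, independently for the
two transitions, and pools the Jaccard indices of *all* cluster pairs
(including zero-overlap pairs) over 1000 replicates; the conserved
sub-network keeps edges whose Jaccard index strictly exceeds the pooled
95th percentile. Because the null Jaccard distribution is discrete with
heavy ties, the strict threshold is conservative: the realized false
conserved-edge rate sits below the nominal 5%.

The opposite-vs-same direction comparison uses a 2×2 table of conserved
edges against *non-conserved* edges (disjoint sets), Pearson chi-square
without continuity correction. Comparing the conserved sub-network against
the full network that contains it would violate the independence assumption
of the test; proportions are still reported for the complete network for
readability.

## Enrichment and motif scanning

Cluster enrichment is the one-sided hypergeometric upper tail (Fisher's
exact test for enrichment; depletion is not of interest here), BH-adjusted
within one family per annotation source. The odds ratio gets a 0.5
continuity correction for reporting only when a table cell is zero.

The PWM scanner scores every window on both strands with log-odds against a
uniform 0.25 background (configurable), normalizes to a relative score
`(s - s_min)/(s_max - s_min)` over the motif's achievable range, and calls
hits at relative score >= threshold (inclusive; default 0.95). `N` bases
score as background. JASPAR-format count matrices get a uniform pseudocount
(default 0.8) before normalization. Promoter regions are caller-supplied
FASTA; the synthetic fixture uses 500 bases per gene.

## Synthetic study conditions

The generator emulates the brood-swap design: per transition, 4 control
replicates coded t = 0 and 8 replicates at 12/24/48/96 h (72 samples in
all); 8 colonies assigned cyclically to both transitions; per-gene,
per-colony log-normal batch effects (sd 0.2, mean 1); log-normal library
depths (sd 0.15); baseline log2 expression ~ N(5, 1.5^2) floored at 1;
per-gene dispersion uniform on [0.05, 0.5] (plausible bulk RNA-seq values;
no empirical estimates exist to match).

Genes respond through a latent phase position `p(t)` in [0, 1]
(1 = reproductive). With timing asymmetry on (the default), the RB path
drops early — `p = (1, .70, .30, .15, 0)` at the design times — and the BR
path rises late — `p = (0, .02, .05, .20, 1)`; per-cluster timing variants
scale the interior path values by 0.7–1.3, which preserves where the
largest change falls. Ten percent of genes (default) are *phase genes*
carrying a gene-level effect `rho = +-effect_size_log2` (default 2, i.e. a
4-fold difference between phase states): their trajectories differ between
transitions in both timing and direction, and they are the planted
interaction DEGs. Another ten percent share one transient disturbance bump
identical in both transitions (time effects without interaction, emulating
manipulation-response genes). Everything scales with `effect_size_log2`, so
setting it to 0 gives an exact null. Trajectories are piecewise linear
between design times, so MCV logic recovers them exactly. An optional 6-h
time point adds a disturbance shock confined to 6 h on 5% of genes, to
exercise the outlier screen.

What the generator does **not** emulate: gene length and GC effects,
correlated genes within pathways, mean-dependent dispersion trends,
empirical phase-path shapes, or annotation structure richer than planted
labels. Passing tests therefore demonstrate correctness and calibration of
the statistical machinery under the stated design, not performance on any
particular real dataset; genome-wide quantities such as total DEG or
cluster counts are data-dependent and are not reproduction targets.

## Problem sizes and determinism

The test and acceptance runs use 2000-gene simulations for DE calibration
(null type-I error, power/FDR), 400 genes for clustering recovery, a
500-gene universe with 10 planted clusters and 1000 permutations for the
network, and 1000 random trajectories for the MCV oracle — sizes at which
the measured quantities are stable to a few percent while the full run
stays interactive. Every stochastic component takes an explicit seed
(simulation, k-means initialization, permutation null), and identical seeds
reproduce results bit-for-bit; run parameters and seeds are recorded in a
JSON-lines log per run directory.
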