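# Methods

## Model

Each taxon's relative abundance x ∈ [0, 1) follows a zero-inflated beta
(ZIB) mixture: an atom of mass p at exactly zero and, with probability
1 − p, a beta density parameterized by mean μ ∈ (0, 1) and dispersion
φ > 0 (shape parameters a = μφ, b = (1 − μ)φ). Values numerically equal to
zero are treated as the atom; values at or above 1 − 1e−12 are clamped into
the open support with a warning (the model's support is [0, 1)).

Each of (p, μ, φ) can be a GLM of per-sample covariates. Links: logit
(default), probit or log–log for p and μ; log (default) or square root for
φ. An intercept-only design is the no-covariate case.

The joint distribution of a taxon pair is F(x_i, x_j) = C(F_i(x_i),
F_j(x_j); θ) with C the Frank copula,

    C(u, v; θ) = −(1/θ) log[1 + (e^{−θu} − 1)(e^{−θv} − 1) / (e^{−θ} − 1)].

Frank was chosen because it covers the maximal dependence range
(θ ∈ (−∞, ∞)\{0}, the limits being the Fréchet bounds), admits negative
dependence (co-exclusion), and is radially symmetric without tail
dependence. The module boundary would admit other Archimedean families,
but only Frank is implemented.

Because the margins are discrete–continuous mixtures, the copula is not
unique and the joint density follows the general mixed-margin construction:
per observation one of four cases applies, determined by the zero pattern —

* both nonzero: c(u, v; θ) f_i(x_i) f_j(x_j), with u, v the full marginal
  CDFs (atom included) and f_k the continuous part (1 − p_k) f_beta;
* x_i = 0 only: ∂C(p_i, v)/∂v · f_j(x_j) — the conditional copula
  probability of the atom mass;
* x_j = 0 only: symmetric;
* both zero: C(p_i, p_j; θ).

The difference operator over jump points collapses to these four terms
because F(0−) = 0. As published, the both-zero term of the profile
log-likelihood carries a factor −θ in front of the logarithm where the
copula definition implies −1/θ; this implementation uses log C(p_i, p_j; θ)
with C as defined above, which normalizes correctly (the four-case density
integrates to 1; this is tested by quadrature over a parameter grid).

## Estimation

Two-stage (inference-for-margins) maximum likelihood:

1. Each margin is fitted by its own likelihood. The likelihood factorizes
   exactly into a Bernoulli part for the zero indicator and a beta part for
   the nonzero values, so the blocks are fitted separately. Intercept-only
   fits use the closed-form zero fraction plus a damped Newton iteration on
   the beta log-likelihood in (log a, log b) — step-halving on likelihood
   decrease, a gradient step when the Newton direction is not an ascent
   direction, Nelder–Mead fallback on stall; initialized from the zero
   fraction and method-of-moments. Convergence: gradient ∞-norm ≤ 1e−8
   (scaled) or relative log-likelihood change ≤ 1e−10, max 100 iterations.
   Covariate fits delegate to statsmodels (Binomial GLM; BetaModel with a
   precision design). At least three nonzero observations are required —
   the identifiability floor for the three beta-block parameters.
2. The fitted margins are plugged into the pairwise likelihood and the
   resulting one-dimensional profile in θ is maximized on
   [−35, 35] by a 25-point grid scan plus bounded Brent refinement
   (xatol 1e−8). |θ| = 35 is within ~1e−6 of the Fréchet bound in
   Kendall's τ, so the cap costs nothing statistically; solutions at the
   cap are flagged rather than hidden. θ within 1e−6 of zero dispatches to
   the independence-limit formulas, keeping the profile continuous through
   the puncture at θ = 0.

Pair-level preconditions mirror identifiability: ≥ 3 nonzero values per
margin, and ≥ 2 jointly nonzero observations (mutual exclusivity or a
single overlapping observation leaves θ unidentified or unstable).

The variance of θ̃ is the leave-one-out jackknife Σ_l (θ̃_(l) − θ̃)², with
both stages re-run on every leave-one-out subset (warm-started at the
full-data estimate; a warm/cold agreement check is in the tests). The
deviations are taken around the full-data estimate and no (n−1)/n factor
is applied — the scaling constant is configurable. This stands in for the
analytic inference-function covariance, whose mixed partial derivatives
are impractical; empirically it tracks the sampling variance closely and
errs, if at all, on the conservative side (see Limitations).

## Testing and networks

The rescaled likelihood-ratio statistic for H₀: θ = θ₀ is
Λ′ = −2ω[ℓ(θ₀, γ̃_i, γ̃_j) − ℓ(θ̃, γ̃_i, γ̃_j)], asymptotically χ²₁. For
the independence null θ₀ = 0 the cross-information between θ and the
marginal parameters vanishes and ω = 1 exactly — no information matrices
are computed. For θ₀ ≠ 0, ω is assembled from the marginal score
covariances J_kl and the joint-likelihood information blocks I_θθ, I_θk,
all estimated as sample averages of central finite differences at the
fitted link-scale coefficients (step 1e−5 for scores, 1e−4 for second
derivatives); ω is clipped into (0, 1]. Simulation at a non-zero null
confirms E[Λ′] ≈ 1. Fits at the θ bound still report Λ′ but carry a
boundary flag.

Network construction runs the independence LRT on all m(m−1)/2 pairs
(margins are fitted once per taxon and shared across its pairs — stage 1
depends only on the margin, so this is exact) and controls FDR with
Benjamini–Yekutieli at q (default 0.01), the step-up rule with harmonic
correction c(m), valid under the arbitrary dependence among overlapping
pairs. Edges are BY rejections, weighted by θ̃; non-significant pairs enter
the weighted matrix as zero. Pairs failing preconditions are recorded with
a reason code and excluded from the FDR family.

Clustering uses complete agglomerative linkage on
d(i, j) = 1 − |θ̃_w(i, j)| / max|θ̃_w| over the significant-weighted matrix
(1 for non-significant pairs), cut to a requested number of clusters
(default 3); the dissimilarity is a package choice and configurable. Note
that |θ| treats strong co-exclusion as similarity; with few taxa the
unit-sum constraint induces negative cross-dependence that can dominate
this metric (see Limitations). Graph summaries are normalized centralities
(degree/(m−1), closeness, betweenness, eigenvector), density, diameter and
mean distance (largest component, flagged, when disconnected), average
clustering coefficient, and the modularity of the produced cluster
partition (not a modularity-maximizing partition). The Erdős–Rényi null
draws G(m, M) graphs with the observed node and edge counts and reports
two-sided empirical p-values (distance from the null mean) for average
clustering and modularity, the latter computed by applying the same
clustering procedure to each null graph's adjacency. Bootstrap consistency
resamples rows with replacement, reruns the full scan + FDR, and reports
overlap (|A∩B|/min|A|,|B|) and Dice (2|A∩B|/(|A|+|B|)) coefficients
against the original edge set plus per-pair selection frequencies.

## Synthetic data

Pairs are drawn by the Rosenblatt transform: U, B independent uniforms,
V = C⁻¹_{v|u}(B | U; θ) in closed form, then each uniform through the ZIB
quantile (0 at or below the atom mass p, a beta quantile above). Datasets
are redrawn whole when a margin has fewer than 3 nonzero values, when the
taxa are mutually exclusive, or when exactly one observation is jointly
nonzero — the estimability preconditions. Rejection truncates the sampling
distribution; attempt counts are reported, and a redo limit (default 1000)
turns degenerate configurations into errors instead of loops.

Default simulation conditions mirror the study design the package is
validated against: θ ∈ {−2.5, −1, 0, 0.5, 1.5, 3}; zero-inflation pairs
(0.10, 0.25), (0.40, 0.50), (0.60, 0.75), (0.20, 0.75); (μ, φ) from
{(2/7, 7), (5/7, 7), (1/2, 4), (1/3, 9), (2/3, 9), (1/2, 6)}; n = 50. The
covariate variant draws a standard-normal confounder per sample and sets
logit p_k = ρ_k0 + ρ_k1 Q_k with coefficient pairs {(−0.5, 0.7),
(−0.3, 0.4)}, {(−0.1, 0.7), (0.1, 0.4)}, {(0.5, 0.7), (0.8, 0.4)}
(low/low, low/high, high/high zero inflation), μ_i = logit⁻¹(−0.7),
μ_j = logit⁻¹(−1), φ = e^{1.5}. A Gaussian-copula pair sampler supports
misspecification experiments.

The multivariate generator assembles a latent Gaussian copula over
n_taxa margins: a chosen subset of pairs (default: a random 10% of all
pairs) gets latent correlation 0.6, the assembled matrix is repaired to
positive definiteness by eigenvalue clipping when needed (this shrinks
realized correlations — warned), margins get p ~ U(0.1, 0.6) and (μ, φ)
from the grid above, and rows are normalized to unit sum. The latent
correlation magnitude and true-pair fraction are exposed as configuration;
the defaults are assumptions, chosen once as a plausible design for a
sparse-signal recovery experiment, not reproductions of any published
parameter file. The headline acceptance quantity — ROC AUC of the LRT
p-value ranking over all pairs of a 75-taxon, 100-sample table — lands at
0.88–0.90 across seeds under these defaults.

What the generator does not emulate: sequencing depth variation and
count-level sampling noise, taxon-specific detection limits, phylogenetic
correlation structure, and any covariation at the absolute-abundance
scale. Passing tests therefore validate the estimator and test under the
model's own sampling scheme (plus the unit-sum distortion), not robustness
to every feature of real surveys.

## Numerical choices

* All copula arithmetic uses expm1/log1p-stable primitives. The common
  denominator (1 − e^{−θ}) − (1 − e^{−θu})(1 − e^{−θv}) is expanded to
  e^{−θu} + e^{−θv} − e^{−θ(u+v)} − e^{−θ} for |θ| ≥ 0.5: the naive form
  cancels catastrophically as (u, v) → (1, 1) at large θ (relative error
  ~3e−4 at θ = 30 without it). The inverse conditional is likewise
  computed as a ratio of positive sums. Boundary identities
  (C(u, 1) = u etc.) are enforced exactly.
* Per-observation log densities are floored at log(1e−300) so extreme θ
  excursions during optimization cannot produce −∞/NaN.
* Marginal CDF values entering copula terms are clipped to
  [1e−12, 1 − 1e−12].
* θ ↔ τ uses the first Debye function by adaptive quadrature; θ ↔ ρ_s uses
  double quadrature of the copula (12∬C − 3).
* Ties and degenerate cases: an all-equal dissimilarity matrix yields one
  cluster with a warning; leave-one-out subsets violating preconditions are
  skipped and the jackknife flagged partial; empty graphs report density 0
  and no diameter.

## Design choices where the design was open

* The links used for any particular published analysis are not knowable
  from the outputs; the defaults (logit, logit, log) are assumptions and
  configurable.
* The jackknife re-runs both stages per leave-one-out subset, since the
  estimator vector being resampled is the full two-stage η̃.
* The ω estimation recipe for θ₀ ≠ 0 (numeric information blocks at the
  fitted parameters) is this package's choice; the independence null, the
  only case used in network construction, bypasses it exactly.
* Modularity is reported for the partition the clustering produced, and the
  ER null applies the identical procedure to each null graph.
* The CLI is a thin convenience layer; the library functions and estimator
  classes are the primary interface.

## Limitations

* Dependence is marginal (pairwise), not conditional: an edge does not
  claim the association is unexplained by other taxa, and covariation is
  at the relative-abundance scale — compositional coupling is part of the
  signal. With few taxa (≲ 10) the unit-sum constraint alone induces
  strong negative cross-dependence.
* The jackknife variance is approximately unbiased to mildly conservative
  in simulation (ratios to the empirical variance of θ̃ within a few
  percent of 1 at n = 50 across zero-inflation settings); it is not
  guaranteed conservative replicate-by-replicate at modest replication.
* The two-stage θ̃ tracks the full 7-parameter joint MLE closely at
  moderate dependence, but on small samples (n ≈ 30) with strong estimated
  dependence (θ̃ ≳ 2.5) the two can differ by several tenths — the profile
  is flat there and both estimators are imprecise.
* Asymptotic χ²₁ calibration of Λ′ is good at n = 50 under the settings
  tested; heavier zero inflation shrinks the effective sample size and
  p-values become conservative before they become invalid.
* p̂ = 0 margins degenerate to a pure beta fit; the link-scale intercept is
  then clipped, and ω estimation (θ₀ ≠ 0 only) may be ill-conditioned.
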