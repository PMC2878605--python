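# Methods

This note records the models implemented in `habitatrates`, their
assumptions, the numerical choices behind them, and what the synthetic-data
generators do and do not emulate.

## Discrete habitat evolution and stochastic mapping

Habitat use is a four-state character (rock, terrestrial, semi-arboreal,
arboreal; "generalists" are assumed to have been excluded upstream) evolving
by a continuous-time Markov process with rate matrix *Q*. Two structures are
supported: equal rates (ER, one symmetric rate) and all rates different
(ARD, 12 rates). **ER is the default**: a 12-parameter ARD model on a ~90-tip
tree is weakly identified, and the downstream analysis consumes maps, not
rate estimates. The likelihood is computed by Felsenstein pruning with
per-branch matrix exponentials (cached per distinct branch length) and
per-node rescaling.

Rates are handled **empirical-Bayes**: maps are sampled under the ML point
estimate of *Q* rather than under a prior over rates (a documented
divergence from fully Bayesian mapping tools, which place priors on the
overall rate). ML optimization is on the log-rate scale, bounded in
[1e-8, 1e3] transitions per unit tree depth; monomorphic data return the
lower bound with a flag rather than an error. The root prior defaults to
uniform over the four states; the stationary distribution of *Q* is
available as an option.

Map sampling follows the standard conditional scheme: pruning pass (shared
across all draws), root state from its marginal posterior, preorder draws of
node states given the parent state and tipward data, then
endpoint-conditioned path simulation per branch. Paths are drawn by forward
rejection sampling, switching to **uniformization** after 1000 rejections —
the uniformized sampler (Poisson number of candidate jumps, bridge-sampled
jump chain, uniform order-statistic times, virtual jumps dropped) terminates
for any endpoints, which rejection alone does not guarantee on long branches
with unequal endpoints.

An *origin* of state *s* on a map is a transition into *s* anywhere on the
tree, plus one if the root starts in *s*.

## Morphometrics

Species values are arithmetic means of log-transformed linear measurements
(13 variables in the standard layout). The natural log is used; the base
cannot affect a correlation-matrix PCA and only rescales scores uniformly.

PCA is an eigendecomposition of the correlation matrix of species means.
Components are ordered by decreasing eigenvalue; within each component the
largest-magnitude loading is made positive (a reporting convention —
eigenvectors are sign-ambiguous). Percent total variation is
eigenvalue/Σ×100; percent *shape* variation for component *j* ≥ 2 divides by
the variance left after component 1. Four components are retained by
default; the count is a parameter, not a rule derived from a variance
threshold.

Sampling variances: all individuals are standardized **in the species-mean
frame** (column means and SDs of the species-mean table — the frame the PCA
itself was fitted in) and projected through the loadings. Because projection
is affine and species means are means over individuals, the per-species mean
of individual scores equals the species score exactly. The pooled
within-species variance uses the within-group degrees of freedom,
Σₛ Σᵢ (scoreₛᵢ − meanₛ)² / (N − S); species measured once contribute nothing
to the numerator and receive pooled/1 like any other species. If *every*
species is a singleton the pooled variance is undefined and the code
instructs the caller to provide a floor instead of silently guessing one.

## Multi-rate Brownian motion

Given a map, each candidate model partitions the states into rate classes
with one σ² each. The per-state shared-path matrices *Sₖ* are accumulated
branch-wise (each branch adds its state occupancy to the tip-pair block
below it); summed over states they reproduce the tree's phylogenetic
covariance matrix exactly, which the tests assert to 1e-9. The model
covariance is V = Σ σ²_class(k) Sₖ + diag(sampling variances).

Numerics:

* Cholesky-based solves throughout; factorization is attempted unjittered
  first, then with diagonal jitter of 1e-10× (then 1e-6×) the mean diagonal.
  A still-singular V raises an error suggesting a sampling-variance floor.
* The root state is profiled analytically as the GLS mean
  (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x — the optimum is identical to optimizing it numerically
  and the conditioning is better.
* Rates are optimized as log σ² with L-BFGS-B and an **analytic gradient**
  (envelope theorem at the profiled mean:
  ∂(−lnL)/∂σ²ᶜ = ½[tr(V⁻¹Aᶜ) − uᵀAᶜu], u = V⁻¹(x − μ̂1)), bounds
  [1e-10, 1e6]. Boundary hits are flagged but valid (near-zero rates are a
  real feature of slow classes).
* The profile likelihood can be **multimodal**: basins exist where one class
  absorbs variance the data assign to another, and uniform rescalings of the
  single-rate estimate all start in the same basin. The default start set is
  therefore the single-rate ML estimate, its ×0.1 and ×10 rescalings, and
  one asymmetric start per class (that class ×10, the rest ×0.1); all starts
  are run and the best optimum kept. Inside the ensemble, nested models are
  instead seeded with the full model's optimum collapsed onto their classes
  (plus the uniform start) — on benchmark ensembles this reproduces the
  full start fan's optima to ~1e-8 at a third of the cost, and the nested
  models' likelihoods are bounded above by the full model's, which the test
  suite checks.
* AICc uses k = n_classes + 1 (rates plus the estimated root state) and
  n = number of species; n ≤ k + 1 makes AICc undefined — an error for the
  scalar function, a flagged NaN inside clade fits where only rates are
  wanted. The n·ln 2π constant is included in lnL (it cancels in ΔAICc).
* Ties in "preferred model" go to the smaller k.

A caution discovered while testing: the intuition that inflating sampling
variances always degrades the fitted likelihood is wrong. When the realized
data look overdispersed relative to the tree covariance, a modest iid
variance component *improves* the ML fit; monotone degradation holds only
once the floor dominates the data's scale, and the test asserts exactly
that.

## Ensemble summaries

All models × all trait axes are fitted on every map. Because the species
data are identical across reconstructions, AICc is averaged across the
ensemble and compared between models; Akaike weights and the headline ΔAICc
column derive from the mean AICc. Per reconstruction, the preferred model is
the AICc minimum and a model with ΔAICc > 2.0 is disfavoured; the mid-95%
ΔAICc interval is the 2.5–97.5 percentile range. Model-averaged per-habitat
rates are computed within each reconstruction (weights from that
reconstruction's AICc) and then summarized.

The ± spread reported for parameters and scores is the **standard
deviation** of per-reconstruction values: the quantity of interest is
reconstruction uncertainty, not the Monte-Carlo error of the ensemble mean.
`se_mode="sem"` switches to sd/√R for readers who want the latter.

Clade-restricted rates use the **censored species subset**: the shared-path
matrices are cut down to the clade's tips and the full multi-rate model is
refitted there; habitats with zero occupancy inside the clade are dropped
and reported as NaN. Reconstructions in which a clade is not monophyletic
are skipped and counted. The size rate is the mean fitted rate on the first
axis; the shape rate is the sum of mean rates on the remaining retained
axes. (The species-subset likelihood is one reasonable reading of
"within-clade rates"; a joint fit with clade-specific rates is a possible
alternative and is not implemented.)

## Synthetic data

The generators reproduce the statistical design the analysis assumes, at
the protocol scale: 90 species; Yule trees rescaled to root depth 1.0; 500
reconstructions as 50 branch-length-jittered trees × 10 stochastic maps;
four habitat states under an ER process with rate 0.6 per unit depth
(roughly 15–20 realized transitions per history, enough for multiple
independent origins of each state); per-habitat Brownian rates
(rock 1, terrestrial 25, semi-arboreal 125, arboreal 5) spanning the two
orders of magnitude typical of a strongly habitat-structured radiation; and
1–36 individuals per species with median 4 (truncated geometric, success
probability tuned so the population median is exactly 4).

Details and deliberate simplifications:

* **Tree uncertainty** is emulated by log-normal branch-length jitter
  (mean 1, CV = sd, default 0.05) with terminal branches stretched to
  restore ultrametricity, *not* by sequence simulation and re-inference:
  the downstream analysis consumes only trees, so only tree variation
  matters. The jitter has no phylogenetic signal or topology uncertainty —
  real posterior samples have both, so passing tests here says nothing
  about topology-driven sensitivity.
* The Yule simulator draws Exp(kλ) waits while k lineages are extant and
  one further Exp(nλ) holding time after the n-th birth; the test suite
  checks the inter-node interval law against this closed form directly.
* **Measurements**: 13 log-scale variables are mixed from four latent trait
  axes through a fixed loading matrix whose first column is the uniform size
  direction (the remaining columns are orthonormalized smooth contrasts),
  at 0.25 log-units per latent unit so the across-species size spread
  (~0.5 log units) dominates the within-species noise (sd 0.1) — producing
  the dominant first principal component typical of linear morphometrics.
  Real measurement error is not iid Gaussian per variable (allometry,
  observer effects, sex dimorphism), so the generator validates the
  pipeline's arithmetic, not its robustness to structured error.
* Brownian tip values are simulated exactly (per-branch Gaussian with
  variance Σ σ²_state × duration); no discretization error.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: 1000 (tests) / 300 (script)
random instances for the likelihood-vs-MVN and pruning-vs-enumeration
oracles; 20,000 maps for sampler-vs-posterior frequencies; 50 (tests) / 20
(script) replicates at 200 tips for four-rate parameter recovery; and one
full protocol-scale ensemble (90 × 500 × 10 × 4), which runs in ~9 minutes
on one CPU. Determinism is asserted byte-for-byte on reports from repeated
same-seed runs.

## Known limitations

* Ornstein–Uhlenbeck (multi-peak) alternatives are out of scope by design;
  the model family is multi-rate BM only.
* Mapping uses an ML point estimate of *Q*; mapping uncertainty due to rate
  uncertainty is therefore understated relative to a fully Bayesian
  treatment. Sensitivity to the ER default and the uniform root prior should
  be checked per dataset (ARD and stationary-prior options are provided).
* The SIMMAP-style I/O dialect (segments rootward→tipward inside `{}`)
  is this package's documented convention; other tools' SIMMAP variants may
  order segments tipward-first and need reversing on import.
* Trees with duplicated tip labels, NEXUS translate tables, and node labels
  other than tip names are not supported.
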