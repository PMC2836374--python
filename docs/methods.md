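# Methods

## The question the package answers

If DNA sequences evolve under a strict molecular clock — one constant
substitution rate on every branch of the tree — how much *apparent*
among-lineage rate variation does the estimation pipeline alone produce?
Any spread in per-branch rate estimates from clock-true simulated data is
estimation error: partly the Poisson noise of the substitution process
itself, partly misestimation of branch lengths (multiple hits at single
sites as divergence grows). `clockdrift` simulates such data, re-estimates
branch rates, and quantifies the spurious variation.

## Simulation model

Sequences evolve under HKY85 with equal base frequencies. The
"transition/transversion ratio of two" that defines the default model is
interpreted as the expected *event* ratio R = 2 (the Seq-Gen `-t`
convention), which under equal frequencies corresponds to the rate ratio
κ = 4; a user who prefers the other reading can pass `kappa=2` directly.
The rate matrix is calibrated so one unit of branch length is one expected
substitution per site. Optional +Γ (continuous draws in simulation,
discrete categories in likelihoods, 4 by default) and +I site-rate mixtures
are available for realistic-model designs; the 8-taxon study uses neither.

The default simulator draws the root sequence from the stationary
frequencies and propagates each branch site-wise through the closed-form
HKY transition matrix P(t). A Gillespie-style exact simulation of the
underlying CTMC is provided as an independent check: it produces the same
tip distribution while exposing the realised substitution count on every
branch, which is Poisson(L·n_sites) under the clock — the quantity the
Poisson yardstick below reasons about but sequence data never reveal.

## Trees and coordinates

The equal-branch design uses the balanced 8-taxon rooted tree
(((t1,t2),(t3,t4)),((t5,t6),(t7,t8))): cherry ancestors at 1 Myr, their
parents at 2 Myr, root at 3 Myr, every rooted branch spanning 1 Myr and
carrying the same length L ∈ {0.01 … 1.4} substitutions/site. This is the
only balanced 8-taxon shape consistent with two node depths and 13 unrooted
branches; node ages increase root-ward with tips at 0, and branch
attributes live on the child node. In the unrooted view the two root-child
branches merge into a central branch spanning 2 Myr with length 2L.
Estimated rates are lengths divided by these fixed time spans.

Group tags: the 8 terminal branches are "depth 1", the 4 cherry-to-parent
branches are "depth 2"; the central branch belongs to neither depth and is
excluded from the depth contrast (keeping both depth classes
time-homogeneous), a choice recorded in every output manifest. The two
root subtrees are clades A and B; because the central branch spans both,
its rate is counted in *both* clade averages rather than dropped.
Arbitrary dated trees (newick with edge lengths in Myr, ultrametric) are
supported through `build_dated_tree(newick, rate)` for mixed-branch-length
designs; depth contrasts are skipped there.

## Estimation

**Maximum likelihood.** Felsenstein pruning over compressed site patterns
with per-node rescaling; HKY P(t) in closed form (checked against the
matrix exponential to 1e-10), GTR by symmetric eigendecomposition. The
free model optimises the 2n−3 unrooted branch lengths on the fixed true
topology, bounds [0, 10] substitutions/site, with κ profiled jointly
(frequencies held at the simulation values, matching the study design).
Optimisation is two-stage: coordinate-wise bounded scalar (Brent) sweeps
over branches and κ, then an L-BFGS-B polish of the full vector. The
sweeps are essential at high divergence: a multivariate line search from a
distance-based start can overshoot onto the saturation plateau (all
branches at the upper bound) and stall there. At saturated starts (initial
distance-based length ≥ 0.6) three additional randomly perturbed starts
are swept and the two best polished; restarts reduce but deliberately do
not eliminate the wild optima, which are part of the phenomenon being
measured. Branch lengths hitting the upper bound are recorded. Estimated
lengths below 1e-6 substitutions/site are flagged "zero" and excluded from
fold-variation ratios (a zero estimate implies an infinite ratio); the
threshold is exposed on the model object.

Initial lengths spread the mean Jukes-Cantor-corrected pairwise distance
over the mean tip-to-tip path (saturated pairs, p ≥ 0.75, capped at 5).

**Clock-constrained ML.** The clock model has n−1 free node heights in
substitution units, parameterised as a root height and per-node fractions
of the parent height (so nesting constraints hold by construction),
initialised from the free fit's implied mean subtree heights. The clock
test statistic is 2(lnL_free − lnL_clock) against χ² with n−2 degrees of
freedom (13 − 7 = 6 for 8 taxa).

**Bayesian.** A deliberately small fixed-topology Metropolis-Hastings
sampler, not a MrBayes replica: single chain, one-parameter multiplier
proposals, i.i.d. Exponential(mean 0.1) priors on branch lengths and
Uniform(0, 100) on κ. Defaults (50k generations, thin 50, 25% burn-in) are
desk-scale; all settings sit in `ChainConfig`, and an effective-sample-size
check (< 100 on any branch) flags non-convergence in the output. Posterior
means are the point estimates. Marginal likelihoods for the Bayes-factor
clock comparison (2ΔlnML > 10 significant) use the stepping-stone
estimator with rungs at β = (k/K)^(1/0.3), K = 8 by default, chains
warm-started from high β downward; the clock model's priors are
Exponential(mean 1.0) on the root height and Uniform(0,1) on height
fractions. Because the sampler, priors and chain lengths differ from the
original MrBayes runs, Bayesian summaries are comparable only
statistically, never digit-for-digit.

## Rate-variation statistics

Per dataset: overall fold variation max/min over the 13 rates
(zero-flagged branches removed); depth and clade contrasts as ratios of
group mean rates oriented ≥ 1, with significance by the
1-SD-error-bar-overlap rule (a Welch t-test p-value is reported alongside,
since the SD rule is unconventional); Shapiro-Wilk normality of the 13
rates. Per experiment cell: counts of datasets exceeding 2-fold and
exceeding the analytic Poisson fold (strict inequalities), one-way ANOVA
of rates across datasets (branches treated as independent samples — they
are not, a caveat inherited from the design and propagated here), and a
diagnostic flag implementing the attribution rule that, were the ~65
out-of-band branch rates spread evenly, at least 35 of 100 datasets should
stay below the Poisson expectation.

The Poisson yardstick: μ = L × n_sites, σ = √μ, expected fold
(μ+2σ)/(μ−2σ), defined only for μ > 4 and strictly decreasing in μ. At
1 kb the 11-length grid gives 4.4, 2.6, 1.8, 1.5, 1.3, 1.2, 1.2, 1.2,
1.1, 1.1, 1.1.

The node-density diagnostic regresses each tip's root-to-tip inferred path
length on the number of nodes along the path (OLS); it is reported as
undefined on trees where every tip passes the same node count (any
balanced design).

## Experiment orchestration and seeding

One config drives simulate → estimate → summarise over the grid. The study
conditions are the defaults: 11 branch lengths, 1000 sites, 100 replicates,
ML estimation with the clock LRT. Replicate k of cell c derives its
generator from `SeedSequence([base_seed, c, k])` — deterministic,
independent streams, invariant to any parallelisation, and any single cell
can be reproduced bit-for-bit from the manifest (config hash and seeding
rule are written into every output). Failed or degenerate replicates are
recorded with their reason and excluded from aggregates with the count
reported, never silently resimulated.

## What the generator does and does not emulate

The simulator reproduces the study conditions exactly: clock-true,
homogeneous HKY, no indels, no ambiguity codes, no among-branch model
heterogeneity. Real data violate most of these, so the measured spurious
rate variation is a *floor* for what estimation error can produce
empirically; passing tests say nothing about selection, rate
autocorrelation, or alignment error.

## Numerical choices

- P(t) stochasticity tolerance 1e-10; Chapman-Kolmogorov checked to 1e-9.
- Pruning rescales at every internal node (log-scale accumulators), so
  likelihoods are stable well beyond 50 taxa.
- Optimiser tolerances: scalar sweeps xatol 1e-5 (1e-4 on log κ), polish
  ftol 1e-9; a polish that worsens the objective is discarded in favour of
  the sweep point.
- LRT statistics clipped at 0; a free lnL more than 1e-6 below the clock
  lnL raises (upstream optimiser failure, never silently absorbed).
- Degenerate inputs: identical sequences → all branches zero-flagged;
  constant rate vectors → Shapiro reported as undefined; all-but-one
  branch flagged → fold variation undefined and recorded.

## Known limitations

- The clock LRT behaves almost exactly nominally here (the statistic's
  null distribution at 1 kb matches χ²₆ closely), so clock-true data still
  yield ≈ α rejections per 100 datasets; claims that this design produces
  *zero* rejections are not reproducible with the test as defined.
- ML optima in the saturated regime (L ≥ 1.0) are genuinely multimodal;
  different optimisers find different wild optima, so extreme maximum-fold
  values are reproducible only in kind, not in digit.
- The Bayesian stage is a simplified sampler (see above); its numbers
  carry Monte-Carlo error and prior sensitivity (a `BayesPriors` field
  exposes the branch-length prior mean; rerun with 1.0 to probe it).

## Problem sizes used in the shipped checks

The packaged test suite and the acceptance script run the full study scale
for the ML arm (100 replicates × 1 kb per branch length on the cells they
examine) and reduced scale for the Bayesian arm (10-15 replicates, 10-20k
generations), consistent with the desk-scale chain defaults above.
Consistency oracles use 10^5-10^6 sites where a closed form is available
(pairwise distances, ML recovery, posterior-vs-ML agreement).
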