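# Methods

## Model

The inference target is the posterior p(ϑ, x₁:K | r₁:K) ∝
p(ϑ) p(x₁:K | ϑ) p(r₁:K | x₁:K), where ϑ collects one selection coefficient
per epoch (optionally the dominance h), x₁:K is the population mutant-allele
frequency at the K distinct sampling times, and r₁:K are the reads of all
sampled individuals, entering only through per-individual genotype
likelihoods p(r | g).

**Latent dynamics.** Between sampling times the frequency follows the
Wright–Fisher diffusion with selection, dX = αX(1−X)(h+(1−2h)X)dt +
√(X(1−X)/β(t)) dW, in time units of 2N₀ generations, α = 2N₀s(t). The
selection coefficient s(t) and the population-size ratio β(t) = N(t)/N₀ are
piecewise constant in generations, evaluated at the left endpoint of each
step, and right-continuous at a change time τ (s(k) = s⁺ for k ≥ τ; an
individual sampled exactly at τ is emitted with s⁺, since sampling happens
in adulthood, after selection).

**Emission.** Given x at the sampling generation, individual genotypes are
the selection-reweighted Hardy–Weinberg proportions ((1−x)², 2(1+hs)x(1−x),
(1+s)x²)/w̄; the per-individual emission is the dot product of this triple
with the (normalized) genotype-likelihood triple, and individuals are
conditionally independent. The rendered heterozygote term is (1+hs)·2x(1−x):
the factor 2 is the Hardy–Weinberg heterozygote coefficient (an exponent
reading would not normalize to genotype frequencies). Indicator likelihoods
recover the called-genotype model exactly; a flat triple (⅓,⅓,⅓) encodes a
missing genotype and contributes a constant factor.

## Numerics

- **Euler–Maruyama.** One generation = `substeps` steps (default 5) of size
  Δt = 1/(2N₀·substeps). The state is clamped into [0,1] after each step and
  the noise uses √max(x(1−x),0): once at a boundary, drift and noise vanish,
  so 0 and 1 are absorbing. The boundary treatment is our choice; nothing in
  the model fixes it, and for the parameter ranges exercised here the
  clamped mass is negligible away from fixation.
- **Bootstrap particle filter.** Particles start from the x₁ prior (uniform
  on [0,1] by default, restrictable to a subinterval), are weighted by the
  emission, resampled multinomially with replacement at every sampling time
  (systematic resampling is available behind a flag but off by default),
  and propagated by the Euler scheme. The marginal-likelihood estimate is
  the product over times of the mean pre-resampling weight, accumulated in
  log space with log-sum-exp. One smoothing trajectory is drawn by picking a
  final particle uniformly and tracing its stored ancestry. If every
  particle has zero emission weight at some time, the filter reports
  log p̂ = −∞ and the proposal is rejected.
- **PMMH.** Gaussian random-walk proposals on ϑ (independent components,
  symmetric, so proposal densities cancel); uniform priors (default
  [−1,1] per coefficient, [0,1] for h when co-estimated) enter only as
  support checks. Rejected iterations repeat the stored
  (ϑ, trajectory, log p̂) triple, so the three are always mutually
  consistent. Co-estimation of h uses the same machinery and is off by
  default.
- **Summaries.** Burn-in fraction 0.5 and thinning 5 by default. MAP is the
  retained draw maximizing a Gaussian KDE (Silverman bandwidth) — jointly
  over the selection coefficients for the headline estimate, per-marginal
  alongside; KDE evaluation is capped at 20,000 points by deterministic
  striding. HPD intervals are shortest sorted-sample windows (deterministic
  given the draws). Note that shortest windows at different masses need not
  nest exactly; for unimodal posteriors they nest up to order-statistic
  granularity. The trajectory estimate is the pointwise posterior mean with
  a pointwise HPD band.
- **Compiled kernels.** The Euler propagation, the particle filter, and the
  discrete Wright–Fisher simulator are numba kernels. The filter consumes
  normals and uniforms pre-drawn from the caller's `numpy.random.Generator`
  (normals in float32: the increment enters at O(√Δt), so single precision
  is far below scheme error); the Wright–Fisher kernel seeds numba's
  `np.random` from an integer drawn from the same Generator, because
  binomial parameters depend on the running state. A single integer seed
  therefore reproduces every simulation, filter run, and chain exactly.

## Mixing aids for short chains

Module defaults follow the plain algorithm: a single prior draw initializes
the chain and one proposal scale (σ = 0.01) is used throughout. Two optional
aids exist for reduced iteration budgets; neither changes the stationary
distribution.

- `init_theta` / `init_best_of`: the chain may start from an explicit point
  — typically `crude_selection_estimate`, a per-epoch linear regression of
  logit frequency (expected mutant dosage under the normalized likelihoods)
  on generation, using d logit x/dk = s(h+(1−2h)x) — and/or from the best of
  N prior draws. Candidates are scored by the **minimum of two** independent
  filter estimates: at implausible parameters the filter degenerates and a
  single estimate can spike upward by tens of log units, and a chain
  started on such a spike is stranded (we observed estimate valleys such as
  −380 ± 40 at intermediate parameter values separating a −97 basin from a
  −178 plateau). The initializer never enters the acceptance ratio.
- `burn_scales`: a wider proposal scale for the first half of the
  iterations (a fixed schedule, not history-dependent adaptation). Fine
  steps of σ = 0.005 match the ~0.003-wide posteriors of the simulation
  studies but cannot carry the chain across O(0.1) distances within a few
  hundred iterations.

## Synthetic data

The generator reproduces the validation conditions: 801 generations from
generation 0; bottleneck demography N = 32,000 / 8,000 / 16,000 switching at
generations 200 and 400 with reference size N₀ = 16,000; selection change at
τ = 350 with s⁻, s⁺ ~ U[−0.05, 0.05] (or fixed, or jointly constrained by a
scenario sampler); h = 0.5; x₁ ~ U[0.1, 0.9]; 10 individuals sampled every
40 generations (210 in total at 21 time points). The whole replicate —
coefficients, x₁, trajectory — is redrawn until the frequency at the final
sampling time is strictly inside (0,1); this retention rule conditions the
kept datasets on segregation, which is known to bias strong-|s| estimates
toward zero (the inference model is unconditioned), and is kept because it
defines the study conditions.

Genotype-likelihood noise is a Dirichlet(3) draw per individual with
concentration φψ at the true genotype and (1−φ)ψ/2 at the other two:
φ ∈ (⅓, 1] is the expected likelihood share of the truth (accuracy), ψ > 0
the concentration (peakedness). Calling at the 10× rule (top entry at least
ten times each other entry; ties are missing) maps (φ, ψ) onto missing and
error rates; per-dataset rates averaged over 1,000 replicates reproduce the
six reference scenarios (A–F) within Monte-Carlo error. Rates are invariant
to the underlying trajectory because the noise is index-symmetric about the
true genotype. What the Dirichlet abstraction does **not** emulate: read
depth, deamination damage patterns, reference bias, or contamination —
passing tests show correct behavior under this noise family, not under
every real aDNA artifact.

## Evaluation harness

Bias and RMSE compare MAP estimates with the simulated truth. The
selection-change test scores each replicate by the posterior probability of
the tested direction, P(Δs > 0) or P(Δs < 0); ROC curves sweep this score
over replicates with a true change (scenarios 3/6/9 for positive changes,
mirrored for negative) against no-change replicates (scenarios 2/5/8), and
AUC is the trapezoidal area (equivalently the normalized Mann–Whitney
statistic). Which scenarios pool into a panel is configurable; the defaults
above are logged by the harness.

## Problem sizes

Simulation-study defaults in this package are desk-scale: 2,000 PMMH
iterations with 500 particles for single-dataset inference, 600 iterations
with 150 particles across ≥25 replicates per class for the ROC study, and
1,000 iterations with 250 particles across 10 seeds for coverage checks,
always with the full 210-individual datasets and 5 Euler substeps. Larger
runs (e.g. 10,000–20,000 iterations with 1,000 particles, 200 replicates
per cell) are a configuration change, not a code change.

## Limitations

- The event time(s) τ, the demography, and (by default) h are prespecified,
  not estimated.
- All samples must postdate the mutation; `filter_pre_mutant` (off by
  default, logged when applied) drops sampling times before the first
  called mutant allele.
- Single biallelic locus; no migration, linkage, or epistasis.
- The diffusion is unconditioned on segregation while the simulator retains
  segregating replicates only, so strong-selection estimates are slightly
  attenuated by design.
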