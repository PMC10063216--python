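# tempsel

Bayesian inference of **temporally variable selection** from ancient-DNA
time series, working directly with **genotype likelihoods** instead of
called genotypes or allele-frequency counts.

Ancient-DNA samples are damaged, fragmented, and sparse: hard genotype calls
discard individuals with ambiguous reads and hard-code the errors of the
rest. `tempsel` models that uncertainty. Each sampled individual enters the
likelihood as a triple p(reads | g) for genotypes g = 0, 1, 2 copies of the
mutant allele, and the analysis marginalizes over the unobserved genotypes
and the unobserved population allele-frequency trajectory. Selection is
piecewise constant in time: a prespecified event time τ (say, the onset of
domestication) splits history into epochs with coefficients s⁻ and s⁺, and
the posterior of Δs = s⁺ − s⁻ tests whether the event changed selection.

## Model

A two-layer hidden Markov model:

- **Latent frequency.** The population mutant-allele frequency X(t) follows
  the Wright–Fisher diffusion with selection,

      dX(t) = α X(1−X) (h + (1−2h)X) dt + sqrt( X(1−X) / β(t) ) dW(t),

  with α = 2N₀s(t) the scaled selection coefficient, h the dominance of the
  mutant allele (h = ½: codominance), and β(t) = N(t)/N₀ a prespecified
  piecewise-constant demographic history. Time is measured in units of 2N₀
  generations; the diffusion is integrated by Euler–Maruyama with five
  substeps per generation.
- **Latent genotypes.** Individuals sampled in adulthood at time t_k are
  draws from the selection-reweighted Hardy–Weinberg proportions
  ((1−x)², 2(1+hs)x(1−x), (1+s)x²)/w̄.
- **Observations.** Each individual contributes its genotype-likelihood
  triple; the emission is the dot product with the genotype proportions.

Inference runs by **particle marginal Metropolis–Hastings (PMMH)**: a
bootstrap particle filter estimates the marginal likelihood p̂(r₁:K | ϑ) and
draws a smoothing trajectory; a Gaussian random-walk proposal over the
per-epoch selection coefficients is accepted with the pseudo-marginal ratio.
Outputs are posterior draws of (s⁻, s⁺, …), Δs, and the latent trajectory,
summarized as KDE-based MAP estimates, 95% highest-posterior-density (HPD)
intervals, and a pointwise trajectory band.

The package also ships the **simulator** used for validation (Wright–Fisher
truth, genotype sampling, Dirichlet(3) genotype-likelihood noise controlled
by an accuracy parameter φ and a concentration parameter ψ, genotype calling
at a 10× likelihood-ratio threshold) and the **evaluation harness**
(bias/RMSE of MAP estimates; ROC/AUC for the selection-change test).

## Worked example

Simulate an aDNA-quality dataset under a selection change and re-infer the
coefficients:

```python
import numpy as np
import tempsel as ts
from tempsel.core import SelectionSchedule, bottleneck_demography
from tempsel.pmmh import crude_selection_estimate, pmmh_run
from tempsel.posterior import summarize

rng = np.random.default_rng(7)

# a horse-style dataset: 210 ancient individuals, selection flips at
# generation 350, aDNA-quality likelihoods (scenario D: phi=0.85, psi=1.0)
config = ts.SimConfig(phi=0.85, psi=1.0, s_values=(0.02, -0.01))
dataset, truth = ts.generate_dataset(config, rng)
report = ts.quality_report(dataset, truth.genotypes)
print(f"dataset: {len(dataset)} individuals at {dataset.K} time points, "
      f"missing {report.missing_rate:.2f}, error {report.error_rate:.3f}")

template = SelectionSchedule((0.0, 0.0), change_times=(350,), dominance=0.5)
start = crude_selection_estimate(dataset, template.change_times, 0.5)
chain = pmmh_run(dataset, template, bottleneck_demography(),
                 n_iter=2000, M=500, scales=0.005, burn_scales=0.02,
                 init_theta=start, init_best_of=25, rng=rng)
summary = summarize(chain)  # burn-in 50%, thin 5
for p in summary.parameters:
    print(f"{p.name}: MAP {p.map:+.4f}, 95% HPD "
          f"[{p.hpd[0]:+.4f}, {p.hpd[1]:+.4f}]")
ch = summary.changes[0]
print(f"delta_s: MAP {ch['map']:+.4f}, P(delta_s < 0) = "
      f"{ch['prob_negative_change']:.3f}")
```

Output (about a minute):

```
dataset: 210 individuals at 21 time points, missing 0.32, error 0.021
s_epoch1: MAP +0.0183, 95% HPD [+0.0100, +0.0274]
s_epoch2: MAP -0.0019, 95% HPD [-0.0115, +0.0159]
delta_s: MAP -0.0165, P(delta_s < 0) = 0.965
```

Both 95% HPD intervals cover the simulated truth (s⁻ = 0.02, s⁺ = −0.01),
and the posterior puts 96.5% of its mass on a negative selection change —
the dataset alone, at ~32% missing genotypes, carries the signal of the
flip at generation 350.

The same pipeline is available from the shell:

```sh
tempsel simulate --scenario D --s-minus 0.02 --s-plus -0.01 --seed 7 --out sim
tempsel infer --config run.yaml --out run
tempsel summarize --chain run --out summary.json
tempsel evaluate --mode roc --scenario D --replicates 25 --seed 1 --out roc
```

Real data enter as a TSV of genotype likelihoods (`id generation gl0 gl1
gl2`), via VCF PL/GL fields (`tempsel.io.read_gl_vcf`), with calendar ages
converted by `tempsel.io.years_to_generations` (e.g. 8-year horse
generations anchored at the oldest sample).

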