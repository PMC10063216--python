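"""Synthetic aDNA-quality genotype-likelihood datasets.

The generator follows the two-step scheme used in the simulation studies:

1. Draw the per-epoch selection coefficients and the starting frequency,
   simulate the discrete Wright-Fisher trajectory forward, and redraw the
   whole replicate from scratch until the frequency at the final sampling
   time lies strictly inside (0, 1).
2. At each sampling time draw each individual's genotype from the
   selection-reweighted Hardy-Weinberg proportions, then draw its
   genotype-likelihood triple from a Dirichlet(3) whose concentration is
   phi*psi at the true genotype and (1-phi)*psi/2 at the other two.

phi in (1/3, 1] sets the expected likelihood share of the true genotype
(accuracy); psi > 0 sets the total concentration (peakedness). Together they
control the missing and error rates obtained when genotypes are called at a
10-fold likelihood-ratio threshold, which :func:`quality_report` measures.

Defaults reproduce the study conditions: 801 generations, a sample of 10
individuals every 40 generations (210 individuals at 21 time points), the
bottleneck demography, s- and s+ uniform on [-0.05, 0.05] changing at
generation 350, codominance, and x1 uniform on [0.1, 0.9].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (DemographicHistory, SelectionSchedule, Trajectory,
                   bottleneck_demography, simulate_wf_discrete)
from .emission import GLDataset, GLRecord, genotype_probabilities

#: Data-quality presets: (phi, psi) combinations of the simulation studies.
QUALITY_SCENARIOS = {
    "A": (0.75, 0.5),
    "B": (0.75, 1.0),
    "C": (0.85, 0.5),
    "D": (0.85, 1.0),
    "E": (0.95, 0.5),
    "F": (0.95, 1.0),
}

#: Selection-scenario presets: sign of s- and direction of the change at tau.
#: Signs: "-" drawn uniform on [-limit, 0), "0" exactly 0, "+" on (0, limit].
#: Changes: "down" s+ < s-, "none" s+ = s-, "up" s+ > s-.
SELECTION_SCENARIOS = {
    "1": ("-", "down"), "2": ("-", "none"), "3": ("-", "up"),
    "4": ("0", "down"), "5": ("0", "none"), "6": ("0", "up"),
    "7": ("+", "down"), "8": ("+", "none"), "9": ("+", "up"),
}


def draw_selection_scenario(name, rng, limit=0.05):
    """Draw (s-, s+) under a named selection scenario."""
    sign, change = SELECTION_SCENARIOS[str(name)]
    if sign == "-":
        s_minus = rng.uniform(-limit, 0.0)
    elif sign == "+":
        s_minus = rng.uniform(0.0, limit)
    else:
        s_minus = 0.0
    if change == "none":
        s_plus = s_minus
    elif change == "down":
        s_plus = rng.uniform(-limit, s_minus)
    else:
        s_plus = rng.uniform(s_minus, limit)
    return float(s_minus), float(s_plus)


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    ``s_values`` holds one entry per selection epoch: either a fixed
    coefficient (float) or a (lo, hi) range drawn uniformly per replicate.
    ``s_sampler``, if given, overrides ``s_values``: a callable
    ``rng -> coefficients`` drawn afresh on every retention attempt (used for
    selection scenarios that constrain the coefficients jointly).
    """

    phi: float = 0.85
    psi: float = 1.0
    s_values: tuple = ((-0.05, 0.05), (-0.05, 0.05))
    change_times: tuple = (350,)
    dominance: float = 0.5
    demography: DemographicHistory = field(default_factory=bottleneck_demography)
    x1_range: tuple = (0.1, 0.9)
    n_gen: int = 801
    sample_every: int = 40
    sample_size: int = 10
    max_attempts: int = 10000
    s_sampler: object = None

    def __post_init__(self):
        if not 1.0 / 3.0 < self.phi <= 1.0:
            raise ValueError("phi must lie in (1/3, 1]")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if len(self.s_values) != len(self.change_times) + 1:
            raise ValueError("need one s entry per epoch")
        if self.n_gen < 1 or self.sample_every < 1 or self.sample_size < 1:
            raise ValueError("n_gen, sample_every and sample_size must be >= 1")

    @property
    def sample_gens(self):
        return np.arange(0, self.n_gen, self.sample_every)

    def quality(self, scenario):
        """Copy of this config with a named (phi, psi) quality scenario."""
        phi, psi = QUALITY_SCENARIOS[scenario]
        return SimConfig(phi, psi, self.s_values, self.change_times,
                         self.dominance, self.demography, self.x1_range,
                         self.n_gen, self.sample_every, self.sample_size,
                         self.max_attempts, self.s_sampler)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    s_values: tuple
    x1: float
    trajectory: Trajectory
    sample_gens: np.ndarray
    genotypes: np.ndarray  # aligned with the dataset's record order


@dataclass
class QualityReport:
    """Missing and error rates under a likelihood-ratio calling threshold.

    ``error_rate`` is computed over called individuals only and is NaN when
    nothing is callable.
    """

    missing_rate: float
    error_rate: float


def draw_genotype(x, s, h, rng, size=None):
    """Categorical genotype draw(s) from the proportions at frequency x."""
    p = genotype_probabilities(x, s, h)
    u = rng.random(size)
    return np.searchsorted(np.cumsum(p)[:2], u, side="right")


def draw_gl(g, phi, psi, rng, size=None):
    """Dirichlet(3) genotype-likelihood triple(s) for true genotype g.

    Concentration is phi*psi at index g and (1-phi)*psi/2 elsewhere, so the
    expected likelihood share of the true genotype is phi. With ``size`` n,
    ``g`` may be an array of n genotypes; returns (n, 3).
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    g = np.broadcast_to(np.asarray(g, dtype=np.int64), (n,))
    alpha = np.full((n, 3), (1.0 - phi) * psi / 2.0)
    alpha[np.arange(n), g] = phi * psi
    draws = rng.gamma(alpha)
    # a Dirichlet draw is a normalized vector of independent gammas
    tot = draws.sum(axis=1, keepdims=True)
    while np.any(tot == 0):  # guard against underflow at tiny concentrations
        bad = tot[:, 0] == 0
        draws[bad] = rng.gamma(alpha[bad])
        tot = draws.sum(axis=1, keepdims=True)
    out = draws / tot
    return out[0] if scalar else out


def call_genotype(gl, threshold=10.0):
    """Call the top genotype iff it is >= threshold times each other entry.

    Returns -1 (missing) when the rule fails or the top entries tie.
    Accepts a triple or an (n, 3) array.
    """
    g = np.atleast_2d(np.asarray(gl, dtype=float))
    order = np.sort(g, axis=1)
    callable_ = order[:, 2] >= threshold * order[:, 1]
    calls = np.where(callable_, np.argmax(g, axis=1), -1)
    return int(calls[0]) if np.ndim(gl) == 1 else calls


def generate_dataset(config, rng):
    """Generate one (GLDataset, SimTruth) pair under ``config``.

    The replicate (coefficients, x1, trajectory) is redrawn from scratch
    until the frequency at the final sampling time is strictly in (0, 1);
    after ``config.max_attempts`` failures an error is raised.
    """
    gens = config.sample_gens
    last = int(gens[-1])
    for _ in range(config.max_attempts):
        if config.s_sampler is not None:
            coeffs = tuple(float(v) for v in config.s_sampler(rng))
        else:
            coeffs = tuple(
                float(v) if np.ndim(v) == 0 else float(rng.uniform(v[0], v[1]))
                for v in config.s_values)
        schedule = SelectionSchedule(coeffs, config.change_times, config.dominance)
        x1 = float(rng.uniform(*config.x1_range))
        traj = simulate_wf_discrete(schedule, config.demography, x1,
                                    config.n_gen, rng)
        if 0.0 < traj.freqs[last] < 1.0:
            break
    else:
        raise RuntimeError(
            f"no replicate with interior final frequency in {config.max_attempts} "
            f"attempts (s_values={config.s_values}, x1_range={config.x1_range})")

    records = []
    genotypes = np.empty(len(gens) * config.sample_size, dtype=np.int64)
    i = 0
    for k, g in enumerate(gens):
        x = traj.freqs[g]
        s = float(schedule.s_at(g))
        gt = draw_genotype(x, s, config.dominance, rng, size=config.sample_size)
        gl = draw_gl(gt, config.phi, config.psi, rng, size=config.sample_size)
        for j in range(config.sample_size):
            records.append(GLRecord(f"t{g}_n{j}", int(g), tuple(gl[j])))
            genotypes[i] = gt[j]
            i += 1
    dataset = GLDataset(records)
    truth = SimTruth(coeffs, x1, traj, gens.copy(),
                     genotypes[dataset.input_order()])
    return dataset, truth


def quality_report(dataset, truth_genotypes, threshold=10.0):
    """Missing/error rates of a dataset against its true genotypes."""
    gl, _, _ = dataset.packed()
    truth = np.asarray(truth_genotypes)
    if truth.shape[0] != gl.shape[0]:
        raise ValueError("truth genotypes must align with the dataset records")
    calls = call_genotype(gl, threshold)
    called = calls >= 0
    missing = 1.0 - called.mean()
    error = float(np.mean(calls[called] != truth[called])) if called.any() else np.nan
    return QualityReport(float(missing), error)


def quality_study(phi, psi, n_replicates, rng, config=None, threshold=10.0):
    """Per-dataset missing/error rates over replicate datasets.

    This is the data-quality accounting experiment: each replicate is a full
    dataset generated under the study conditions with the given (phi, psi),
    called at the likelihood-ratio threshold. Returns a DataFrame with one
    row per replicate.
    """
    if config is None:
        config = SimConfig()
    config = SimConfig(phi, psi, config.s_values, config.change_times,
                       config.dominance, config.demography, config.x1_range,
                       config.n_gen, config.sample_every, config.sample_size,
                       config.max_attempts, config.s_sampler)
    rows = []
    for _ in range(n_replicates):
        dataset, truth = generate_dataset(config, rng)
        rep = quality_report(dataset, truth.genotypes, threshold)
        rows.append((rep.missing_rate, rep.error_rate))
    return pd.DataFrame(rows, columns=["missing_rate", "error_rate"])


def flat_dataset(sample_gens, sample_size):
    """All-uninformative dataset: every record carries flat likelihoods."""
    records = [GLRecord(f"t{g}_n{j}", int(g), (1, 1, 1))
               for g in sample_gens for j in range(sample_size)]
    return GLDataset(records)
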