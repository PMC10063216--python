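"""Bootstrap particle filter over the latent allele-frequency trajectory.

The filter initializes particles from the starting-frequency prior at the
first sampling time, weights them by the emission, resamples multinomially
with replacement, and alternates diffusion propagation / weighting /
resampling across the remaining sampling times. It returns the standard
product estimator of the marginal likelihood (computed in log space from the
pre-resampling weights) and one smoothing draw of the trajectory, obtained by
uniformly choosing a final particle and tracing back its ancestry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import _bpf
from .core import Trajectory

log = logging.getLogger(__name__)


@dataclass
class ParticleSystem:
    """A weighted particle cloud at one time point."""

    states: np.ndarray
    log_weights: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if self.states.shape != self.log_weights.shape or self.states.size < 2:
            raise ValueError("need M >= 2 matched states and log-weights")
        if np.any((self.states < 0) | (self.states > 1)):
            raise ValueError("particle states must lie in [0, 1]")

    @property
    def M(self):
        return self.states.size

    def weights(self):
        """Normalized weights (sum to one); raises if all are zero."""
        mx = self.log_weights.max()
        if mx == -np.inf:
            raise ValueError("all particle weights are zero")
        w = np.exp(self.log_weights - mx)
        return w / w.sum()

    def ess(self):
        w = self.weights()
        return 1.0 / np.sum(w**2)


def resample(system, rng, scheme="multinomial"):
    """Resample M particles with replacement; returns (new system, ancestors).

    Multinomial resampling (the default) draws each ancestor independently
    with probability proportional to its weight; systematic resampling uses a
    single stratified uniform.
    """
    w = system.weights()
    M = system.M
    if scheme == "multinomial":
        ancestors = rng.choice(M, size=M, replace=True, p=w)
    elif scheme == "systematic":
        u = (rng.random() + np.arange(M)) / M
        ancestors = np.searchsorted(np.cumsum(w), u)
        ancestors[ancestors >= M] = M - 1
    else:
        raise ValueError(f"unknown resampling scheme: {scheme}")
    new = ParticleSystem(system.states[ancestors], np.zeros(M))
    return new, ancestors


@dataclass
class PFResult:
    """Marginal-likelihood estimate and one smoothing draw of the trajectory.

    ``sampled_trajectory`` is None when the filter collapsed (log_marginal is
    -inf because every particle had zero emission weight at some time point);
    callers must treat that as a rejected proposal.
    """

    log_marginal: float
    sampled_trajectory: Trajectory | None
    ess: np.ndarray


def bpf_run(dataset, schedule, demography, M=1000, substeps=5,
            x1_prior=(0.0, 1.0), rng=None, systematic=False):
    """Run the bootstrap particle filter on a genotype-likelihood dataset.

    Parameters
    ----------
    dataset : GLDataset
    schedule : SelectionSchedule (fully specified coefficients)
    demography : DemographicHistory
    M : particle count (>= 2)
    substeps : Euler-Maruyama steps per generation
    x1_prior : (lo, hi) uniform prior for the frequency at the first
        sampling time; default uniform on [0, 1]
    rng : numpy Generator supplying the seed for the compiled kernel
    systematic : use systematic instead of multinomial resampling
    """
    if M < 2:
        raise ValueError("particle count M must be >= 2")
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    lo, hi = float(x1_prior[0]), float(x1_prior[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("x1_prior must be a subinterval of [0, 1]")
    gl, offsets, gens = dataset.packed()
    n_gen = int(gens[-1]) + 1
    K = len(gens)
    n_steps = (int(gens[-1]) - int(gens[0])) * int(substeps)
    u_init = rng.random(M)
    # float32 increments halve RNG cost; each is promoted in the kernel and
    # contributes O(dt^(1/2)) so single precision is far below scheme error
    normals = rng.standard_normal((M, max(n_steps, 1)), dtype=np.float32)
    u_res = rng.random((K, M))
    u_final = rng.random()
    logm, path, ess = _bpf(int(M), gl, offsets, gens,
                           schedule.s_by_gen(n_gen),
                           demography.beta_by_gen(n_gen),
                           float(schedule.dominance), float(demography.N0),
                           int(substeps), lo, hi, bool(systematic),
                           u_init, normals, u_res, u_final)
    if not np.isfinite(logm):
        log.debug("particle filter collapsed (all weights zero)")
        return PFResult(-np.inf, None, ess)
    log.debug("bpf: log_marginal=%.4f min ESS=%.1f/%d", logm, ess.min(), M)
    return PFResult(float(logm), Trajectory(gens, path), ess)
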