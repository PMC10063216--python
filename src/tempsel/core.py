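"""Population-genetic state types and Wright-Fisher simulators.

Two forward models live here: the discrete Wright-Fisher model with viability
selection (binomial resampling of 2N(k) gametes per generation) and its
diffusion limit, integrated by the Euler-Maruyama scheme. Time is measured in
integer generations k >= 0; diffusion time is t = k / (2 N0) with N0 the
reference diploid size, so the scaled selection coefficient is alpha = 2 N0 s
and the population-size ratio beta(t) = N(t) / N0 enters the noise term.

Selection coefficients and population sizes are piecewise constant in
generations and evaluated at the left endpoint of each step; the lookup is
right-continuous at a change time tau (s(k) = s+ for k >= tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import _euler_paths, _wf_discrete


@dataclass(frozen=True)
class DemographicHistory:
    """Piecewise-constant diploid population size N(k) with reference size N0.

    Parameters
    ----------
    breakpoints : strictly increasing generation indices, first must be 0.
    sizes : diploid size per epoch, aligned with ``breakpoints``.
    N0 : reference diploid size used for the diffusion time scale.
    """

    breakpoints: tuple
    sizes: tuple
    N0: int

    def __post_init__(self):
        bp = tuple(int(b) for b in self.breakpoints)
        sz = tuple(int(n) for n in self.sizes)
        if len(bp) != len(sz) or not bp:
            raise ValueError("breakpoints and sizes must be equal-length and nonempty")
        if bp[0] != 0:
            raise ValueError("first breakpoint must be generation 0")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(n < 1 for n in sz) or self.N0 < 1:
            raise ValueError("population sizes and N0 must be >= 1")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "sizes", sz)
        object.__setattr__(self, "N0", int(self.N0))

    @classmethod
    def constant(cls, N, N0=None):
        return cls((0,), (N,), N if N0 is None else N0)

    def size_at(self, gen):
        i = np.searchsorted(self.breakpoints, gen, side="right") - 1
        return np.asarray(self.sizes)[i]

    def beta_at(self, gen):
        return self.size_at(gen) / self.N0

    def size_by_gen(self, n_gen):
        """Array of N(k) for k = 0 .. n_gen-1."""
        return np.asarray(self.size_at(np.arange(n_gen)), dtype=np.int64)

    def beta_by_gen(self, n_gen):
        return self.size_by_gen(n_gen) / self.N0


@dataclass(frozen=True)
class SelectionSchedule:
    """Piecewise-constant selection coefficients s(k) with dominance h.

    ``coefficients`` has one entry per epoch (one more than ``change_times``);
    the relative viabilities of genotypes 0/1/2 are 1, 1+hs, 1+s.
    """

    coefficients: tuple
    change_times: tuple = ()
    dominance: float = 0.5

    def __post_init__(self):
        ct = tuple(int(t) for t in self.change_times)
        co = tuple(float(s) for s in self.coefficients)
        if len(co) != len(ct) + 1:
            raise ValueError("need one coefficient per epoch (len(change_times)+1)")
        if any(t2 <= t1 for t1, t2 in zip(ct, ct[1:])):
            raise ValueError("change times must be strictly increasing")
        if any(s < -1.0 for s in co):
            raise ValueError("selection coefficients must be >= -1")
        if not 0.0 <= self.dominance <= 1.0:
            raise ValueError("dominance must lie in [0, 1]")
        object.__setattr__(self, "change_times", ct)
        object.__setattr__(self, "coefficients", co)
        object.__setattr__(self, "dominance", float(self.dominance))

    @property
    def n_epochs(self):
        return len(self.coefficients)

    def s_at(self, gen):
        """Right-continuous lookup: s(k) = s- for k < tau, s+ for k >= tau."""
        i = np.searchsorted(self.change_times, gen, side="right")
        return np.asarray(self.coefficients)[i]

    def s_by_gen(self, n_gen):
        return np.asarray(self.s_at(np.arange(n_gen)), dtype=float)

    def with_coefficients(self, coefficients):
        return SelectionSchedule(tuple(float(s) for s in coefficients),
                                 self.change_times, self.dominance)


@dataclass
class Trajectory:
    """Mutant-allele frequencies indexed by generation."""

    generations: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.generations.shape != self.freqs.shape:
            raise ValueError("generations and freqs must have matching length")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be increasing")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")

    def __len__(self):
        return len(self.generations)

    def at(self, gen):
        i = np.searchsorted(self.generations, gen)
        if i >= len(self.generations) or self.generations[i] != gen:
            raise KeyError(f"generation {gen} not on trajectory")
        return self.freqs[i]


def scaled_selection(s, N0):
    """Scaled selection coefficient alpha = 2 N0 s."""
    return 2.0 * N0 * s


def post_selection_freq(x, s, h):
    """Deterministic one-generation selection update of the mutant frequency.

    Returns [x^2 (1+s) + x(1-x)(1+hs)] / wbar with mean fitness
    wbar = (1-x)^2 + 2 x (1-x)(1+hs) + x^2 (1+s). Equals x when s = 0.
    """
    x = np.asarray(x, dtype=float)
    wbar = (1 - x) ** 2 + 2 * x * (1 - x) * (1 + h * s) + x**2 * (1 + s)
    assert np.all((wbar > 0) | (x == 0) | (x == 1)), "non-positive mean fitness"
    num = x**2 * (1 + s) + x * (1 - x) * (1 + h * s)
    out = np.where(x >= 1, 1.0, np.where(x <= 0, 0.0,
                   num / np.where(wbar > 0, wbar, 1.0)))
    return float(out) if np.ndim(out) == 0 else out


def simulate_wf_discrete(schedule, demography, x1, n_gen, rng):
    """Discrete Wright-Fisher trajectory of length ``n_gen`` starting at x1.

    Generation k+1 is Binomial(2 N(k+1), p) / (2 N(k+1)) with
    p = post_selection_freq(x_k, s(k), h). Boundaries 0 and 1 are absorbing.
    """
    if not 0.0 <= x1 <= 1.0:
        raise ValueError("x1 must lie in [0, 1]")
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    seed = int(rng.integers(1, 2**31))
    freqs = _wf_discrete(seed, float(x1), int(n_gen),
                         schedule.s_by_gen(n_gen),
                         demography.size_by_gen(n_gen),
                         float(schedule.dominance))
    return Trajectory(np.arange(n_gen), freqs)


def diffusion_propagate(x, gen_from, gen_to, schedule, demography,
                        substeps=5, rng=None):
    """Propagate frequency x from gen_from to gen_to under the diffusion.

    Applies (gen_to - gen_from) * substeps Euler-Maruyama steps of size
    dt = 1 / (2 N0 substeps) in diffusion time, with drift
    alpha x(1-x)(h + (1-2h)x) and noise sqrt(x(1-x)/beta(t)) dW, clamping the
    state into [0, 1] after every step. Accepts a scalar or 1-D array of
    start frequencies (one independent path per entry).
    """
    if gen_to <= gen_from:
        raise ValueError("gen_to must exceed gen_from")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((x_arr < 0) | (x_arr > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    n_steps = (gen_to - gen_from) * substeps
    normals = rng.standard_normal((x_arr.shape[0], n_steps))
    out = _euler_paths(x_arr, gen_from, gen_to, substeps,
                       schedule.s_by_gen(gen_to), demography.beta_by_gen(gen_to),
                       float(schedule.dominance), float(demography.N0), normals)
    return float(out[0]) if np.ndim(x) == 0 else out


#: Bottleneck demography used throughout the simulation studies: 32,000
#: diploids before generation 200, 8,000 until generation 400, then 16,000,
#: with reference size N0 = 16,000 (mimicking the horse population history).
def bottleneck_demography():
    return DemographicHistory(breakpoints=(0, 200, 400),
                              sizes=(32000, 8000, 16000), N0=16000)
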