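"""Particle marginal Metropolis-Hastings over the selection coefficients.

The parameter vector holds one selection coefficient per epoch of the
selection schedule (and optionally the dominance parameter). Each iteration
proposes a Gaussian random-walk move, runs a bootstrap particle filter at the
proposal to estimate the marginal likelihood and draw a latent trajectory,
and accepts with the pseudo-marginal ratio

    A = [p(theta') phat(r | theta')] / [p(theta) phat(r | theta)],

the proposal terms cancelling for the symmetric kernel. On rejection the
previous (theta, trajectory, log-marginal) triple is repeated, so stored
triples are always mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .particle import bpf_run

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Priors:
    """Independent uniform priors, one (lo, hi) interval per parameter."""

    intervals: tuple

    def __post_init__(self):
        iv = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        if not iv or any(hi <= lo for lo, hi in iv):
            raise ValueError("each prior interval must be nonempty")
        object.__setattr__(self, "intervals", iv)

    @classmethod
    def uniform_selection(cls, n_epochs, lo=-1.0, hi=1.0):
        """Default prior: uniform over [-1, 1] for every selection coefficient."""
        return cls(tuple((lo, hi) for _ in range(n_epochs)))

    @property
    def n_params(self):
        return len(self.intervals)

    def contains(self, theta):
        return all(lo <= v <= hi for v, (lo, hi) in zip(theta, self.intervals))

    def sample(self, rng):
        return np.array([rng.uniform(lo, hi) for lo, hi in self.intervals])


def crude_selection_estimate(dataset, change_times, dominance):
    """Moment-style starting point for the sampler: per-epoch logit-slope fit.

    Expected mutant dosage under the normalized genotype likelihoods gives a
    rough frequency estimate per sampling time; under the deterministic
    selection dynamics d logit(x)/dk = s (h + (1-2h) x), so a linear fit of
    logit frequency on generation within each epoch yields a crude s. Biased
    (GL noise shrinks dosages toward 1/2) but accurate enough to start the
    chain near the posterior basin; it never enters the acceptance ratio.
    """
    gl, offsets, gens = dataset.packed()
    xhat = np.empty(len(gens))
    for k in range(len(gens)):
        block = gl[offsets[k]:offsets[k + 1]]
        xhat[k] = np.mean(block[:, 1] * 0.5 + block[:, 2])
    xhat = np.clip(xhat, 0.02, 0.98)
    logit = np.log(xhat / (1 - xhat))
    bounds = [int(gens[0])] + [int(t) for t in change_times] + [int(gens[-1]) + 1]
    h = float(dominance)
    est = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (gens >= lo) & (gens < hi)
        if sel.sum() < 2:
            est.append(0.0)
            continue
        slope = np.polyfit(gens[sel], logit[sel], 1)[0]
        denom = h + (1 - 2 * h) * float(xhat[sel].mean())
        if abs(denom) < 0.1:
            denom = np.sign(denom) * 0.1 if denom != 0 else 0.1
        est.append(float(np.clip(slope / denom, -0.95, 0.95)))
    return np.array(est)


def propose(theta, scales, rng):
    """Symmetric Gaussian random-walk proposal."""
    theta = np.asarray(theta, dtype=float)
    scales = np.broadcast_to(np.asarray(scales, dtype=float), theta.shape)
    if np.any(scales < 0):
        raise ValueError("proposal scales must be >= 0")
    return theta + scales * rng.standard_normal(theta.shape)


def acceptance_ratio(log_marginal_prop, log_marginal_cur,
                     log_prior_prop=0.0, log_prior_cur=0.0):
    """Pseudo-marginal MH ratio A for a symmetric proposal kernel."""
    return float(np.exp((log_prior_prop - log_prior_cur)
                        + (log_marginal_prop - log_marginal_cur)))


@dataclass
class Chain:
    """PMMH draws: parameters, latent trajectories, and log marginals."""

    param_names: list
    sample_gens: np.ndarray
    thetas: np.ndarray          # (n_iter, P)
    trajectories: np.ndarray    # (n_iter, K)
    log_marginals: np.ndarray   # (n_iter,)
    accepted: np.ndarray        # (n_iter,) bool; first entry counts as accepted

    @property
    def n_iter(self):
        return self.thetas.shape[0]

    @property
    def acceptance_count(self):
        return int(self.accepted[1:].sum())

    @property
    def acceptance_rate(self):
        return self.acceptance_count / max(self.n_iter - 1, 1)


def pmmh_run(dataset, schedule_template, demography, priors=None, n_iter=10000,
             M=1000, scales=0.01, substeps=5, x1_prior=(0.0, 1.0), rng=None,
             estimate_h=False, init_redraws=100, init_best_of=1,
             init_theta=None, burn_scales=None, burn_iters=None, log_every=0):
    """Run PMMH and return the Chain.

    Parameters
    ----------
    schedule_template : SelectionSchedule carrying the change times and
        dominance; its coefficients are overwritten by the sampled values.
    priors : Priors for the sampled parameters (selection coefficients in
        epoch order, then h if ``estimate_h``); defaults to uniform [-1, 1]
        per coefficient (and uniform [0, 1] for h).
    scales : per-parameter random-walk standard deviations (scalar or array).
    estimate_h : include the dominance parameter in the sampled vector.
    init_redraws : prior redraws allowed before aborting when the initial
        particle filter keeps collapsing.
    init_best_of : score this many prior draws with the particle filter and
        start from the best. The default (1) starts from a single prior
        draw; short runs benefit from a larger value, which only shortens
        burn-in and leaves the chain's target unchanged.
    init_theta : optional explicit starting point (e.g. from
        :func:`crude_selection_estimate`), scored against the prior-draw
        candidates; must lie inside the prior support to be used.
    burn_scales : optional wider proposal scales used for the first
        ``burn_iters`` iterations (default: the first half). The schedule is
        fixed in advance, so each phase is a valid Metropolis kernel for the
        same target; summaries discard the wide-step phase as burn-in.
        Useful for short runs, where fine steps alone cannot carry the chain
        from a prior draw to the posterior mass.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_epochs = schedule_template.n_epochs
    names = [f"s_epoch{i + 1}" for i in range(n_epochs)]
    if priors is None:
        intervals = [(-1.0, 1.0)] * n_epochs
        if estimate_h:
            intervals.append((0.0, 1.0))
        priors = Priors(tuple(intervals))
    if estimate_h:
        names = names + ["h"]
    if priors.n_params != len(names):
        raise ValueError("prior dimension does not match sampled parameters")

    def build_schedule(theta):
        sched = schedule_template.with_coefficients(theta[:n_epochs])
        if estimate_h:
            sched = type(sched)(sched.coefficients, sched.change_times,
                                float(theta[n_epochs]))
        return sched

    def run_pf(theta):
        return bpf_run(dataset, build_schedule(theta), demography, M=M,
                       substeps=substeps, x1_prior=x1_prior, rng=rng)

    K = dataset.K
    thetas = np.empty((n_iter, priors.n_params))
    trajs = np.empty((n_iter, K))
    logms = np.empty(n_iter)
    accepted = np.zeros(n_iter, dtype=bool)

    # Initialization: an optional explicit start (init_theta) plus prior
    # draws compete as candidates. When several candidates are scored, each
    # finite one is ranked by the smaller of two independent filter
    # estimates: a single estimate can spike upward by many log units at
    # implausible parameters, and starting the chain on such a spike strands
    # it. The winning candidate's conservative estimate seeds the chain.
    theta, cur, best = None, None, -np.inf
    budget = max(int(init_best_of), 1)
    seeded = []
    if init_theta is not None and priors.contains(np.asarray(init_theta, float)):
        seeded.append(np.asarray(init_theta, dtype=float))
    score_twice = budget > 1 or bool(seeded)
    attempts = 0
    while seeded or attempts < budget \
            or (theta is None and attempts < init_redraws):
        if seeded:
            cand = seeded.pop()
        else:
            cand = priors.sample(rng)
            attempts += 1
        res = run_pf(cand)
        if not np.isfinite(res.log_marginal):
            continue
        if score_twice:
            res2 = run_pf(cand)
            if not np.isfinite(res2.log_marginal):
                continue
            if res2.log_marginal < res.log_marginal:
                res = res2
        if res.log_marginal > best:
            theta, cur, best = cand, res, res.log_marginal
    if theta is None:
        raise RuntimeError(
            f"initial particle filter collapsed for {init_redraws} prior draws; "
            "check the data/model compatibility")
    thetas[0], trajs[0], logms[0] = theta, cur.sampled_trajectory.freqs, cur.log_marginal
    accepted[0] = True

    if burn_iters is None:
        burn_iters = n_iter // 2
    n_acc = 0
    for i in range(1, n_iter):
        step = scales if burn_scales is None or i > burn_iters else burn_scales
        cand = propose(theta, step, rng)
        ok = False
        if priors.contains(cand):
            res = run_pf(cand)
            if np.isfinite(res.log_marginal):
                log_a = res.log_marginal - cur.log_marginal  # uniform priors cancel
                ok = np.log(rng.random()) < log_a
        if ok:
            theta, cur = cand, res
            n_acc += 1
        thetas[i] = theta
        trajs[i] = cur.sampled_trajectory.freqs
        logms[i] = cur.log_marginal
        accepted[i] = ok
        if log_every and i % log_every == 0:
            log.info("pmmh iter %d/%d acc_rate=%.3f log_marginal=%.3f",
                     i, n_iter, n_acc / i, cur.log_marginal)

    chain = Chain(names, dataset.sample_gens.copy(), thetas, trajs, logms, accepted)
    log.info("pmmh finished: %d iterations, acceptance rate %.3f",
             n_iter, chain.acceptance_rate)
    return chain
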