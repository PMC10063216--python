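"""Posterior post-processing: burn-in/thinning, MAP, HPD, selection-change
summaries, and the latent-trajectory band.

MAP estimates come from a Gaussian kernel density estimate (Silverman
bandwidth) evaluated at the retained draws themselves; the headline MAP uses
the joint density over all selection coefficients, with per-marginal MAPs
reported alongside. HPD intervals are the shortest sorted-sample windows
containing the target mass, which is deterministic given the draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .pmmh import Chain


@dataclass
class PosteriorDraws:
    """Retained draws after burn-in and thinning."""

    param_names: list
    sample_gens: np.ndarray
    thetas: np.ndarray        # (n, P)
    trajectories: np.ndarray  # (n, K)

    @property
    def n(self):
        return self.thetas.shape[0]

    def param(self, name):
        return self.thetas[:, self.param_names.index(name)]


def burn_thin(chain, burn_fraction=0.5, thin=5):
    """Drop the first ``burn_fraction`` of draws, keep every ``thin``-th.

    Defaults follow common practice for these chains: discard the first half
    and keep every fifth value.
    """
    if not 0.0 <= burn_fraction < 1.0:
        raise ValueError("burn_fraction must lie in [0, 1)")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if isinstance(chain, Chain):
        n = chain.n_iter
        idx = np.arange(int(np.floor(burn_fraction * n)), n, thin)
        if idx.size == 0:
            raise ValueError("no draws retained after burn-in/thinning")
        return PosteriorDraws(list(chain.param_names), chain.sample_gens.copy(),
                              chain.thetas[idx], chain.trajectories[idx])
    arr = np.asarray(chain)
    idx = np.arange(int(np.floor(burn_fraction * arr.shape[0])), arr.shape[0], thin)
    if idx.size == 0:
        raise ValueError("no draws retained after burn-in/thinning")
    return arr[idx]


def map_estimate(samples):
    """MAP from a Gaussian KDE (Silverman bandwidth) over the draws.

    ``samples`` is (n,) for a single parameter or (n, P) for a joint
    estimate; the MAP is the sample point maximizing the estimated density
    (ties broken by first occurrence). Zero-variance draws return the common
    value directly.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        return np.asarray(samples, dtype=float).reshape(-1)[:x.shape[1]].squeeze()
    if np.allclose(x.std(axis=0), 0):
        out = x[0]
        return float(out[0]) if out.size == 1 else out
    # KDE evaluation is quadratic in the draw count; cap with a deterministic
    # stride (harmless for MCMC output, which is thinned anyway)
    if x.shape[0] > 20000:
        x = x[:: int(np.ceil(x.shape[0] / 20000))]
    try:
        kde = gaussian_kde(x.T, bw_method="silverman")
        dens = kde(x.T)
    except np.linalg.LinAlgError:
        # singular joint covariance: fall back to per-marginal MAPs
        return np.array([map_estimate(x[:, j]) for j in range(x.shape[1])])
    best = x[np.argmax(dens)]
    return float(best[0]) if best.size == 1 else best


def hpd_interval(samples, mass=0.95):
    """Shortest contiguous interval of sorted draws containing ``mass``."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def change_summary(s_minus, s_plus):
    """Posterior draws of ds = s+ - s- and the sign probabilities.

    Returns (ds draws, P(ds > 0), P(ds < 0)); draws exactly at zero count
    toward neither probability.
    """
    s_minus = np.asarray(s_minus, dtype=float)
    s_plus = np.asarray(s_plus, dtype=float)
    if s_minus.shape != s_plus.shape:
        raise ValueError("paired draws required")
    ds = s_plus - s_minus
    return ds, float(np.mean(ds > 0)), float(np.mean(ds < 0))


def trajectory_posterior(trajectories, mass=0.95):
    """Pointwise posterior mean and HPD band of the latent trajectory.

    ``trajectories`` is (n draws, K time points); returns (mean, lower,
    upper) arrays of length K.
    """
    t = np.asarray(trajectories, dtype=float)
    if t.ndim != 2:
        raise ValueError("expected an (n_draws, K) array")
    mean = t.mean(axis=0)
    bounds = np.array([hpd_interval(t[:, k], mass) for k in range(t.shape[1])])
    return mean, bounds[:, 0], bounds[:, 1]


@dataclass
class ParameterSummary:
    name: str
    map: float
    marginal_map: float
    mean: float
    hpd: tuple
    prob_positive: float


@dataclass
class PosteriorSummary:
    """Structured report of a PMMH run after burn-in and thinning."""

    parameters: list
    changes: list            # one dict per adjacent epoch pair
    sample_gens: np.ndarray
    traj_mean: np.ndarray
    traj_lower: np.ndarray
    traj_upper: np.ndarray
    n_draws: int

    def to_dict(self):
        return {
            "n_draws": self.n_draws,
            "parameters": [
                {"name": p.name, "map": p.map, "marginal_map": p.marginal_map,
                 "mean": p.mean, "hpd_lower": p.hpd[0], "hpd_upper": p.hpd[1],
                 "prob_positive": p.prob_positive}
                for p in self.parameters
            ],
            "changes": self.changes,
            "trajectory": {
                "generation": self.sample_gens.tolist(),
                "mean": self.traj_mean.tolist(),
                "hpd_lower": self.traj_lower.tolist(),
                "hpd_upper": self.traj_upper.tolist(),
            },
        }


def summarize(chain, burn_fraction=0.5, thin=5, mass=0.95):
    """Full posterior report: per-parameter MAP/mean/HPD, per-change-point
    ds summaries, and the trajectory band."""
    draws = burn_thin(chain, burn_fraction, thin)
    sel_names = [n for n in draws.param_names if n.startswith("s_epoch")]
    sel = np.column_stack([draws.param(n) for n in sel_names])
    joint = np.atleast_1d(map_estimate(sel))
    params = []
    for j, name in enumerate(draws.param_names):
        x = draws.thetas[:, j]
        params.append(ParameterSummary(
            name=name,
            map=float(joint[j]) if j < joint.size and name in sel_names
                else float(map_estimate(x)),
            marginal_map=float(map_estimate(x)),
            mean=float(x.mean()),
            hpd=hpd_interval(x, mass),
            prob_positive=float(np.mean(x > 0)),
        ))
    changes = []
    for j in range(len(sel_names) - 1):
        ds, p_pos, p_neg = change_summary(sel[:, j], sel[:, j + 1])
        lo, hi = hpd_interval(ds, mass)
        changes.append({
            "epochs": (sel_names[j], sel_names[j + 1]),
            "map": float(map_estimate(ds)),
            "mean": float(ds.mean()),
            "hpd_lower": lo, "hpd_upper": hi,
            "prob_positive_change": p_pos,
            "prob_negative_change": p_neg,
        })
    mean, lower, upper = trajectory_posterior(draws.trajectories, mass)
    return PosteriorSummary(params, changes, draws.sample_gens,
                            mean, lower, upper, draws.n)
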