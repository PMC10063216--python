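"""Performance metrics and simulation-study harnesses.

Estimation accuracy is summarized by the bias and RMSE of MAP estimates
against the simulated truth. The selection-change test is scored by the
posterior probability of the tested change direction (P(ds > 0) or
P(ds < 0)); sweeping that probability as a classification threshold over
replicates with and without a true change yields an ROC curve, summarized by
the trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .pmmh import Priors, crude_selection_estimate, pmmh_run
from .posterior import summarize
from .simulate import SimConfig, draw_selection_scenario, generate_dataset


@dataclass
class EvalRecord:
    """One replicate of the change-detection study."""

    s_minus_true: float
    s_plus_true: float
    label: bool     # did a change truly occur (in the tested direction)?
    score: float    # posterior probability of the tested change direction
    map_s_minus: float
    map_s_plus: float


def bias_rmse(estimates, truths):
    """(mean(estimate - truth), root mean squared deviation)."""
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape or e.size == 0:
        raise ValueError("estimates and truths must be equal-length and nonempty")
    d = e - t
    return float(d.mean()), float(np.sqrt(np.mean(d**2)))


def roc_auc(scores, labels):
    """ROC points and trapezoidal AUC for a binary classification score.

    Thresholds sweep all distinct scores (tied scores grouped); requires
    both classes present. Returns (DataFrame[threshold, fpr, tpr], auc).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, auc


def infer_dataset(dataset, config, n_iter=2000, M=500, scales=0.005,
                  substeps=5, burn_fraction=0.5, thin=5, rng=None,
                  prior_limit=1.0, init_best_of=25, burn_scales=0.02):
    """Run PMMH on one dataset and summarize (convenience for the harnesses)."""
    from .core import SelectionSchedule
    sched = SelectionSchedule(tuple(0.0 for _ in config.s_values),
                              config.change_times, config.dominance)
    priors = Priors.uniform_selection(sched.n_epochs, -prior_limit, prior_limit)
    start = crude_selection_estimate(dataset, config.change_times,
                                     config.dominance)
    chain = pmmh_run(dataset, sched, config.demography, priors=priors,
                     n_iter=n_iter, M=M, scales=scales, substeps=substeps,
                     rng=rng, init_best_of=init_best_of, init_theta=start,
                     burn_scales=burn_scales)
    return summarize(chain, burn_fraction, thin)


def change_detection_study(n_alt, n_null, phi, psi, direction="positive",
                           alt_scenarios=("3", "6", "9"),
                           null_scenarios=("2", "5", "8"),
                           n_iter=2000, M=500, scales=0.005, substeps=5,
                           rng=None, config=None):
    """Replicated generate -> infer -> score experiment for the change test.

    Alternatives are drawn by cycling over ``alt_scenarios`` (selection
    scenarios with a change in the tested direction), nulls over
    ``null_scenarios`` (no change). Returns a DataFrame of EvalRecords; feed
    its score/label columns to :func:`roc_auc`.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if config is None:
        config = SimConfig(phi=phi, psi=psi)
    rows = []
    plan = ([(True, alt_scenarios[i % len(alt_scenarios)]) for i in range(n_alt)]
            + [(False, null_scenarios[i % len(null_scenarios)]) for i in range(n_null)])
    for label, scen in plan:
        def sampler(r, scen=scen, flip=(direction == "negative" and label)):
            # redrawn on every retention attempt, as in the generation scheme;
            # the scenario grid encodes "up" changes, mirrored for negatives
            s_minus, s_plus = draw_selection_scenario(scen, r)
            return (-s_minus, -s_plus) if flip else (s_minus, s_plus)
        cfg = SimConfig(phi, psi, config.s_values, config.change_times,
                        config.dominance, config.demography, config.x1_range,
                        config.n_gen, config.sample_every, config.sample_size,
                        config.max_attempts, sampler)
        dataset, truth = generate_dataset(cfg, rng)
        summ = infer_dataset(dataset, cfg, n_iter=n_iter, M=M, scales=scales,
                             substeps=substeps, rng=rng)
        ch = summ.changes[0]
        score = (ch["prob_positive_change"] if direction == "positive"
                 else ch["prob_negative_change"])
        rows.append(EvalRecord(truth.s_values[0], truth.s_values[1], label,
                               score, summ.parameters[0].map,
                               summ.parameters[1].map))
    return pd.DataFrame([r.__dict__ for r in rows])


def estimation_study(n_replicates, phi, psi, scenario="5", n_iter=2000, M=500,
                     scales=0.005, substeps=5, rng=None, config=None):
    """Replicated generate -> infer experiment for bias/RMSE of the MAPs."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if config is None:
        config = SimConfig(phi=phi, psi=psi)
    rows = []
    sampler = lambda r: draw_selection_scenario(scenario, r)
    for _ in range(n_replicates):
        cfg = SimConfig(phi, psi, config.s_values, config.change_times,
                        config.dominance, config.demography, config.x1_range,
                        config.n_gen, config.sample_every, config.sample_size,
                        config.max_attempts, sampler)
        dataset, truth = generate_dataset(cfg, rng)
        summ = infer_dataset(dataset, cfg, n_iter=n_iter, M=M, scales=scales,
                             substeps=substeps, rng=rng)
        rows.append({"s_minus_true": truth.s_values[0],
                     "s_plus_true": truth.s_values[1],
                     "map_s_minus": summ.parameters[0].map,
                     "map_s_plus": summ.parameters[1].map})
    return pd.DataFrame(rows)
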