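"""Observation model: from population allele frequency to genotype likelihoods.

Each sampled individual contributes a genotype-likelihood triple
gl = (p(reads | g=0), p(reads | g=1), p(reads | g=2)). Marginalizing the
latent genotype against the population genotype proportions at the sampling
time gives the per-individual emission probability; records at a time point
are conditionally independent given the population frequency, so the
time-point log emission is a sum of logs of dot products.

Individuals are assumed sampled in adulthood (after selection), so the
genotype proportions at frequency x are Hardy-Weinberg weights reweighted by
the viabilities 1, 1+hs, 1+s of the selection coefficient in force at the
sampling generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: genotype-likelihood triple of an individual with no usable reads
FLAT_GL = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


def genotype_probabilities(x, s, h):
    """Genotype proportions ((1-x)^2, 2(1+hs)x(1-x), (1+s)x^2) / wbar.

    Entries are nonnegative and sum to one; x may be a scalar or array
    (trailing axis of the result indexes the genotype).
    """
    x = np.asarray(x, dtype=float)
    a = (1 - x) ** 2
    b = 2 * (1 + h * s) * x * (1 - x)
    c = (1 + s) * x**2
    w = a + b + c
    safe = np.where(w > 0, w, 1.0)
    out = np.stack([a / safe, b / safe, c / safe], axis=-1)
    # x=1 with s=-1 degenerates (lethal homozygote at fixation): keep g=2
    out = np.where((w == 0)[..., None], np.array([0.0, 0.0, 1.0]), out)
    return out


def individual_emission(gl, geno_probs):
    """p(reads | x) = sum_g gl[g] * p(g | x): the dot product of the triples."""
    return float(np.dot(np.asarray(gl, dtype=float),
                        np.asarray(geno_probs, dtype=float)))


@dataclass(frozen=True)
class GLRecord:
    """One sampled individual: id, sampling generation, genotype likelihoods."""

    individual_id: str
    generation: int
    gl: tuple

    def __post_init__(self):
        g = np.asarray(self.gl, dtype=float)
        if g.shape != (3,):
            raise ValueError(f"record {self.individual_id}: gl must have 3 entries")
        if np.any(g < 0):
            raise ValueError(f"record {self.individual_id}: negative genotype likelihood")
        tot = g.sum()
        if tot <= 0:
            raise ValueError(f"record {self.individual_id}: all-zero genotype likelihoods")
        if self.generation < 0:
            raise ValueError(f"record {self.individual_id}: negative sampling generation")
        object.__setattr__(self, "gl", tuple(g / tot))


class GLDataset:
    """Time-stamped genotype-likelihood records grouped by sampling generation.

    Records are kept sorted by sampling generation (stable, so the order
    within a time point is the input order). Exposes the sorted distinct
    sampling generations t_1 < ... < t_K and the per-time record blocks.
    """

    def __init__(self, records):
        records = list(records)
        if not records:
            raise ValueError("dataset must contain at least one record")
        order = np.argsort([r.generation for r in records], kind="stable")
        self.records = [records[i] for i in order]
        self._order = order
        gens = np.array([r.generation for r in self.records], dtype=np.int64)
        self.sample_gens, self.counts = np.unique(gens, return_counts=True)
        self._offsets = np.concatenate([[0], np.cumsum(self.counts)]).astype(np.int64)
        self._gl = np.array([r.gl for r in self.records], dtype=float)

    @property
    def K(self):
        return len(self.sample_gens)

    def __len__(self):
        return len(self.records)

    def gl_at(self, k):
        """(N_k, 3) genotype-likelihood block of time point k."""
        return self._gl[self._offsets[k]:self._offsets[k + 1]]

    def packed(self):
        """(gl matrix, per-time offsets, sampling generations) for the kernels."""
        return self._gl, self._offsets, self.sample_gens

    def input_order(self):
        """Permutation mapping constructor input order to stored order."""
        return self._order

    @classmethod
    def from_frame(cls, df):
        return cls(GLRecord(str(r.id), int(r.generation),
                            (r.gl0, r.gl1, r.gl2))
                   for r in df.itertuples(index=False))

    def to_frame(self):
        return pd.DataFrame({
            "id": [r.individual_id for r in self.records],
            "generation": [r.generation for r in self.records],
            "gl0": self._gl[:, 0],
            "gl1": self._gl[:, 1],
            "gl2": self._gl[:, 2],
        })


def timepoint_log_emission(dataset, k, x, schedule):
    """log p(r_k | x_k): sum over the N_k individuals at time point k.

    Returns -inf when some individual's emission is zero (impossible state).
    """
    s = float(schedule.s_at(dataset.sample_gens[k]))
    probs = genotype_probabilities(x, s, schedule.dominance)
    w = dataset.gl_at(k) @ probs
    if np.any(w <= 0):
        return -np.inf
    return float(np.sum(np.log(w)))
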