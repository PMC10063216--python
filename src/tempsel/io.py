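"""File formats, calendar-time conversion, and run configuration.

All tables are plain TSV so they remain diff-able and round-trip through the
package's own readers. Generations are the canonical internal time unit;
calendar years appear only at this boundary and are converted with an
explicit generation time and anchor year (the anchor maps to generation 0,
so BC/AD bookkeeping never enters the core).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .core import DemographicHistory
from .emission import GLDataset, GLRecord
from .pmmh import Chain

GL_COLUMNS = ["id", "generation", "gl0", "gl1", "gl2"]


def read_gl_table(path):
    """Read a genotype-likelihood TSV (columns id, generation, gl0..gl2)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            records.append(GLRecord(str(r.id), int(r.generation),
                                    (r.gl0, r.gl1, r.gl2)))
        except ValueError as e:
            raise ValueError(f"{path}: row {i + 1}: {e}") from e
    return GLDataset(records)


def write_gl_table(dataset, path):
    dataset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_demography(path, N0):
    """Read a demography TSV (columns start_gen, N) plus the reference size."""
    df = pd.read_csv(path, sep="\t")
    for c in ("start_gen", "N"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return DemographicHistory(tuple(int(v) for v in df["start_gen"]),
                              tuple(int(v) for v in df["N"]), int(N0))


def write_demography(demography, path):
    pd.DataFrame({"start_gen": demography.breakpoints,
                  "N": demography.sizes}).to_csv(path, sep="\t", index=False)


def read_gl_vcf(path, site=None, mutant_is_ref=False, scale="phred",
                generations=None):
    """Import genotype likelihoods for one biallelic site from a VCF.

    PL fields ("phred") convert by 10**(-PL/10); GL fields ("log10") by
    10**GL; triples are then normalized. The mutant allele is ALT unless
    ``mutant_is_ref``. ``generations`` maps sample id -> sampling generation
    (required, since VCF carries no sampling times). ``site`` selects
    "CHROM:POS"; default is the first biallelic record.
    """
    from cyvcf2 import VCF  # optional dependency, only needed here
    if generations is None:
        raise ValueError("a sample-id -> generation mapping is required")
    if scale not in ("phred", "log10"):
        raise ValueError("scale must be 'phred' or 'log10'")
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if site is not None and f"{var.CHROM}:{var.POS}" != site:
            continue
        if scale == "phred":
            pl = np.asarray(var.format("PL"), dtype=float)
            lik = np.power(10.0, -pl / 10.0)
        else:
            gl10 = np.asarray(var.format("GL"), dtype=float)
            lik = np.power(10.0, gl10)
        if mutant_is_ref:
            lik = lik[:, ::-1]
        records = []
        for name, triple in zip(samples, lik):
            if name not in generations:
                raise ValueError(f"no sampling generation for sample {name}")
            records.append(GLRecord(name, int(generations[name]), tuple(triple)))
        return GLDataset(records)
    raise ValueError(f"{path}: no matching biallelic site found")


def years_to_generations(years, generation_time=8.0, anchor=None):
    """Convert calendar years to generation indices.

    ``years`` and ``anchor`` use one numeric convention (e.g., negative for
    BC or years before present with a sign); the anchor year maps to
    generation 0 and later years to larger indices, rounding half away from
    zero. Samples older than the anchor raise.
    """
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    y = np.asarray(years, dtype=float)
    if anchor is None:
        anchor = float(np.min(y))
    if np.any(y < anchor):
        raise ValueError("sample predates the anchor year")
    gens = np.floor((y - anchor) / generation_time + 0.5).astype(np.int64)
    return int(gens) if np.ndim(years) == 0 else gens


def filter_pre_mutant(dataset, threshold=10.0):
    """Drop records sampled before the mutant allele is first called.

    The first retained time point is the earliest whose records include a
    called genotype carrying at least one mutant copy; used when the data
    may predate the mutation (off by default in the pipeline).
    """
    from .simulate import call_genotype
    gl, offsets, gens = dataset.packed()
    calls = call_genotype(gl, threshold)
    first = None
    for k, g in enumerate(gens):
        if np.any(calls[offsets[k]:offsets[k + 1]] >= 1):
            first = g
            break
    if first is None:
        raise ValueError("mutant allele never called in the dataset")
    kept = [r for r in dataset.records if r.generation >= first]
    return GLDataset(kept)


def write_chain(chain, path_prefix):
    """Write a chain as <prefix>.chain.tsv plus <prefix>.traj.tsv."""
    df = pd.DataFrame(chain.thetas, columns=chain.param_names)
    df.insert(0, "iter", np.arange(1, chain.n_iter + 1))
    df["log_marginal"] = chain.log_marginals
    df["accepted"] = chain.accepted.astype(int)
    df.to_csv(f"{path_prefix}.chain.tsv", sep="\t", index=False,
              float_format="%.10g")
    traj = pd.DataFrame(chain.trajectories,
                        columns=[f"gen{g}" for g in chain.sample_gens])
    traj.insert(0, "iter", np.arange(1, chain.n_iter + 1))
    traj.to_csv(f"{path_prefix}.traj.tsv", sep="\t", index=False,
                float_format="%.10g")


def read_chain(path_prefix):
    df = pd.read_csv(f"{path_prefix}.chain.tsv", sep="\t")
    traj = pd.read_csv(f"{path_prefix}.traj.tsv", sep="\t")
    names = [c for c in df.columns if c not in ("iter", "log_marginal", "accepted")]
    gens = np.array([int(c[3:]) for c in traj.columns if c.startswith("gen")])
    return Chain(names, gens, df[names].to_numpy(float),
                 traj[[c for c in traj.columns if c.startswith("gen")]].to_numpy(float),
                 df["log_marginal"].to_numpy(float),
                 df["accepted"].to_numpy(bool))


def write_summary(summary, path):
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)


def write_truth(truth, path):
    pd.DataFrame({
        "generation": truth.trajectory.generations,
        "freq": truth.trajectory.freqs,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class RunConfig:
    """Inference-run configuration, loadable from YAML."""

    data: str
    demography: str | None = None
    N0: int = 16000
    change_times: tuple = ()
    dominance: float = 0.5
    x1_prior: tuple = (0.0, 1.0)
    iterations: int = 10000
    particles: int = 1000
    substeps: int = 5
    scales: float = 0.01
    prior_limit: float = 1.0
    burn_fraction: float = 0.5
    thin: int = 5
    init_best_of: int = 1
    seed: int = 1

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.change_times = tuple(cfg.change_times)
        cfg.x1_prior = tuple(cfg.x1_prior)
        return cfg

    def digest(self):
        """Short stable hash of the configuration, for run logging."""
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
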