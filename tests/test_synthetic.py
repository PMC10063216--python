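"""Synthetic-data generator: genotype sampling, Dirichlet likelihood noise,
calling rule, retention scheme, and quality accounting."""

import numpy as np
import pytest

from tempsel.emission import GLDataset, GLRecord
from tempsel.simulate import (QUALITY_SCENARIOS, SimConfig, call_genotype,
                              draw_genotype, draw_gl, draw_selection_scenario,
                              generate_dataset, quality_report, quality_study)


class TestDrawGenotype:
    def test_monomorphic_states(self, rng):
        assert np.all(draw_genotype(0.0, 0.1, 0.5, rng, size=50) == 0)
        assert np.all(draw_genotype(1.0, 0.1, 0.5, rng, size=50) == 2)

    def test_multinomial_frequencies(self, rng):
        g = draw_genotype(0.5, 0.0, 0.5, rng, size=30000)
        freqs = np.bincount(g, minlength=3) / g.size
        for got, want in zip(freqs, (0.25, 0.5, 0.25)):
            assert abs(got - want) < 3 * np.sqrt(want * (1 - want) / g.size)


class TestDrawGL:
    def test_normalized(self, rng):
        gl = draw_gl(1, 0.85, 1.0, rng, size=100)
        np.testing.assert_allclose(gl.sum(axis=1), 1.0)
        assert np.all(gl >= 0)

    def test_mean_share_of_true_genotype_is_phi(self, rng):
        phi, psi, n = 0.75, 0.5, 30000
        gl = draw_gl(2, phi, psi, rng, size=n)
        se = np.sqrt(phi * (1 - phi) / (psi + 1) / n)
        assert abs(gl[:, 2].mean() - phi) < 3 * se

    def test_large_psi_concentrates(self, rng):
        gl = draw_gl(0, 0.8, 1e6, rng, size=20)
        np.testing.assert_allclose(gl, np.tile([0.8, 0.1, 0.1], (20, 1)),
                                   atol=0.01)


class TestCallGenotype:
    @pytest.mark.parametrize("gl,expect", [
        ((1 / 3, 1 / 3, 1 / 3), -1),
        ((0.91, 0.05, 0.04), 0),
        ((0.50, 0.45, 0.05), -1),
        ((0.0, 0.05, 0.95), 2),
        ((0.5, 0.5, 0.0), -1),       # tied top entries
        ((1.0, 0.0, 0.0), 0),
    ])
    def test_rule(self, gl, expect):
        assert call_genotype(gl) == expect

    def test_vectorized(self):
        calls = call_genotype(np.array([[0.91, 0.05, 0.04],
                                        [0.4, 0.3, 0.3]]))
        np.testing.assert_array_equal(calls, [0, -1])


class TestSelectionScenarios:
    def test_sign_patterns(self, rng):
        for _ in range(30):
            sm, sp = draw_selection_scenario("1", rng)
            assert sm < 0 and sp < sm
            sm, sp = draw_selection_scenario("5", rng)
            assert sm == 0 and sp == 0
            sm, sp = draw_selection_scenario("9", rng)
            assert sm > 0 and sp > sm
            sm, sp = draw_selection_scenario("2", rng)
            assert sm < 0 and sp == sm


class TestGenerateDataset:
    def test_default_scheme_yields_210_individuals(self, rng):
        ds, truth = generate_dataset(SimConfig(), rng)
        assert len(ds) == 210
        assert ds.K == 21
        np.testing.assert_array_equal(ds.counts, np.full(21, 10))
        np.testing.assert_array_equal(ds.sample_gens, np.arange(0, 801, 40))

    def test_retention_and_x1_range(self, rng):
        for _ in range(5):
            ds, truth = generate_dataset(SimConfig(), rng)
            assert 0.0 < truth.trajectory.freqs[800] < 1.0
            assert 0.1 <= truth.x1 <= 0.9
            assert -0.05 <= truth.s_values[0] <= 0.05

    def test_truth_alignment(self, rng):
        ds, truth = generate_dataset(SimConfig(), rng)
        assert truth.genotypes.shape == (210,)
        assert set(np.unique(truth.genotypes)) <= {0, 1, 2}

    def test_deterministic_given_seed(self):
        a = generate_dataset(SimConfig(), np.random.default_rng(3))[0]
        b = generate_dataset(SimConfig(), np.random.default_rng(3))[0]
        np.testing.assert_array_equal(a.packed()[0], b.packed()[0])

    def test_impossible_retention_raises(self, rng):
        cfg = SimConfig(s_values=(-0.5, -0.5), max_attempts=5)
        with pytest.raises(RuntimeError, match="attempts"):
            generate_dataset(cfg, rng)


class TestQualityReport:
    def test_exact_indicators(self):
        truth = np.array([0, 1, 2])
        recs = []
        for i, g in enumerate(truth):
            gl = [0.0, 0.0, 0.0]
            gl[g] = 1.0
            recs.append(GLRecord(f"n{i}", 0, tuple(gl)))
        rep = quality_report(GLDataset(recs), truth)
        assert rep.missing_rate == 0.0 and rep.error_rate == 0.0

    def test_all_flat(self):
        recs = [GLRecord(f"n{i}", 0, (1, 1, 1)) for i in range(5)]
        rep = quality_report(GLDataset(recs), np.zeros(5, int))
        assert rep.missing_rate == 1.0
        assert np.isnan(rep.error_rate)

    def test_quality_monotone_in_phi_and_psi(self, rng):
        # Larger phi (at fixed psi) must lower the error rate; larger psi
        # (at fixed phi) lowers the error rate but raises the missing rate.
        means = {}
        for scen in ("A", "B", "E"):
            phi, psi = QUALITY_SCENARIOS[scen]
            means[scen] = quality_study(phi, psi, 60, rng).mean()
        assert means["E"]["error_rate"] < means["A"]["error_rate"]    # phi up
        assert means["B"]["error_rate"] < means["A"]["error_rate"]    # psi up
        assert means["B"]["missing_rate"] > means["A"]["missing_rate"]

    def test_rates_invariant_to_selection_scenario(self, rng):
        # the Dirichlet noise is symmetric given the truth, so rates do not
        # depend on the underlying trajectory
        base = SimConfig()
        strong = SimConfig(s_values=(0.02, -0.02))
        r1 = quality_study(0.85, 1.0, 60, rng, config=base).mean()
        r2 = quality_study(0.85, 1.0, 60, rng, config=strong).mean()
        assert abs(r1["missing_rate"] - r2["missing_rate"]) < 0.02
        assert abs(r1["error_rate"] - r2["error_rate"]) < 0.01
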