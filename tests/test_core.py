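"""Wright-Fisher state types and forward simulators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempsel.core import (DemographicHistory, SelectionSchedule, Trajectory,
                          diffusion_propagate, post_selection_freq,
                          scaled_selection, simulate_wf_discrete)


class TestTypes:
    def test_demography_validation(self):
        with pytest.raises(ValueError):
            DemographicHistory((1, 200), (100, 100), 100)  # first bp != 0
        with pytest.raises(ValueError):
            DemographicHistory((0, 0), (100, 100), 100)    # not increasing
        with pytest.raises(ValueError):
            DemographicHistory((0,), (0,), 100)            # size < 1

    def test_demography_lookup(self):
        d = DemographicHistory((0, 200, 400), (32000, 8000, 16000), 16000)
        assert d.size_at(0) == 32000
        assert d.size_at(199) == 32000
        assert d.size_at(200) == 8000
        assert d.size_at(400) == 16000
        assert d.beta_at(300) == 0.5
        np.testing.assert_array_equal(d.size_by_gen(3), [32000] * 3)

    def test_schedule_right_continuous(self):
        sch = SelectionSchedule((0.02, -0.01), (350,), 0.5)
        assert sch.s_at(349) == 0.02
        assert sch.s_at(350) == -0.01  # post-change value applies at tau
        np.testing.assert_array_equal(sch.s_by_gen(352)[[348, 349, 350, 351]],
                                      [0.02, 0.02, -0.01, -0.01])

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            SelectionSchedule((0.1,), (350,), 0.5)   # epoch count mismatch
        with pytest.raises(ValueError):
            SelectionSchedule((-1.5,), (), 0.5)      # s < -1
        with pytest.raises(ValueError):
            SelectionSchedule((0.0,), (), 1.5)       # h outside [0, 1]

    def test_trajectory_validation(self):
        with pytest.raises(ValueError):
            Trajectory([0, 1], [0.5, 1.2])
        t = Trajectory([0, 1, 2], [0.1, 0.2, 0.3])
        assert t.at(1) == 0.2


class TestScaledSelection:
    @pytest.mark.parametrize("s,n0,expect", [
        (0.01, 16000, 320.0), (0.0, 12345, 0.0), (-0.005, 16000, -160.0)])
    def test_definition(self, s, n0, expect):
        assert scaled_selection(s, n0) == pytest.approx(expect)


class TestPostSelectionFreq:
    @pytest.mark.parametrize("x,s,h,expect", [
        (0.5, 0.1, 0.5, 0.5375 / 1.05),  # hand evaluation, wbar = 1.05
        (1.0, 0.3, 0.2, 1.0),            # fixation is absorbing
        (0.0, 0.3, 0.2, 0.0),
        (0.3, 0.0, 0.5, 0.3),            # neutrality identity
    ])
    def test_values(self, x, s, h, expect):
        assert post_selection_freq(x, s, h) == pytest.approx(expect, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(s=st.floats(-1, 2), h=st.floats(0, 1))
    def test_weakly_monotone_in_x(self, s, h):
        x = np.linspace(0, 1, 201)
        y = post_selection_freq(x, s, h)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= 0) & (y <= 1))


class TestDiscreteWF:
    def test_absorbing_boundary(self, neutral_schedule, constant_demography, rng):
        t = simulate_wf_discrete(neutral_schedule, constant_demography, 0.0, 50, rng)
        assert np.all(t.freqs == 0.0)

    def test_neutral_martingale(self, neutral_schedule, rng):
        dem = DemographicHistory.constant(8000)
        finals = np.array([
            simulate_wf_discrete(neutral_schedule, dem, 0.5, 50, rng).freqs[-1]
            for _ in range(2000)])
        se = finals.std(ddof=1) / np.sqrt(len(finals))
        assert abs(finals.mean() - 0.5) < 3 * se

    def test_one_generation_variance(self, neutral_schedule, rng):
        # binomial sampling noise: var = x(1-x) / (2N) per generation
        dem = DemographicHistory.constant(8000)
        nxt = np.array([
            simulate_wf_discrete(neutral_schedule, dem, 0.5, 2, rng).freqs[1]
            for _ in range(20000)])
        target = 0.5 * 0.5 / (2 * 8000)
        rel = abs(nxt.var(ddof=1) - target) / target
        assert rel < 3 * np.sqrt(2 / len(nxt))  # 3 sigma of a sample variance


class TestDiffusion:
    def test_boundaries_fixed(self, two_epoch_schedule, bottleneck, rng):
        assert diffusion_propagate(0.0, 0, 40, two_epoch_schedule, bottleneck,
                                   rng=rng) == 0.0
        assert diffusion_propagate(1.0, 0, 40, two_epoch_schedule, bottleneck,
                                   rng=rng) == 1.0

    def test_neutral_martingale(self, neutral_schedule, rng):
        dem = DemographicHistory.constant(16000)
        x = diffusion_propagate(np.full(4000, 0.5), 0, 40, neutral_schedule,
                                dem, substeps=5, rng=rng)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 0.5) < 3 * se

    def test_one_substep_drift(self, rng):
        # mean increment of a single Euler step equals the drift term:
        # alpha x(1-x)(h + (1-2h)x) * dt with dt = 1/(2 N0)
        sch = SelectionSchedule((0.02,), (), 0.5)
        dem = DemographicHistory.constant(16000)
        x0 = 0.3
        x = diffusion_propagate(np.full(100000, x0), 0, 1, sch, dem,
                                substeps=1, rng=rng)
        alpha = scaled_selection(0.02, 16000)
        dt = 1.0 / (2 * 16000)
        target = alpha * x0 * (1 - x0) * 0.5 * dt
        inc = x - x0
        se = inc.std(ddof=1) / np.sqrt(len(inc))
        assert abs(inc.mean() - target) < 3 * se

    def test_frequencies_stay_in_unit_interval(self, two_epoch_schedule,
                                               bottleneck, rng):
        x = diffusion_propagate(rng.random(500), 300, 400, two_epoch_schedule,
                                bottleneck, rng=rng)
        assert np.all((x >= 0) & (x <= 1))

    def test_matches_discrete_model_moments(self, rng):
        # diffusion-limit consistency at matched parameters
        sch = SelectionSchedule((0.01,), (), 0.5)
        dem = DemographicHistory.constant(10000)
        n, gens = 6000, 20
        disc = np.array([
            simulate_wf_discrete(sch, dem, 0.4, gens + 1, rng).freqs[-1]
            for _ in range(n)])
        diff = diffusion_propagate(np.full(n, 0.4), 0, gens, sch, dem,
                                   substeps=5, rng=rng)
        se_mean = np.sqrt(disc.var() / n + diff.var() / n)
        assert abs(disc.mean() - diff.mean()) < 3 * se_mean
        v1, v2 = disc.var(ddof=1), diff.var(ddof=1)
        se_var = np.sqrt(2 / n) * (v1 + v2) / 2 * np.sqrt(2)
        assert abs(v1 - v2) < 3 * se_var

    def test_determinism(self, two_epoch_schedule, bottleneck):
        a = diffusion_propagate(0.3, 0, 40, two_epoch_schedule, bottleneck,
                                rng=np.random.default_rng(9))
        b = diffusion_propagate(0.3, 0, 40, two_epoch_schedule, bottleneck,
                                rng=np.random.default_rng(9))
        assert a == b
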