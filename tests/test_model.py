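"""ESM rate functions, Gini modulation, reception probability, integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import esmnet as em
from esmnet.model import (
    ESMParams,
    clearance_rate,
    gini_coefficient,
    infection_rate,
    marginal_rates,
    reception_probability,
    split_rates,
)


class TestGini:
    def test_perfect_equality_is_zero(self):
        assert gini_coefficient([0.3, 0.3, 0.3]) == pytest.approx(0.0)

    def test_single_holder(self):
        # sum_ij |x_i - x_j| = 4, 4 / (2 * 9 * (1/3)) = 2/3
        assert gini_coefficient([0, 0, 1]) == pytest.approx(2 / 3)

    def test_all_zero_degenerate(self):
        assert gini_coefficient([0.0, 0.0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gini_coefficient([0.2, -0.1])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=10))
    def test_matches_double_loop_oracle(self, x):
        x = np.asarray(x)
        mean = x.mean()
        expected = 0.0
        if mean > 0:
            expected = sum(
                abs(a - b) for a in x for b in x
            ) / (2 * x.size**2 * mean)
        assert gini_coefficient(x) == pytest.approx(expected, abs=1e-12)


class TestRates:
    def test_infection_rate_anchors(self):
        assert infection_rate(0.0, beta0=0.7) == pytest.approx(0.0)
        assert infection_rate(1.0, beta0=0.8) == pytest.approx(0.8)
        assert infection_rate(1.0, beta0=3.0) == pytest.approx(1.0)  # clamped

    def test_infection_rate_midpoint_symmetry(self):
        # normalized logistic at its midpoint: (1/2 - s0) / (s1 - s0)
        s0 = 1 / (1 + math.exp(5.0))
        expected = (0.5 - s0) / ((1 - s0) - s0)
        assert infection_rate(0.5, beta0=1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.5, abs=1e-12)

    def test_infection_rate_strictly_increasing(self):
        grid = np.linspace(0, 1, 101)
        vals = infection_rate(grid, beta0=0.9)
        assert np.all(np.diff(vals) > 0)

    def test_clearance_rate_closed_forms(self):
        assert clearance_rate(0.0, delta0=0.4) == pytest.approx(0.4)
        assert clearance_rate(1.0, delta0=1.0) == pytest.approx(math.exp(-1))
        grid = np.linspace(0, 1, 101)
        assert np.all(np.diff(clearance_rate(grid, delta0=0.6)) < 0)

    def test_split_conservation(self, rng):
        bt = rng.random(20)
        for g in (0.0, 0.3, 0.75, 0.999):
            ext, intr = split_rates(bt, g)
            np.testing.assert_allclose(ext + intr, bt)
        ext, intr = split_rates(np.array([0.4]), 0.75)
        np.testing.assert_allclose(ext, [0.3])
        np.testing.assert_allclose(intr, [0.1])

    def test_split_rejects_bad_gini(self):
        with pytest.raises(ValueError):
            split_rates([0.5], 1.0)

    def test_reception_probability_complement_product(self):
        acp = np.array([1.0, 1.0, 1.0, 0.0])
        bext = np.array([0.1, 0.2, 0.0, 0.9])
        p = reception_probability(None, None, acp * np.array([1, 1, 1, 0]),
                                  bext, beta_int_i=0.05)
        assert p == pytest.approx(1 - 0.95 * 0.9 * 0.8)

    def test_reception_probability_edge_cases(self):
        zeros = np.zeros(3)
        assert reception_probability(None, None, zeros, zeros, 0.0) == 0.0
        assert reception_probability(None, None, zeros, zeros, 1.0) == 1.0


class TestMarginalRates:
    def test_zero_production(self):
        p = ESMParams(beta0=0.0, delta0=0.5)
        beta_eff, _ = marginal_rates(p)
        assert beta_eff == pytest.approx(0.0)

    def test_clearance_integral_analytic(self):
        # integral of exp(-p) over [0, 1] = 1 - 1/e
        _, delta_eff = marginal_rates(ESMParams(beta0=0.5, delta0=1.0))
        assert delta_eff == pytest.approx(1 - math.exp(-1), abs=1e-6)

    def test_monotone_in_own_constant(self):
        betas = [marginal_rates(ESMParams(beta0=b, delta0=0.2))[0]
                 for b in np.linspace(0.05, 1.0, 8)]
        assert np.all(np.diff(betas) > 0)


class TestSimulate:
    def test_initial_condition_and_bounds(self, geometric_conn):
        params = ESMParams(beta0=0.6, delta0=0.2, p_seed_init=0.9,
                           velocity=0.004, horizon_days=2000)
        traj = em.simulate(geometric_conn, params, {0, 3})
        assert traj.p[0, 0] == traj.p[0, 3] == 0.9
        assert np.all(traj.p[0, [1, 2, 4, 5, 6, 7, 8, 9]] == 0.0)
        assert traj.p.min() >= 0.0 and traj.p.max() <= 1.0

    def test_deterministic_and_stochastic_reproducibility(self, geometric_conn):
        params = ESMParams(beta0=0.6, delta0=0.2, noise_sd=0.05,
                           p_seed_init=0.9, velocity=0.004, horizon_days=500)
        a = em.simulate(geometric_conn, params, {0}, rng_seed=42)
        b = em.simulate(geometric_conn, params, {0}, rng_seed=42)
        np.testing.assert_array_equal(a.p, b.p)
        c = em.simulate(geometric_conn, params, {0}, rng_seed=43)
        assert not np.array_equal(a.p, c.p)

    def test_pure_decay_matches_fine_step_oracle(self):
        # isolated region: dP/dt = -P * delta0 * exp(-P), no incoming edges
        acp = np.eye(2)
        conn = em.Connectome(acp=acp, fiber_length=np.zeros((2, 2)),
                             labels=["a", "b"])
        params = ESMParams(beta0=0.5, delta0=0.3, p_seed_init=0.8,
                           horizon_days=200)
        traj = em.simulate(conn, params, {0})
        assert np.all(np.diff(traj.p[:, 0]) <= 0)
        # fine-step reference integration of the same right-hand side;
        # the intrinsic production term stays active, scaled by (1 - gini)
        h = 1e-3
        p = 0.8
        from esmnet.model import clearance_rate, gini_coefficient, infection_rate
        for _ in range(int(200 / h)):
            g = gini_coefficient([p, 0.0])
            r = 1 - (1 - (1 - g) * infection_rate(p, 0.5))
            p = p + h * ((1 - p) * r - p * clearance_rate(p, 0.3))
        assert traj.p[-1, 0] == pytest.approx(p, abs=5e-3)

    def test_no_clearance_is_monotone_nondecreasing(self, geometric_conn):
        params = ESMParams(beta0=0.6, delta0=1e-12, p_seed_init=0.9,
                           velocity=0.004, horizon_days=4000)
        traj = em.simulate(geometric_conn, params, {0})
        assert np.all(np.diff(traj.p, axis=0) >= -1e-15)

    def test_seeding_locality_first_step(self, geometric_conn):
        # all delays > dt, so only seeds and their direct neighbors can move
        params = ESMParams(beta0=0.9, delta0=0.1, p_seed_init=0.9,
                           velocity=0.004, horizon_days=2)
        traj = em.simulate(geometric_conn, params, {0})
        neighbors = set(np.nonzero(geometric_conn.acp[0])[0]) | {0}
        for i in range(geometric_conn.n_regions):
            if i not in neighbors:
                assert traj.p[1, i] == 0.0

    def test_one_step_decomposes_into_rate_functions(self, geometric_conn):
        from esmnet.model import (clearance_rate, gini_coefficient,
                                  infection_rate, reception_probability,
                                  split_rates)

        params = ESMParams(beta0=0.7, delta0=0.2, p_seed_init=0.9,
                           velocity=0.004, horizon_days=3)
        traj = em.simulate(geometric_conn, params, {0, 2})
        p0 = traj.p[0]
        g = gini_coefficient(p0)
        bt = infection_rate(p0, params.beta0)
        bext, bint = split_rates(bt, g)
        delta = clearance_rate(p0, params.delta0)
        expected = np.empty_like(p0)
        for i in range(p0.size):
            col = geometric_conn.acp[:, i].copy()
            col[i] = 0.0
            r = reception_probability(p0, p0[i], col, bext, bint[i])
            expected[i] = np.clip(p0[i] + (1 - p0[i]) * r - p0[i] * delta[i], 0, 1)
        np.testing.assert_allclose(traj.p[1], expected, atol=1e-14)

    def test_clearance_suppresses_spread_monotonically(self):
        # on a homogeneous chain, raising delta0 eventually stops the wave
        spec = em.SyntheticSpec(n_regions=5, geometry="chain", rng_seed=1,
                                acp_range=(0.7, 0.7))
        conn = em.make_connectome(spec)
        reached = []
        for d0 in (0.05, 0.2, 0.5, 0.9):
            params = spec.params.replace(beta0=0.5, delta0=d0,
                                         horizon_days=18250)
            traj = em.simulate(conn, params, {0})
            reached.append(int((traj.p.max(axis=0) >= 0.5).sum()))
        assert reached[0] == 5
        assert all(a >= b for a, b in zip(reached, reached[1:]))
        assert reached[-1] == 1  # only the seed itself

    def test_trajectory_time_grid(self, geometric_conn):
        params = ESMParams(beta0=0.5, delta0=0.2, horizon_days=10, dt=0.5)
        traj = em.simulate(geometric_conn, params, {0})
        assert traj.p.shape[0] == 21
        assert traj.time_days[-1] == pytest.approx(10.0)
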