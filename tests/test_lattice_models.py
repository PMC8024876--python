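"""Read-write lattice (M) model and passive-dilution comparator."""

import numpy as np
import pytest

from episwitch import (
    DilutionParams,
    MModelParams,
    build_dilution_model,
    build_m_model,
    exact_mfpt,
    first_passage_ensemble,
    methylation_propensity,
    replicate_lattice,
)
from episwitch.lattice_models import (
    MetastabilityError,
    dilution_init,
    m_model_init,
    steady_methylation,
)
from episwitch.stochastic_engine import StateSpaceError


class TestMethylationPropensity:
    @pytest.mark.parametrize(
        "methyl, i, hill, expected",
        [
            # 2 of 4 neighbors methylated, linear feedback
            (np.array([1, 0, 0, 0, 1]), 2, 1.0, 0.1 + 1.0 * (2 / 4)),
            # same neighborhood, quadratic feedback
            (np.array([1, 0, 0, 0, 1]), 2, 2.0, 0.1 + 1.0 * 0.25),
            # fully unmethylated array: basal rate only
            (np.zeros(5, dtype=int), 2, 1.0, 0.1),
        ],
    )
    def test_direct_formula(self, methyl, i, hill, expected):
        p = MModelParams(N=5, k0=0.1, k_fb=1.0, reach=2, hill_n=hill, alpha=0.1)
        assert methylation_propensity(i, methyl, p) == pytest.approx(expected)

    def test_methylated_site_has_zero_rate(self):
        p = MModelParams(N=4, reach=1)
        assert methylation_propensity(0, np.array([1, 1, 0, 0]), p) == 0.0

    def test_edge_clipping_no_wraparound(self):
        # site 0 has only right-hand neighbors
        p = MModelParams(N=5, k0=0.0, k_fb=1.0, reach=2, alpha=0.1)
        methyl = np.array([0, 1, 1, 0, 0])
        # window = {1, 2}, both methylated
        assert methylation_propensity(0, methyl, p) == pytest.approx(1.0)


class TestReplicateLattice:
    def test_unmethylated_unchanged(self):
        rng = np.random.default_rng(0)
        out = replicate_lattice(np.zeros(10, dtype=int), rng)
        assert np.all(out == 0)

    def test_half_retention_moments(self):
        # Binomial(60, 1/2): mean 30, SD sqrt(15) ~ 3.873
        rng = np.random.default_rng(1)
        survivors = np.array(
            [replicate_lattice(np.ones(60, dtype=int), rng).sum() for _ in range(10_000)]
        )
        assert survivors.mean() == pytest.approx(30.0, abs=0.15)
        assert survivors.std(ddof=1) == pytest.approx(np.sqrt(15), rel=0.03)

    def test_never_methylates(self):
        rng = np.random.default_rng(2)
        start = np.array([1, 0, 1, 0, 1])
        out = replicate_lattice(start, rng)
        assert np.all(out <= start)


class TestMModel:
    def test_absorbing_unreachable_when_alpha_zero(self):
        p = MModelParams(N=3, alpha=0.0, T_div=None, theta_act=0.3)
        system = build_m_model(p)
        with pytest.raises(StateSpaceError, match="unreachable"):
            exact_mfpt(system, m_model_init(p))

    def test_gillespie_matches_exact_mfpt(self):
        # N=3 lattice: 8 methylation states, independent linear solve
        p = MModelParams(N=3, k0=0.1, k_fb=2.0, reach=1, alpha=0.8, T_div=None, theta_act=0.3)
        system = build_m_model(p)
        init = m_model_init(p)
        exact = exact_mfpt(system, init)
        sample = first_passage_ensemble(system, init, 4_000, t_max=exact * 60, seed=7)
        times = sample.uncensored_times
        se = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - exact) < 3 * se

    def test_exact_mfpt_matches_hand_assembled_chain(self):
        # global coupling reduces to a birth-death chain on n; solve that
        # chain densely by hand and compare
        p = MModelParams(N=4, k0=0.2, k_fb=1.0, reach=3, hill_n=1.0,
                         alpha=1.0, T_div=None, theta_act=0.2)
        system = build_m_model(p)
        lattice_mfpt = exact_mfpt(system, m_model_init(p))

        # chain states n = 1..4, absorbing at n <= 0.8
        N, k0, k_fb, alpha = 4, 0.2, 1.0, 1.0
        n_states = [1, 2, 3, 4]
        A = np.zeros((4, 4))
        b = -np.ones(4)
        for row, n in enumerate(n_states):
            birth = (N - n) * (k0 + k_fb * n / (N - 1))
            death = alpha * n
            A[row, row] = -(birth + death)
            if n < 4:
                A[row, row + 1] = birth
            if n > 1:
                A[row, row - 1] = death
        tau = np.linalg.solve(A, b)
        assert lattice_mfpt == pytest.approx(tau[3], rel=1e-9)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError, match="theta_act"):
            MModelParams(N=4, theta_act=1.5)
        with pytest.raises(ValueError, match="theta_act"):
            MModelParams(N=4, theta_act=0.0)

    def test_fast_kernel_agrees_with_generic_engine(self):
        # same model through the compiled kernel and the reference engine
        p = MModelParams(N=5, k0=0.1, k_fb=2.0, reach=2, alpha=0.9, T_div=None, theta_act=0.2)
        system = build_m_model(p)
        init = m_model_init(p)
        fast = first_passage_ensemble(system, init, 2_000, t_max=500.0, seed=11)
        slow = first_passage_ensemble(system, init, 500, t_max=500.0, seed=11, use_fast=False)
        se = np.hypot(
            fast.uncensored_times.std(ddof=1) / np.sqrt(fast.uncensored_times.size),
            slow.uncensored_times.std(ddof=1) / np.sqrt(slow.uncensored_times.size),
        )
        assert abs(fast.uncensored_times.mean() - slow.uncensored_times.mean()) < 3.5 * se


class TestDilutionModel:
    def test_mean_divisions_to_cross_threshold(self):
        # halving from N to theta*N takes ~log2(1/theta) divisions
        p = DilutionParams(N=40, T_div=20.0, theta_act=0.1)
        system = build_dilution_model(p)
        sample = first_passage_ensemble(system, dilution_init(p), 2_000, t_max=2_000.0, seed=3)
        mean_divisions = sample.activation_times.mean() / p.T_div
        assert 3.0 <= mean_divisions <= 4.5

    def test_mean_time_proportional_to_t_div(self):
        means = {}
        for T_div in (20.0, 40.0):
            p = DilutionParams(N=40, T_div=T_div, theta_act=0.1)
            s = first_passage_ensemble(
                build_dilution_model(p), dilution_init(p), 2_000, t_max=4_000.0, seed=5
            )
            means[T_div] = s.activation_times.mean()
        assert means[40.0] / means[20.0] == pytest.approx(2.0, rel=0.10)

    def test_no_division_never_activates(self):
        p = DilutionParams(N=20, T_div=np.inf, theta_act=0.1, residual_alpha=0.0)
        system = build_dilution_model(p)
        sample = first_passage_ensemble(system, dilution_init(p), 20, t_max=100.0, seed=0)
        assert sample.fully_censored


class TestSteadyMethylation:
    def test_frozen_fully_methylated(self):
        p = MModelParams(N=10, alpha=0.0, T_div=None, theta_act=0.1)
        system = build_m_model(p)
        mbar = steady_methylation(system, m_model_init(p), burn_in=5, window=10, seed=1)
        assert mbar == pytest.approx(1.0)

    def test_no_feedback_matches_two_state_equilibrium(self):
        # k_fb = 0: every site is an independent telegraph with
        # equilibrium occupancy k0 / (k0 + alpha)
        k0, alpha = 1.2, 0.8
        p = MModelParams(N=30, k0=k0, k_fb=0.0, alpha=alpha, T_div=None, theta_act=0.01)
        system = build_m_model(p)
        mbar = steady_methylation(
            system, m_model_init(p), burn_in=20, window=60, seed=2, n_reps=12
        )
        assert mbar == pytest.approx(k0 / (k0 + alpha), abs=0.02)

    def test_unstable_parameters_raise(self):
        # demethylation overwhelming: every replicate activates quickly
        p = MModelParams(N=10, k0=0.01, k_fb=0.1, alpha=5.0, T_div=None, theta_act=0.4)
        system = build_m_model(p)
        with pytest.raises(MetastabilityError):
            steady_methylation(system, m_model_init(p), burn_in=50, window=100, seed=3)
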