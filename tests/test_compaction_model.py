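"""Methylation-compaction (MC) model and transcription-factor couplings."""

import numpy as np
import pytest

from episwitch import (
    MCParams,
    ReactionSystem,
    TFParams,
    build_mc_model,
    build_tf_model,
    exact_mfpt,
    first_passage_ensemble,
    replicate_mc,
    surface_factor,
)
from episwitch.compaction_model import mc_init, tf_init
from episwitch.stochastic_engine import gillespie_run

# fast-switching MC regime for cheap statistical tests
FAST = dict(N=15, k_me=1.0, gamma_c=1.0, alpha=1.0, beta_c=1.0, k_on=0.5,
            k_off=6.0, a_me=1.0, d_me=1.0, C_min=3, phi=0.0, T_div=None)


class TestSurfaceFactor:
    def test_two_thirds_power(self):
        assert surface_factor(27) == pytest.approx(9.0)
        assert surface_factor(8) == pytest.approx(4.0)

    def test_zero_assembly(self):
        assert surface_factor(0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            surface_factor(-1)


class TestReplicateMC:
    def test_phi_zero_preserves_compartments(self):
        p = MCParams(phi=0.0)
        rng = np.random.default_rng(0)
        state = np.array([30, 10, 15, 5], dtype=np.int64)
        out = replicate_mc(state, p, rng)
        # in/out totals unchanged, only methylation relabeled
        assert out[0] + out[2] == 45
        assert out[1] + out[3] == 15
        assert out.sum() == 60

    def test_phi_one_empties_assembly(self):
        p = MCParams(phi=1.0)
        rng = np.random.default_rng(1)
        out = replicate_mc(np.array([40, 0, 20, 0], dtype=np.int64), p, rng)
        assert out[0] + out[2] == 0
        assert out.sum() == 60

    def test_expected_ejection_and_halving(self):
        p = MCParams(N=60, phi=0.2)
        rng = np.random.default_rng(2)
        state = np.array([60, 0, 0, 0], dtype=np.int64)
        kept_me = np.empty(10_000)
        ejected = np.empty(10_000)
        for i in range(10_000):
            out = replicate_mc(state, p, rng)
            kept_me[i] = out[0] + out[1]
            ejected[i] = out[1] + out[3]
        assert kept_me.mean() == pytest.approx(30.0, abs=0.2)  # Binomial(60, 1/2)
        assert ejected.mean() == pytest.approx(0.2 * 60, abs=0.2)  # phi * C_T


class TestMCModel:
    def test_nucleosome_conservation_along_trajectory(self):
        p = MCParams(**{**FAST, "T_div": 7.0, "phi": 0.3})
        system = build_mc_model(p)
        traj = gillespie_run(system, mc_init(p), t_max=200.0, seed=4)
        assert np.all(traj.states.sum(axis=1) == p.N)

    def test_frozen_assembly_never_activates(self):
        p = MCParams(k_off=0.0, phi=0.0, T_div=20.0)
        system = build_mc_model(p)
        sample = first_passage_ensemble(system, mc_init(p), 10, t_max=300.0, seed=0)
        assert sample.fully_censored

    def test_decoupled_assembly_matches_birth_death_oracle(self):
        # with all methylation couplings at 1 the compaction marginal is a
        # birth-death chain on C_T solved exactly
        p = MCParams(**FAST)
        system = build_mc_model(p)
        sample = first_passage_ensemble(system, mc_init(p), 4_000, t_max=4_000.0, seed=11)

        chain = ReactionSystem(
            species_labels=["c"],
            propensities=lambda s: np.array(
                [p.k_on * s[0] ** (2 / 3) * (p.N - s[0]), p.k_off * s[0] ** (2 / 3)]
            ),
            stoichiometry=np.array([[1], [-1]]),
            absorbing=lambda s: s[0] < p.C_min,
        )
        exact = exact_mfpt(chain, np.array([p.N]))
        times = sample.uncensored_times
        se = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - exact) < 3.5 * se

    def test_fast_kernel_agrees_with_generic_engine(self):
        p = MCParams(**FAST)
        system = build_mc_model(p)
        fast = first_passage_ensemble(system, mc_init(p), 3_000, t_max=2_000.0, seed=6)
        slow = first_passage_ensemble(system, mc_init(p), 400, t_max=2_000.0, seed=6,
                                      use_fast=False)
        se = np.hypot(
            fast.uncensored_times.std(ddof=1) / np.sqrt(fast.uncensored_times.size),
            slow.uncensored_times.std(ddof=1) / np.sqrt(slow.uncensored_times.size),
        )
        assert abs(fast.uncensored_times.mean() - slow.uncensored_times.mean()) < 3.5 * se

    def test_c_min_above_init_rejected(self):
        with pytest.raises(ValueError):
            MCParams(N=20, C_min=20)

    def test_invalid_adhesion_parameters_rejected(self):
        with pytest.raises(ValueError, match="k_on"):
            MCParams(k_on=0.0)
        with pytest.raises(ValueError, match="u_adhesion"):
            MCParams(u_adhesion=-0.5)


class TestTFModel:
    def test_zero_concentration_matches_base_model(self):
        p = MCParams(**FAST)
        tf = TFParams(N_B=4, tf_conc=0.0, mechanism="blocking")
        base = first_passage_ensemble(build_mc_model(p), mc_init(p), 1_500,
                                      t_max=2_000.0, seed=21)
        with_tf = first_passage_ensemble(build_tf_model(p, tf), tf_init(p), 1_500,
                                         t_max=2_000.0, seed=22)
        se = np.hypot(
            base.uncensored_times.std(ddof=1) / np.sqrt(base.uncensored_times.size),
            with_tf.uncensored_times.std(ddof=1) / np.sqrt(with_tf.uncensored_times.size),
        )
        assert abs(base.uncensored_times.mean() - with_tf.uncensored_times.mean()) < 3.5 * se

    def test_no_binding_sites_matches_base_model(self):
        p = MCParams(**FAST)
        tf = TFParams(N_B=0, tf_conc=50.0, mechanism="blocking")
        base = first_passage_ensemble(build_mc_model(p), mc_init(p), 1_500,
                                      t_max=2_000.0, seed=23)
        with_tf = first_passage_ensemble(build_tf_model(p, tf), tf_init(p), 1_500,
                                         t_max=2_000.0, seed=24)
        se = np.hypot(
            base.uncensored_times.std(ddof=1) / np.sqrt(base.uncensored_times.size),
            with_tf.uncensored_times.std(ddof=1) / np.sqrt(with_tf.uncensored_times.size),
        )
        assert abs(base.uncensored_times.mean() - with_tf.uncensored_times.mean()) < 3.5 * se

    def test_saturating_blocking_accelerates_activation(self):
        # all nucleosomes bindable, saturating TF: recruitment is blocked,
        # so dissolution comes sooner (one-sided comparison of means)
        p = MCParams(**FAST)
        tf = TFParams(N_B=p.N, tf_conc=100.0, k_bind_per_conc=10.0, k_unbind=0.1,
                      mechanism="blocking")
        base = first_passage_ensemble(build_mc_model(p), mc_init(p), 1_500,
                                      t_max=2_000.0, seed=25)
        blocked = first_passage_ensemble(build_tf_model(p, tf), tf_init(p), 1_500,
                                         t_max=2_000.0, seed=26)
        se = np.hypot(
            base.uncensored_times.std(ddof=1) / np.sqrt(base.uncensored_times.size),
            blocked.uncensored_times.std(ddof=1) / np.sqrt(blocked.uncensored_times.size),
        )
        assert (base.uncensored_times.mean() - blocked.uncensored_times.mean()) > 2 * se

    def test_demethylation_mechanism_requires_reach(self):
        with pytest.raises(ValueError, match="N_R"):
            TFParams(mechanism="demethylation", N_R=0)

    def test_tf_conservation_along_trajectory(self):
        p = MCParams(**{**FAST, "T_div": 9.0, "phi": 0.2})
        tf = TFParams(N_B=3, tf_conc=1.0, mechanism="blocking")
        system = build_tf_model(p, tf)
        traj = gillespie_run(system, tf_init(p), t_max=150.0, seed=8)
        assert np.all(traj.states[:, :4].sum(axis=1) == p.N)
        assert np.all(traj.states[:, 4] >= 0)
        assert np.all(traj.states[:, 4] <= tf.N_B)
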