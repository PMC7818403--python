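"""Voxel population generator and BOLD simulator."""

import numpy as np
import pytest

from numact import bold
from numact.bold import (EffectSizes, ROI_VOXEL_COUNTS, TUNING_CLASSES,
                         make_motion_regressors, make_population,
                         simulate_bold, simulate_psc_runs)
from numact.glm import run_psc


class TestMakePopulation:
    def test_default_voxel_counts(self):
        pop = make_population("NPC3_L", (0.25, 0.25, 0.25, 0.25), seed=0)
        assert pop.n_voxels == 203
        assert ROI_VOXEL_COUNTS["phAIP_L"] == 419

    def test_null_mixture_has_no_signal(self):
        pop = make_population("NPC3_L", (0, 0, 0, 1), n_voxels=30, seed=1)
        amps = pop.amplitudes()
        assert np.all(amps == 0)

    def test_class_fractions_within_binomial_error(self):
        mixture = (0.4, 0.3, 0.2, 0.1)
        pop = make_population("NPC3_L", mixture, n_voxels=1000, seed=2)
        counts = np.array([sum(v.tuning_class == c for v in pop.voxels)
                           for c in TUNING_CLASSES])
        for frac, p in zip(counts / 1000, mixture):
            se = np.sqrt(p * (1 - p) / 1000)
            assert abs(frac - p) < 4 * se

    def test_class_invariants(self):
        pop = make_population("NPC3_L", (0.25, 0.25, 0.25, 0.25),
                              n_voxels=200, seed=3)
        for v in pop.voxels:
            if v.tuning_class == "action_numerosity":
                assert v.delta_action > 0 and v.delta_ball == 0
            elif v.tuning_class == "ball_numerosity":
                assert v.delta_ball > 0 and v.delta_action == 0
            elif v.tuning_class == "null":
                assert v.attend_gain_action == 0 and v.delta_action == 0

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            make_population("NPC3_L", (0.5, 0.5, 0.5, -0.5), n_voxels=10)
        with pytest.raises(ValueError):
            make_population("nowhere", (0.25, 0.25, 0.25, 0.25))


class TestSimulateBold:
    def test_null_voxel_without_noise_is_constant(self, schedules,
                                                  noiseless_effects):
        pop = make_population("NPC3_L", (0, 0, 0, 1), n_voxels=3,
                              effects=noiseless_effects, seed=4)
        Y = simulate_bold(pop, schedules[0], seed=5)
        assert np.allclose(Y, pop.baselines[:, None])

    def test_glm_recovers_programmed_tuning_depth(self, schedules,
                                                  noiseless_effects):
        """On noiseless data the GLM percent-signal-change difference between
        preferred and non-preferred action blocks equals delta_action."""
        pop = make_population("NPC3_L", (1, 0, 0, 0), n_voxels=5,
                              effects=noiseless_effects, seed=6)
        sched = schedules[0]
        Y = simulate_bold(pop, sched, seed=7)
        motion = make_motion_regressors(sched.n_tr, seed=8)
        psc = run_psc(Y, sched, motion)
        for i, v in enumerate(pop.voxels):
            pref = 0 if v.preferred_action_numerosity == 1 else 1
            assert psc[i, pref] - psc[i, 1 - pref] == pytest.approx(
                v.delta_action, abs=1e-9)
            assert psc[i, 2] - psc[i, 3] == pytest.approx(0, abs=1e-9)

    def test_seed_contract(self, schedules):
        pop = make_population("NPC3_L", (0.5, 0, 0, 0.5), n_voxels=4, seed=9)
        a = simulate_bold(pop, schedules[0], seed=10)
        b = simulate_bold(pop, schedules[0], seed=10)
        c = simulate_bold(pop, schedules[0], seed=11)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        # the noiseless component is seed-independent
        quiet = bold.ROIPopulation(
            roi_name=pop.roi_name, n_voxels=pop.n_voxels,
            class_mixture=pop.class_mixture,
            voxels=tuple(bold.VoxelTuning(
                baseline=v.baseline,
                attend_gain_action=v.attend_gain_action,
                attend_gain_ball=v.attend_gain_ball,
                preferred_action_numerosity=v.preferred_action_numerosity,
                delta_action=v.delta_action,
                preferred_ball_numerosity=v.preferred_ball_numerosity,
                delta_ball=v.delta_ball, noise_sd=0.0,
                tuning_class=v.tuning_class) for v in pop.voxels))
        assert np.array_equal(simulate_bold(quiet, schedules[0], seed=10),
                              simulate_bold(quiet, schedules[0], seed=11))


class TestMotionRegressors:
    def test_shape_mean_and_seed(self):
        m = make_motion_regressors(128, seed=12)
        assert m.shape == (6, 128)
        assert np.allclose(m.mean(axis=1), 0, atol=1e-12)
        assert np.array_equal(m, make_motion_regressors(128, seed=12))
        with pytest.raises(ValueError):
            make_motion_regressors(0)


class TestRecoverability:
    def test_glm_psc_unbiased_under_noise(self, schedules):
        """Mean PSC over many noisy replicates approaches the programmed
        amplitudes (replicates realised as identical-tuning voxels)."""
        eff = EffectSizes(noise_sd=1.0, baseline_sd=0.0, gain_sd=0.0,
                          delta_sd=0.0)
        pop = make_population("NPC3_L", (1, 0, 0, 0), n_voxels=500,
                              effects=eff, seed=13)
        sched = schedules[0]
        Y = simulate_bold(pop, sched, seed=14)
        motion = make_motion_regressors(sched.n_tr, seed=15)
        psc = run_psc(Y, sched, motion)
        amps = pop.amplitudes()[:, :4]
        err = psc - amps
        se = err.std(ddof=1, axis=0) / np.sqrt(len(err))
        assert np.all(np.abs(err.mean(axis=0)) < 4 * se + 1e-3)

    def test_split_half_reliability_grows_with_snr(self):
        """Split-half correlation of per-run PSC estimates increases
        monotonically as estimation noise falls."""
        eff = EffectSizes(delta_sd=0.3, gain_sd=0.3)
        pop = make_population("NPC3_L", (0.5, 0.5, 0, 0), n_voxels=300,
                              effects=eff, seed=16)
        rels = []
        for noise in (2.0, 0.7, 0.2):
            psc = simulate_psc_runs(pop, 8, noise, seed=17)
            a = psc[:, ::2, :].mean(axis=1).ravel()
            b = psc[:, 1::2, :].mean(axis=1).ravel()
            rels.append(np.corrcoef(a, b)[0, 1])
        assert rels[0] < rels[1] < rels[2]
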