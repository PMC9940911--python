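import numpy as np
import pytest

from rlddm.learning import AgentParams, compute_q_trajectory
from rlddm.task import (CohortSpec, DEFAULT_GROUP_MEANS, InvalidDesignError,
                        generate_agent_dataset, generate_cohort_data,
                        make_schedule, sample_cohort, synth_stim_volumes,
                        synth_voxel_cohort)


class TestMakeSchedule:
    def test_default_reversal_design(self):
        s = make_schedule(0.8, 40, 3, 60)
        assert s.n_trials == 120
        assert np.all(s.p_reward[:60, 0] == 0.8)
        assert np.allclose(s.p_reward[60:, 0], 0.2)
        assert np.all(s.p_reward[:60, 1] == pytest.approx(0.2))
        assert s.session_bounds == ((1, 40), (41, 80), (81, 120))

    def test_exact_probability_swap_at_reversal(self):
        s = make_schedule(0.8, 40, 3, 60)
        # trial 60 of option A equals trial 61 of option B
        assert s.p_reward[59, 0] == s.p_reward[60, 1] == 0.8
        np.testing.assert_array_equal(s.p_reward[:60, 0], s.p_reward[60:, 1])

    def test_session_lengths_sum_to_n_trials(self):
        s = make_schedule(0.7, 25, 4, 50)
        assert sum(e - b + 1 for b, e in s.session_bounds) == s.n_trials

    def test_degenerate_probability_rewards_every_exploit(self):
        s = make_schedule(1.0, 10, 1, 5)
        rng = np.random.default_rng(0)
        better = s.better_option()
        wins = [rng.random() < s.p_reward[i, better[i]] for i in range(5)]
        assert all(wins)

    @pytest.mark.parametrize("rev", [0, 120, 200])
    def test_reversal_outside_range_rejected(self, rev):
        with pytest.raises(InvalidDesignError):
            make_schedule(0.8, 40, 3, rev)

    def test_exploit_policy_reward_rate(self):
        """A perfect exploiter earns at the committed arm probability."""
        s = make_schedule(0.8, 40, 3, 60)
        rng = np.random.default_rng(5)
        n = 10000
        wins = rng.random((n, 60)) < 0.8
        rate = wins.mean()
        assert abs(rate - 0.8) < 3 * np.sqrt(0.8 * 0.2 / (n * 60))


class TestSampleCohort:
    def test_zero_variance_collapses_to_group_means(self):
        spec = CohortSpec(n_subjects=4, group_sds={k: 0.0 for k in
                          ("a", "t", "z", "m", "alpha_pos_raw", "alpha_neg_raw")})
        cohort = sample_cohort(spec, np.random.default_rng(0))
        for subj in cohort:
            for cond, p in subj.items():
                assert p.m == DEFAULT_GROUP_MEANS[cond]["m"]
                assert p.a == DEFAULT_GROUP_MEANS[cond]["a"]

    def test_deterministic_under_seed(self):
        spec = CohortSpec(n_subjects=18)
        c1 = sample_cohort(spec, np.random.default_rng(99))
        c2 = sample_cohort(spec, np.random.default_rng(99))
        for s1, s2 in zip(c1, c2):
            for cond in s1:
                assert s1[cond] == s2[cond]

    def test_shared_traits_across_conditions(self):
        cohort = sample_cohort(CohortSpec(n_subjects=6), np.random.default_rng(1))
        for subj in cohort:
            ts = {round(p.t, 12) for p in subj.values()}
            zs = {round(p.z, 12) for p in subj.values()}
            assert len(ts) == 1 and len(zs) == 1

    def test_large_sample_recovers_group_means(self):
        """Law of large numbers on the unbounded drift-scaling parameter."""
        spec = CohortSpec(n_subjects=1000,
                          group_sds={"a": 0.1, "t": 0.02, "z": 0.01, "m": 0.3,
                                     "alpha_pos_raw": 0.3, "alpha_neg_raw": 0.3})
        cohort = sample_cohort(spec, np.random.default_rng(7))
        ms = [s["OFF"].m for s in cohort]
        se = 0.3 / np.sqrt(1000)
        assert abs(np.mean(ms) - DEFAULT_GROUP_MEANS["OFF"]["m"]) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(CohortSpec(n_subjects=0), np.random.default_rng(0))
        bad = CohortSpec(n_subjects=2)
        bad.group_means["ON"]["m"] = np.nan
        with pytest.raises(ValueError):
            sample_cohort(bad, np.random.default_rng(0))


def agent(**kw):
    base = dict(a=1.8, t=0.4, z=0.5, m=4.0, alpha_pos_raw=-0.5,
                alpha_neg_raw=-2.0, condition="OFF")
    base.update(kw)
    return AgentParams(**base)


class TestGenerateCohortData:
    def test_record_counts_and_dt_bounds(self, schedule):
        ds = generate_agent_dataset(agent(), schedule, 0.02,
                                    np.random.default_rng(0))
        assert ds.n_trials == schedule.n_trials
        resp = ds.responded
        assert np.all(ds.dt[resp] > 0.4)          # dt exceeds non-decision time
        assert np.all(ds.dt[resp] <= 3.0)         # response window
        assert np.all(np.isnan(ds.outcome[~resp]))

    def test_frozen_learner_has_constant_drift(self, schedule):
        p = agent(alpha_pos_raw=-60.0, alpha_neg_raw=-60.0)  # rates -> 0
        ds = generate_agent_dataset(p, schedule, 0.0, np.random.default_rng(1))
        traj = compute_q_trajectory(ds, p)
        assert np.allclose(traj.drift, 0.0)       # Q never moves from (0.5, 0.5)

    def test_value_blind_diffusion_splits_evenly(self, schedule):
        p = agent(m=0.0, t=0.1)
        rng = np.random.default_rng(2)
        choices = []
        for _ in range(10):
            ds = generate_agent_dataset(p, schedule, 0.0, rng)
            choices.append(ds.choice[ds.responded])
        frac_a = np.concatenate(choices) == 0
        se = 0.5 / np.sqrt(len(frac_a))
        assert abs(frac_a.mean() - 0.5) < 4 * se

    def test_omission_fraction_converges(self):
        # fast-terminating agent so window censoring is negligible
        sched = make_schedule(0.8, 5000, 2, 5000)
        p = agent(m=8.0, t=0.3, a=1.5)
        ds = generate_agent_dataset(p, sched, 0.05, np.random.default_rng(3))
        frac = ds.n_omissions / ds.n_trials
        se = np.sqrt(0.05 * 0.95 / ds.n_trials)
        assert abs(frac - 0.05) < 3 * se + 0.005

    def test_bit_identical_under_seed(self, schedule):
        cohort = sample_cohort(CohortSpec(n_subjects=3), np.random.default_rng(4))
        d1 = generate_cohort_data(cohort, schedule, rng=np.random.default_rng(10))
        d2 = generate_cohort_data(cohort, schedule, rng=np.random.default_rng(10))
        for a_, b_ in zip(d1, d2):
            np.testing.assert_array_equal(a_.choice, b_.choice)
            np.testing.assert_array_equal(a_.outcome, b_.outcome)
            np.testing.assert_array_equal(a_.dt, b_.dt)

    def test_on_state_explores_more_than_off(self, schedule):
        """Lower drift-rate scaling under stimulation yields more exploratory
        choices in generative simulation (direction check over cohorts)."""
        from rlddm.summaries import pexplore

        rng = np.random.default_rng(8)
        means = {}
        for cond in ("ON", "OFF"):
            spec = CohortSpec(
                n_subjects=10,
                group_means={cond: dict(DEFAULT_GROUP_MEANS[cond])},
                group_sds={k: 0.0 for k in DEFAULT_GROUP_MEANS[cond]})
            vals = []
            for _ in range(8):
                cohort = sample_cohort(spec, rng)
                for i, subj in enumerate(cohort):
                    ds = generate_agent_dataset(subj[cond], schedule, 0.0, rng,
                                                subject=f"s{i+1:02d}")
                    traj = compute_q_trajectory(ds, subj[cond])
                    vals.append(pexplore(ds, traj))
            means[cond] = np.mean(vals)
        assert means["ON"] > means["OFF"]


class TestSynthVoxelCohort:
    def test_null_effect_correlations_centre_at_zero(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((6, 6, 6), bool)
        mask[:2] = True
        stack, beh = synth_voxel_cohort(40, (6, 6, 6), mask, 0.0, 1.0, rng)
        flat = stack.reshape(40, -1)
        r = np.array([np.corrcoef(flat[:, j], beh)[0, 1] for j in range(flat.shape[1])])
        assert abs(r.mean()) < 0.05

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((5, 5, 5), bool)
        mask[2] = True
        stack, beh = synth_voxel_cohort(20, (5, 5, 5), mask, 0.9, 0.5, rng)
        flat = stack[:, mask]
        r = np.array([np.corrcoef(flat[:, j], beh)[0, 1] for j in range(flat.shape[1])])
        assert r.mean() > 0.7

    def test_two_subjects_degenerate_correlation(self):
        rng = np.random.default_rng(2)
        mask = np.ones((3, 3, 3), bool)
        stack, beh = synth_voxel_cohort(2, (3, 3, 3), mask, 0.5, 1.0, rng)
        flat = stack.reshape(2, -1)
        r = np.array([np.corrcoef(flat[:, j], beh)[0, 1] for j in range(flat.shape[1])])
        assert np.allclose(np.abs(r), 1.0)

    def test_empty_mask_with_effect_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            synth_voxel_cohort(10, (4, 4, 4), np.zeros((4, 4, 4), bool), 0.5,
                               1.0, np.random.default_rng(0))

    def test_stim_volumes_are_binary_spheres(self):
        vols = synth_stim_volumes(5, (12, 12, 12), np.random.default_rng(0))
        assert vols.shape == (5, 12, 12, 12)
        assert vols.dtype == bool
        assert np.all(vols.reshape(5, -1).sum(axis=1) > 0)
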