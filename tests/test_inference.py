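import numpy as np
import pytest

from rlddm.inference import (ContrastSummary, ModelSpec, PosteriorDraws,
                             build_model, compute_dic, dic_from_deviance, hdi,
                             load_posterior, posterior_contrast, run_mcmc,
                             save_posterior)
from rlddm.learning import AgentParams, compute_q_trajectory
from rlddm.wfpt import DiffusionSpec, wfpt_logpdf


class TestBuildModel:
    def test_dual_rate_node_bookkeeping(self, patient_cohort):
        _, data = patient_cohort
        model = build_model(data, ModelSpec())
        # 4 condition-dependent params x 2 conditions + shared t, z
        assert model.P == 10
        assert set(model.param_names) == {
            "a[ON]", "m[ON]", "alpha_pos_raw[ON]", "alpha_neg_raw[ON]",
            "a[OFF]", "m[OFF]", "alpha_pos_raw[OFF]", "alpha_neg_raw[OFF]",
            "t", "z"}

    @pytest.mark.parametrize("window,pred", [
        ("pre_reversal", lambda tr: tr <= 60),
        ("post_reversal", lambda tr: tr > 60),
    ])
    def test_window_slices_likelihood_trials(self, patient_cohort, window, pred):
        _, data = patient_cohort
        model = build_model(data, ModelSpec(window=window))
        expected = sum(int((ds.responded & pred(ds.trial)).sum()) for ds in data)
        assert model.offs[-1] == expected

    def test_empty_window_rejected(self, patient_cohort):
        _, data = patient_cohort
        with pytest.raises(ValueError, match="window"):
            build_model(data, ModelSpec(window="pre_reversal", reversal_trial=0))

    def test_loglik_equals_sum_of_wfpt_terms(self, patient_cohort):
        """The model likelihood at a point is exactly the trial-wise sum of
        WFPT log densities along the delta-rule trajectory."""
        _, data = patient_cohort
        model = build_model(data, ModelSpec())
        rng = np.random.default_rng(0)
        theta = model._init_theta(rng)
        expected = 0.0
        for ds in data:
            s = model.subjects.index(ds.subject)
            p = AgentParams(
                a=theta[s, model.col("a", ds.condition)],
                m=theta[s, model.col("m", ds.condition)],
                alpha_pos_raw=theta[s, model.col("alpha_pos_raw", ds.condition)],
                alpha_neg_raw=theta[s, model.col("alpha_neg_raw", ds.condition)],
                t=theta[s, model.col("t")], z=theta[s, model.col("z")])
            traj = compute_q_trajectory(ds, p)
            for i in np.where(ds.responded)[0]:
                spec = DiffusionSpec(v=traj.drift[i], a=p.a, z=p.z, t=p.t)
                expected += wfpt_logpdf(ds.dt[i], "upper" if ds.choice[i] == 0
                                        else "lower", spec)
        assert model.loglik(theta) == pytest.approx(expected, rel=1e-10)


class TestRunMcmc:
    def test_deterministic_under_seed(self, patient_cohort):
        _, data = patient_cohort
        model = build_model(data[:4], ModelSpec())
        p1 = run_mcmc(model, chains=1, burn=100, draws=100, seed=3)
        p2 = run_mcmc(model, chains=1, burn=100, draws=100, seed=3)
        np.testing.assert_array_equal(p1.group_mu, p2.group_mu)
        np.testing.assert_array_equal(p1.subject, p2.subject)

    def test_converged_fit_recovers_group_structure(self, fitted_patients):
        model, post = fitted_patients
        assert max(post.rhat.values()) < 1.1
        # lower drift-rate scaling under stimulation, as generated
        on = post.group_mu_flat("m", "ON").mean()
        off = post.group_mu_flat("m", "OFF").mean()
        assert on < off

    def test_single_rate_variant_ties_learning_rates(self, patient_cohort):
        _, data = patient_cohort
        model = build_model(data[:6], ModelSpec(variant="single_rate"))
        post = run_mcmc(model, chains=1, burn=200, draws=200, seed=1)
        for cond in post.conditions:
            np.testing.assert_array_equal(
                post.group_mu_flat("alpha_pos_raw", cond),
                post.group_mu_flat("alpha_neg_raw", cond))

    def test_posterior_round_trips_through_disk(self, fitted_patients, tmp_path):
        _, post = fitted_patients
        path = tmp_path / "post.npz"
        save_posterior(post, path)
        back = load_posterior(path)
        np.testing.assert_array_equal(back.group_mu, post.group_mu)
        assert back.param_names == post.param_names
        assert back.conditions == post.conditions


class TestDic:
    def test_degenerate_posterior_has_zero_complexity(self):
        dev = np.full(500, 123.4)
        assert dic_from_deviance(dev, 123.4) == pytest.approx(123.4)

    def test_conjugate_normal_mean_oracle(self):
        """DIC on a normal-mean model matches the closed form: the effective
        number of parameters is n * posterior variance."""
        rng = np.random.default_rng(0)
        n, prior_var = 20, 100.0
        y = rng.normal(1.0, 1.0, n)
        post_var = 1.0 / (n + 1.0 / prior_var)
        post_mean = post_var * y.sum()
        theta = rng.normal(post_mean, np.sqrt(post_var), 200000)
        dev = np.array([np.sum((y - th) ** 2) for th in theta]) + n * np.log(2 * np.pi)
        dev_hat = np.sum((y - post_mean) ** 2) + n * np.log(2 * np.pi)
        dic = dic_from_deviance(dev, dev_hat)
        pd_expected = n * post_var
        assert dic == pytest.approx(dev_hat + 2 * pd_expected, abs=0.1)

    def test_dic_of_fit_exceeds_fitted_deviance(self, fitted_patients):
        model, post = fitted_patients
        d_hat = -2.0 * model.loglik(post.subject_point_estimates())
        assert compute_dic(post, model) > d_hat


class TestHdiAndContrasts:
    def test_hdi_matches_normal_quantiles(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0, 1, 100000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)
        lo85, hi85 = hdi(draws, 0.85)
        assert lo < lo85 < hi85 < hi  # nesting

    def _fake_posterior(self, draws_on, draws_off):
        names = ["a[OFF]", "m[OFF]", "alpha_pos_raw[OFF]", "alpha_neg_raw[OFF]",
                 "a[ON]", "m[ON]", "alpha_pos_raw[ON]", "alpha_neg_raw[ON]",
                 "t", "z"]
        n = len(draws_on)
        gmu = np.zeros((1, n, 10))
        gmu[0, :, names.index("m[ON]")] = draws_on
        gmu[0, :, names.index("m[OFF]")] = draws_off
        return PosteriorDraws(subject=np.zeros((1, n, 1, 10)), group_mu=gmu,
                              group_sd=np.ones_like(gmu),
                              deviance=np.zeros((1, n)), param_names=names,
                              subjects=["s01"], conditions=["OFF", "ON"],
                              rhat={}, accept_rate=0.4)

    def test_self_contrast_is_null(self):
        rng = np.random.default_rng(2)
        d = rng.normal(2.0, 1.0, 5000)
        post = self._fake_posterior(d, d.copy())
        c = posterior_contrast(post, "m", "ON", "OFF")
        assert c.m_diff == pytest.approx(0.0)
        assert c.hdi95[0] <= 0 <= c.hdi95[1]
        assert not c.significant

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        off = rng.normal(4.0, 1.0, 5000)
        post0 = self._fake_posterior(off.copy(), off)
        post1 = self._fake_posterior(off + 0.7, off)
        c0 = posterior_contrast(post0, "m", "ON", "OFF")
        c1 = posterior_contrast(post1, "m", "ON", "OFF")
        assert c1.m_diff - c0.m_diff == pytest.approx(0.7)

    def test_unknown_node_rejected(self):
        post = self._fake_posterior(np.zeros(10), np.zeros(10))
        with pytest.raises((KeyError, ValueError)):
            posterior_contrast(post, "m", "ON", "HC")
        with pytest.raises(KeyError):
            posterior_contrast(post, "t", "ON", "OFF")

    def test_hdi85_nested_in_hdi95(self):
        rng = np.random.default_rng(4)
        post = self._fake_posterior(rng.normal(1, 1, 5000), rng.normal(0, 1, 5000))
        c = posterior_contrast(post, "m", "ON", "OFF")
        assert c.hdi95[0] < c.hdi85[0] < c.hdi85[1] < c.hdi95[1]
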