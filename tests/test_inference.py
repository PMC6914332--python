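"""Model construction, priors, MCMC and variational estimation."""

import numpy as np
import pandas as pd
import pytest

from conftest import uniform_random_table
from gazerace import likelihood as lk
from gazerace._stats import hpd_interval, kde_map, truncnorm_mean
from gazerace.inference import build_model, extract_estimates, fit_mcmc, fit_vi
from gazerace.simulate import GroupSpec, simulate_group


class TestBuildModel:
    def test_pooled_has_four_free_parameters(self):
        df = uniform_random_table(np.random.default_rng(0), 50, n_subjects=2)
        model = build_model(df, kind="pooled")
        assert model.n_free_parameters == 4

    def test_fixed_gamma_removed_from_free_parameters(self):
        df = uniform_random_table(np.random.default_rng(0), 50, n_subjects=2)
        model = build_model(df, kind="individual", gamma_val=1.0)
        assert {i.param for i in model.instances} == {"v", "sigma", "tau"}
        assert np.all(model.fixed_values["gamma"] == 1.0)

    def test_hierarchical_group_dependencies_make_level_instances(self, grouped_sim):
        model = build_model(grouped_sim.data, kind="hierarchical",
                            depends_on={"v": "group", "gamma": "group",
                                        "s": "group", "tau": "group"})
        assert model.n_instances == 8  # 4 parameters x 2 groups
        assert len(model.hyper_mu) == 8 and len(model.hyper_sd) == 8
        # between-subject design: each subject only owns its group's instances
        assert model.used.sum(axis=1).tolist() == [4] * 16

    def test_unknown_dependency_errors(self):
        df = uniform_random_table(np.random.default_rng(0), 20)
        with pytest.raises(ValueError, match="unknown parameter"):
            build_model(df, depends_on={"zeta": "speed"})
        with pytest.raises(ValueError, match="unknown factor"):
            build_model(df, depends_on={"v": "speed"})

    def test_fixed_and_dependent_conflict(self):
        df = uniform_random_table(np.random.default_rng(0), 20)
        df["cond"] = "a"
        with pytest.raises(ValueError, match="both fixed and dependent"):
            build_model(df, depends_on={"gamma": "cond"}, gamma_val=1.0)

    def test_per_subject_fixed_list_length_checked(self):
        df = uniform_random_table(np.random.default_rng(0), 20, n_subjects=2)
        with pytest.raises(ValueError, match="length-2"):
            build_model(df, gamma_val=[1.0, 0.5, 0.3])

    def test_within_subject_dependency(self, table1_path):
        from gazerace.data import load_trial_table

        big = []
        rng = np.random.default_rng(1)
        for s in range(2):
            df = uniform_random_table(rng, 30)
            df["subject"] = s
            df["speed"] = np.where(df["trial"] % 2 == 0, "fast", "slow")
            big.append(df)
        df = pd.concat(big, ignore_index=True)
        model = build_model(df, kind="individual", depends_on={"v": "speed"})
        names = [i.name for i in model.instances]
        assert "v_fast" in names and "v_slow" in names
        assert model.n_free_parameters == 2 * 5  # (2 v's + 3 others) per subject


class TestLogDensity:
    def test_model_likelihood_matches_trial_likelihood(self, biased_sim):
        model = build_model(biased_sim.data, kind="individual")
        rng = np.random.default_rng(2)
        theta = np.column_stack([
            rng.uniform(0.3, 1.5, 4), rng.uniform(-1, 1, 4),
            rng.uniform(0.15, 0.5, 4), rng.uniform(0.3, 2.5, 4)])
        pointwise = model.loglik_pointwise(theta)
        bounds = biased_sim.data.groupby("subject")["rt"].agg(["min", "max"])
        for idx in rng.choice(len(biased_sim.data), 25, replace=False):
            row = biased_sim.data.iloc[idx]
            s = int(row["subject"])
            params = lk.ParameterSet(*theta[s])
            cont = lk.ContaminantModel(3, bounds.loc[s, "min"],
                                       bounds.loc[s, "max"], 0.05)
            ref = lk.trial_likelihood(row, params, cont).log_likelihood
            assert abs(pointwise[idx] - ref) < 1e-8


class TestPriorSampling:
    def test_prior_only_respects_bounds_and_hyperprior_means(self, monkeypatch):
        # disable the likelihood: the sampler must reproduce the priors
        df = uniform_random_table(np.random.default_rng(3), 30, n_subjects=2)
        model = build_model(df, kind="hierarchical")
        monkeypatch.setattr(
            model, "loglik_pointwise",
            lambda theta: np.zeros(model.n_trials))
        post = fit_mcmc(model, draws=2500, tune=1000, chains=2, seed=4)
        import arviz as az

        idata = post.to_inference_data()
        for k, inst in enumerate(model.instances):
            mu = post.stacked(f"{inst.name}_mu")
            hyper = model.hyper_mu[k]
            assert mu.min() >= hyper.lower and mu.max() <= hyper.upper
            expected = truncnorm_mean(hyper.loc, hyper.scale, hyper.lower,
                                      hyper.upper)
            ess = float(az.ess(idata, var_names=[f"{inst.name}_mu"])
                        [f"{inst.name}_mu"].values)
            se = mu.std() / np.sqrt(max(ess, 4.0))
            assert abs(mu.mean() - expected) < 5 * se
            for s in range(2):
                sub = post.stacked(f"{inst.name}[{s}]")
                lo, hi = model.bounds_lo[k], model.bounds_hi[k]
                assert sub.min() >= lo and sub.max() <= hi

    def test_uniform_prior_bounds_respected(self, monkeypatch):
        df = uniform_random_table(np.random.default_rng(5), 30)
        model = build_model(df, kind="individual")
        monkeypatch.setattr(model, "loglik_pointwise",
                            lambda theta: np.zeros(model.n_trials))
        post = fit_mcmc(model, draws=1500, tune=500, chains=2, seed=6)
        for k, inst in enumerate(model.instances):
            x = post.stacked(f"{inst.name}[0]")
            assert x.min() >= model.bounds_lo[k]
            assert x.max() <= model.bounds_hi[k]


class TestMCMC:
    def test_recovery_and_convergence(self, biased_sim, individual_fit):
        est = extract_estimates(individual_fit)
        truth = biased_sim.parameters
        for p in ("v", "gamma"):
            err = est[p].to_numpy() - truth[p].to_numpy()
            assert np.max(np.abs(err)) < 0.2
        diag = individual_fit.diagnostics()
        assert (diag["rhat"] < 1.1).all()
        assert (diag["ess_bulk"] > 50).all()

    def test_truth_inside_most_hpds(self, biased_sim, individual_fit):
        est = extract_estimates(individual_fit)
        truth = biased_sim.parameters
        inside = 0
        for p in ("v", "gamma", "sigma", "tau"):
            inside += int(((truth[p] >= est[f"{p}_hpd_2.5"]) &
                           (truth[p] <= est[f"{p}_hpd_97.5"])).sum())
        assert inside >= 13  # of 16 subject x parameter cells

    def test_fixed_gamma_absent_from_samples(self, biased_sim):
        model = build_model(biased_sim.data.query("subject < 2").copy(),
                            kind="individual", gamma_val=1.0)
        post = fit_mcmc(model, draws=150, tune=150, chains=2, seed=8)
        assert not any(v.startswith("gamma") for v in post.samples)
        est = extract_estimates(post)
        assert "gamma" not in est.columns

    def test_chain_requirements(self, biased_sim):
        model = build_model(biased_sim.data, kind="individual")
        with pytest.raises(ValueError, match="two chains"):
            fit_mcmc(model, draws=10, tune=10, chains=1)
        with pytest.raises(ValueError, match="positive"):
            fit_mcmc(model, draws=0, tune=10, chains=2)

    def test_mala_step_runs(self, biased_sim):
        small = biased_sim.data.query("subject == 0").copy()
        model = build_model(small, kind="individual")
        post = fit_mcmc(model, draws=100, tune=200, chains=2, seed=9,
                        step="mala")
        assert np.isfinite(post.stacked("v[0]")).all()

    def test_shrinkage_of_hierarchical_estimates(self):
        sim = simulate_group(GroupSpec(
            kind="hierarchical", n_individuals=10, n_trials=50,
            parameters={"gamma": {"mu": 0.2, "sd": 0.3}}, seed=10))
        mh = build_model(sim.data, kind="hierarchical")
        mi = build_model(sim.data, kind="individual")
        ph = fit_mcmc(mh, draws=800, tune=1200, chains=2, seed=11)
        pi_ = fit_mcmc(mi, draws=800, tune=1200, chains=2, seed=11)
        gh = extract_estimates(ph)["gamma"].to_numpy()
        gi = extract_estimates(pi_)["gamma"].to_numpy()
        assert np.var(gh) <= np.var(gi)


class TestEstimates:
    def test_hpd_and_map_degenerate_and_symmetric(self):
        x = np.full(500, 1.23)
        assert kde_map(x) == 1.23
        lo, hi = hpd_interval(x)
        assert lo == hi == 1.23
        rng = np.random.default_rng(12)
        y = rng.normal(2.0, 0.1, 4000)
        assert abs(kde_map(y) - 2.0) < 0.02
        lo, hi = hpd_interval(y, 0.95)
        assert abs(lo - (2 - 1.96 * 0.1)) < 0.02
        assert abs(hi - (2 + 1.96 * 0.1)) < 0.02

    def test_too_few_samples_rejected(self, biased_sim):
        model = build_model(biased_sim.data.query("subject == 0").copy(),
                            kind="individual")
        post = fit_mcmc(model, draws=30, tune=50, chains=2, seed=13)
        with pytest.raises(ValueError, match="100"):
            extract_estimates(post)

    def test_group_level_rows_present(self, hierarchical_fit):
        grp = extract_estimates(hierarchical_fit, level="group")
        assert set(grp["parameter"]) == {"v", "gamma", "sigma", "tau"}
        gamma_rows = grp[grp["parameter"] == "gamma"]
        assert set(gamma_rows["condition"]) == {"ctrl", "pat"}
        assert (grp["mu_hpd_2.5"] < grp["mu_hpd_97.5"]).all()

    def test_pooled_estimates_replicated_per_subject(self):
        df = uniform_random_table(np.random.default_rng(14), 60, n_subjects=2)
        model = build_model(df, kind="pooled")
        post = fit_mcmc(model, draws=200, tune=300, chains=2, seed=15)
        est = extract_estimates(post)
        assert len(est) == 2
        assert est["v"].nunique() == 1


@pytest.fixture(scope="module")
def vi_fit(biased_sim):
    small = biased_sim.data.query("subject < 2").copy()
    model = build_model(small, kind="individual")
    return model, fit_vi(model, iterations=2500, seed=16)


class TestVI:
    def test_metadata_flags_approximation(self, vi_fit):
        _, post = vi_fit
        assert post.metadata["method"] == "VI"
        assert post.metadata["approximate"] is True

    def test_vi_close_to_mcmc(self, vi_fit, individual_fit):
        _, post = vi_fit
        vi_est = extract_estimates(post)
        mc_est = extract_estimates(individual_fit).query("subject < 2")
        for p in ("v", "gamma"):
            diff = vi_est[p].to_numpy() - mc_est[p].to_numpy()
            assert np.max(np.abs(diff)) < 0.15

    def test_vi_reproducible_under_seed(self, vi_fit):
        model, post = vi_fit
        again = fit_vi(model, iterations=2500, seed=16)
        np.testing.assert_array_equal(post.stacked("v[0]"),
                                      again.stacked("v[0]"))
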