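"""Joint posterior, MCMC machinery, convergence diagnostics, PPC."""

import numpy as np
import pytest
from scipy import stats

from cetipm.inference import (
    FitConfig, IPMData, LatentState, PriorConfig, _default_init, _init_latents,
    _me_loglik, _Prepared, fit, joint_log_posterior, posterior_predictive_check,
    rhat, rhat_array, sample_latent_state,
)
from cetipm.multievent import dataset_loglik
from cetipm.population import aggregate_detection, aggregate_latent


def make_params(T, seed=0):
    return _default_init(T, np.random.default_rng(seed))


def make_latents(params, data, seed=0):
    rng = np.random.default_rng(seed)
    rates = params.to_rate_series()
    N0 = np.array([20, 15, 11, 8, 5, 2, 36, 24, 19, 26, 34])
    return sample_latent_state(N0, rates, rng)


class TestJointLogPosterior:
    def test_component_decomposition(self, ipm_data):
        """Joint equals the sum of its four published components."""
        params = make_params(ipm_data.n_years, seed=3)
        latents = _init_latents(params, ipm_data, PriorConfig())
        comps = joint_log_posterior(params, latents, ipm_data, return_components=True)
        total = joint_log_posterior(params, latents, ipm_data)
        assert np.isfinite(total)
        assert total == pytest.approx(sum(comps), abs=1e-10)

    def test_out_of_support_is_minus_inf(self, ipm_data):
        params = make_params(ipm_data.n_years, seed=3)
        latents = _init_latents(params, ipm_data, PriorConfig())
        params.means["phiF"] = 1.2
        assert joint_log_posterior(params, latents, ipm_data) == -np.inf
        params.means["phiF"] = 0.9
        params.sds["sd_gamma"] = -0.1
        assert joint_log_posterior(params, latents, ipm_data) == -np.inf

    def test_empty_histories_drop_multievent_term(self, ipm_data):
        params = make_params(ipm_data.n_years, seed=3)
        latents = _init_latents(params, ipm_data, PriorConfig())
        full = joint_log_posterior(params, latents, ipm_data, return_components=True)
        empty = IPMData(histories=[], counts=ipm_data.counts, effort=ipm_data.effort)
        comps = joint_log_posterior(params, latents, empty, return_components=True)
        assert comps[0] == 0.0
        assert comps[1:] == full[1:]

    def test_state_process_matches_scipy_oracle(self, ipm_data):
        """Branch-count log-probability vs direct scipy binomial/Poisson sums."""
        params = make_params(ipm_data.n_years, seed=5)
        lat = make_latents(params, ipm_data, seed=5)
        _, _, got, _ = joint_log_posterior(
            params, lat, IPMData([], ipm_data.counts, ipm_data.effort),
            return_components=True)
        # independent recomputation
        r = params.rate_arrays()
        N = lat.abundances().N
        L = lat.branches
        want = 0.0
        for t in range(L.shape[0]):
            pairs = [
                (L[t, 0], N[0, t], r["phiF"][t]), (L[t, 1], L[t, 0], r["psiJuvPb"][t]),
                (L[t, 2], N[1, t], r["phiF"][t]), (L[t, 3], L[t, 2], r["psiPbBy"][t]),
                (L[t, 4], N[2, t], r["phiF"][t]), (L[t, 5], L[t, 4], r["phiBy"][t]),
                (L[t, 6], N[3, t], r["phiF"][t]), (L[t, 7], L[t, 6], r["phiBy"][t]),
                (L[t, 8], N[4, t], r["phiF"][t]), (L[t, 9], L[t, 8], r["phiBy"][t]),
                (L[t, 10], L[t, 9], r["F"][t]), (L[t, 11], N[5, t], r["phiF"][t]),
                (L[t, 12], N[6, t], r["phiF"][t]), (L[t, 13], L[t, 12], r["gamma"][t]),
                (L[t, 14], N[7, t], r["phiJuvSub"][t]), (L[t, 15], L[t, 14], r["psiM"][t]),
                (L[t, 16], N[8, t], r["phiJuvSub"][t]), (L[t, 17], L[t, 16], r["psiM"][t]),
                (L[t, 18], N[9, t], r["phiAd"][t]), (L[t, 19], L[t, 18], r["psiM"][t]),
                (L[t, 20], N[10, t], r["phiAd"][t]),
                (L[t, 21], (L[t, 9] - L[t, 10]) + N[5, t], 0.5),
                (L[t, 23], L[t, 22], 0.5),
            ]
            want += sum(stats.binom.logpmf(k, n, p) for k, n, p in pairs)
            want += stats.poisson.logpmf(L[t, 22], r["omega"][t])
        assert got == pytest.approx(want, abs=1e-8)

    def test_count_term_matches_population_module(self, ipm_data):
        """Jitted count kernel vs the population module's count_loglik."""
        from cetipm.population import count_loglik
        params = make_params(ipm_data.n_years, seed=5)
        latents = _init_latents(params, ipm_data, PriorConfig())
        _, got, _, _ = joint_log_posterior(params, latents, ipm_data,
                                           return_components=True)
        prep = _Prepared(ipm_data)
        pF, pM = params.detection_arrays(prep.effort_z)
        N = latents.abundances().N
        counts = ipm_data.counts.as_matrix()
        want = sum(
            count_loglik(counts[:, t], N[:, t], aggregate_detection(N[:, t], pF[t], pM[t]))
            for t in range(ipm_data.n_years)
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_multievent_term_matches_reference_implementation(self, ipm_data):
        """Batched jitted forward pass vs the plain per-history likelihood."""
        params = make_params(ipm_data.n_years, seed=7)
        prep = _Prepared(ipm_data)
        got = _me_loglik(params, prep, params.rate_arrays())
        eps_F = params.sds["sd_eps_F"] * params.z_eps_F
        eps_M = params.sds["sd_eps_M"] * params.z_eps_M
        want = dataset_loglik(ipm_data.histories, params.to_rate_series(),
                              params.detection_params(), ipm_data.effort,
                              eps_F, eps_M)
        assert got == pytest.approx(want, rel=1e-9)

    def test_latent_abundances_nonnegative_and_consistent(self, ipm_data):
        params = make_params(ipm_data.n_years, seed=5)
        lat = make_latents(params, ipm_data, seed=6)
        N = lat.abundances().N
        assert np.all(N >= 0)
        assert N.shape == (11, ipm_data.n_years)


class TestFit:
    def test_prior_only_determinism(self):
        data = IPMData(histories=[], counts=None, effort=np.full(6, 8))
        cfg = FitConfig(n_chains=2, n_iterations=200, n_burnin=100, thin=5, seed=5)
        a = fit(data, config=cfg)
        b = fit(data, config=cfg)
        for k in a.scalars:
            np.testing.assert_array_equal(a.scalars[k], b.scalars[k])

    def test_full_model_determinism(self, ipm_data):
        cfg = FitConfig(n_chains=2, n_iterations=60, n_burnin=30, thin=3, seed=21)
        a = fit(ipm_data, config=cfg)
        b = fit(ipm_data, config=cfg)
        np.testing.assert_array_equal(a.latent_draws, b.latent_draws)
        for k in a.scalars:
            np.testing.assert_array_equal(a.scalars[k], b.scalars[k])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(n_chains=1).validate()
        with pytest.raises(ValueError):
            FitConfig(n_iterations=100, n_burnin=100).validate()

    def test_stored_draws_satisfy_invariants(self, small_fit):
        for name in ("mean_phiF", "mean_gamma", "mean_deltaPb"):
            x = small_fit.scalar_pooled(name)
            assert np.all((x > 0) & (x < 1))
        for name in ("sd_phiF", "sd_omega"):
            assert np.all(small_fit.scalar_pooled(name) > 0)
        assert np.all(small_fit.scalar_pooled("omega_mean") > 0)
        assert np.all(small_fit.latent_draws >= 0)
        assert np.isfinite(small_fit.diagnostics["log_posterior"]).all()

    def test_posterior_tracks_truth_direction(self, small_fit, scenario):
        """Even a short run should put survival posteriors in the right region."""
        assert small_fit.scalar_pooled("mean_phiF").mean() > 0.85
        assert small_fit.scalar_pooled("mean_phiAd").mean() > 0.8

    def test_summary_and_long_format(self, small_fit):
        s = small_fit.summary()
        assert "mean" in s.columns and "rhat" in s.columns
        df = small_fit.to_dataframe()
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
        assert df["parameter"].nunique() == len(small_fit.scalars)


class TestRhat:
    def test_identical_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 10_000))
        assert rhat_array(x) < 1.01

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 2000))
        x[1] += 10
        assert rhat_array(x) > 1.5

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(42)
        x = np.cumsum(rng.standard_normal((3, 400)), axis=1) * 0.05 \
            + rng.standard_normal((3, 400))
        want = float(az.rhat(x, method="split"))
        assert rhat_array(x) == pytest.approx(want, abs=1e-6)

    def test_requires_multiple_chains(self):
        with pytest.raises(ValueError):
            rhat_array(np.zeros((1, 100)))

    def test_posterior_interface(self, small_fit):
        out = rhat(small_fit)
        assert "mean_phiF" in out
        assert isinstance(out["converged"], bool)


def truth_draws(sim, data, n_chains=2, n_kept=15):
    """Degenerate posterior concentrated at the generative truth."""
    from cetipm.inference import PosteriorDraws, _SCALAR_STORE
    from cetipm.multievent import standardize_effort, detection_probability
    t = sim.truth
    total = n_chains * n_kept
    truth_values = {
        "mean_phiF": t.phiF, "mean_phiBy": t.phiBy, "mean_F": t.F,
        "mean_gamma": t.gamma, "mean_psiJuvPb": t.psiJuvPb,
        "mean_psiPbBy": t.psiPbBy, "mean_phiJuvSub": t.phiJuvSubM,
        "mean_phiAd": t.phiAdM, "mean_psiM": t.psiM,
        "mean_deltaPb": t.detection.deltaPb, "mean_deltaNb": t.detection.deltaNb,
        "mean_deltaAdNt": t.detection.deltaAdNt, "mean_deltaAd": t.detection.deltaAd,
        "alpha_F": t.detection.alpha_F, "beta_effort": t.detection.beta_effort,
        "alpha_M_0": t.detection.alpha_M_by_stage[0],
        "alpha_M_1": t.detection.alpha_M_by_stage[1],
        "alpha_M_2": t.detection.alpha_M_by_stage[2],
        "alpha_M_3": t.detection.alpha_M_by_stage[3],
        "omega_mean": t.omega_mean,
    }
    scalars = {k: np.full((n_chains, n_kept), truth_values.get(k, 0.1))
               for k in _SCALAR_STORE}
    z = standardize_effort(sim.effort)
    pF = detection_probability(t.detection.alpha_F, t.detection.beta_effort,
                               z, sim.eps_F)
    pM = np.stack([
        detection_probability(t.detection.alpha_M_by_stage,
                              t.detection.beta_effort, z[i], sim.eps_M[i])
        for i in range(len(z))
    ])
    return PosteriorDraws(
        scalars=scalars,
        rate_draws={k: np.tile(getattr(sim.rates, k), (total, 1))
                    for k in ("phiF", "phiBy", "F", "gamma", "phiJuvSub", "phiAd", "omega")},
        detection_pF=np.tile(pF, (total, 1)),
        detection_pM=np.tile(pM, (total, 1, 1)),
        latent_draws=np.tile(sim.latent.N, (total, 1, 1)),
        chain=np.repeat(np.arange(n_chains), n_kept),
        iteration=np.tile(np.arange(n_kept), n_chains),
        n_years=sim.truth.n_years,
    )


class TestPosteriorPredictiveCheck:
    def test_bounded_and_deterministic(self, sim, ipm_data):
        draws = truth_draws(sim, ipm_data)
        a = posterior_predictive_check(draws, ipm_data, seed=3, max_draws=20)
        b = posterior_predictive_check(draws, ipm_data, seed=3, max_draws=20)
        assert a == b
        for v in a.values():
            assert 0.0 <= v <= 1.0

    def test_null_calibration(self, scenario):
        """Data generated at the truth should rarely look extreme."""
        from cetipm import simulate_dataset
        inside = 0
        n_reps = 6
        for rep in range(n_reps):
            s = simulate_dataset(scenario, seed=1000 + rep)
            d = IPMData(histories=s.histories, counts=s.counts, effort=s.effort)
            draws = truth_draws(s, d)
            pvals = posterior_predictive_check(draws, d, seed=rep, max_draws=25)
            if all(0.05 < v < 0.95 for v in pvals.values()):
                inside += 1
        assert inside >= n_reps - 2

    def test_on_fitted_model(self, small_fit, ipm_data):
        pvals = posterior_predictive_check(small_fit, ipm_data, seed=0, max_draws=25)
        assert set(pvals) == {"counts", "histories"}
        for v in pvals.values():
            assert 0.0 <= v <= 1.0
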