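import numpy as np
import pytest
from scipy import stats

from tdmbayes import (EventRecord, PatientCovariates, SamplerSettings,
                      TDMDataset, get_default_prior, get_sample_data)
from tdmbayes.engine import (PosteriorDesign, batched_hmc, batched_map,
                             ess_bulk, nuts_sample, split_rhat)
from tdmbayes.estimators import prior_only_design
from tdmbayes.priors import ErrorModel, ParameterPrior, PriorSpec


def _one_obs_dataset(drug="amikacin", t=8.0, dv=6.0):
    ds = TDMDataset(drug=drug)
    ds.covariates[1] = PatientCovariates(weight=65.1, height=165.1, age=50.2,
                                         sex="male", scr=1.0)
    amt, rate = (500.0, 1000.0) if drug != "theophylline" else (200.0, 0.0)
    if drug == "phenytoin":
        amt, rate = 100.0, 50.0
    ds.events[1] = [EventRecord(id=1, time=0.0, evid=1, amt=amt, rate=rate,
                                ii=8.0),
                    EventRecord(id=1, time=t, evid=0, dv=dv)]
    return ds


def _single_param_prior():
    """Amikacin-like prior with only CLslope free (for grid-search oracles)."""
    base = get_default_prior("amikacin")
    params = tuple(
        p if p.name == "CLslope" else
        ParameterPrior(p.name, p.mean, 0.0, unit=p.unit)
        for p in base.parameters)
    return PriorSpec(drug="amikacin", model_id="1cmt_iv", parameters=params,
                     error=base.error)


class TestLogPosterior:
    def test_hand_summed_value(self):
        """One observation, one free parameter: the log posterior equals
        prior + likelihood normal log-densities summed by hand."""
        prior = _single_param_prior()
        ds = _one_obs_dataset(dv=6.0)
        design = PosteriorDesign.from_dataset(ds, prior)
        eta = np.array([[0.3]])
        lp = design.log_posterior(eta)[0]
        # independent computation
        from tdmbayes import derive_structural_params, IndividualParams
        from tdmbayes.pkmodels import Dose, conc_1cmt_iv
        cov, _ = ds.single()
        p = IndividualParams.from_prior(prior, {"CLslope": 0.3})
        d = derive_structural_params("amikacin", p, cov)
        cpred = conc_1cmt_iv(d.cl, d.v, [Dose(0.0, 500.0, 1000.0)], [8.0])[0]
        sigma = 0.15 * cpred + 0.25
        omega = prior["CLslope"].omega
        want = stats.norm.logpdf(0.3, 0.0, omega) \
            + stats.norm.logpdf(6.0, cpred, sigma)
        assert lp == pytest.approx(want, rel=1e-12)

    def test_sigma_from_predicted_concentration(self):
        """sigma = 0.15*C_pred + 0.25 at C_pred = 10 gives 1.75."""
        err = get_default_prior("amikacin").error
        assert err.sigma(10.0) == pytest.approx(1.75)

    def test_prior_only_gradient_zero_at_origin(self):
        design = prior_only_design(get_default_prior("vancomycin"))
        _, g = design.value_and_grad(np.zeros((1, design.K)))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)


class TestGradient:
    @pytest.mark.parametrize("drug,tol", [
        ("amikacin", 1e-4), ("vancomycin", 1e-4), ("theophylline", 1e-4),
        ("phenytoin", 1e-3),
    ])
    def test_matches_central_finite_differences(self, drug, tol, rng):
        ds = _one_obs_dataset(drug, t=8.0, dv=4.0)
        design = PosteriorDesign.from_dataset(ds, get_default_prior(drug))
        eta = 0.3 * rng.standard_normal((1, design.K))
        _, g = design.value_and_grad(eta)
        h = 1e-5
        for k in range(design.K):
            ep, em = eta.copy(), eta.copy()
            ep[0, k] += h
            em[0, k] -= h
            fd = (design.log_posterior(ep)[0] - design.log_posterior(em)[0]) / (2 * h)
            assert g[0, k] == pytest.approx(fd, rel=tol)

    def test_sigma_dependence_contributes(self, rng):
        """The gradient differs from the fixed-sigma variant: sigma's
        dependence on C_pred is part of the likelihood."""
        ds = _one_obs_dataset("amikacin", dv=6.0)
        design = PosteriorDesign.from_dataset(ds, get_default_prior("amikacin"))
        eta = np.array([[0.1, -0.1, 0.2]])
        _, g = design.value_and_grad(eta)
        # fixed-sigma likelihood gradient by finite differences
        sig0 = 0.15 * design.predict(eta) + 0.25

        def lp_fixed(e):
            cp = design.predict(e)
            z = (design.obs - cp) / sig0
            return design.log_prior(e) + (-0.5 * np.log(2 * np.pi)
                                          - np.log(sig0) - 0.5 * z * z).sum(-1)
        h = 1e-6
        g_fixed = np.zeros(design.K)
        for k in range(design.K):
            ep, em = eta.copy(), eta.copy()
            ep[0, k] += h
            em[0, k] -= h
            g_fixed[k] = (lp_fixed(ep)[0] - lp_fixed(em)[0]) / (2 * h)
        assert not np.allclose(g[0], g_fixed, rtol=1e-3)


class TestSamplers:
    def test_nuts_reproducible(self):
        design = prior_only_design(get_default_prior("amikacin"))
        s = SamplerSettings(chains=2, warmup=100, samples=100)
        d1, _ = nuts_sample(design, s, np.random.default_rng(42))
        d2, _ = nuts_sample(design, s, np.random.default_rng(42))
        np.testing.assert_array_equal(d1, d2)

    def test_batched_hmc_reproducible_and_prior_correct(self):
        prior = get_default_prior("theophylline")
        design = PosteriorDesign(prior, np.empty(0), np.empty((40, 0)), [],
                                 lbw=np.full(40, 50.0), crcl_lh=np.full(40, 4.0))
        s = SamplerSettings.reduced(chains=1)
        d1, i1 = batched_hmc(design, s, np.random.default_rng(3))
        d2, _ = batched_hmc(design, s, np.random.default_rng(3))
        np.testing.assert_array_equal(d1, d2)
        pooled = d1.reshape(-1, design.K)
        # 40 rows x 500 draws of the prior: means near 0, sd near omega
        assert np.abs(pooled.mean(0)) .max() < 0.02
        np.testing.assert_allclose(pooled.std(0), design.omega, rtol=0.05)
        assert i1["divergences"].sum() == 0

    def test_dense_low_noise_data_recovers_clearance(self):
        """Hourly near-noiseless data pins CL within 5%."""
        from tdmbayes import IndividualParams, simulate_profile, \
            derive_structural_params
        prior = get_default_prior("amikacin")
        cov = PatientCovariates(weight=65.1, height=165.1, age=50.2,
                                sex="male", scr=1.0)
        truth = IndividualParams.from_prior(prior, {"CLslope": 0.25,
                                                    "CLnr": -0.1, "Vnr": 0.2})
        ev = [EventRecord(time=0.0, evid=1, amt=500.0, rate=1000.0, ii=8.0)]
        times = np.arange(1.0, 9.0)
        conc = simulate_profile("amikacin", truth, cov, ev, times).conc
        ds = TDMDataset(drug="amikacin")
        ds.covariates[1] = cov
        ds.events[1] = [ev[0]] + [EventRecord(id=1, time=float(t), evid=0,
                                              dv=float(c))
                                  for t, c in zip(times, conc)]
        low_noise = PriorSpec(
            drug="amikacin", model_id="1cmt_iv",
            parameters=prior.parameters,
            error=ErrorModel(cv_assay=1e-3, s_assay=1e-3))
        design = PosteriorDesign.from_dataset(ds, low_noise)
        draws, _ = nuts_sample(design, SamplerSettings(chains=2, warmup=300,
                                                       samples=300),
                               np.random.default_rng(5))
        eta_med = np.median(draws.reshape(-1, design.K), axis=0)
        est = IndividualParams.from_prior(
            prior, dict(zip(prior.estimated_names, eta_med)))
        cl_est = derive_structural_params("amikacin", est, cov).cl
        cl_true = derive_structural_params("amikacin", truth, cov).cl
        assert cl_est == pytest.approx(cl_true, rel=0.05)


class TestMAP:
    def test_no_observations_returns_prior_means_exactly(self):
        design = prior_only_design(get_default_prior("phenytoin"))
        eta, val, info = batched_map(design)
        np.testing.assert_array_equal(eta, 0.0)
        assert info["n_restarts_used"] == 0

    @pytest.mark.parametrize("objective", ["phi", "posterior_mode"])
    def test_single_parameter_matches_grid_search(self, objective):
        """Quasi-Newton optimum vs a 4001-point grid over +-4 omega."""
        prior = _single_param_prior()
        ds = _one_obs_dataset(dv=9.0)
        design = PosteriorDesign.from_dataset(ds, prior)
        eta, _, _ = batched_map(design, starts=3,
                                rng=np.random.default_rng(0),
                                objective=objective)
        omega = design.omega[0]
        grid = np.linspace(-4 * omega, 4 * omega, 4001)
        if objective == "phi":
            vals = design.phi(grid[:, None, None])[:, 0]
        else:
            vals = -design.log_posterior(grid[:, None, None])[:, 0]
        best = grid[np.argmin(vals)]
        assert eta[0, 0] == pytest.approx(best, abs=(grid[1] - grid[0]))

    def test_phi_at_optimum_not_worse_than_prior_means(self):
        ds = _one_obs_dataset(dv=9.0)
        design = PosteriorDesign.from_dataset(ds,
                                              get_default_prior("amikacin"))
        eta, val, _ = batched_map(design, objective="phi")
        assert design.phi(eta)[0] <= design.phi(np.zeros_like(eta))[0]


class TestDiagnostics:
    def test_iid_draws_rhat_near_one(self, rng):
        x = rng.standard_normal((4, 4, 1000))
        r = split_rhat(x)
        np.testing.assert_allclose(r, 1.0, atol=0.01)

    def test_constant_chains_flagged(self):
        x = np.ones((2, 100))
        r = split_rhat(x)
        assert not np.isfinite(r) or r > 1.1

    def test_ess_bounded_by_total_draws(self, rng):
        x = rng.standard_normal((4, 500))
        assert ess_bulk(x) <= 2000

    def test_autocorrelated_chain_has_smaller_ess(self, rng):
        iid = rng.standard_normal((4, 1000))
        ar = np.empty((4, 1000))
        ar[:, 0] = iid[:, 0]
        for t in range(1, 1000):
            ar[:, t] = 0.9 * ar[:, t - 1] + np.sqrt(1 - 0.81) * iid[:, t]
        assert ess_bulk(ar) < 0.5 * ess_bulk(iid)

    def test_matches_arviz(self, rng):
        """Dual-route check of the vectorized R-hat/ESS against arviz."""
        az = pytest.importorskip("arviz")
        x = rng.standard_normal((4, 400))
        x[1] += 0.3  # mild between-chain shift
        assert split_rhat(x) == pytest.approx(
            float(az.rhat(x[None].transpose(1, 0, 2)[:, 0, :])), rel=0.01)
        assert ess_bulk(x) == pytest.approx(
            float(az.ess(x[None].transpose(1, 0, 2)[:, 0, :], method="bulk")),
            rel=0.05)

    def test_single_chain_rhat_requires_two(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).standard_normal((1, 100)))
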