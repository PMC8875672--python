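"""Individual-patient estimators: full-posterior HMC and MAP optimization.

`HMCEstimator` and `MAPEstimator` are scikit-learn style estimators: they
are configured in ``__init__``, fitted on a single-patient TDM dataset with
``fit``, expose fitted attributes with trailing underscores, and predict
concentrations at requested times with ``predict``. The module-level
functions (`log_posterior`, `grad_log_posterior`, `hmc_fit`, `map_fit`,
`diagnostics`) are thin wrappers over the same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .covariates import PatientCovariates
from .dataio import TDMDataset
from .engine import (PosteriorDesign, SamplerSettings, batched_map, ess_bulk,
                     nuts_sample, split_rhat)
from .params import IndividualParams
from .pkmodels import EventRecord, simulate_profile
from .priors import PriorSpec, get_default_prior

__all__ = [
    "HMCEstimator",
    "MAPEstimator",
    "PosteriorResult",
    "MAPResult",
    "log_posterior",
    "grad_log_posterior",
    "hmc_fit",
    "map_fit",
    "diagnostics",
    "prior_only_design",
]

RHAT_LIMIT = 1.1


def prior_only_design(prior: PriorSpec) -> PosteriorDesign:
    """Design with no observations: the posterior equals the prior."""
    return PosteriorDesign(prior, obs_times=np.empty(0), obs=np.empty((1, 0)),
                           doses=[], lbw=50.0, crcl_lh=4.0, tbw=65.0)


def _design_for(drug: str, ds: TDMDataset, prior: PriorSpec | None,
                rk4_h: float = 0.1) -> PosteriorDesign:
    prior = prior or get_default_prior(drug)
    if prior.drug != get_default_prior(drug).drug:
        raise ValueError(f"prior is for {prior.drug!r}, not {drug!r}")
    return PosteriorDesign.from_dataset(ds, prior, rk4_h=rk4_h)


def log_posterior(drug: str, ds: TDMDataset, prior: PriorSpec, eta) -> float:
    """Log posterior density (up to no constant: fully normalized normal
    terms) of the eta vector for one patient."""
    design = _design_for(drug, ds, prior)
    eta = np.asarray(eta, float)
    if eta.shape != (design.K,):
        raise ValueError(f"eta must have length {design.K} for {drug}")
    return float(design.log_posterior(eta[None, :])[0])


def grad_log_posterior(drug: str, ds: TDMDataset, prior: PriorSpec, eta) -> np.ndarray:
    """Gradient of `log_posterior` with respect to eta (complex-step)."""
    design = _design_for(drug, ds, prior)
    eta = np.asarray(eta, float)
    _, g = design.value_and_grad(eta[None, :])
    return g[0]


@dataclass
class PosteriorResult:
    """Posterior draws and summaries for one patient."""

    drug: str
    names: tuple[str, ...]
    eta_draws: np.ndarray            # (chains, samples, K)
    draws: dict[str, np.ndarray]     # natural scale, (chains, samples)
    point_estimate: dict[str, float]  # posterior median, natural scale
    mean: dict[str, float]
    intervals: dict[str, tuple[float, float]]  # central 90%
    diagnostics: dict
    converged: bool
    settings: SamplerSettings
    flavor: str

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "flavor": self.flavor,
            "point_estimate": self.point_estimate,
            "mean": self.mean,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()},
            "converged": bool(self.converged),
        }

    def draws_to_csv(self, path) -> None:
        """Write the natural-scale draws as CSV (chain, draw, one column
        per parameter)."""
        import pandas as pd
        C, S, _ = self.eta_draws.shape
        chain, draw = np.divmod(np.arange(C * S), S)
        frame = {"chain": chain, "draw": draw}
        for name in self.names:
            frame[name] = self.draws[name].reshape(-1)
        pd.DataFrame(frame).to_csv(path, index=False)


@dataclass
class MAPResult:
    """Phi-minimizing point estimate for one patient."""

    drug: str
    names: tuple[str, ...]
    eta: np.ndarray
    estimate: dict[str, float]       # natural scale
    phi: float
    converged: bool
    n_restarts_used: int

    def to_dict(self) -> dict:
        return {"drug": self.drug, "estimate": self.estimate, "phi": self.phi,
                "converged": bool(self.converged),
                "n_restarts_used": self.n_restarts_used}


def _summarize_posterior(design: PosteriorDesign, eta_draws: np.ndarray,
                         info: dict, settings: SamplerSettings) -> PosteriorResult:
    """Medians, 90% intervals and diagnostics from (chains, samples, K) draws."""
    names = design.names
    pooled = eta_draws.reshape(-1, design.K)
    med = np.median(pooled, axis=0)
    q05, q95 = np.quantile(pooled, [0.05, 0.95], axis=0)
    natural = {}
    point = {}
    mean_nat = {}
    intervals = {}
    for k, name in enumerate(names):
        m = design.means[k]
        natural[name] = m * np.exp(eta_draws[:, :, k])
        point[name] = float(m * np.exp(med[k]))
        mean_nat[name] = float(natural[name].mean())
        intervals[name] = (float(m * np.exp(q05[k])), float(m * np.exp(q95[k])))
    diag: dict = {"divergences": np.asarray(info.get("divergences", 0))}
    if settings.chains >= 2:
        per_param = eta_draws.transpose(2, 0, 1)  # (K, C, S)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = split_rhat(per_param)
            ess = ess_bulk(per_param)
        diag["rhat"] = {n: float(rhat[k]) for k, n in enumerate(names)}
        diag["ess_bulk"] = {n: float(ess[k]) for k, n in enumerate(names)}
        rhat_ok = np.all(np.isfinite(rhat)) and np.all(rhat < RHAT_LIMIT)
    else:
        diag["rhat"] = None
        diag["ess_bulk"] = None
        rhat_ok = True
    total_div = int(np.sum(diag["divergences"]))
    converged = bool(rhat_ok) and total_div < settings.samples * settings.chains
    if not converged:
        warnings.warn(f"{design.drug}: sampler flagged non-converged "
                      f"(R-hat limit {RHAT_LIMIT}, divergences {total_div})",
                      RuntimeWarning)
    return PosteriorResult(
        drug=design.drug, names=names, eta_draws=eta_draws, draws=natural,
        point_estimate=point, mean=mean_nat, intervals=intervals,
        diagnostics=diag, converged=converged, settings=settings,
        flavor=info.get("flavor", "nuts"))


class HMCEstimator(BaseEstimator):
    """Full-Bayes individual PK estimator (dynamic NUTS over eta).

    Parameters
    ----------
    drug : one of amikacin, vancomycin, theophylline, phenytoin.
    prior : optional PriorSpec overriding the registry default.
    chains, warmup, samples, target_accept, max_treedepth : sampler settings;
        defaults are 4 chains of 2500 warmup + 2500 sampling iterations.
    seed : reproducibility seed; identical seeds give identical draws.
    rk4_h : fixed integration step (h) for the phenytoin kernel inside the
        sampler.

    Fitted attributes: ``result_`` (PosteriorResult), ``params_`` (posterior
    medians, natural scale), ``intervals_``, ``diagnostics_``,
    ``converged_``, ``cov_``, ``events_``.
    """

    def __init__(self, drug: str = "amikacin", prior: PriorSpec | None = None,
                 chains: int = 4, warmup: int = 2500, samples: int = 2500,
                 seed: int | None = None, target_accept: float = 0.8,
                 max_treedepth: int = 10, rk4_h: float = 0.1,
                 prior_only: bool = False):
        self.drug = drug
        self.prior = prior
        self.chains = chains
        self.warmup = warmup
        self.samples = samples
        self.seed = seed
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.rk4_h = rk4_h
        self.prior_only = prior_only

    def _settings(self) -> SamplerSettings:
        return SamplerSettings(chains=self.chains, warmup=self.warmup,
                               samples=self.samples, seed=self.seed,
                               target_accept=self.target_accept,
                               max_treedepth=self.max_treedepth)

    def fit(self, X: TDMDataset | None, y=None) -> "HMCEstimator":
        """Fit on a single-patient dataset (or prior-only if requested)."""
        prior = self.prior or get_default_prior(self.drug)
        if self.prior_only:
            design = prior_only_design(prior)
            self.cov_ = None
            self.events_ = []
        else:
            if X is None:
                raise ValueError("a dataset is required unless prior_only=True")
            design = _design_for(self.drug, X, prior, rk4_h=self.rk4_h)
            if design.obs.shape[1] < 1:
                raise ValueError("dataset has no observations; pass "
                                 "prior_only=True for prior sampling")
            self.cov_, self.events_ = X.single()
        settings = self._settings()
        rng = np.random.default_rng(self.seed)
        draws, info = nuts_sample(design, settings, rng)
        self.result_ = _summarize_posterior(design, draws, info, settings)
        self.design_ = design
        self.params_ = self.result_.point_estimate
        self.intervals_ = self.result_.intervals
        self.diagnostics_ = self.result_.diagnostics
        self.converged_ = self.result_.converged
        return self

    def individual_params_(self) -> IndividualParams:
        prior = self.prior or get_default_prior(self.drug)
        eta = {n: float(np.log(self.params_[n] / prior[n].mean))
               for n in self.result_.names}
        return IndividualParams.from_prior(prior, eta)

    def predict(self, times, events: Sequence[EventRecord] | None = None,
                at_steady_state: bool = False,
                cov: PatientCovariates | None = None) -> np.ndarray:
        """Concentrations at ``times`` under the fitted point estimate."""
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        cov = cov or self.cov_
        if cov is None:
            raise ValueError("prior-only fits need explicit covariates to predict")
        events = list(events) if events is not None else self.events_
        prof = simulate_profile(self.drug, self.individual_params_(), cov,
                                events, times, at_steady_state=at_steady_state)
        return prof.conc


class MAPEstimator(BaseEstimator):
    """Maximum a posteriori estimator over log-scale parameters.

    By default the full posterior mode is found (negative log posterior
    including the log sigma(C_pred) normalization); ``objective='phi'``
    minimizes the classical penalized least-squares objective instead.
    Multi-start quasi-Newton: the prior mean plus ``starts``-1 starts
    jittered by 0.5*omega; the lowest objective wins. With no observations
    the estimate equals the prior means exactly. ``phi_`` always reports
    the penalized least-squares value at the optimum.
    """

    def __init__(self, drug: str = "amikacin", prior: PriorSpec | None = None,
                 starts: int = 3, seed: int | None = None, rk4_h: float = 0.1,
                 objective: str = "posterior_mode"):
        self.drug = drug
        self.prior = prior
        self.starts = starts
        self.seed = seed
        self.rk4_h = rk4_h
        self.objective = objective

    def fit(self, X: TDMDataset, y=None) -> "MAPEstimator":
        prior = self.prior or get_default_prior(self.drug)
        design = _design_for(self.drug, X, prior, rk4_h=self.rk4_h)
        self.cov_, self.events_ = X.single()
        rng = np.random.default_rng(self.seed)
        eta, val, info = batched_map(design, starts=self.starts, rng=rng,
                                     objective=self.objective)
        if not np.isfinite(val[0]):
            raise RuntimeError("MAP optimization failed: non-finite objective")
        est = {n: float(design.means[k] * np.exp(eta[0, k]))
               for k, n in enumerate(design.names)}
        self.design_ = design
        self.result_ = MAPResult(drug=design.drug, names=design.names,
                                 eta=eta[0], estimate=est,
                                 phi=float(design.phi(eta[:1])[0]),
                                 converged=bool(np.all(info["converged"])),
                                 n_restarts_used=info["n_restarts_used"])
        self.params_ = est
        self.phi_ = self.result_.phi
        self.converged_ = self.result_.converged
        return self

    def individual_params_(self) -> IndividualParams:
        prior = self.prior or get_default_prior(self.drug)
        eta = {n: float(self.result_.eta[k]) for k, n in enumerate(self.result_.names)}
        return IndividualParams.from_prior(prior, eta)

    def predict(self, times, events: Sequence[EventRecord] | None = None,
                at_steady_state: bool = False,
                cov: PatientCovariates | None = None) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        cov = cov or self.cov_
        events = list(events) if events is not None else self.events_
        prof = simulate_profile(self.drug, self.individual_params_(), cov,
                                events, times, at_steady_state=at_steady_state)
        return prof.conc


def hmc_fit(drug: str, ds: TDMDataset | None, prior: PriorSpec | None = None,
            settings: SamplerSettings | None = None,
            prior_only: bool = False) -> PosteriorResult:
    """Fit one patient by NUTS and return the PosteriorResult."""
    settings = settings or SamplerSettings()
    est = HMCEstimator(drug=drug, prior=prior, chains=settings.chains,
                       warmup=settings.warmup, samples=settings.samples,
                       seed=settings.seed, target_accept=settings.target_accept,
                       max_treedepth=settings.max_treedepth,
                       prior_only=prior_only)
    return est.fit(ds).result_


def map_fit(drug: str, ds: TDMDataset, prior: PriorSpec | None = None,
            starts: int = 3, seed: int | None = None) -> MAPResult:
    """Fit one patient by MAP and return the MAPResult."""
    return MAPEstimator(drug=drug, prior=prior, starts=starts, seed=seed) \
        .fit(ds).result_


def diagnostics(result: PosteriorResult) -> dict:
    """Convergence summary: rank-normalized split R-hat, bulk ESS, and
    divergence counts per chain. Single-chain results report R-hat absent."""
    draws = result.eta_draws
    chains = draws.shape[0]
    out: dict = {"divergences": np.asarray(result.diagnostics["divergences"]).tolist()}
    if chains < 2:
        out["rhat"] = None
        out["ess_bulk"] = None
        return out
    per_param = draws.transpose(2, 0, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = split_rhat(per_param)
        ess = ess_bulk(per_param)
    out["rhat"] = {n: float(rhat[k]) for k, n in enumerate(result.names)}
    out["ess_bulk"] = {n: float(ess[k]) for k, n in enumerate(result.names)}
    return out
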