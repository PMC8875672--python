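"""Virtual-patient generation for the simulation studies.

Demographics emulate an adult hospital cohort (height 165.1 +/- 8.7 cm,
weight 65.1 +/- 10.2 kg, age 50.2 +/- 17.1 y, sexes balanced, serum
creatinine lognormal around 1.1 mg/dL). True parameters come either from
the same models the estimator uses (internal validation) or from
independently published population models (external validation); observed
concentrations add the assay error model to the noise-free truth.

The scenario grid is 4 drugs x 2 dose cases (single dose, steady state)
x 4 sampling sets (peak, trough, peak+trough, hourly) = 32 scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .covariates import (ML_MIN_TO_L_H, PatientCovariates, creatinine_clearance,
                         derive_structural_params, lean_body_weight)
from .dataio import SAMPLE_REGIMENS, TDMDataset
from .params import IndividualParams
from .pkmodels import (ConcProfile, Dose, EventRecord, conc_1cmt_iv,
                       conc_2cmt_iv, conc_1cmt_oral1, conc_mm_zero)
from .priors import ErrorModel, PriorSpec, get_default_prior, DRUGS

__all__ = [
    "Scenario",
    "scenario",
    "all_scenarios",
    "SAMPLING_SETS",
    "DOSE_CASES",
    "generate_demographics",
    "sample_individual_params",
    "simulate_observations",
    "external_truth",
    "internal_kernel",
    "kernel_conc",
    "observation_schedule",
    "build_scenario_dataset",
    "PatientTruth",
    "TruthRecord",
]

DOSE_CASES = ("single", "steady")
SAMPLING_SETS = ("peak", "trough", "peak_trough", "q1h")

# Within-interval peak sampling times (h) per drug; troughs sample at the
# end of the interval and the hourly set covers 1..tau.
_PEAK_TIMES = {"amikacin": 1.0, "vancomycin": 2.0, "theophylline": 4.0,
               "phenytoin": 2.0}

# Demographic distribution: mean, SD, resampling truncation bounds.
_DEMOGRAPHICS = {
    "height": (165.1, 8.7, 140.0, 200.0),
    "weight": (65.1, 10.2, 35.0, 120.0),
    "age": (50.2, 17.1, 18.0, 90.0),
}
_SCR_LOG_MEDIAN = np.log(1.1)  # mg/dL
_SCR_LOG_SD = 0.2
_SCR_BOUNDS = (0.4, 3.0)


@dataclass(frozen=True)
class Scenario:
    """One validation cell: drug, dose case, sampling set, and the regimen."""

    drug: str
    dose_case: str
    sampling_set: str
    amt: float
    rate: float
    ii: float
    sampling_times: tuple[float, ...]

    @property
    def label(self) -> str:
        return f"{self.drug}/{self.dose_case}/{self.sampling_set}"


def scenario(drug: str, dose_case: str, sampling_set: str) -> Scenario:
    """Build the scenario for a (drug, dose case, sampling set) cell."""
    drug = str(drug).lower()
    reg = SAMPLE_REGIMENS[drug]
    if dose_case not in DOSE_CASES:
        raise ValueError(f"dose_case must be one of {DOSE_CASES}")
    if sampling_set not in SAMPLING_SETS:
        raise ValueError(f"sampling_set must be one of {SAMPLING_SETS}")
    ii = reg["ii"]
    peak, trough = _PEAK_TIMES[drug], ii
    times = {
        "peak": (peak,),
        "trough": (trough,),
        "peak_trough": (peak, trough),
        "q1h": tuple(float(t) for t in np.arange(1.0, ii + 0.5)),
    }[sampling_set]
    return Scenario(drug=drug, dose_case=dose_case, sampling_set=sampling_set,
                    amt=reg["amt"], rate=reg["rate"], ii=ii, sampling_times=times)


def all_scenarios() -> list[Scenario]:
    """The full 32-cell grid, drug-major."""
    return [scenario(d, c, s) for d in DRUGS for c in DOSE_CASES
            for s in SAMPLING_SETS]


# ---------------------------------------------------------------------------
# demographics and parameters
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    for _ in range(1000):
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    raise RuntimeError("truncated-normal resampling did not terminate")


def generate_demographics(n: int, seed=None) -> list[PatientCovariates]:
    """Draw n virtual adults; reproducible given the seed (or Generator)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ht = _truncated_normal(rng, *_DEMOGRAPHICS["height"], n)
    wt = _truncated_normal(rng, *_DEMOGRAPHICS["weight"], n)
    age = _truncated_normal(rng, *_DEMOGRAPHICS["age"], n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    scr = np.exp(_truncated_normal(rng, _SCR_LOG_MEDIAN, _SCR_LOG_SD,
                                   np.log(_SCR_BOUNDS[0]), np.log(_SCR_BOUNDS[1]), n))
    return [PatientCovariates(weight=float(wt[i]), height=float(ht[i]),
                              age=float(age[i]), sex=str(sex[i]), scr=float(scr[i]))
            for i in range(n)]


def sample_individual_params(prior: PriorSpec, seed=None) -> IndividualParams:
    """Draw one parameter vector: P = mean*exp(eta), eta ~ N(0, omega^2),
    rejected and resampled until inside the registry bounds; fixed
    parameters are copied."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = {}
    for p in prior.estimated:
        for _ in range(1000):
            e = rng.normal(0.0, p.omega)
            val = p.mean * np.exp(e)
            if (p.lower is None or val >= p.lower) and \
               (p.upper is None or val <= p.upper):
                eta[p.name] = float(e)
                break
        else:
            raise RuntimeError(f"{prior.drug}.{p.name}: prior bounds reject "
                               "all draws; check the prior configuration")
    return IndividualParams.from_prior(prior, eta)


def simulate_observations(true_conc, error: ErrorModel, seed=None) -> np.ndarray:
    """Observed = true + eps, eps ~ N(0, sigma^2) with
    sigma = cv_assay*C_true + s_assay.

    The error model is applied exactly as written: no truncation, so an
    observation can come out non-positive when sigma is large relative to
    the concentration (phenytoin troughs). The Gaussian likelihood handles
    such values; truncating them instead would bias low-concentration
    scenarios upward by several percent."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    true_conc = np.asarray(true_conc, float)
    sig = error.sigma(true_conc)
    return true_conc + rng.normal(0.0, 1.0, true_conc.shape) * sig


# ---------------------------------------------------------------------------
# kernel-level truth
# ---------------------------------------------------------------------------

def internal_kernel(drug: str, params: IndividualParams,
                    cov: PatientCovariates) -> dict:
    """Structural (kernel-level) parameters for the internal models."""
    prior = get_default_prior(drug)
    d = derive_structural_params(drug, params, cov)
    if prior.model_id == "1cmt_iv":
        return {"model": "1cmt_iv", "cl": d.cl, "v": d.v}
    if prior.model_id == "2cmt_iv":
        return {"model": "2cmt_iv", "cl": d.cl, "v": d.v,
                "k12": params["k12"], "k21": params["k21"]}
    if prior.model_id == "1cmt_oral1":
        return {"model": "1cmt_oral1", "cl": d.cl, "v": d.v,
                "ka": params["ka"], "f": params["F"]}
    return {"model": "mm_zero", "vmax_h": params["Vmax"] / 24.0,
            "km": params["km"], "v": d.v,
            "cl_lin": params["CLslope"] * d.crcl_l_h, "f": params["F"]}


def external_truth(drug: str, cov: PatientCovariates, seed=None,
                   eta: dict | None = None) -> tuple[dict, dict]:
    """Draw one patient from the published external population models.

    Returns (reported parameters, kernel parameters). The external models:

    - amikacin:    CL = 1.40 + 1.42*(CrCl/71.2)*e^eta (omega 0.303),
                   V = 10.8 + 7.24*(TBW/57); proportional residual 0.307.
    - vancomycin:  CL = 2.82*(CrCl/72)^0.836*e^eta1 (0.828), Vc 31.8,
                   Q 11.7, Vp = 75.4*(TBW/60)*e^eta2 (0.466); residual 0.253.
    - theophylline: ka 0.0773 fixed; CL/F = 0.0539*0.876^elderly*e^eta1
                   L/h/kg (0.313), V/F = 0.320*e^eta2 L/kg (0.284),
                   elderly = age >= 65; exponential residual 0.178.
    - phenytoin:   Vmax = 9.80*42*(TBW/42)^0.463*(1+eta1) mg/d (0.150),
                   km = 9.19*(1+eta2) mg/L (0.306),
                   V = 1.23*TBW*(1+eta3) L (0.433); proportional 0.181.

    CrCl here is in mL/min; (1+eta) draws are redrawn if non-positive.
    ``eta`` optionally fixes individual deviations (keys eta1, eta2, eta3)
    instead of drawing them — useful for typical-value checks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drug = str(drug).lower()
    tbw = cov.weight
    crcl = creatinine_clearance(cov)

    def draw(name, sd):
        if eta is not None and name in eta:
            return eta[name]
        return rng.normal(0.0, sd)

    def pos1(name, sd):
        if eta is not None and name in eta:
            return 1.0 + eta[name]
        for _ in range(1000):
            e = rng.normal(0.0, sd)
            if 1.0 + e > 0:
                return 1.0 + e
        raise RuntimeError("(1+eta) redraw did not terminate")

    if drug == "amikacin":
        cl = (1.40 + 1.42 * crcl / 71.2) * np.exp(draw("eta1", 0.303))
        v = 10.8 + 7.24 * (tbw / 57.0)
        return {"CL": cl, "V": v}, {"model": "1cmt_iv", "cl": cl, "v": v}
    if drug == "vancomycin":
        cl = 2.82 * (crcl / 72.0) ** 0.836 * np.exp(draw("eta1", 0.828))
        vc, q = 31.8, 11.7
        vp = 75.4 * (tbw / 60.0) * np.exp(draw("eta2", 0.466))
        return ({"CL": cl, "Vc": vc, "Q": q, "Vp": vp},
                {"model": "2cmt_iv", "cl": cl, "v": vc,
                 "k12": q / vc, "k21": q / vp})
    if drug == "theophylline":
        elderly = cov.age >= 65.0
        cl = 0.0539 * (0.876 if elderly else 1.0) * np.exp(draw("eta1", 0.313)) * tbw
        v = 0.320 * np.exp(draw("eta2", 0.284)) * tbw
        ka = 0.0773
        return ({"CL": cl, "V": v, "ka": ka},
                {"model": "1cmt_oral1", "cl": cl, "v": v, "ka": ka, "f": 1.0})
    if drug == "phenytoin":
        vmax = 9.80 * 42.0 * (tbw / 42.0) ** 0.463 * pos1("eta1", 0.150)  # mg/d
        km = 9.19 * pos1("eta2", 0.306)
        v = 1.23 * tbw * pos1("eta3", 0.433)
        return ({"Vmax": vmax, "km": km, "V": v},
                {"model": "mm_zero", "vmax_h": vmax / 24.0, "km": km, "v": v,
                 "cl_lin": 0.0, "f": 1.0})
    raise ValueError(f"no external model for {drug!r}")


_EXTERNAL_RESIDUAL = {
    "amikacin": ("proportional", 0.307),
    "vancomycin": ("proportional", 0.253),
    "theophylline": ("exponential", 0.178),
    "phenytoin": ("proportional", 0.181),
}


def _apply_external_error(true_conc, drug, rng):
    """Residual error of the external models, as published: proportional
    C*(1+eps) or exponential C*exp(eps); no truncation."""
    form, sd = _EXTERNAL_RESIDUAL[drug]
    true_conc = np.asarray(true_conc, float)
    if form == "exponential":
        return true_conc * np.exp(rng.normal(0.0, sd, true_conc.shape))
    return true_conc * (1.0 + rng.normal(0.0, sd, true_conc.shape))


def kernel_conc(kernel: dict, doses: Sequence[Dose], times,
                tau_ss: float | None = None,
                rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Noise-free concentrations from kernel-level structural parameters."""
    m = kernel["model"]
    if m == "1cmt_iv":
        return np.asarray(conc_1cmt_iv(kernel["cl"], kernel["v"], doses, times,
                                       tau_ss))
    if m == "2cmt_iv":
        return np.asarray(conc_2cmt_iv(kernel["cl"], kernel["v"], kernel["k12"],
                                       kernel["k21"], doses, times, tau_ss))
    if m == "1cmt_oral1":
        return np.asarray(conc_1cmt_oral1(kernel["cl"], kernel["v"], kernel["ka"],
                                          kernel["f"], doses, times, tau_ss))
    if m == "mm_zero":
        if tau_ss is not None:
            raise ValueError("use an explicit multi-dose schedule for phenytoin")
        return conc_mm_zero(kernel["vmax_h"], kernel["km"], kernel["v"],
                            kernel["cl_lin"], kernel["f"], doses, times,
                            rtol=rtol, atol=atol)
    raise ValueError(f"unknown kernel model {m!r}")


def observation_schedule(sc: Scenario):
    """(doses, absolute observation times, tau_ss) used to generate the
    observed data for a scenario.

    Single dose: one dose, samples within the first interval. Steady state:
    linear drugs use the analytic steady-state profile (tau_ss set);
    phenytoin doses 20 consecutive intervals and samples within the 20th.
    """
    times = np.asarray(sc.sampling_times, float)
    if sc.dose_case == "single":
        return [Dose(0.0, sc.amt, sc.rate)], times, None
    if sc.drug == "phenytoin":
        doses = [Dose(k * sc.ii, sc.amt, sc.rate) for k in range(20)]
        return doses, 19.0 * sc.ii + times, None
    return [Dose(0.0, sc.amt, sc.rate)], times, sc.ii


@dataclass(frozen=True)
class PatientTruth:
    """Ground truth for one virtual patient: covariates, generating
    parameters (reported scale), kernel-level structural parameters, and
    noise-free/observed concentrations at the sampling times. Observed
    values carry the raw (untruncated) residual error."""

    cov: PatientCovariates
    params: dict
    kernel: dict
    true_conc: np.ndarray
    obs_conc: np.ndarray


@dataclass(frozen=True)
class TruthRecord:
    scenario: Scenario
    source: str
    patients: tuple[PatientTruth, ...]


def build_scenario_dataset(sc: Scenario, n: int, model_source: str = "internal",
                           seed=None) -> tuple[TDMDataset, TruthRecord]:
    """Generate the estimation dataset and the truth record for a scenario.

    model_source 'internal' draws true parameters from the estimation
    priors; 'external' draws them from the published external models (the
    estimation prior stays internal — that mismatch is the point of the
    external validation).
    """
    if model_source not in ("internal", "external"):
        raise ValueError("model_source must be 'internal' or 'external'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior = get_default_prior(sc.drug)
    covs = generate_demographics(n, rng)
    doses, obs_times, tau_ss = observation_schedule(sc)

    patients = []
    ds = TDMDataset(drug=sc.drug)
    addl = 19 if (sc.dose_case == "steady" and sc.drug == "phenytoin") else 0
    for i, cov in enumerate(covs):
        if model_source == "internal":
            params = sample_individual_params(prior, rng)
            report = dict(params.values)
            kern = internal_kernel(sc.drug, params, cov)
        else:
            report, kern = external_truth(sc.drug, cov, rng)
        true_conc = kernel_conc(kern, doses, obs_times, tau_ss)
        if model_source == "internal":
            obs = simulate_observations(true_conc, prior.error, rng)
        else:
            obs = _apply_external_error(true_conc, sc.drug, rng)
        pid = i + 1
        events = [EventRecord(id=pid, time=0.0, evid=1, amt=sc.amt,
                              rate=sc.rate, ii=sc.ii, addl=addl)]
        for t, dv in zip(obs_times, obs):
            events.append(EventRecord(id=pid, time=float(t), evid=0,
                                      dv=float(dv)))
        ds.covariates[pid] = cov
        ds.events[pid] = events
        patients.append(PatientTruth(cov=cov, params=report, kernel=kern,
                                     true_conc=true_conc, obs_conc=obs))
    ds.validate()
    return ds, TruthRecord(scenario=sc, source=model_source,
                           patients=tuple(patients))
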