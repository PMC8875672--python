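"""Forward concentration prediction for the four structural models.

Linear models (one-compartment IV infusion, two-compartment IV infusion,
one-compartment first-order oral) are evaluated in closed form as sums of
exponential modes superposed over the dose schedule; steady state applies
the per-mode accumulation factor 1/(1 - exp(-lambda*tau)). The phenytoin
model (Michaelis-Menten elimination with zero-order input) is integrated
numerically.

All closed-form kernels broadcast over leading parameter axes and are
holomorphic in the parameters, so complex-step differentiation through them
is exact; the sampler relies on this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .covariates import PatientCovariates, derive_structural_params
from .params import IndividualParams
from .priors import get_default_prior

__all__ = [
    "EventRecord",
    "Dose",
    "ConcProfile",
    "ScheduleError",
    "expand_events",
    "conc_1cmt_iv",
    "conc_2cmt_iv",
    "conc_1cmt_oral1",
    "conc_mm_zero",
    "simulate_profile",
]


class ScheduleError(ValueError):
    """Invalid dosing schedule (e.g. addl without a dosing interval)."""


@dataclass(frozen=True)
class EventRecord:
    """One NONMEM-style event row.

    evid 0 = observation (dv holds the measured concentration, mg/L),
    evid 1 = dose (amt mg; rate mg/h, 0 for bolus; ii/addl for repeats).
    Compartment convention: IV models dose cmt 1 = central; oral models dose
    cmt 1 = depot; observations always read the central compartment.
    """

    time: float
    evid: int
    id: int = 1
    amt: float | None = None
    cmt: int = 1
    rate: float = 0.0
    ii: float = 0.0
    addl: int = 0
    dv: float | None = None

    def __post_init__(self):
        if self.evid not in (0, 1):
            raise ValueError(f"evid must be 0 or 1, got {self.evid}")
        if self.time < 0:
            raise ValueError("event times must be non-negative")
        if self.evid == 1:
            if self.amt is None or self.amt <= 0:
                raise ValueError("dose rows require amt > 0")
            if self.addl > 0 and self.ii <= 0:
                raise ScheduleError("addl > 0 requires ii > 0")
        else:
            if self.dv is not None and not np.isfinite(self.dv):
                raise ValueError("observed concentrations must be finite")


@dataclass(frozen=True)
class Dose:
    """A single expanded dose: zero-order input at ``rate`` for amt/rate
    hours (rate > 0), or an instantaneous bolus (rate == 0)."""

    time: float
    amt: float
    rate: float = 0.0
    cmt: int = 1

    @property
    def duration(self) -> float:
        return self.amt / self.rate if self.rate > 0 else 0.0


@dataclass(frozen=True)
class ConcProfile:
    times: np.ndarray
    conc: np.ndarray
    amounts: np.ndarray | None = None


def expand_events(events: Sequence[EventRecord]) -> list[Dose]:
    """Expand dose rows (addl/ii) into an explicit time-sorted dose list."""
    doses = []
    for ev in events:
        if ev.evid != 1:
            continue
        if ev.addl > 0 and ev.ii <= 0:
            raise ScheduleError("addl > 0 requires ii > 0")
        for k in range(ev.addl + 1):
            doses.append(Dose(time=ev.time + k * ev.ii, amt=ev.amt,
                              rate=ev.rate, cmt=ev.cmt))
    return sorted(doses, key=lambda d: d.time)


# ---------------------------------------------------------------------------
# linear kernels: sums of exponential modes
# ---------------------------------------------------------------------------

def _one_dose_modes(lam, B, dose: Dose, t, famt: float = 1.0):
    """Mode-wise response (..., M, T) to a single dose at times t (T,).

    famt scales the delivered amount (bioavailability).
    """
    s = np.asarray(t, float) - dose.time
    if dose.rate > 0:
        dur = dose.duration
        s_in = np.clip(s, 0.0, dur)
        s_post = np.maximum(s - dur, 0.0)
        R = famt * dose.rate
        return R * (B / lam) * (1.0 - np.exp(-lam * s_in)) * np.exp(-lam * s_post)
    # bolus
    mask = s >= 0
    s_pos = np.maximum(s, 0.0)
    return famt * dose.amt * B * np.exp(-lam * s_pos) * mask


def _complete_dose_tail(lam, B, dose: Dose, s, famt: float = 1.0):
    """Mode-wise response at times ``s`` assuming the dose has completed."""
    if dose.rate > 0:
        dur = dose.duration
        R = famt * dose.rate
        return R * (B / lam) * (1.0 - np.exp(-lam * dur)) * np.exp(-lam * (s - dose.time - dur))
    return famt * dose.amt * B * np.exp(-lam * (s - dose.time))


def _linear_conc(lam, B, doses: Sequence[Dose], t, tau_ss: float | None = None,
                 famt: float = 1.0):
    """Superposed concentration for exponential modes lam/B of shape (..., M).

    If ``tau_ss`` is given, ``doses`` describes one dosing interval and the
    concentration is the steady-state profile at ``t`` hours after an
    interval start; the infinite history of earlier doses is summed with the
    per-mode accumulation factor. Times t >= tau_ss are reduced modulo the
    interval (the profile is periodic at steady state).
    """
    t = np.atleast_1d(np.asarray(t, float))
    if tau_ss is not None:
        t = t - tau_ss * np.floor(t / tau_ss)
    lam_ = np.asarray(lam)[..., :, None]
    B_ = np.asarray(B)[..., :, None]
    total = 0.0
    for d in doses:
        total = total + _one_dose_modes(lam_, B_, d, t, famt)
        if tau_ss is not None:
            if d.time + d.duration > tau_ss + 1e-9:
                raise ScheduleError("steady-state dose must complete within one interval")
            acc = 1.0 / (1.0 - np.exp(-lam_ * tau_ss))
            total = total + _complete_dose_tail(lam_, B_, d, t + tau_ss, famt) * acc
    return total.sum(axis=-2)


def conc_1cmt_iv(cl, v, doses: Sequence[Dose], t, tau_ss: float | None = None):
    """One-compartment IV infusion model: k = CL/V, C = A/V."""
    cl = np.asarray(cl)
    v = np.asarray(v)
    lam = (cl / v)[..., None]
    B = (1.0 / v)[..., None]
    return _linear_conc(lam, B, doses, t, tau_ss)


def conc_2cmt_iv(cl, v, k12, k21, doses: Sequence[Dose], t,
                 tau_ss: float | None = None):
    """Two-compartment IV infusion model (central volume v, micro-constants).

    Hybrid rate constants are the roots of
    lambda^2 - (k10+k12+k21)*lambda + k10*k21 = 0 with k10 = CL/V.
    """
    cl, v, k12, k21 = map(np.asarray, (cl, v, k12, k21))
    k10 = cl / v
    ssum = k10 + k12 + k21
    disc = ssum * ssum - 4.0 * k10 * k21
    if not np.iscomplexobj(disc) and np.any(np.real(disc) < 0):
        raise ArithmeticError("negative discriminant in two-compartment model")
    sq = np.sqrt(disc)
    lam1 = 0.5 * (ssum + sq)
    lam2 = 0.5 * (ssum - sq)
    denom = v * (lam1 - lam2)
    B1 = (lam1 - k21) / denom
    B2 = (k21 - lam2) / denom
    lam = np.stack(np.broadcast_arrays(lam1, lam2), axis=-1)
    B = np.stack(np.broadcast_arrays(B1, B2), axis=-1)
    return _linear_conc(lam, B, doses, t, tau_ss)


def conc_1cmt_oral1(cl, v, ka, f, doses: Sequence[Dose], t,
                    tau_ss: float | None = None):
    """One-compartment model with first-order absorption (Bateman equation).

    Near ka == ke the kernel switches to the limiting form
    C = F*D*ka*t*exp(-ka*t)/V to avoid the 0/0 in the Bateman expression.
    """
    cl, v, ka, f = map(np.asarray, (cl, v, ka, f))
    ke = cl / v
    close = np.abs(np.real(ka - ke)) < 1e-8 * np.abs(np.real(ke))
    ka_safe = np.where(close, ka * (1.0 + 1e-6), ka)
    coef = f * ka_safe / (v * (ka_safe - ke))
    lam = np.stack(np.broadcast_arrays(ke, ka_safe), axis=-1)
    B = np.stack(np.broadcast_arrays(coef, -coef), axis=-1)
    out = _linear_conc(lam, B, doses, t, tau_ss)
    if np.any(close):
        t_arr = np.atleast_1d(np.asarray(t, float))
        if tau_ss is not None:
            t_arr = t_arr - tau_ss * np.floor(t_arr / tau_ss)
        lim = 0.0
        for d in doses:
            if d.rate > 0:
                raise ScheduleError("oral model supports bolus doses only")
            s = np.maximum(t_arr - d.time, 0.0)
            mask = t_arr >= d.time
            lim = lim + f * d.amt * ka * s * np.exp(-ka * s) / v * mask
            if tau_ss is not None:
                s2 = t_arr + tau_ss - d.time
                # d/dka of the accumulation is neglected; use nudged modes there
                lim = lim + f * d.amt * ka * s2 * np.exp(-ka * s2) / v \
                    / (1.0 - np.exp(-ka * tau_ss))
        out = np.where(close[..., None] if np.ndim(close) else close, lim, out)
    return out


# ---------------------------------------------------------------------------
# Michaelis-Menten kernel (phenytoin)
# ---------------------------------------------------------------------------

def _input_segments(doses: Sequence[Dose], f: float, t_end: float):
    """Piecewise-constant zero-order input rate: list of (t0, t1, rate)."""
    cuts = {0.0, t_end}
    for d in doses:
        if d.rate <= 0:
            raise ScheduleError("phenytoin doses require a zero-order rate > 0")
        cuts.add(d.time)
        cuts.add(min(d.time + d.duration, t_end))
    edges = sorted(c for c in cuts if 0.0 <= c <= t_end)
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        rate = sum(f * d.rate for d in doses if d.time <= mid < d.time + d.duration)
        segs.append((a, b, rate))
    return segs


def conc_mm_zero(vmax, km, v, cl_lin, f, doses: Sequence[Dose], t,
                 rtol: float = 1e-8, atol: float = 1e-10):
    """Concentration under Michaelis-Menten plus linear elimination.

    dA/dt = input(t)*F - [Vmax*C/(km + C) + CL_lin*C],  C = A/V,
    with Vmax in mg/h, km in mg/L, V in L, CL_lin in L/h. Integrated with an
    adaptive solver segment-by-segment between input discontinuities.
    """
    t = np.atleast_1d(np.asarray(t, float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    t_end = float(max(t.max(), max((d.time + d.duration) for d in doses)))
    segs = _input_segments(doses, float(f), t_end)
    conc = np.zeros_like(t)
    conc[t == 0.0] = 0.0
    A0 = 0.0
    for (a, b, rate) in segs:
        def rhs(_t, y, rate=rate):
            C = max(y[0], 0.0) / v
            return [rate - vmax * C / (km + C) - cl_lin * C]

        sel = (t > a) & (t <= b)
        t_eval = np.unique(np.append(t[sel], b))  # always carry the state to b
        sol = solve_ivp(rhs, (a, b), [A0], t_eval=t_eval,
                        rtol=rtol, atol=atol, method="RK45", dense_output=False)
        if not sol.success:
            raise RuntimeError(f"phenytoin ODE integration failed on [{a}, {b}]: "
                               f"{sol.message}")
        amounts = np.maximum(sol.y[0], 0.0)
        lookup = dict(zip(sol.t, amounts))
        conc[sel] = np.array([lookup[x] for x in t[sel]]) / v
        A0 = max(float(sol.y[0, -1]), 0.0)
    return conc


def mm_conc_rk4(vmax, km, v, cl_lin, f, doses: Sequence[Dose], t_obs, h: float = 0.05):
    """Fixed-step RK4 integration of the Michaelis-Menten model, vectorized
    over leading parameter axes and complex-step safe.

    Dose times, durations and observation times must lie on the step grid.
    Used inside the samplers (speed) and as an alternative integration route;
    the adaptive `conc_mm_zero` is the high-accuracy path.
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, float))
    vmax, km, v, cl_lin, f = map(np.asarray, (vmax, km, v, cl_lin, f))
    t_end = float(max(t_obs.max(), max(d.time + d.duration for d in doses)))
    n_steps = int(round(t_end / h))
    if abs(n_steps * h - t_end) > 1e-9:
        raise ValueError("integration horizon must be a multiple of the step size")
    obs_idx = np.round(t_obs / h).astype(int)
    if np.any(np.abs(obs_idx * h - t_obs) > 1e-9):
        raise ValueError("observation times must lie on the RK4 grid")
    # per-step constant input rate
    grid = np.arange(n_steps) * h + 0.5 * h
    rate_t = np.zeros(n_steps)
    for d in doses:
        rate_t += np.where((grid > d.time) & (grid < d.time + d.duration), d.rate, 0.0)

    shape = np.broadcast_shapes(vmax.shape, km.shape, v.shape, cl_lin.shape, f.shape)
    dtype = np.result_type(vmax, km, v, cl_lin, f, float)
    A = np.zeros(shape, dtype=dtype)
    out = np.zeros(shape + (t_obs.size,), dtype=dtype)
    for j in np.flatnonzero(obs_idx == 0):
        out[..., j] = 0.0

    def rhs(Acur, R):
        C = Acur / v
        return R * f - vmax * C / (km + C) - cl_lin * C

    want = {}
    for j, idx in enumerate(obs_idx):
        want.setdefault(int(idx), []).append(j)
    for i in range(n_steps):
        R = rate_t[i]
        k1 = rhs(A, R)
        k2 = rhs(A + 0.5 * h * k1, R)
        k3 = rhs(A + 0.5 * h * k2, R)
        k4 = rhs(A + h * k3, R)
        A = A + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for j in want.get(i + 1, ()):
            out[..., j] = A / v
    return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _regimen_from_events(events: Sequence[EventRecord]):
    dose_rows = [ev for ev in events if ev.evid == 1]
    if not dose_rows:
        raise ScheduleError("no dose rows in event list")
    first = dose_rows[0]
    ii = first.ii
    if ii <= 0:
        raise ScheduleError("steady-state simulation requires ii > 0 on the dose row")
    return first.amt, first.rate, ii


def simulate_profile(drug: str, params: IndividualParams, cov: PatientCovariates,
                     events: Sequence[EventRecord], times,
                     at_steady_state: bool = False,
                     rtol: float = 1e-8, atol: float = 1e-10) -> ConcProfile:
    """Simulate the concentration profile for one patient.

    With ``at_steady_state`` the event list defines the repeating regimen and
    ``times`` are hours after a steady-state interval start. Linear models
    use the analytic accumulation factor; phenytoin simulates 20 consecutive
    doses and reports times relative to the start of the 20th interval.
    """
    prior = get_default_prior(drug)
    derived = derive_structural_params(drug, params, cov)
    times = np.atleast_1d(np.asarray(times, float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    if prior.model_id == "mm_zero":
        vmax_h = params["Vmax"] / 24.0
        cl_lin = params["CLslope"] * derived.crcl_l_h
        f = params["F"]
        if at_steady_state:
            amt, rate, ii = _regimen_from_events(events)
            doses = [Dose(time=k * ii, amt=amt, rate=rate) for k in range(20)]
            abs_times = 19.0 * ii + times
        else:
            doses = expand_events(events)
            abs_times = times
        conc = conc_mm_zero(vmax_h, params["km"], derived.v, cl_lin, f,
                            doses, abs_times, rtol=rtol, atol=atol)
        return ConcProfile(times=times, conc=conc)

    if at_steady_state:
        amt, rate, ii = _regimen_from_events(events)
        doses = [Dose(time=0.0, amt=amt, rate=rate)]
        tau_ss = ii
    else:
        doses = expand_events(events)
        tau_ss = None

    if prior.model_id == "1cmt_iv":
        conc = conc_1cmt_iv(derived.cl, derived.v, doses, times, tau_ss)
    elif prior.model_id == "2cmt_iv":
        conc = conc_2cmt_iv(derived.cl, derived.v, params["k12"], params["k21"],
                            doses, times, tau_ss)
    elif prior.model_id == "1cmt_oral1":
        conc = conc_1cmt_oral1(derived.cl, derived.v, params["ka"], params["F"],
                               doses, times, tau_ss)
    else:  # pragma: no cover
        raise ValueError(f"unknown model {prior.model_id}")
    return ConcProfile(times=times, conc=np.asarray(conc))
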