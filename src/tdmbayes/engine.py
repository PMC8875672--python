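"""Posterior construction, HMC/NUTS sampling, MAP optimization, and
convergence diagnostics for individual PK parameters.

The posterior over the log-scale deviations eta is

    log p(eta | y) = sum_k N(eta_k; 0, omega_k^2)
                   + sum_i N(y_i; C_pred,i(eta), sigma_i^2),
    sigma_i = cv_assay * C_pred,i + s_assay,

with C_pred computed by the (holomorphic) forward kernels. Gradients are
obtained by complex-step differentiation, exact to machine precision.

Two sampler flavors are provided: a per-patient dynamic NUTS sampler (the
default for single-patient fits) and a fixed-length jittered HMC batched
over patients x chains (used by the validation harness, where hundreds of
independent posteriors are sampled at once). Both use leapfrog integration,
dual-averaging step-size adaptation, and diagonal mass-matrix adaptation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .covariates import ML_MIN_TO_L_H, PatientCovariates, lean_body_weight, \
    creatinine_clearance
from .dataio import TDMDataset
from .pkmodels import Dose, conc_1cmt_iv, conc_2cmt_iv, conc_1cmt_oral1, \
    expand_events, mm_conc_rk4
from .priors import PriorSpec, get_default_prior

__all__ = [
    "SamplerSettings",
    "PosteriorDesign",
    "batched_hmc",
    "nuts_sample",
    "batched_map",
    "split_rhat",
    "ess_bulk",
]

_CSTEP = 1e-150
_LOG2PI = math.log(2.0 * math.pi)

# CLnr unit conversion to L/h/kg (see covariates module)
_CLNR_U = {"amikacin": 0.06, "vancomycin": 0.06, "theophylline": 0.001}


@dataclass(frozen=True)
class SamplerSettings:
    """HMC run configuration. The default profile matches four chains of
    5000 iterations (2500 warmup + 2500 samples); ``reduced`` is the named
    preset used for the scaled-down validation runs."""

    chains: int = 4
    warmup: int = 2500
    samples: int = 2500
    seed: int | None = None
    target_accept: float = 0.8
    max_treedepth: int = 10
    max_leapfrog: int = 16  # batched flavor: L ~ Uniform{1..max_leapfrog}

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("chains, warmup, samples must all be >= 1")

    @classmethod
    def default(cls, **kw) -> "SamplerSettings":
        return cls(**kw)

    @classmethod
    def reduced(cls, **kw) -> "SamplerSettings":
        kw.setdefault("warmup", 500)
        kw.setdefault("samples", 500)
        return cls(**kw)


class PosteriorDesign:
    """Vectorized log-posterior for B independent patients (rows) sharing
    one observation-time grid and dose schedule.

    Parameters are the estimated-parameter deviations eta, ordered as in the
    prior registry. ``predict`` and ``log_posterior`` broadcast over leading
    axes of eta (..., B, K) and accept complex eta.
    """

    def __init__(self, prior: PriorSpec, obs_times, obs, doses: Sequence[Dose],
                 tau_ss: float | None = None,
                 lbw=None, crcl_lh=None, tbw=None, rk4_h: float = 0.1):
        self.prior = prior
        self.drug = prior.drug
        self.model_id = prior.model_id
        self.obs_times = np.atleast_1d(np.asarray(obs_times, float))
        obs = np.asarray(obs, float)
        if obs.ndim == 1:
            obs = obs[None, :]
        self.obs = obs
        self.B = obs.shape[0] if obs.size else (np.atleast_1d(lbw).size)
        self.doses = list(doses)
        self.tau_ss = tau_ss
        self.lbw = np.broadcast_to(np.asarray(lbw, float), (self.B,))
        self.crcl_lh = np.broadcast_to(np.asarray(crcl_lh, float), (self.B,))
        self.tbw = np.broadcast_to(np.asarray(tbw, float), (self.B,)) \
            if tbw is not None else None
        self.rk4_h = rk4_h
        self.names = prior.estimated_names
        self.K = len(self.names)
        self.means = np.array([prior[n].mean for n in self.names])
        self.omega = np.array(prior.omegas)
        self.cv_assay = prior.error.cv_assay
        self.s_assay = prior.error.s_assay
        self._fixed = {p.name: p.mean for p in prior.parameters if p.fixed}
        self._idx = {n: k for k, n in enumerate(self.names)}

    @classmethod
    def from_dataset(cls, ds: TDMDataset, prior: PriorSpec | None = None,
                     rk4_h: float = 0.1) -> "PosteriorDesign":
        """Single-patient design from a dataset (explicit dose schedule)."""
        prior = prior or get_default_prior(ds.drug)
        cov, events = ds.single()
        pid = next(iter(ds.events))
        t, dv = ds.observations(pid)
        lbw = lean_body_weight(cov)
        crcl_lh = creatinine_clearance(cov, lbw=lbw) * ML_MIN_TO_L_H
        doses = expand_events(events)
        return cls(prior, t, dv.reshape(1, -1) if dv.size else np.empty((1, 0)),
                   doses, tau_ss=None, lbw=lbw, crcl_lh=crcl_lh, tbw=cov.weight,
                   rk4_h=rk4_h)

    # -- forward model ------------------------------------------------------

    def natural(self, eta):
        """Natural-scale estimated parameters, (..., B, K)."""
        return self.means * np.exp(np.asarray(eta))

    def _p(self, nat, name):
        """Parameter by symbol: estimated column of ``nat`` or fixed value."""
        k = self._idx.get(name)
        return nat[..., k] if k is not None else self._fixed[name]

    def predict(self, eta):
        """Predicted concentrations (..., B, T) at the observation times."""
        nat = self.natural(eta)
        m = self.model_id
        if m == "1cmt_iv":
            cl = self._p(nat, "CLslope") * self.crcl_lh \
                + self._p(nat, "CLnr") * self.lbw * _CLNR_U[self.drug]
            v = self._p(nat, "Vnr") * self.lbw
            return conc_1cmt_iv(cl, v, self.doses, self.obs_times, self.tau_ss)
        if m == "2cmt_iv":
            cl = self._p(nat, "CLslope") * self.crcl_lh \
                + self._p(nat, "CLnr") * self.lbw * _CLNR_U[self.drug]
            v = self._p(nat, "Vnr") * self.lbw
            return conc_2cmt_iv(cl, v, self._p(nat, "k12"), self._p(nat, "k21"),
                                self.doses, self.obs_times, self.tau_ss)
        if m == "1cmt_oral1":
            cl = self._p(nat, "CLnr") * self.lbw * _CLNR_U[self.drug]
            v = self._p(nat, "Vnr") * self.lbw
            return conc_1cmt_oral1(cl, v, self._p(nat, "ka"), self._p(nat, "F"),
                                   self.doses, self.obs_times, self.tau_ss)
        if m == "mm_zero":
            vmax_h = self._p(nat, "Vmax") / 24.0
            km = self._p(nat, "km")
            v = self._p(nat, "Vnr") * 70.0 * (self.tbw / 70.0) ** 0.6
            cl_lin = self._p(nat, "CLslope") * self.crcl_lh
            return mm_conc_rk4(vmax_h, km, v, cl_lin, self._p(nat, "F"),
                               self.doses, self.obs_times, h=self.rk4_h)
        raise ValueError(f"unknown model {m}")  # pragma: no cover

    # -- posterior ----------------------------------------------------------

    def log_prior(self, eta):
        eta = np.asarray(eta)
        z = eta / self.omega
        return (-0.5 * _LOG2PI - np.log(self.omega) - 0.5 * z * z).sum(axis=-1)

    def log_posterior(self, eta):
        lp = self.log_prior(eta)
        if self.obs.shape[1]:
            cp = self.predict(eta)
            sig = self.cv_assay * cp + self.s_assay
            z = (self.obs - cp) / sig
            lp = lp + (-0.5 * _LOG2PI - np.log(sig) - 0.5 * z * z).sum(axis=-1)
        return lp

    def value_and_grad(self, eta):
        """(log posterior (B,), gradient (B, K)) via complex-step.

        Overflow at extreme trial points (possible during leapfrog
        exploration) yields non-finite values that the samplers treat as
        divergent; it is not an error here."""
        eta = np.asarray(eta, float)
        pert = eta[None, :, :] + (1j * _CSTEP) * np.eye(self.K)[:, None, :]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            lp = self.log_posterior(pert)  # (K, B)
        return lp[0].real.copy(), (lp.imag / _CSTEP).T.copy()

    # -- MAP objective ------------------------------------------------------

    def phi(self, eta):
        """Penalized least-squares MAP objective (no log-sigma term):
        sum_i (y_i - C_pred,i)^2 / sigma_i^2 + sum_k eta_k^2 / omega_k^2."""
        eta = np.asarray(eta)
        out = ((eta / self.omega) ** 2).sum(axis=-1)
        if self.obs.shape[1]:
            cp = self.predict(eta)
            sig = self.cv_assay * cp + self.s_assay
            out = out + (((self.obs - cp) / sig) ** 2).sum(axis=-1)
        return out

    def phi_value_and_grad(self, eta):
        eta = np.asarray(eta, float)
        pert = eta[None, :, :] + (1j * _CSTEP) * np.eye(self.K)[:, None, :]
        ph = self.phi(pert)
        return ph[0].real.copy(), (ph.imag / _CSTEP).T.copy()


# ---------------------------------------------------------------------------
# batched fixed-length HMC
# ---------------------------------------------------------------------------

def batched_hmc(design: PosteriorDesign, settings: SamplerSettings,
                rng: np.random.Generator):
    """Jittered fixed-length HMC over B = patients x chains rows.

    Returns (draws, info): draws has shape (samples, B, K); info carries
    per-row divergence counts, adapted step sizes and acceptance rates.
    """
    B, K = design.B, design.K
    warmup, samples = settings.warmup, settings.samples
    minv = np.broadcast_to(design.omega ** 2, (B, K)).copy()  # inverse mass
    eta = 0.1 * rng.standard_normal((B, K))
    lp, grad = design.value_and_grad(eta)

    log_eps = np.full(B, math.log(0.1))
    mu = np.full(B, math.log(1.0))
    log_eps_bar = np.zeros(B)
    h_bar = np.zeros(B)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = np.zeros(B)

    window_lo, window_hi = warmup // 4, warmup // 2
    window: list[np.ndarray] = []

    draws = np.empty((samples, B, K))
    divergences = np.zeros(B, dtype=int)
    n_acc = np.zeros(B)

    for it in range(warmup + samples):
        adapting = it < warmup
        eps = np.exp(log_eps if adapting else log_eps_bar)[:, None]
        L = int(rng.integers(1, settings.max_leapfrog + 1))
        p0 = rng.standard_normal((B, K)) / np.sqrt(minv)
        # leapfrog
        q, g = eta, grad
        p = p0 + 0.5 * eps * g
        for l in range(L):
            q = q + eps * minv * p
            lp_new, g = design.value_and_grad(q)
            if l < L - 1:
                p = p + eps * g
        p = p + 0.5 * eps * g
        h0 = -lp + 0.5 * (minv * p0 * p0).sum(axis=1)
        h1 = -lp_new + 0.5 * (minv * p * p).sum(axis=1)
        with np.errstate(over="ignore", invalid="ignore"):
            dh = h0 - h1
            alpha = np.exp(np.minimum(dh, 0.0))
        bad = ~np.isfinite(dh)
        alpha = np.where(bad, 0.0, alpha)
        divergent = bad | (-dh > 1000.0)
        accept = (rng.random(B) < alpha) & ~divergent
        eta = np.where(accept[:, None], q, eta)
        lp = np.where(accept, lp_new, lp)
        grad = np.where(accept[:, None], g, grad)

        if adapting:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (settings.target_accept - alpha)
            log_eps = mu - math.sqrt(it + 1) / gamma * h_bar
            np.clip(log_eps, -8.0, 2.0, out=log_eps)
            w = da_count ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            if window_lo <= it < window_hi:
                window.append(eta.copy())
            if it + 1 == window_hi and len(window) >= 10:
                warr = np.asarray(window)
                var = warr.var(axis=0, ddof=1)
                w_n = warr.shape[0]
                minv = (w_n / (w_n + 5.0)) * var + (5.0 / (w_n + 5.0)) * design.omega ** 2
                minv = np.maximum(minv, 1e-10)
                # restart step-size adaptation around the current step size
                mu = log_eps + math.log(10.0)
                h_bar = np.zeros(B)
                da_count = np.zeros(B)
                window.clear()
        else:
            draws[it - warmup] = eta
            divergences += divergent
            n_acc += alpha
    info = {
        "flavor": "hmc_jittered_static",
        "divergences": divergences,
        "step_size": np.exp(log_eps_bar),
        "accept_rate": n_acc / samples,
        "inv_mass": minv,
    }
    return draws, info


# ---------------------------------------------------------------------------
# per-patient NUTS
# ---------------------------------------------------------------------------

def _leapfrog(vg, q, p, g, eps, minv):
    p = p + 0.5 * eps * g
    q = q + eps * minv * p
    lp, g = vg(q)
    p = p + 0.5 * eps * g
    return q, p, lp, g


def _nuts_chain(vg: Callable, K: int, omega: np.ndarray, settings: SamplerSettings,
                rng: np.random.Generator):
    """One NUTS chain (slice-sampling variant with dynamic doubling)."""
    warmup, samples = settings.warmup, settings.samples
    minv = omega.astype(float) ** 2
    q = 0.1 * rng.standard_normal(K)
    lp, g = vg(q)

    log_eps = math.log(0.1)
    mu = math.log(1.0)
    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    window_lo, window_hi = warmup // 4, warmup // 2
    window = []
    draws = np.empty((samples, K))
    divergences = 0
    depths = np.zeros(samples, dtype=int)

    def build_tree(q, p, g, logu, v, j, eps, h0):
        if j == 0:
            q1, p1, lp1, g1 = _leapfrog(vg, q, p, g, v * eps, minv)
            h1 = -lp1 + 0.5 * float((minv * p1 * p1).sum())
            if not math.isfinite(h1):
                h1 = math.inf
            n1 = 1 if logu <= -h1 else 0
            s1 = 1 if logu < 1000.0 - h1 else 0
            a1 = min(1.0, math.exp(min(h0 - h1, 0.0)))
            return q1, p1, g1, q1, p1, g1, q1, n1, s1, a1, 1, (1 - s1)
        qm, pm, gm, qp, pp, gp, qq, n1, s1, a1, na1, dv1 = \
            build_tree(q, p, g, logu, v, j - 1, eps, h0)
        dv2 = 0
        if s1:
            if v == -1:
                qm, pm, gm, _, _, _, q2, n2, s2, a2, na2, dv2 = \
                    build_tree(qm, pm, gm, logu, v, j - 1, eps, h0)
            else:
                _, _, _, qp, pp, gp, q2, n2, s2, a2, na2, dv2 = \
                    build_tree(qp, pp, gp, logu, v, j - 1, eps, h0)
            if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
                qq = q2
            dq = qp - qm
            s1 = s2 * (1 if (dq * (minv * pm)).sum() >= 0 else 0) \
                * (1 if (dq * (minv * pp)).sum() >= 0 else 0)
            n1 += n2
            a1 += a2
            na1 += na2
        return qm, pm, gm, qp, pp, gp, qq, n1, s1, a1, na1, dv1 + dv2

    for it in range(warmup + samples):
        adapting = it < warmup
        eps = math.exp(log_eps if adapting else log_eps_bar)
        p0 = rng.standard_normal(K) / np.sqrt(minv)
        h0 = -lp + 0.5 * float((minv * p0 * p0).sum())
        logu = math.log(rng.random()) - h0
        qm = qp = q
        pm = pp = p0
        gm = gp = g
        qq = q
        n, s, j = 1, 1, 0
        alpha_sum, n_alpha = 0.0, 0
        div = 0
        while s and j < settings.max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                qm, pm, gm, _, _, _, q2, n2, s2, a2, na2, dv = \
                    build_tree(qm, pm, gm, logu, v, j, eps, h0)
            else:
                _, _, _, qp, pp, gp, q2, n2, s2, a2, na2, dv = \
                    build_tree(qp, pp, gp, logu, v, j, eps, h0)
            div += dv
            if s2 and rng.random() < min(1.0, n2 / max(n, 1)):
                qq = q2
            n += n2
            alpha_sum += a2
            n_alpha += na2
            dq = qp - qm
            s = s2 * (1 if (dq * (minv * pm)).sum() >= 0 else 0) \
                * (1 if (dq * (minv * pp)).sum() >= 0 else 0)
            j += 1
        if not np.array_equal(qq, q):
            q = qq
            lp, g = vg(q)
        alpha = alpha_sum / max(n_alpha, 1)

        if adapting:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (settings.target_accept - alpha)
            log_eps = mu - math.sqrt(da_count) / gamma * h_bar
            log_eps = min(max(log_eps, -8.0), 2.0)
            w = da_count ** -kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            if window_lo <= it < window_hi:
                window.append(q.copy())
            if it + 1 == window_hi and len(window) >= 10:
                warr = np.asarray(window)
                var = warr.var(axis=0, ddof=1)
                w_n = warr.shape[0]
                minv = (w_n / (w_n + 5.0)) * var + (5.0 / (w_n + 5.0)) * omega ** 2
                minv = np.maximum(minv, 1e-10)
                mu = log_eps + math.log(10.0)
                h_bar, da_count = 0.0, 0
                window.clear()
        else:
            draws[it - warmup] = q
            divergences += div
            depths[it - warmup] = j
    return draws, {"divergences": divergences, "step_size": math.exp(log_eps_bar),
                   "mean_treedepth": float(depths.mean())}


def nuts_sample(design: PosteriorDesign, settings: SamplerSettings,
                rng: np.random.Generator):
    """Multi-chain NUTS for a single-patient design (B must be 1).

    Returns (draws (chains, samples, K), info dict)."""
    if design.B != 1:
        raise ValueError("nuts_sample expects a single-patient design")

    def vg(q):
        lp, g = design.value_and_grad(q[None, :])
        return float(lp[0]), g[0]

    child_rngs = rng.spawn(settings.chains)
    out = np.empty((settings.chains, settings.samples, design.K))
    infos = []
    for c in range(settings.chains):
        out[c], info = _nuts_chain(vg, design.K, design.omega, settings, child_rngs[c])
        infos.append(info)
    return out, {"flavor": "nuts", "chains": infos,
                 "divergences": np.array([i["divergences"] for i in infos])}


# ---------------------------------------------------------------------------
# MAP
# ---------------------------------------------------------------------------

def batched_map(design: PosteriorDesign, starts: int = 3,
                rng: np.random.Generator | None = None, maxiter: int = 500,
                objective: str = "posterior_mode"):
    """Multi-start quasi-Newton MAP estimation.

    objective 'posterior_mode' (default) minimizes the full negative log
    posterior, including the log sigma(C_pred) normalization of the
    heteroscedastic error model — the posterior mode proper. objective
    'phi' minimizes the classical penalized least-squares objective
    Phi = sum (y-C)^2/sigma^2 + sum eta^2/omega^2, which drops that term.
    The two coincide when sigma is constant; with prediction-dependent
    sigma the mode sits slightly lower (the normalization rewards smaller
    predicted concentrations).

    The B per-patient problems are independent; they are optimized jointly
    (block-diagonal objective) and the best objective value per patient
    across starts wins. With no observations the prior means (eta = 0) are
    returned exactly. Returns (eta (B, K), objective values (B,), info)."""
    if objective not in ("posterior_mode", "phi"):
        raise ValueError("objective must be 'posterior_mode' or 'phi'")
    B, K = design.B, design.K
    if design.obs.shape[1] == 0:
        zero = np.zeros((B, K))
        return zero, design.phi(zero), \
            {"converged": np.ones(B, bool), "n_restarts_used": 0}
    rng = rng or np.random.default_rng(0)

    if objective == "phi":
        def rows(eta):
            return design.phi_value_and_grad(eta)
    else:
        def rows(eta):
            lp, g = design.value_and_grad(eta)
            return -lp, -g

    def fun(x):
        val, g = rows(x.reshape(B, K))
        return val.sum(), g.ravel()

    best_eta = np.zeros((B, K))
    best_val, _ = rows(best_eta)
    converged = np.zeros(B, bool)
    for s in range(max(1, starts)):
        x0 = np.zeros((B, K)) if s == 0 else \
            0.5 * design.omega * rng.standard_normal((B, K))
        res = optimize.minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter})
        eta_s = res.x.reshape(B, K)
        val_s, _ = rows(eta_s)
        better = val_s < best_val
        best_eta[better] = eta_s[better]
        best_val = np.where(better, val_s, best_val)
        converged |= res.success
    return best_eta, best_val, {"converged": converged,
                                "n_restarts_used": max(1, starts)}


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _split(x):
    """Split chains in half: (..., C, S) -> (..., 2C, S//2)."""
    x = np.asarray(x, float)
    C, S = x.shape[-2:]
    S2 = S // 2
    x = x[..., : 2 * S2]
    return x.reshape(x.shape[:-2] + (C, 2, S2)).reshape(x.shape[:-2] + (2 * C, S2))

def _rank_normalize(x):
    """Rank-normalize jointly over the last two (chain, draw) axes."""
    shape = x.shape
    n = shape[-2] * shape[-1]
    flat = x.reshape(shape[:-2] + (n,))
    r = stats.rankdata(flat, axis=-1, method="average")
    z = special.ndtri((r - 0.375) / (n + 0.25))
    return z.reshape(shape)


def split_rhat(x):
    """Rank-normalized split R-hat. x: (..., C, S) -> (...)."""
    x = np.asarray(x, float)
    if x.shape[-2] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    z = _rank_normalize(_split(x))
    S = z.shape[-1]
    cm = z.mean(axis=-1)
    W = z.var(axis=-1, ddof=1).mean(axis=-1)
    Bv = S * cm.var(axis=-1, ddof=1)
    var_plus = (S - 1) / S * W + Bv / S
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / W)


def _acov_fft(z):
    """Per-chain autocovariance (biased, denominator S) along the last axis."""
    S = z.shape[-1]
    zc = z - z.mean(axis=-1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * S)))
    f = np.fft.rfft(zc, n=nfft, axis=-1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=-1).real[..., :S]
    return acov / S


def ess_bulk(x):
    """Bulk effective sample size on rank-normalized split chains.

    x: (..., C, S) -> (...). Uses Geyer's initial monotone positive
    sequence on paired autocorrelations."""
    x = np.asarray(x, float)
    z = _rank_normalize(_split(x))
    C, S = z.shape[-2:]
    if S < 4:
        raise ValueError("too few draws for ESS")
    acov = _acov_fft(z)
    within = acov[..., 0].mean(axis=-1) * S / (S - 1)
    cm = z.mean(axis=-1)
    Bv = cm.var(axis=-1, ddof=1)
    var_plus = (S - 1) / S * within + Bv
    mean_acov = acov.mean(axis=-2)  # over chains
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 1.0 - (within[..., None] - mean_acov) / var_plus[..., None]
    rho[..., 0] = 1.0
    npairs = S // 2
    pairs = rho[..., : 2 * npairs].reshape(rho.shape[:-1] + (npairs, 2)).sum(axis=-1)
    pos = np.cumprod(pairs > 0.0, axis=-1).astype(bool)
    mono = np.minimum.accumulate(np.where(pos, pairs, 0.0), axis=-1)
    tau = -1.0 + 2.0 * np.where(pos, np.maximum(mono, 0.0), 0.0).sum(axis=-1)
    tau = np.maximum(tau, 1.0 / np.log10(C * S + 10.0))
    ess = C * S / tau
    return np.minimum(ess, C * S)
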