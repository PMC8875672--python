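"""Independent numeric oracles used by the tests.

Everything here integrates the compartment ODEs directly with scipy's
adaptive solvers (or fixed-step RK4), sharing no code with the package's
closed-form kernels.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def _input_rate(doses, t):
    """Zero-order input rate into the dosed compartment at time t."""
    r = 0.0
    for (t0, amt, rate) in doses:
        if rate > 0 and t0 <= t < t0 + amt / rate:
            r += rate
    return r


def _breakpoints(doses, t_end):
    cuts = {0.0, t_end}
    for (t0, amt, rate) in doses:
        cuts.add(t0)
        if rate > 0:
            cuts.add(min(t0 + amt / rate, t_end))
    return sorted(c for c in cuts if 0.0 <= c <= t_end)


def _integrate(rhs_factory, y0, doses, times, bolus_cmt=None, f=1.0,
               rtol=1e-10, atol=1e-12):
    """Piecewise integration between input discontinuities; bolus doses
    (rate == 0) are applied as state jumps in ``bolus_cmt``."""
    times = np.atleast_1d(np.asarray(times, float))
    t_end = float(max(times.max(), max(t0 + (amt / rate if rate > 0 else 0.0)
                                       for (t0, amt, rate) in doses)))
    edges = _breakpoints(doses, t_end)
    y = np.array(y0, float)
    out = np.zeros((len(times), len(y)))
    out[times == 0.0] = y
    for a, b in zip(edges[:-1], edges[1:]):
        for (t0, amt, rate) in doses:
            if rate == 0 and abs(t0 - a) < 1e-12:
                y[bolus_cmt] += f * amt
        mid = 0.5 * (a + b)
        R = _input_rate(doses, mid)
        rhs = rhs_factory(R)
        sel = (times > a) & (times <= b)
        t_eval = np.unique(np.append(times[sel], b))
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, rtol=rtol, atol=atol,
                        method="LSODA")
        assert sol.success, sol.message
        for j in np.flatnonzero(sel):
            out[j] = sol.y[:, list(sol.t).index(times[j])]
        y = sol.y[:, -1].copy()
    return out


def ode_1cmt_iv(cl, v, doses, times):
    def factory(R):
        return lambda t, y: [R - (cl / v) * y[0]]
    amounts = _integrate(factory, [0.0], doses, times)
    return amounts[:, 0] / v


def ode_2cmt_iv(cl, v, k12, k21, doses, times):
    k10 = cl / v

    def factory(R):
        return lambda t, y: [R - (k10 + k12) * y[0] + k21 * y[1],
                             k12 * y[0] - k21 * y[1]]
    amounts = _integrate(factory, [0.0, 0.0], doses, times)
    return amounts[:, 0] / v


def ode_1cmt_oral1(cl, v, ka, f, doses, times):
    ke = cl / v

    def factory(R):
        return lambda t, y: [R - ka * y[0], ka * y[0] - ke * y[1]]
    amounts = _integrate(factory, [0.0, 0.0], doses, times, bolus_cmt=0, f=f)
    return amounts[:, 1] / v


def rk4_mm_zero(vmax, km, v, cl_lin, f, doses, times, h=1e-3):
    """Fixed-step RK4 for the Michaelis-Menten model (independent of the
    package's vectorized integrator)."""
    times = np.atleast_1d(np.asarray(times, float))
    t_end = float(max(times.max(), max(t0 + amt / rate for (t0, amt, rate) in doses)))
    n = int(round(t_end / h))
    idx = {int(round(t / h)): j for j, t in enumerate(times)}
    out = np.zeros(len(times))
    A = 0.0

    def rhs(t, A):
        R = _input_rate(doses, t) * f
        C = A / v
        return R - vmax * C / (km + C) - cl_lin * C

    for i in range(n):
        t = i * h
        k1 = rhs(t + 1e-12, A)          # sample inputs just inside the step
        k2 = rhs(t + h / 2, A + h * k1 / 2)
        k3 = rhs(t + h / 2, A + h * k2 / 2)
        k4 = rhs(t + h - 1e-12, A + h * k3)
        A += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i + 1 in idx:
            out[idx[i + 1]] = A / v
    if 0 in idx:
        out[idx[0]] = 0.0
    return out
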