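"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's solver machinery: the forward oracle
is a fixed-step integrator that re-solves the algebraic force balance by
bisection at every step and steps the Maxwell tension explicitly.
"""

from __future__ import annotations

import math

import numpy as np


def fixed_step_bisection_sim(d, k_clv, T0, k1, k2, eta, v0, delta_s_star, t_hold,
                             t_eval, dt=1e-4):
    """Fixed-step reference trajectory of the cantilever-fiber system.

    At each step the stage position is advanced, the balance
    k_clv*(delta_s - e) = 2*(T0 + k1*delta(e) + T_m)*e/sqrt(d^2+e^2)
    is solved for e by bisection (warm-started from the previous e), and T_m
    is updated explicitly from the elongation increment. Returns (e, T_m)
    sampled at ``t_eval`` (which must be multiples of dt up to round-off).
    """
    t_eval = np.asarray(t_eval, dtype=float)
    t_star = delta_s_star / v0
    t_end = float(t_eval[-1])
    n_steps = int(round(t_end / dt))

    def balance(e, ds, tm):
        root = math.sqrt(d * d + e * e)
        return k_clv * (ds - e) - 2.0 * (T0 + k1 * (root - d) + tm) * e / root

    e = 0.0
    tm = 0.0
    delta_prev = 0.0
    e_out = np.empty(t_eval.size)
    tm_out = np.empty(t_eval.size)
    targets = np.rint(t_eval / dt).astype(int)
    out_i = 0
    if targets[0] == 0:
        e_out[0] = e
        tm_out[0] = tm
        out_i = 1
    for n in range(1, n_steps + 1):
        t = n * dt
        ds = min(v0 * t, delta_s_star)
        # bracket around the previous solution, widening if necessary
        width = max(2.0 * v0 * dt, 1e-3)
        lo, hi = max(0.0, e - width), min(ds + 1e-9, e + width) if ds > 0 else (0.0, 0.0)
        if ds <= 0:
            e_new = 0.0
        else:
            lo = max(0.0, e - width)
            hi = min(ds, e + width)
            while balance(lo, ds, tm) < 0 and lo > 0.0:
                lo = max(0.0, lo - width)
                width *= 2.0
            width = max(2.0 * v0 * dt, 1e-3)
            while balance(hi, ds, tm) > 0 and hi < ds:
                hi = min(ds, hi + width)
                width *= 2.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if balance(mid, ds, tm) > 0:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-13:
                    break
            e_new = 0.5 * (lo + hi)
        root = math.sqrt(d * d + e_new * e_new)
        delta = root - d
        tm = tm + k2 * (delta - delta_prev) - dt * (k2 / eta) * tm
        delta_prev = delta
        e = e_new
        if out_i < targets.size and n == targets[out_i]:
            e_out[out_i] = e
            tm_out[out_i] = tm
            out_i += 1
    if out_i != targets.size:
        raise RuntimeError("t_eval not aligned with oracle step grid")
    return e_out, tm_out


def exp_relax_tau(t, y):
    """Plain saturating-exponential fit (scipy) used to time a relaxation."""
    from scipy.optimize import curve_fit

    def f(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    p0 = (y[-1], max(t[-1] / 5.0, 1e-3))
    popt, _ = curve_fit(f, t, y, p0=p0, maxfev=20000)
    resid = y - f(t, *popt)
    r2 = 1.0 - float(np.sum(resid**2)) / float(np.sum((y - y.mean()) ** 2))
    return float(popt[1]), float(popt[0]), r2
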