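"""Geometry, constitutive law and forward simulation of the cantilever–fiber system.

A single peripheral stress fiber of half-length ``d`` is deflected at its
midpoint by a soft cantilever of spring constant ``k_clv``. The motorized
stage moves the cell by ``delta_s(t)`` (a constant-speed ramp followed by a
hold); the cantilever bends by ``delta_clv`` and the fiber midpoint moves
transversely by ``e = delta_s - delta_clv``. Inertia is negligible, so at
every instant the cantilever force balances the transverse projection of the
tension carried by the two fiber half-segments::

    k_clv * (delta_s - e) = 2 * T * sin(theta),   sin(theta) = e / sqrt(d^2 + e^2)

The fiber itself is an *active standard linear solid*: a spring ``k1`` in
parallel with a Maxwell element (spring ``k2`` in series with a dashpot
``eta``) and a constant motor pre-tension ``T0``::

    T = T0 + k1 * delta + T_m
    dT_m/dt = k2 * ddelta/dt - (k2 / eta) * T_m

where ``delta = sqrt(d^2 + e^2) - d`` is the elongation of one half-segment
and ``T_m`` is the tension carried by the Maxwell branch.

Units are fixed package-wide and never inferred: lengths in um, time in s,
force in nN, stiffness in nN/um, viscosity in nN*s/um.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FiberGeometry",
    "CantileverProbe",
    "MechanicalParams",
    "StageProtocol",
    "SolverConfig",
    "SimTrace",
    "SolverError",
    "UndefinedTensionError",
    "transverse_to_elongation",
    "projection_sine",
    "tension_from_force",
    "constitutive_tension",
    "maxwell_rate",
    "forward_simulate",
    "simulate_ensemble",
    "elastic_equilibrium",
    "relax_from_state",
    "asymmetric_tension_error",
    "asymmetric_tension_error_numeric",
    "E_MIN_DEFAULT",
]

#: Minimum transverse displacement (um) below which tension inference from
#: force is rejected: near e = 0 both force and sin(theta) vanish and the
#: ratio amplifies measurement noise without bound.
E_MIN_DEFAULT = 1.0


class SolverError(RuntimeError):
    """Forward integration failed; carries the last valid state."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class UndefinedTensionError(ValueError):
    """Tension cannot be inferred (e below the e_min guard)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberGeometry:
    """Rest geometry of the probed fiber.

    Parameters
    ----------
    d : float
        Fiber half-length in um (probe assumed at the midpoint).
    """

    d: float

    def __post_init__(self):
        if not self.d > 0:
            raise ValueError(f"fiber half-length d must be positive, got {self.d}")
        if not 10.0 <= self.d <= 60.0:
            warnings.warn(
                f"fiber half-length d={self.d} um is outside the plausible "
                "range [10, 60] um (experimental fibers: 22-35 um)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class CantileverProbe:
    """Calibrated probe. ``k_clv`` is the cantilever spring constant, nN/um."""

    k_clv: float

    def __post_init__(self):
        if not self.k_clv > 0:
            raise ValueError(f"k_clv must be positive, got {self.k_clv}")
        if not 1.0 <= self.k_clv <= 10.0:
            warnings.warn(
                f"k_clv={self.k_clv} nN/um is outside the plausible range "
                "[1, 10] nN/um (experimental probes: 1.53-6.25 nN/um)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MechanicalParams:
    """Active standard-linear-solid parameters of one fiber.

    T0 : pre-tension, nN (motor activity; tension at zero elongation).
    k1 : parallel spring constant, nN/um.
    k2 : Maxwell-branch spring constant, nN/um. ``k2 = 0`` disables the
         Maxwell branch entirely (pure elastic fiber, T_m identically 0).
    eta : dashpot viscosity, nN*s/um.
    """

    T0: float
    k1: float
    k2: float
    eta: float

    def __post_init__(self):
        if self.T0 < 0:
            raise ValueError(f"pre-tension T0 must be >= 0, got {self.T0}")
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be >= 0, got {self.k2}")
        if not self.eta > 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.k2 > 0 and not math.isfinite(self.eta / self.k2):
            raise ValueError("intrinsic Maxwell time eta/k2 must be finite")

    @property
    def maxwell_time(self) -> float:
        """Intrinsic Maxwell time eta/k2 in s (inf for a pure elastic fiber)."""
        return self.eta / self.k2 if self.k2 > 0 else math.inf

    @property
    def is_elastic(self) -> bool:
        return self.k2 == 0.0


@dataclass(frozen=True)
class StageProtocol:
    """Stage trajectory: ramp at ``v0`` to ``delta_s_star``, then hold.

    delta_s(t) = v0*t for t <= t_star = delta_s_star/v0, constant afterwards.
    The corner at t_star is deliberately not smoothed; integration restarts
    there. ``sample_rate`` sets the uniform output grid (>= 10 Hz so a
    5 um/s ramp is adequately sampled).
    """

    v0: float = 5.0
    delta_s_star: float = 20.0
    t_hold: float = 10.0
    sample_rate: float = 50.0

    def __post_init__(self):
        if not self.v0 > 0:
            raise ValueError("stage speed v0 must be > 0")
        if not self.delta_s_star > 0:
            raise ValueError("delta_s_star must be > 0")
        if self.t_hold < 0:
            raise ValueError("t_hold must be >= 0")
        if self.sample_rate < 10.0:
            raise ValueError("sample_rate must be >= 10 Hz")

    @property
    def t_star(self) -> float:
        """Halt time: stage displacement reaches delta_s_star."""
        return self.delta_s_star / self.v0

    @property
    def t_end(self) -> float:
        return self.t_star + self.t_hold

    def time_grid(self) -> np.ndarray:
        dt = 1.0 / self.sample_rate
        n = int(math.floor(self.t_end / dt + 1e-9))
        return np.arange(n + 1) * dt

    def stage_position(self, t):
        return np.minimum(np.asarray(t, dtype=float) * self.v0, self.delta_s_star)


@dataclass(frozen=True)
class SolverConfig:
    """Integration accuracy knobs (ode45-class defaults).

    After integration each output sample is projected back onto the algebraic
    force balance with a few Newton iterations (``project=True``), which pins
    the balance residual to round-off without altering the dynamics.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "RK45"
    project: bool = True
    max_step: float = math.inf


@dataclass
class SimTrace:
    """Forward-model output on the protocol's uniform grid (all arrays, SI-μm units).

    Satisfies by construction: delta_clv = delta_s - e, F_clv = k_clv*delta_clv,
    and the quasi-static balance F_clv = 2*T*sin(theta) to solver accuracy.
    """

    t: np.ndarray
    delta_s: np.ndarray
    e: np.ndarray
    delta_clv: np.ndarray
    F_clv: np.ndarray
    delta: np.ndarray
    T: np.ndarray
    T_m: np.ndarray
    geometry: FiberGeometry
    probe: CantileverProbe
    params: MechanicalParams
    protocol: StageProtocol
    solver: SolverConfig

    def force_balance_residual(self) -> np.ndarray:
        """k_clv*(delta_s - e) - 2*T*sin(theta), nN, per sample."""
        s = projection_sine(self.geometry, self.e)
        return self.probe.k_clv * (self.delta_s - self.e) - 2.0 * self.T * s

    @property
    def strain(self) -> np.ndarray:
        return self.delta / self.geometry.d

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.t,
                "stage_um": self.delta_s,
                "cantilever_um": self.delta_clv,
                "e_um": self.e,
                "force_nN": self.F_clv,
                "delta_um": self.delta,
                "tension_nN": self.T,
                "tmaxwell_nN": self.T_m,
            }
        )


# ---------------------------------------------------------------------------
# kinematics and constitutive operations
# ---------------------------------------------------------------------------


def _half_length(d, e):
    return np.sqrt(d * d + np.asarray(e, dtype=float) ** 2)


def transverse_to_elongation(geometry: FiberGeometry, e):
    """Elongation of one fiber half-segment, delta = sqrt(d^2+e^2) - d (um).

    ``e`` is the magnitude of the transverse midpoint displacement and must be
    non-negative (probing direction is recorded as metadata, not as a sign).
    Works elementwise on arrays. Strain is ``delta / d``.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("transverse displacement e must be >= 0")
    out = _half_length(geometry.d, e) - geometry.d
    return out if out.ndim else float(out)


def projection_sine(geometry: FiberGeometry, e):
    """sin(theta) = e / sqrt(d^2 + e^2), the transverse projection factor."""
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("transverse displacement e must be >= 0")
    out = e / _half_length(geometry.d, e)
    return out if out.ndim else float(out)


def tension_from_force(F_clv, geometry: FiberGeometry, e, e_min: float = E_MIN_DEFAULT):
    """Fiber tension from cantilever force: T = F_clv / (2 sin(theta)), nN.

    Valid only away from e = 0 where the balance degenerates (0/0); samples
    with ``e < e_min`` must be excluded from tension curves and raise
    :class:`UndefinedTensionError` here.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < e_min):
        raise UndefinedTensionError(
            f"tension undefined for e < e_min = {e_min} um (got min e = "
            f"{float(np.min(e_arr))}); exclude these samples"
        )
    out = np.asarray(F_clv, dtype=float) / (2.0 * projection_sine(geometry, e_arr))
    return out if out.ndim else float(out)


def constitutive_tension(params: MechanicalParams, delta, T_m):
    """Total fiber tension T = T0 + k1*delta + T_m (active SLS network)."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("elongation delta must be >= 0")
    out = params.T0 + params.k1 * delta + np.asarray(T_m, dtype=float)
    return out if out.ndim else float(out)


def maxwell_rate(params: MechanicalParams, delta_dot, T_m):
    """dT_m/dt = k2*delta_dot - (k2/eta)*T_m.

    At constant elongation rate the branch saturates at T_m = eta*delta_dot;
    at delta_dot = 0 it decays with the intrinsic time eta/k2.
    """
    out = params.k2 * np.asarray(delta_dot, dtype=float) - (
        params.k2 / params.eta
    ) * np.asarray(T_m, dtype=float)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------
#
# State-space form. The quasi-static balance
#     G(e, T_m, t) = k_clv*(delta_s(t) - e) - 2*(T0 + k1*delta(e) + T_m)*s(e) = 0
# is an index-1 constraint; differentiating it in time and substituting
# d(delta)/dt = s(e)*de/dt and the Maxwell law gives an explicit ODE for e:
#
#     de/dt = [k_clv*v(t) + 2*s*(k2/eta)*T_m] / [k_clv + 2*(k1+k2)*s^2 + 2*T*s']
#     dT_m/dt = k2*s*de/dt - (k2/eta)*T_m
#
# with s'(e) = d^2/(d^2+e^2)^(3/2). The denominator is strictly positive for
# any admissible parameters, so no pathology arises even at e = 0. The stage
# speed v(t) is piecewise constant, so the two phases are integrated
# separately and the solver restarts at the ramp/hold corner.


def _make_rhs(d, k_clv, T0, k1, k2, eta, v, m):
    k2_over_eta = k2 / eta

    def rhs(t, y):
        e = y[:m]
        T_m = y[m:]
        root = np.sqrt(d * d + e * e)
        s = e / root
        sprime = (d * d) / root**3
        T = T0 + k1 * (root - d) + T_m
        denom = k_clv + 2.0 * (k1 + k2) * s * s + 2.0 * T * sprime
        edot = (k_clv * v + 2.0 * s * k2_over_eta * T_m) / denom
        out = np.empty_like(y)
        out[:m] = edot
        out[m:] = k2 * s * edot - k2_over_eta * T_m
        return out

    return rhs


def _project_onto_balance(d, k_clv, T0, k1, k2_unused, e, T_m, delta_s, iters=4):
    """Newton-polish e so the algebraic balance holds to round-off.

    Vectorized over arbitrary shapes; T_m and delta_s broadcast against e.
    """
    e = np.array(e, dtype=float)
    for _ in range(iters):
        root = np.sqrt(d * d + e * e)
        s = e / root
        sprime = (d * d) / root**3
        T = T0 + k1 * (root - d) + T_m
        G = k_clv * (delta_s - e) - 2.0 * T * s
        Gp = -k_clv - 2.0 * (k1 * s * s + T * sprime)
        e = np.maximum(e - G / Gp, 0.0)
    return e


def simulate_ensemble(
    geometry: FiberGeometry,
    probe: CantileverProbe,
    T0,
    k1,
    k2,
    eta,
    protocol: StageProtocol,
    t_eval: np.ndarray | None = None,
    solver: SolverConfig | None = None,
):
    """Integrate many parameter sets at once over the same protocol.

    ``T0, k1, k2, eta`` are broadcast to a common shape ``(m,)``; all m
    two-state systems are stacked into a single 2m-dimensional ODE whose
    right-hand side is evaluated with vectorized numpy, which is how the
    fitting grid search stays tractable. Returns ``(e, T_m)`` arrays of shape
    ``(m, len(t_eval))``.
    """
    solver = solver or SolverConfig()
    T0, k1, k2, eta = np.broadcast_arrays(
        *[np.atleast_1d(np.asarray(a, dtype=float)) for a in (T0, k1, k2, eta)]
    )
    T0, k1, k2, eta = (np.ascontiguousarray(a) for a in (T0, k1, k2, eta))
    m = T0.shape[0]
    if t_eval is None:
        t_eval = protocol.time_grid()
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval[0] < 0 or t_eval[-1] > protocol.t_end + 1e-9:
        raise ValueError("t_eval must lie within [0, t_star + t_hold]")

    d = geometry.d
    k_clv = probe.k_clv
    t_star = protocol.t_star
    y = np.zeros(2 * m)
    e_out = np.empty((m, t_eval.size))
    tm_out = np.empty((m, t_eval.size))

    phases = [(0.0, min(t_star, t_eval[-1]), protocol.v0)]
    if t_eval[-1] > t_star:
        phases.append((t_star, t_eval[-1], 0.0))

    filled = 0
    for t0_phase, t1_phase, v in phases:
        sel = (t_eval >= t0_phase - 1e-12) & (t_eval <= t1_phase + 1e-12)
        # each output time is assigned to exactly one phase
        sel &= np.arange(t_eval.size) >= filled
        te = t_eval[sel]
        if t1_phase <= t0_phase + 1e-15:
            # degenerate phase (t_hold = 0 etc.)
            if te.size:
                e_out[:, sel] = y[:m, None]
                tm_out[:, sel] = y[m:, None]
                filled += te.size
            continue
        rhs = _make_rhs(d, k_clv, T0, k1, k2, eta, v, m)
        sol = solve_ivp(
            rhs,
            (t0_phase, t1_phase),
            y,
            method=solver.method,
            t_eval=te if te.size else None,
            rtol=solver.rtol,
            atol=solver.atol,
            max_step=solver.max_step,
            dense_output=False,
        )
        if not sol.success:
            raise SolverError(
                f"forward integration failed in phase [{t0_phase}, {t1_phase}]: "
                f"{sol.message}",
                t=sol.t[-1] if sol.t.size else t0_phase,
                state=sol.y[:, -1] if sol.t.size else y,
            )
        if te.size:
            e_out[:, sel] = sol.y[:m]
            tm_out[:, sel] = sol.y[m:]
            filled += te.size
        # re-integrate to the exact phase end for the restart state
        if sol.t[-1] < t1_phase - 1e-12:
            sol_end = solve_ivp(
                rhs,
                (sol.t[-1], t1_phase),
                sol.y[:, -1],
                method=solver.method,
                rtol=solver.rtol,
                atol=solver.atol,
                max_step=solver.max_step,
            )
            if not sol_end.success:
                raise SolverError(
                    f"forward integration failed approaching t={t1_phase}: "
                    f"{sol_end.message}",
                    t=sol_end.t[-1],
                    state=sol_end.y[:, -1],
                )
            y = sol_end.y[:, -1].copy()
        else:
            y = sol.y[:, -1].copy()

    if solver.project:
        delta_s = protocol.stage_position(t_eval)[None, :]
        e_out = _project_onto_balance(
            d, k_clv, T0[:, None], k1[:, None], None, e_out, tm_out, delta_s
        )
    return e_out, tm_out


def forward_simulate(
    geometry: FiberGeometry,
    probe: CantileverProbe,
    params: MechanicalParams,
    protocol: StageProtocol,
    solver: SolverConfig | None = None,
) -> SimTrace:
    """Simulate one ramp-and-hold pull; returns the full :class:`SimTrace`.

    A pure elastic fiber (``k2 = 0``) is handled by the same path: the Maxwell
    state stays identically zero and the trajectory tracks the algebraic
    elastic balance.
    """
    solver = solver or SolverConfig()
    t = protocol.time_grid()
    e, T_m = simulate_ensemble(
        geometry,
        probe,
        params.T0,
        params.k1,
        params.k2,
        params.eta,
        protocol,
        t_eval=t,
        solver=solver,
    )
    e = e[0]
    T_m = T_m[0]
    delta_s = protocol.stage_position(t)
    delta = transverse_to_elongation(geometry, e)
    T = constitutive_tension(params, delta, T_m)
    delta_clv = delta_s - e
    return SimTrace(
        t=t,
        delta_s=delta_s,
        e=e,
        delta_clv=delta_clv,
        F_clv=probe.k_clv * delta_clv,
        delta=delta,
        T=T,
        T_m=T_m,
        geometry=geometry,
        probe=probe,
        params=params,
        protocol=protocol,
        solver=solver,
    )


def elastic_equilibrium(
    geometry: FiberGeometry,
    probe: CantileverProbe,
    params: MechanicalParams,
    delta_s,
    T_m=0.0,
):
    """Closed algebraic solution of the balance for a given stage position.

    Solves k_clv*(delta_s - e) = 2*(T0 + k1*delta(e) + T_m)*sin(theta(e)) for
    e; with T_m = 0 this is the exact quasi-static response of a pure elastic
    fiber. Vectorized over delta_s via damped Newton (the balance is strictly
    monotone in e, so the iteration is globally convergent from e = 0).
    """
    delta_s = np.atleast_1d(np.asarray(delta_s, dtype=float))
    e = 0.5 * delta_s  # starting guess between the two rigid limits
    for _ in range(100):
        e_new = _project_onto_balance(
            geometry.d, probe.k_clv, params.T0, params.k1, None, e, T_m, delta_s, iters=1
        )
        if np.max(np.abs(e_new - e)) < 1e-14:
            e = e_new
            break
        e = e_new
    return e if e.ndim and e.size > 1 else float(e[0])


def relax_from_state(
    geometry: FiberGeometry,
    probe: CantileverProbe,
    params: MechanicalParams,
    e0: float,
    T_m0: float,
    duration: float,
    sample_rate: float = 50.0,
    solver: SolverConfig | None = None,
):
    """Hold-phase-only simulation from a prescribed state (e0, T_m0).

    The stage is pinned at the position that balances the initial state, then
    the Maxwell branch relaxes and e creeps toward its plateau. Used to study
    the relaxation timescale in isolation. Returns ``(t, e, T_m)``.
    """
    solver = solver or SolverConfig()
    d, k_clv = geometry.d, probe.k_clv
    delta0 = transverse_to_elongation(geometry, e0)
    s0 = projection_sine(geometry, e0)
    T_init = constitutive_tension(params, delta0, T_m0)
    delta_s = e0 + 2.0 * T_init * s0 / k_clv
    t = np.arange(int(math.floor(duration * sample_rate)) + 1) / sample_rate
    T0a = np.atleast_1d(float(params.T0))
    k1a = np.atleast_1d(float(params.k1))
    k2a = np.atleast_1d(float(params.k2))
    etaa = np.atleast_1d(float(params.eta))
    rhs = _make_rhs(d, k_clv, T0a, k1a, k2a, etaa, 0.0, 1)
    sol = solve_ivp(
        rhs,
        (0.0, float(t[-1])),
        np.array([e0, T_m0]),
        method=solver.method,
        t_eval=t,
        rtol=solver.rtol,
        atol=solver.atol,
    )
    if not sol.success:
        raise SolverError(f"hold-phase integration failed: {sol.message}")
    e, T_m = sol.y[0], sol.y[1]
    if solver.project:
        e = _project_onto_balance(d, k_clv, params.T0, params.k1, None, e, T_m, delta_s)
    return t, e, T_m


# ---------------------------------------------------------------------------
# probe-placement asymmetry
# ---------------------------------------------------------------------------


def asymmetric_tension_error(length_ratio: float) -> float:
    """Relative tension error from off-center probe placement (small-e limit).

    If the probe splits the fiber into rest lengths d1:d2 = r with
    d1 + d2 = 2d and the tension T is the same in both segments (the probe
    applies a purely transverse force), the transverse balance gives
    F = T*(sin th1 + sin th2) with sin th_i ~ e/d_i as e -> 0. Inferring
    tension with the symmetric formula F/(2 sin th), sin th ~ e/d, then
    overestimates T by::

        err = (d/2)*(1/d1 + 1/d2) - 1 = (r - 1)^2 / (4 r)

    which is ~4.2% for r = 1.5, i.e. off-center placement is benign: the
    tension rise on the short side nearly compensates the drop on the long
    side. Returns the dimensionless relative error (0 for r = 1).
    """
    r = float(length_ratio)
    if r < 1.0:
        raise ValueError("length_ratio is the long/short ratio and must be >= 1")
    # algebraically (d/2)(1/d1 + 1/d2) - 1 with d1 = 2dr/(1+r), d2 = 2d/(1+r);
    # this form is exact and free of cancellation at r -> 1
    return (r - 1.0) ** 2 / (4.0 * r)


def asymmetric_tension_error_numeric(
    length_ratio: float, e_over_d: np.ndarray | None = None
) -> float:
    """Finite-e force-balance evaluation of the placement error, extrapolated to e -> 0.

    Independent check of :func:`asymmetric_tension_error`: at each finite
    transverse displacement e the exact projection factors
    sin th_i = e/sqrt(d_i^2+e^2) are used, the apparent tension ratio is
    formed with the symmetric formula, and a quadratic in e^2 is extrapolated
    to zero displacement.
    """
    r = float(length_ratio)
    if r < 1.0:
        raise ValueError("length_ratio must be >= 1")
    if e_over_d is None:
        e_over_d = np.array([0.4, 0.3, 0.2, 0.1, 0.05, 0.025])
    e = np.asarray(e_over_d, dtype=float)  # in units of d = 1
    d1 = 2.0 * r / (1.0 + r)
    d2 = 2.0 / (1.0 + r)
    apparent_over_true = (
        np.sqrt(1.0 + e * e) / 2.0 * (1.0 / np.sqrt(d1 * d1 + e * e) + 1.0 / np.sqrt(d2 * d2 + e * e))
    )
    err = apparent_over_true - 1.0
    coef = np.polyfit(e * e, err, 2)
    return float(coef[-1])
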