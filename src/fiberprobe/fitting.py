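"""Staged inference of active-SLS parameters from a pull-and-hold trace.

The pipeline mirrors how the probing experiment is analyzed:

a. **Pre-tension** T0: y-intercept of a straight line through the loading-phase
   tension-deformation curve T(delta). The line's slope is kept as a
   diagnostic; it is the stiffness a purely elastic reading would assign, and
   therefore an upper bound for k1.
b. **Relaxation time** tau: after the stage halts at t*, the additional
   transverse displacement e' = e - e* follows e_inf*(1 - exp(-t'/tau)).
c. **Viscosity from k2**: the hold-phase dynamics are linearized about the
   relaxed plateau (angle frozen at theta*, tension at its balance value T*),
   giving a single exponential with

       1/tau = (k2/eta) * (k_clv + 2 sin^2(th*) k1 + G)
                        / (k_clv + 2 sin^2(th*) (k1 + k2) + G)

   where G = 2 T* cos^3(th*)/d is the geometric stiffness of the taut fiber.
   eta is therefore determined by (k1, k2, tau) and need not be searched.
d. **Grid search** over (k1, k2): a coarse pass (2 nN/um) then a fine pass
   (0.1 nN/um) around the coarse optimum; each candidate is forward-simulated
   and scored with a normalized RMSE on e(t). Since F_clv = k_clv*(delta_s-e),
   the force residual carries no extra information and is only reported as a
   diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .mechanics import (
    E_MIN_DEFAULT,
    CantileverProbe,
    FiberGeometry,
    MechanicalParams,
    SimTrace,
    SolverConfig,
    StageProtocol,
    forward_simulate,
    projection_sine,
    simulate_ensemble,
    tension_from_force,
    transverse_to_elongation,
)

__all__ = [
    "ExperimentTrace",
    "TensionCurve",
    "RelaxationFit",
    "PretensionEstimate",
    "HaltInfo",
    "FitConfig",
    "GridDiagnostics",
    "FitResult",
    "ConditionRatios",
    "HaltNotFoundError",
    "InsufficientDataError",
    "derive_kinematics",
    "detect_halt",
    "tension_deformation_curve",
    "extract_pretension",
    "fit_relaxation",
    "eta_from_k2",
    "aggregated_error",
    "grid_search",
    "fit_experiment",
    "compare_conditions",
]


class HaltNotFoundError(RuntimeError):
    """No sustained zero-speed phase found; supply t_star manually."""


class InsufficientDataError(RuntimeError):
    """Too few usable samples for the requested estimate."""


# ---------------------------------------------------------------------------
# trace container
# ---------------------------------------------------------------------------


@dataclass
class ExperimentTrace:
    """One pull: measured stage and cantilever displacement vs time.

    ``e`` and ``F_clv`` are derived once on construction (e = delta_s -
    delta_clv, F = k_clv * delta_clv) and cached. ``provenance`` may carry a
    ground-truth parameter dict for synthetic traces.
    """

    t: np.ndarray
    delta_s: np.ndarray
    delta_clv: np.ndarray
    d: float
    k_clv: float
    condition: str = ""
    provenance: dict = field(default_factory=dict)
    e: np.ndarray = field(init=False, repr=False)
    F_clv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.delta_s = np.asarray(self.delta_s, dtype=float)
        self.delta_clv = np.asarray(self.delta_clv, dtype=float)
        if not (self.t.shape == self.delta_s.shape == self.delta_clv.shape):
            raise ValueError("t, delta_s and delta_clv must have equal length")
        if self.t.size < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if 1.0 / np.median(dt) < 10.0 - 1e-9:
            raise ValueError("sample rate below 10 Hz is insufficient at 5 um/s")
        FiberGeometry(self.d)  # validate (may warn)
        CantileverProbe(self.k_clv)
        self.e = self.delta_s - self.delta_clv
        self.F_clv = self.k_clv * self.delta_clv

    @property
    def geometry(self) -> FiberGeometry:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return FiberGeometry(self.d)

    @property
    def probe(self) -> CantileverProbe:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return CantileverProbe(self.k_clv)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @classmethod
    def from_sim(cls, sim: SimTrace, condition: str = "", provenance: dict | None = None):
        """Project a noise-free simulation onto the measured channels."""
        return cls(
            t=sim.t.copy(),
            delta_s=sim.delta_s.copy(),
            delta_clv=sim.delta_clv.copy(),
            d=sim.geometry.d,
            k_clv=sim.probe.k_clv,
            condition=condition,
            provenance=provenance or {},
        )


def derive_kinematics(trace: ExperimentTrace):
    """Return (e(t), F_clv(t)) = (delta_s - delta_clv, k_clv * delta_clv)."""
    return trace.e.copy(), trace.F_clv.copy()


# ---------------------------------------------------------------------------
# halt detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaltInfo:
    t_star: float
    e_star: float
    delta_s_star: float
    index: int
    v0_est: float


def detect_halt(trace: ExperimentTrace, v0_nominal: float | None = None) -> HaltInfo:
    """Locate the instant the stage stops (end of the loading ramp).

    Speed is estimated with a 0.2 s-baseline finite difference of the stage
    channel (robust to sub-pixel tracking noise); the halt is the first
    sample where speed stays below 10% of the ramp speed for at least three
    consecutive samples. t* is then refined to sub-sample accuracy as the
    intersection of the fitted ramp line with the plateau level and snapped
    back to the sample grid.
    """
    t, ds = trace.t, trace.delta_s
    dt = 1.0 / trace.sample_rate
    k = max(1, int(round(0.2 / dt)))
    if t.size <= k + 3:
        raise InsufficientDataError("trace too short for halt detection")
    speed = (ds[k:] - ds[:-k]) / (t[k:] - t[:-k])  # speed over [i, i+k]
    v0_est = float(v0_nominal) if v0_nominal is not None else float(np.percentile(speed, 95))

    if v0_est <= 0.05:  # um/s: stage essentially never moves -> hold from t=0
        return HaltInfo(t_star=float(t[0]), e_star=float(trace.e[0]),
                        delta_s_star=float(np.median(ds)), index=0, v0_est=v0_est)

    below = speed < 0.1 * v0_est
    sustained = below[:-2] & below[1:-1] & below[2:]
    hits = np.flatnonzero(sustained)
    if hits.size == 0:
        raise HaltNotFoundError(
            "no sustained halt found in the stage channel; pass t_star "
            "explicitly (pure-ramp trace?)"
        )
    j = int(hits[0]) + k  # sample index where the trailing window is slow
    plateau = float(np.median(ds[j:]))
    resid = ds[j:] - plateau
    sigma = 1.4826 * float(np.median(np.abs(resid))) if resid.size else 0.0
    margin = max(0.02 * max(plateau - ds[0], dt * v0_est), 4.0 * sigma)
    ramp_mask = (np.arange(t.size) < j + k) & (ds < plateau - margin)
    if ramp_mask.sum() < 2:
        t_star = t[j]
    else:
        slope, intercept = np.polyfit(t[ramp_mask], ds[ramp_mask], 1)
        t_star = (plateau - intercept) / slope
    idx = int(np.clip(np.argmin(np.abs(t - t_star)), 0, t.size - 1))
    return HaltInfo(
        t_star=float(t[idx]),
        e_star=float(trace.e[idx]),
        delta_s_star=plateau,
        index=idx,
        v0_est=v0_est,
    )


# ---------------------------------------------------------------------------
# tension-deformation curve and pre-tension
# ---------------------------------------------------------------------------


@dataclass
class TensionCurve:
    """Loading-phase (delta, T) samples with the retention mask used."""

    delta: np.ndarray
    T: np.ndarray
    retained: np.ndarray  # boolean mask over the source trace


def tension_deformation_curve(
    trace: ExperimentTrace,
    e_min: float = E_MIN_DEFAULT,
    halt: HaltInfo | None = None,
) -> TensionCurve:
    """Per-sample (delta, T) over the loading phase, excluding e < e_min.

    Near e = 0 the tension formula is a 0/0 and would amplify noise, hence
    the guard; the retained mask records exactly which samples entered the
    curve.
    """
    halt = halt or detect_halt(trace)
    geom = trace.geometry
    mask = (trace.t <= halt.t_star + 1e-12) & (trace.e >= e_min)
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} loading samples with e >= {e_min} um; "
            "need at least 5 for a tension curve"
        )
    e = trace.e[mask]
    delta = transverse_to_elongation(geom, e)
    T = tension_from_force(trace.F_clv[mask], geom, e, e_min=e_min)
    return TensionCurve(delta=np.asarray(delta), T=np.asarray(T), retained=mask)


@dataclass(frozen=True)
class PretensionEstimate:
    T0_hat: float
    slope: float  # elastic-reading stiffness; upper bound proxy for k1
    n: int
    negative_intercept: bool = False


def extract_pretension(curve: TensionCurve) -> PretensionEstimate:
    """Pre-tension as the y-intercept of the OLS line through T(delta).

    With a viscous branch active during loading the curve lies above the
    elastic line, so the estimate inherits a bias; the grid search uses it
    as-is (step a of the pipeline). A negative intercept is returned but
    flagged: it indicates an unusable trace.
    """
    if curve.delta.size < 5 or np.ptp(curve.delta) < 1.0:
        raise InsufficientDataError(
            "pre-tension needs >= 5 points spanning >= 1 um of elongation"
        )
    slope, intercept = np.polyfit(curve.delta, curve.T, 1)
    negative = intercept < 0
    if negative:
        warnings.warn(
            f"negative pre-tension intercept ({intercept:.3g} nN): unphysical, "
            "trace likely unusable",
            stacklevel=2,
        )
    return PretensionEstimate(
        T0_hat=float(intercept), slope=float(slope), n=int(curve.delta.size),
        negative_intercept=bool(negative),
    )


# ---------------------------------------------------------------------------
# relaxation fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelaxationFit:
    tau: float
    e_inf: float
    r_squared: float
    t_star: float
    e_star: float
    degenerate: bool = False
    rejected: bool = False

    def __post_init__(self):
        if not self.degenerate and not self.tau > 0:
            raise ValueError("relaxation time tau must be positive")


def _saturating_exp(tp, e_inf, tau):
    return e_inf * (1.0 - np.exp(-tp / tau))


def fit_relaxation(
    trace: ExperimentTrace,
    halt: HaltInfo | None = None,
    r2_min: float = 0.9,
    min_samples: int = 10,
) -> RelaxationFit:
    """Fit e'(t') = e_inf*(1 - exp(-t'/tau)) to the hold phase.

    The window runs from one sample after t* to the end of the hold (no
    outlier rejection). Initial guesses come from the plateau level and a
    log-linearization; the fit is flagged ``rejected`` when R^2 < ``r2_min``
    and ``degenerate`` when there is no resolvable relaxation amplitude.
    """
    halt = halt or detect_halt(trace)
    sel = trace.t > halt.t_star + 1e-12
    tp = trace.t[sel] - halt.t_star
    ep = trace.e[sel] - halt.e_star
    if tp.size < min_samples:
        raise InsufficientDataError(
            f"hold phase has {tp.size} samples; need >= {min_samples}"
        )
    # noise floor from first differences; amplitude below it is unresolvable
    sigma = float(np.std(np.diff(ep))) / math.sqrt(2.0) if tp.size > 2 else 0.0
    tail = float(np.mean(ep[-max(3, tp.size // 10):]))
    if abs(tail) <= max(1e-9, 3.0 * sigma / math.sqrt(max(3, tp.size // 10))):
        return RelaxationFit(
            tau=math.nan, e_inf=0.0, r_squared=math.nan,
            t_star=halt.t_star, e_star=halt.e_star, degenerate=True,
        )
    e_inf0 = tail
    # log-linearized guess for tau from the early rise
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - ep / e_inf0
        ok = (frac > 0.05) & (frac < 0.95) & (tp > 0)
        tau0 = float(-1.0 / np.polyfit(tp[ok], np.log(frac[ok]), 1)[0]) if ok.sum() >= 2 else 1.0
    if not (tau0 > 0 and math.isfinite(tau0)):
        tau0 = 1.0
    try:
        popt, _ = curve_fit(
            _saturating_exp, tp, ep, p0=(e_inf0, tau0),
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"relaxation fit did not converge (guess e_inf={e_inf0:.3g}, "
            f"tau={tau0:.3g}): {exc}"
        ) from exc
    e_inf, tau = float(popt[0]), float(popt[1])
    ss_res = float(np.sum((ep - _saturating_exp(tp, e_inf, tau)) ** 2))
    ss_tot = float(np.sum((ep - ep.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return RelaxationFit(
        tau=tau, e_inf=e_inf, r_squared=r2,
        t_star=halt.t_star, e_star=halt.e_star,
        degenerate=False, rejected=bool(r2 < r2_min),
    )


# ---------------------------------------------------------------------------
# eta from (k1, k2, tau)
# ---------------------------------------------------------------------------


def eta_from_k2(k1, k2, tau, sin_theta_star, k_clv, T_star=None, d=None):
    """Viscosity implied by the observed relaxation time at frozen angle theta*.

    During the hold the additional elongation is small relative to e*, so the
    projection angle can be frozen and the coupled fiber-cantilever system
    linearized; the relaxation is then a single exponential with

        eta = tau * k2 * (k_clv + 2 sin^2 th* k1 + G)
                        / (k_clv + 2 sin^2 th* (k1 + k2) + G)

    where ``G = 2 T* s'(e*) = 2 T* (1 - sin^2 th*)^{3/2} / d`` is the
    geometric stiffness contributed by the tension itself (the restoring
    force a taut string exerts against transverse displacement). G is not
    negligible for soft cantilevers and is retained whenever the tension
    ``T_star`` and the half-length ``d`` at the linearization state are
    supplied; with ``T_star=None`` the bare two-spring expression is used.

    The linearization state should be the relaxed plateau (the fixed point of
    the hold dynamics): tension there follows from the measured balance,
    T* = k_clv*(delta_s^* - e) / (2 sin th).

    Limits: k_clv -> inf gives eta -> tau*k2 (the intrinsic Maxwell time);
    k2 -> 0 gives eta -> 0 (branch vanishes). Vectorized over any argument.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    s2 = np.asarray(sin_theta_star, dtype=float) ** 2
    if T_star is None:
        G = 0.0
    else:
        if d is None:
            raise ValueError("d is required when T_star is given")
        G = 2.0 * np.asarray(T_star, dtype=float) * (1.0 - s2) ** 1.5 / d
    num = k_clv + 2.0 * s2 * k1 + G
    den = k_clv + 2.0 * s2 * (k1 + k2) + G
    out = np.asarray(tau, dtype=float) * k2 * num / den
    return out if out.ndim else float(out)


def relaxation_linearization_state(trace: ExperimentTrace, relaxation: "RelaxationFit",
                                   halt: "HaltInfo"):
    """(sin th*, T*) at the relaxed plateau e* + e_inf, from the force balance."""
    e_plateau = max(halt.e_star + max(relaxation.e_inf, 0.0), 1e-9)
    s = projection_sine(trace.geometry, e_plateau)
    T_star = trace.k_clv * (halt.delta_s_star - e_plateau) / (2.0 * s)
    return s, float(T_star)


# ---------------------------------------------------------------------------
# model-data misfit
# ---------------------------------------------------------------------------


def aggregated_error(e_sim, e_exp, t_sim=None, t_exp=None):
    """Normalized RMSE of the transverse displacement.

    err = sqrt( mean( ((e_exp - e_sim)/max|e_exp|)^2 ) ). When time grids are
    supplied they must match exactly (the simulator is evaluated on the
    experimental grid). The force residual is proportional to the e residual
    for a shared stage trace and is not double-counted.
    """
    e_sim = np.asarray(e_sim, dtype=float)
    e_exp = np.asarray(e_exp, dtype=float)
    if t_sim is not None and t_exp is not None:
        t_sim, t_exp = np.asarray(t_sim), np.asarray(t_exp)
        if t_sim.shape != t_exp.shape or not np.allclose(t_sim, t_exp, atol=1e-9):
            raise ValueError("simulation and experiment time grids differ")
    if e_sim.shape[-1] != e_exp.shape[-1]:
        raise ValueError("e_sim and e_exp length mismatch")
    scale = float(np.max(np.abs(e_exp)))
    if scale == 0.0:
        scale = 1.0
    resid = (e_exp - e_sim) / scale
    out = np.sqrt(np.mean(resid * resid, axis=-1))
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the staged fit; every default is overridable.

    coarse_step / fine_step: grid resolutions in nN/um (coarse pass over the
    whole admissible box, fine pass in a +/- fine_halfwidth neighborhood of
    the coarse optimum). ``k1_max`` of None means "use the elastic-reading
    slope of the tension curve" (all loading resistance assigned to k1).
    """

    coarse_step: float = 2.0
    fine_step: float = 0.1
    fine_halfwidth: float = 2.0
    k1_min: float = 0.0
    k1_max: float | None = None
    k2_min: float = 0.1
    k2_max: float = 40.0
    e_min: float = E_MIN_DEFAULT
    r2_min: float = 0.9
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if self.fine_step > self.coarse_step:
            raise ValueError("fine_step must be <= coarse_step")
        if self.k2_max <= self.k2_min or (
            self.k1_max is not None and self.k1_max <= self.k1_min
        ):
            raise ValueError("empty parameter bounds")


@dataclass(frozen=True)
class GridDiagnostics:
    n_evaluated: int
    error_opt: float
    runner_up_gap: float
    on_boundary: bool
    tied: bool
    coarse_opt: tuple


@dataclass
class FitResult:
    params: MechanicalParams
    relaxation: RelaxationFit
    pretension: PretensionEstimate
    halt: HaltInfo
    error: float
    grid: GridDiagnostics
    config: FitConfig


def _grid_axis(lo, hi, step):
    n = int(math.floor((hi - lo) / step + 1e-9))
    vals = lo + step * np.arange(n + 1)
    if vals[-1] < hi - 1e-9:
        vals = np.append(vals, hi)
    return vals


def _evaluate_grid(k1g, k2g, t0, relaxation, trace, protocol, sin_star, T_star, config):
    eta = eta_from_k2(k1g, k2g, relaxation.tau, sin_star, trace.k_clv,
                      T_star=T_star, d=trace.d)
    e_sim, _ = simulate_ensemble(
        trace.geometry,
        trace.probe,
        np.full_like(k1g, t0),
        k1g,
        k2g,
        eta,
        protocol,
        t_eval=trace.t,
        solver=config.solver,
    )
    errs = aggregated_error(e_sim, trace.e[None, :])
    return np.atleast_1d(errs), eta


def _argmin_lexical(errs, k1g, k2g):
    order = np.lexsort((k2g, k1g, errs))
    best = order[0]
    tied = bool(np.sum(errs == errs[best]) > 1)
    distinct = errs[errs > errs[best]]
    gap = float(distinct.min() - errs[best]) if distinct.size else math.inf
    return best, tied, gap


def grid_search(
    trace: ExperimentTrace,
    t0_hat: float,
    relaxation: RelaxationFit,
    config: FitConfig | None = None,
    halt: HaltInfo | None = None,
    k1_upper: float | None = None,
) -> FitResult:
    """Two-pass (k1, k2) search; eta is slaved to each candidate through tau.

    The stage input for candidate simulations is the idealized ramp-and-hold
    reconstructed from the detected halt (nominal speed delta_s*/t*), and the
    misfit is the normalized e-RMSE over the full trace. Ties are broken
    toward the smallest (k1, k2) and flagged, as is an optimum landing on the
    search boundary.
    """
    config = config or FitConfig()
    halt = halt or detect_halt(trace)
    if relaxation.degenerate:
        raise InsufficientDataError(
            "relaxation is degenerate (no resolvable amplitude): the Maxwell "
            "branch is unidentifiable; fit an elastic model instead"
        )
    t0 = max(float(t0_hat), 0.0)
    sin_star, T_star = relaxation_linearization_state(trace, relaxation, halt)
    protocol = StageProtocol(
        v0=halt.delta_s_star / halt.t_star,
        delta_s_star=halt.delta_s_star,
        t_hold=max(float(trace.t[-1] - halt.t_star), 0.0),
        sample_rate=trace.sample_rate,
    )

    k1_hi = config.k1_max if config.k1_max is not None else k1_upper
    if k1_hi is None:
        raise ValueError("k1 upper bound required (elastic-reading slope)")
    k1_hi = max(float(k1_hi), config.k1_min + config.fine_step)

    k1_coarse = _grid_axis(config.k1_min, k1_hi, config.coarse_step)
    k2_coarse = _grid_axis(config.k2_min, config.k2_max, config.coarse_step)
    K1c, K2c = (a.ravel() for a in np.meshgrid(k1_coarse, k2_coarse, indexing="ij"))
    errs_c, _ = _evaluate_grid(K1c, K2c, t0, relaxation, trace, protocol, sin_star, T_star, config)
    ic, _, _ = _argmin_lexical(errs_c, K1c, K2c)

    # fine pass around the coarse optimum; if the optimum lands on a fine-window
    # edge that is not a global bound, recenter and repeat (the coarse surface
    # can be flat enough to mislocate the valley by more than the window width)
    c1, c2 = float(K1c[ic]), float(K2c[ic])
    n_eval = int(errs_c.size)
    for _ in range(12):
        k1_lo = max(config.k1_min, c1 - config.fine_halfwidth)
        k1_up = min(k1_hi, c1 + config.fine_halfwidth)
        k2_lo = max(config.k2_min, c2 - config.fine_halfwidth)
        k2_up = min(config.k2_max, c2 + config.fine_halfwidth)
        k1_fine = _grid_axis(k1_lo, k1_up, config.fine_step)
        k2_fine = _grid_axis(k2_lo, k2_up, config.fine_step)
        K1f, K2f = (a.ravel() for a in np.meshgrid(k1_fine, k2_fine, indexing="ij"))
        errs_f, etas_f = _evaluate_grid(
            K1f, K2f, t0, relaxation, trace, protocol, sin_star, T_star, config
        )
        n_eval += int(errs_f.size)
        i_best, tied, gap = _argmin_lexical(errs_f, K1f, K2f)
        b1, b2 = float(K1f[i_best]), float(K2f[i_best])
        on_window_edge = (
            (np.isclose(b1, k1_lo) and k1_lo > config.k1_min + 1e-12)
            or (np.isclose(b1, k1_up) and k1_up < k1_hi - 1e-12)
            or (np.isclose(b2, k2_lo) and k2_lo > config.k2_min + 1e-12)
            or (np.isclose(b2, k2_up) and k2_up < config.k2_max - 1e-12)
        )
        if not on_window_edge:
            break
        c1, c2 = b1, b2

    k1_best, k2_best = float(K1f[i_best]), float(K2f[i_best])
    on_boundary = bool(
        np.isclose(k1_best, config.k1_min)
        or np.isclose(k1_best, k1_hi)
        or np.isclose(k2_best, config.k2_min)
        or np.isclose(k2_best, config.k2_max)
    )
    if on_boundary:
        warnings.warn(
            f"grid-search optimum (k1={k1_best}, k2={k2_best}) lies on the "
            "search boundary",
            stacklevel=2,
        )
    if tied:
        warnings.warn("tied grid-search optima; smallest (k1, k2) chosen", stacklevel=2)

    params = MechanicalParams(
        T0=t0, k1=k1_best, k2=k2_best, eta=float(np.atleast_1d(etas_f)[i_best])
    )
    diag = GridDiagnostics(
        n_evaluated=n_eval,
        error_opt=float(errs_f[i_best]),
        runner_up_gap=gap,
        on_boundary=on_boundary,
        tied=tied,
        coarse_opt=(float(K1c[ic]), float(K2c[ic])),
    )
    return FitResult(
        params=params,
        relaxation=relaxation,
        pretension=PretensionEstimate(T0_hat=t0_hat, slope=k1_hi, n=0),
        halt=halt,
        error=diag.error_opt,
        grid=diag,
        config=config,
    )


def fit_experiment(trace: ExperimentTrace, config: FitConfig | None = None) -> FitResult:
    """Run the full staged pipeline on one trace (steps a-d composed)."""
    config = config or FitConfig()
    halt = detect_halt(trace)
    curve = tension_deformation_curve(trace, e_min=config.e_min, halt=halt)
    pre = extract_pretension(curve)
    relax = fit_relaxation(trace, halt=halt, r2_min=config.r2_min)
    result = grid_search(
        trace, pre.T0_hat, relax, config=config, halt=halt, k1_upper=pre.slope
    )
    result.pretension = pre
    return result


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionRatios:
    """Elementwise after/before parameter ratios (e.g. drug/control)."""

    T0: float
    k1: float
    k2: float
    eta: float
    undefined: tuple = ()


def compare_conditions(
    fit_before: FitResult, fit_after: FitResult, eps: float = 1e-9
) -> ConditionRatios:
    """Per-parameter ratios after/before; near-zero denominators are flagged NaN."""
    ratios = {}
    undefined = []
    for name in ("T0", "k1", "k2", "eta"):
        b = getattr(fit_before.params, name)
        a = getattr(fit_after.params, name)
        if abs(b) < eps:
            ratios[name] = math.nan
            undefined.append(name)
        else:
            ratios[name] = a / b
    return ConditionRatios(**ratios, undefined=tuple(undefined))
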