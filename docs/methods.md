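# Methods

## System and model

A peripheral stress fiber of rest half-length `d` (um) spans two anchor
points; a calibrated soft cantilever (spring constant `k_clv`, nN/um)
contacts it at the midpoint and the motorized stage imposes a displacement
`delta_s(t)` perpendicular to the fiber axis. The measured channels are the
stage position and the cantilever deflection `delta_clv`; the fiber's
transverse midpoint displacement is `e = delta_s - delta_clv` and the probe
force is `F_clv = k_clv * delta_clv`. Each half-segment stretches to
`sqrt(d^2 + e^2)`, i.e. elongates by `delta = sqrt(d^2+e^2) - d` (strain
`delta/d`), and makes an angle `theta` with the original axis with
`sin(theta) = e / sqrt(d^2+e^2)`.

Inertia is negligible at these speeds and sizes, so the probe force is
balanced at every instant by the transverse projection of the fiber tension
carried by the two segments:

    k_clv (delta_s - e) = 2 T sin(theta).                      (force balance)

The fiber is modeled as an *active standard linear solid*: three parallel
elements sharing the elongation `delta` of a half-segment,

    T = T0 + k1 delta + T_m,
    dT_m/dt = k2 d(delta)/dt - (k2/eta) T_m,

where `T0` (nN) is the motor pre-tension (tension at zero elongation), `k1`
(nN/um) a parallel spring, and the Maxwell branch — spring `k2` (nN/um) in
series with a dashpot `eta` (nN·s/um) — carries the history-dependent
tension `T_m` with intrinsic relaxation time `eta/k2`. A plain Kelvin–Voigt
element cannot produce the observed combination of small relaxation
amplitude and seconds-long timescale, because it ties the two together; the
series spring decouples them. `k2 = 0` is accepted as an explicit
pure-elastic mode (`T_m ≡ 0`).

Units are fixed package-wide (um, s, nN, nN/um, nN·s/um); nothing is
inferred from magnitudes.

## Forward simulation

The force balance is an index-1 algebraic constraint linking `e` to the
dynamic state `T_m`. Differentiating it in time and substituting
`d(delta)/dt = sin(theta) de/dt` gives an explicit two-state ODE:

    de/dt   = [k_clv v(t) + 2 s (k2/eta) T_m] / [k_clv + 2 (k1+k2) s^2 + 2 T s'],
    dT_m/dt = k2 s de/dt - (k2/eta) T_m,

with `s = sin(theta)`, `s'(e) = d^2/(d^2+e^2)^{3/2}`, and `v(t)` the stage
speed. The denominator is the total transverse stiffness seen by the probe —
cantilever, elastic branches projected through `s^2`, and the *geometric
stiffness* `2 T s'` with which any taut string resists transverse deflection
— and is strictly positive, so the system is never singular, including at
`e = 0`.

The stage trajectory is a deliberately un-smoothed ramp-and-hold
(`v0 = 5 um/s` to `delta_s* = 20 um`, then still); the integrator (RK45,
rtol 1e-8, atol 1e-10) restarts at the corner. After integration each output
sample is projected back onto the algebraic balance by a few Newton
iterations, which pins the force-balance residual to round-off (observed
~1e-14 nN) without perturbing the dynamics. Correctness is established
against an independent fixed-step oracle (dt = 1e-4 s) that re-solves the
balance by bisection at every step and steps `T_m` explicitly: maximum
|Delta e| = 6e-5 um over the reference protocol. The simulator runs without
failure to at least 82% strain (the fiber nearly doubling its length).

For the fitting grid, all candidate parameter sets are stacked into one
vectorized ODE system and integrated together ("ensemble" integration); this
is numerically identical to the scalar path (asserted in the tests) and is
purely a performance device — a full two-pass grid search costs a few
seconds.

## Staged inference

Mirroring how the probing experiment is analyzed, the pipeline is
sequential; every stage's output is recorded in the fit result.

1. **Halt detection.** Stage speed is estimated with a 0.2 s-baseline finite
   difference (robust to sub-pixel tracking noise); the halt is the first
   sample where speed stays below 10% of the ramp speed for three
   consecutive samples, then `t*` is refined to sub-sample accuracy by
   intersecting the fitted ramp line with the plateau level and snapped to
   the grid. A stationary stage yields the degenerate `t* = 0`; a trace with
   no halt is an error (the user must supply `t*`).
2. **Pre-tension.** Loading-phase samples with `e >= e_min = 1 um` (below
   which `T = F/(2 sin theta)` is a 0/0 that amplifies noise) are converted
   to a tension–elongation curve `T(delta)`; `T0_hat` is the intercept of an
   ordinary least-squares line through all retained points. The slope is
   kept as the stiffness a purely elastic reading would assign — an upper
   bound for `k1` and the cap of the search grid.
3. **Relaxation.** After `t*`, the additional displacement
   `e' = e - e*` is fitted with `e_inf (1 - exp(-t'/tau))`, initialized from
   the plateau level and a log-linearization, with `R^2` reported and fits
   below 0.9 flagged. A hold with no resolvable amplitude (relative to the
   first-difference noise floor) is flagged degenerate — the Maxwell branch
   is then unidentifiable and the grid search refuses to run.
4. **Viscosity from k2.** Linearizing the hold-phase dynamics about the
   relaxed plateau (angle frozen at `theta*`, tension at its balance value
   `T*`) gives a single exponential with

       1/tau = (k2/eta) (k_clv + 2 s^2 k1 + G) / (k_clv + 2 s^2 (k1+k2) + G),
       G = 2 T* cos^3(theta*) / d,

   so `eta` is determined by `(k1, k2, tau)` and never searched. The
   geometric-stiffness term `G` is first-order for soft cantilevers —
   dropping it, or linearizing at the halt point instead of the plateau,
   degrades the timescale agreement with the full nonlinear simulation from
   ~1.6% to ~6% at the reference conditions — so it is retained, and the
   linearization state is the fixed point of the hold dynamics, whose
   tension follows from the measured balance rather than from unknown
   parameters. The relation is verified against a numerical oracle
   (small-amplitude hold simulations timed by an independent exponential
   fit) to within 2% across `k2/k1` in {0.5, 3, 10}, `sin(theta*)` in
   {0.2, 0.5}, `k_clv` in {1.53, 6.25} nN/um.
5. **Grid search.** `(k1, k2)` are searched on a coarse 2 nN/um grid over
   `[0, slope] x (0.1, 40]`, then on a 0.1 nN/um grid in a ±2 nN/um window
   around the coarse optimum; the fine pass recenters and repeats (bounded
   repeats) whenever its optimum lands on a window edge that is not a global
   bound, because the coarse surface of this problem is shallow enough to
   mislocate the valley by more than one window. Each candidate is
   forward-simulated on the idealized ramp-and-hold reconstructed from the
   detected halt and scored with

       err = sqrt( mean( ((e_exp - e_sim)/max|e_exp|)^2 ) ).

   Because `F_clv = k_clv (delta_s - e)` for a shared stage trace, the force
   residual is proportional to the displacement residual and is deliberately
   not double-counted. Exact ties break toward the smallest `(k1, k2)` and
   are flagged, as are optima on the search boundary.

Condition comparisons (e.g. drug vs control on the same fiber) are
elementwise after/before parameter ratios, with near-zero denominators
flagged rather than divided.

## Known estimator bias (and why it is reported, not hidden)

On a noise-free reference fiber (T0 = 7.44 nN, k1 = 3.23, k2 = 10.94 nN/um,
eta = 7.85 nN·s/um — the control-population means — with d = 28.4 um,
k_clv = 3 nN/um, standard protocol) the intercept estimator overshoots:
`T0_hat = 8.89 nN (+19.5%)`. The cause is structural: early in the ramp the
elongation grows quadratically in time while the elongation *rate* grows
linearly, so the Maxwell tension rises roughly like `sqrt(delta)` — a
concave additive contribution that any straight line through `T(delta)`
converts into an inflated intercept. The bias direction is always upward
(asserted over a k2 × eta sweep). Because the grid search holds `T0` fixed
at the intercept, the bias propagates: on the same trace the pipeline
returns k1 low by ~0.4 nN/um and k2 low by ~1.1 nN/um, whereas an otherwise
identical search started from the true pre-tension recovers k1 within 0.03
and k2 within 0.6 nN/um and eta within 1%. The staged design (estimate T0
first, then fit springs) is the method being implemented, so the package
reports this bias in its analysis outputs instead of compensating for it;
ratio readouts (drug/control) partially cancel it for high-tension fibers
but inflate it for low-tension ones.

## Synthetic data

The generator emulates the study conditions: fiber parameters drawn
independently per parameter from truncated normals with the reported control
means ± s.d. (floors T0 ≥ 0.5 nN, k1 ≥ 0.2, k2 ≥ 0.5 nN/um, eta ≥ 0.5
nN·s/um keep draws physical; the half-length is truncated to the observed
22–35 um and the cantilever picked from {1.53, 3.0, 6.25} nN/um spanning the
experimental stiffness range); the standard ramp-and-hold protocol sampled
at 50 Hz; and additive i.i.d. Gaussian noise on the two *measured
displacement* channels (sigma_stage = 0.02 um, sigma_clv = 0.05 um) — image
registration measures displacements, force is derived, so force noise is
inherited, not injected. The true noise magnitude of the tracking method is
not reported; these sub-pixel defaults are stated choices and remain
configurable. Repeated pulls of one fiber share its parameters (replicate
pulls, up to 5); the paired drug scenario multiplies the drawn T0 by 0.58
(the reported mean treated/control pre-tension ratio) and leaves the passive
elements untouched. Cohorts are pure functions of a master seed via spawned
RNG streams.

What synthetic traces do *not* emulate: parameter covariances (none are
reported, so draws are independent — truncation also shifts realized means
above the location parameters, most visibly for k2), pull-to-pull
remodeling, heterogeneity along the fiber, tracking-noise autocorrelation,
or any image-formation effects. Passing recovery tests therefore demonstrate
the inference chain under the model's own assumptions, not robustness to
real-microscopy artifacts.

## Problem sizes and numerical choices

Default analyses use one pull per fiber, 14 s traces at 50 Hz (701 samples),
cohorts of 3–8 fibers, and grid searches of a few thousand candidate pairs;
these sizes make every script and the full test suite a desk-scale run while
keeping the fine grid at the stated 0.1 nN/um resolution. Solver tolerances
(rtol 1e-8 / atol 1e-10), the Newton projection, the e_min = 1 um guard, the
relaxation window (one sample after `t*` to the end, no outlier rejection),
tie-breaking and boundary flags are all fixed defaults of `SolverConfig` /
`FitConfig` and overridable per run; every output embeds the config hash,
seed and package version.

## Limitations

- The probe is assumed at the midpoint; the off-center analysis
  (`asymmetric_tension_error`, closed form `(r-1)^2/(4r)`) quantifies the
  small-displacement reading error but placement asymmetry is not otherwise
  modeled.
- No bending stiffness, membrane tension, distributed load, inertia, or
  force-induced remodeling; compression probing is represented by the same
  equations with a direction flag only.
- `eta` is identifiable only through the relaxation: fibers whose drawn
  `k2` or viscous buildup is small relative to noise produce flagged
  degenerate or wildly uncertain `eta` estimates (visible as heavy tails in
  the cohort recovery study).
- No posterior uncertainty or bootstrap intervals; the grid diagnostics
  (runner-up gap, boundary/tie flags) are the only sensitivity readouts.
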