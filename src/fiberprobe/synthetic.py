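"""Synthetic probing experiments with the statistical structure of the study.

Generates cohorts of pull-and-hold traces: fiber parameters drawn from the
reported control population (truncated normals), the standard ramp protocol
(5 um/s over 20 um, then hold, 50 Hz), and additive Gaussian tracking noise
on the two measured displacement channels. Ground truth is carried in each
trace's provenance so recovery can be scored. Everything is a pure function
of its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import ExperimentTrace
from .mechanics import (
    CantileverProbe,
    FiberGeometry,
    MechanicalParams,
    StageProtocol,
    forward_simulate,
)

__all__ = [
    "NoiseModel",
    "PopulationSpec",
    "ScenarioSpec",
    "FiberSample",
    "Cohort",
    "sample_parameters",
    "generate_trace",
    "generate_cohort",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the measured displacement channels.

    Image-registration tracking errors act on displacements, not forces, so
    noise is applied to delta_s and delta_clv; force inherits it through
    k_clv. Defaults are sub-pixel-scale guesses (the real magnitude is not
    reported) and stay configurable.
    """

    sigma_stage: float = 0.02  # um
    sigma_clv: float = 0.05  # um

    def __post_init__(self):
        if self.sigma_stage < 0 or self.sigma_clv < 0:
            raise ValueError("noise sigmas must be >= 0")


#: truncation floors keeping draws physical (stated units)
_PARAM_FLOORS = {"T0": 0.5, "k1": 0.2, "k2": 0.5, "eta": 0.5}


@dataclass(frozen=True)
class PopulationSpec:
    """Control-population statistics: per-parameter mean +/- s.d.

    Parameter draws are independent truncated normals (no covariance is
    reported, a documented limitation). The half-length d is truncated to the
    observed 22-35 um range; the cantilever is picked uniformly from a small
    set spanning the experimental stiffness range.
    """

    T0_mean: float = 7.44
    T0_sd: float = 5.69
    k1_mean: float = 3.23
    k1_sd: float = 2.74
    k2_mean: float = 10.94
    k2_sd: float = 10.75
    eta_mean: float = 7.85
    eta_sd: float = 6.74
    d_mean: float = 28.4
    d_sd: float = 3.6
    d_bounds: tuple = (22.0, 35.0)
    k_clv_choices: tuple = (1.53, 3.0, 6.25)

    def __post_init__(self):
        for name in ("T0", "k1", "k2", "eta", "d"):
            if getattr(self, f"{name}_sd") < 0:
                raise ValueError(f"{name}_sd must be >= 0")
        if not all(k > 0 for k in self.k_clv_choices):
            raise ValueError("cantilever spring constants must be positive")


@dataclass(frozen=True)
class FiberSample:
    params: MechanicalParams
    geometry: FiberGeometry
    probe: CantileverProbe


def _truncnorm_draw(rng, mean, sd, lo, hi=math.inf):
    if sd == 0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_parameters(
    pop: PopulationSpec, seed: int | np.random.Generator
) -> FiberSample:
    """Draw one fiber (mechanics + geometry + probe) from the population."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = {
        name: _truncnorm_draw(
            rng, getattr(pop, f"{name}_mean"), getattr(pop, f"{name}_sd"),
            _PARAM_FLOORS[name],
        )
        for name in ("T0", "k1", "k2", "eta")
    }
    d = _truncnorm_draw(rng, pop.d_mean, pop.d_sd, pop.d_bounds[0], pop.d_bounds[1])
    k_clv = float(rng.choice(np.asarray(pop.k_clv_choices, dtype=float)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return FiberSample(
            params=MechanicalParams(**vals),
            geometry=FiberGeometry(d),
            probe=CantileverProbe(k_clv),
        )


def generate_trace(
    geometry: FiberGeometry,
    probe: CantileverProbe,
    params: MechanicalParams,
    protocol: StageProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    condition: str = "CTRL",
) -> ExperimentTrace:
    """Simulate one pull and corrupt the measured channels with noise.

    The provenance block records the ground-truth parameters and the seed so
    recovery studies can score themselves.
    """
    protocol = protocol or StageProtocol()
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = forward_simulate(geometry, probe, params, protocol)
    n = sim.t.size
    delta_s = sim.delta_s + rng.normal(0.0, noise.sigma_stage, n) if noise.sigma_stage else sim.delta_s.copy()
    delta_clv = sim.delta_clv + rng.normal(0.0, noise.sigma_clv, n) if noise.sigma_clv else sim.delta_clv.copy()
    provenance = {
        "truth": {
            "T0": params.T0, "k1": params.k1, "k2": params.k2, "eta": params.eta,
            "d": geometry.d, "k_clv": probe.k_clv,
        },
        "noise": {"sigma_stage": noise.sigma_stage, "sigma_clv": noise.sigma_clv},
        "protocol": {
            "v0": protocol.v0, "delta_s_star": protocol.delta_s_star,
            "t_hold": protocol.t_hold, "sample_rate": protocol.sample_rate,
        },
        "seed": None if isinstance(seed, np.random.Generator) else int(seed),
        "synthetic": True,
    }
    return ExperimentTrace(
        t=sim.t.copy(),
        delta_s=delta_s,
        delta_clv=delta_clv,
        d=geometry.d,
        k_clv=probe.k_clv,
        condition=condition,
        provenance=provenance,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A whole synthetic study: cohort size, protocol, noise, optional drug arm.

    ``treatment`` maps parameter names to multiplicative factors applied to
    each fiber's drawn parameters; when present, every fiber is probed both
    before ("CTRL") and after ("TREATED") the perturbation, emulating the
    paired myosin-inhibition design (pre-tension roughly halved, default
    factor 0.58). Repeated pulls of one fiber share its parameters.
    """

    n_fibers: int
    pulls_per_fiber: int = 3
    protocol: StageProtocol = field(default_factory=StageProtocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    treatment: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if not 1 <= self.pulls_per_fiber <= 5:
            raise ValueError("pulls_per_fiber must be in [1, 5] (replicate pulls)")
        if self.treatment is not None:
            unknown = set(self.treatment) - {"T0", "k1", "k2", "eta"}
            if unknown:
                raise ValueError(f"unknown treatment parameters: {sorted(unknown)}")


#: default paired-arm factors: myosin (ROCK) inhibition mainly halves T0
Y27632_TREATMENT = {"T0": 0.58, "k1": 1.0, "k2": 1.0, "eta": 1.0}


@dataclass
class Cohort:
    traces: list
    truth: pd.DataFrame


def _apply_treatment(params: MechanicalParams, factors: dict) -> MechanicalParams:
    vals = {n: getattr(params, n) * factors.get(n, 1.0) for n in ("T0", "k1", "k2", "eta")}
    return MechanicalParams(**vals)


def generate_cohort(scenario: ScenarioSpec) -> Cohort:
    """Expand a scenario into traces plus a ground-truth table.

    Deterministic: per-fiber and per-pull RNG streams are spawned from the
    master seed, so the cohort is a pure function of the ScenarioSpec.
    """
    master = np.random.SeedSequence(scenario.seed)
    fiber_seeds = master.spawn(scenario.n_fibers)
    traces = []
    rows = []
    for i, fiber_ss in enumerate(fiber_seeds):
        draw_ss, noise_ss = fiber_ss.spawn(2)
        sample = sample_parameters(scenario.population, np.random.default_rng(draw_ss))
        arms = [("CTRL", sample.params)]
        if scenario.treatment is not None:
            arms.append(("TREATED", _apply_treatment(sample.params, scenario.treatment)))
        pull_streams = noise_ss.spawn(len(arms) * scenario.pulls_per_fiber)
        k = 0
        for condition, params in arms:
            for pull in range(scenario.pulls_per_fiber):
                rng = np.random.default_rng(pull_streams[k])
                k += 1
                trace = generate_trace(
                    sample.geometry, sample.probe, params,
                    protocol=scenario.protocol, noise=scenario.noise,
                    seed=rng, condition=condition,
                )
                trace.provenance["fiber_id"] = i
                trace.provenance["pull"] = pull
                trace.provenance["seed"] = None  # stream-spawned, not scalar
                traces.append(trace)
                rows.append(
                    {
                        "fiber_id": i, "pull": pull, "condition": condition,
                        "T0": params.T0, "k1": params.k1, "k2": params.k2,
                        "eta": params.eta, "d": sample.geometry.d,
                        "k_clv": sample.probe.k_clv,
                    }
                )
    columns = ["fiber_id", "pull", "condition", "T0", "k1", "k2", "eta", "d", "k_clv"]
    truth = pd.DataFrame(rows, columns=columns)
    return Cohort(traces=traces, truth=truth)
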