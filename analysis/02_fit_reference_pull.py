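"""Fit the staged pipeline to a noise-free reference pull and score recovery.

Runs the full inference chain (halt detection, tension-curve intercept,
relaxation fit, eta-slaved grid search) on the simulation from script 01 and
compares every recovered parameter with the generating truth. This is the
cleanest possible input, so any deviation measures the estimator itself, not
noise: the pre-tension intercept inherits the loading-phase viscous bias and
drags k1/k2 with it (quantified here), while a search started from the true
pre-tension recovers the spring constants to grid resolution.

Writes: results/reference_fit.json, results/reference_fit_comparison.csv.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

import fiberprobe as fp
import fiberprobe.fitting as F
from fiberprobe.io import save_fit_result

OUT = Path(__file__).resolve().parents[1] / "results"
TRUTH = {"T0": 7.44, "k1": 3.23, "k2": 10.94, "eta": 7.85}


def main():
    geometry = fp.FiberGeometry(28.4)
    probe = fp.CantileverProbe(3.0)
    params = fp.MechanicalParams(**TRUTH)
    sim = fp.forward_simulate(geometry, probe, params, fp.StageProtocol())
    trace = fp.ExperimentTrace.from_sim(sim)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fp.fit_experiment(trace)
        halt = result.halt
        rel = result.relaxation
        oracle_start = F.grid_search(
            trace, TRUTH["T0"], rel, halt=halt, k1_upper=result.pretension.slope
        )

    OUT.mkdir(exist_ok=True)
    save_fit_result(result, OUT / "reference_fit.json")

    rows = []
    for name in TRUTH:
        rows.append(
            {
                "param": name,
                "truth": TRUTH[name],
                "pipeline_estimate": getattr(result.params, name),
                "estimate_from_true_T0": getattr(oracle_start.params, name),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "reference_fit_comparison.csv", index=False)

    print("Noise-free staged fit vs truth (reference fiber):")
    print(df.round(3).to_string(index=False))
    print(
        f"\nIntercept pre-tension: {result.pretension.T0_hat:.2f} nN "
        f"(truth {TRUTH['T0']}, bias {result.pretension.T0_hat / TRUTH['T0'] - 1:+.1%}); "
        f"relaxation tau = {rel.tau:.2f} s (R^2 = {rel.r_squared:.4f})."
    )
    print(
        "Starting the grid search from the true pre-tension recovers "
        f"k1 = {oracle_start.params.k1:.2f}, k2 = {oracle_start.params.k2:.2f}, "
        f"eta = {oracle_start.params.eta:.2f}: the residual pipeline error is "
        "the intercept bias, not the search."
    )


if __name__ == "__main__":
    main()
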