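#!/usr/bin/env python
"""Forager exit decisions: three decision-rate schedules and the
separation of variables.

On a colony with the measured interaction-rate decline, decision points are
extracted under the constant, interaction-rate and unloading-rate schedules
and a 2-D logistic of exit on (crop, colony) is fit to each.  The relative
colony effect shrinks toward zero under the unloading-rate schedule —
foragers need only their own crop once decisions are paced by unloading.
A colony-dependent exit rule (negative control) does not shrink.  Writes
results/exit_model_comparison.csv and results/exit_crop_projection.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from antflow.exits import (extract_decision_points, fit_exit_logistic,
                           separation_of_variables_test)
from antflow.macro import compute_colony_state
from antflow.simulate import SimulationConfig, simulate_colony

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=103)
    ap.add_argument("--delta-crop", type=float, default=0.10)
    args = ap.parse_args()

    rows = []
    for label, extra in [("crop_only_rule", {}),
                         ("colony_rule_control", {"exit_colony_coef": -3.0})]:
        cfg = SimulationConfig(seed=args.seed, r1=0.017, **extra)
        sx = simulate_colony(cfg)
        state = compute_colony_state(
            sx.experiment, intake_target=sum(sx.targets.values()))
        rep = separation_of_variables_test(sx.experiment, args.delta_crop,
                                           state)
        t = rep["table"].reset_index()
        t.insert(0, "generator", label)
        rows.append(t)
        covers = rep["unloading_colony_covers_zero"]
        print(f"{label}: colony/crop ratio "
              + " -> ".join(f"{m}={r:.2f}" for m, r in
                            rep["table"]["colony_to_crop"].items())
              + ("; under the unloading-rate schedule the colony effect is "
                 "indistinguishable from zero" if covers else
                 "; the colony effect persists under every schedule"))
        if label == "crop_only_rule":
            pts = extract_decision_points(sx.experiment, "unloading_rate",
                                          args.delta_crop, state)
            g = fit_exit_logistic(pts, ("crop",))
            lo, hi = g.conf_int["crop"]
            pd.DataFrame([{"intercept": g.params["intercept"],
                           "crop_slope": g.params["crop"],
                           "ci_lo": lo, "ci_hi": hi,
                           "n": g.n, "n_exits": g.n_exits}]).to_csv(
                RESULTS / "exit_crop_projection.csv", index=False)
            print(f"  G(crop) 1-D projection: slope {g.params['crop']:.2f} "
                  f"(95% CI {lo:.2f}..{hi:.2f}); marginalizing out the "
                  "decision pacing attenuates it relative to the 2-D crop "
                  f"coefficient (generator rule {cfg.exit_crop_coef})")

    pd.concat(rows, ignore_index=True).to_csv(
        RESULTS / "exit_model_comparison.csv", index=False)


if __name__ == "__main__":
    main()
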