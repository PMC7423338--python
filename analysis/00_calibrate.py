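#!/usr/bin/env python
"""Calibration procedure behind the shipped default parameters.

Two quantitative anchors fix the otherwise free rate constants:

1. the bare BisDC feedback loop, started from binomially distributed BisDC
   (mean 8 molecules per cell), must yield a clearly bimodal output — a
   substantial exact-zero class coexisting with a well-separated positive
   mode — which pins the feedback-node rates (A1, A2, A3, A4) to the
   bistable regime;
2. the full TciR cascade under its default input must place the
   positive-state share inside the 3-5% transfer-competent cell range
   observed in stationary-phase populations, which pins the upstream
   binding strength (T1) once the other cascade rates are set.

This script re-runs both anchors over a T1 grid, plus the deviation-
multiplier (k) grid for the qq subpopulation estimator against samples with
known activated fractions, and writes the tables to the output directory.
The shipped defaults (DEFAULT_RATES, k = 2.0) are the values these tables
select; re-running with other seeds moves the numbers only within
Monte-Carlo noise.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from iceswitch import (
    InputSpec,
    build_full_cascade,
    classify_states,
    generate_cells,
    qq_subpopulation_estimate,
    run_ensemble,
)
from iceswitch.config import default_config
from iceswitch.network import DEFAULT_RATES


def feedback_anchor(seed: int, n_cells: int) -> dict:
    cfg = default_config("feedback", n_cells=n_cells, seed=seed)
    s = classify_states(cfg.run().endpoint("BisDC"))
    return {
        "zero_fraction": s.zero_fraction,
        "positive_median": s.positive_median,
        "separation_vs_bin_width": s.positive_median / s.bin_width,
    }


def cascade_anchor(seed: int, n_cells: int, t1_grid) -> pd.DataFrame:
    rows = []
    spec = InputSpec("TciR", "uniform", {"low": 0, "high": 16})
    for t1 in t1_grid:
        ens = run_ensemble(build_full_cascade({"T1": t1}), spec, n_cells, 100.0, seed)
        rows.append({
            "T1": t1,
            "positive_percent": 100.0 * (ens.endpoint("BisDC") > 0).mean(),
            "in_3_5_band": bool(3.0 <= 100.0 * (ens.endpoint("BisDC") > 0).mean() <= 5.0),
        })
    return pd.DataFrame(rows)


def estimator_anchor(seed: int, k_grid, reps: int = 50) -> pd.DataFrame:
    rows = []
    for k in k_grid:
        for f in (0.01, 0.05, 0.2):
            errs = [
                qq_subpopulation_estimate(
                    generate_cells(1000, f, rng=np.random.default_rng(seed + 997 * r + int(1e5 * f))),
                    k=k,
                ).estimated_fraction - f
                for r in range(reps)
            ]
            rows.append({"k": k, "true_fraction": f,
                         "median_abs_error": float(np.median(np.abs(errs))),
                         "mean_signed_error": float(np.mean(errs))})
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cells", type=int, default=10_000)
    ap.add_argument("--out", type=Path, default=Path("results/calibration"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fb = feedback_anchor(args.seed, args.n_cells)
    print("feedback-loop anchor (binomial mean-8 input):")
    print(f"  zero fraction {fb['zero_fraction']:.3f}, positive median "
          f"{fb['positive_median']:.0f} ({fb['separation_vs_bin_width']:.0f}x bin width)")

    t1_grid = [0.0004, 0.0006, 0.0008, 0.0010, 0.0012]
    casc = cascade_anchor(args.seed, args.n_cells, t1_grid)
    print("\ncascade anchor: positive-state percent vs TciR binding strength T1")
    print(casc.to_string(index=False))
    print(f"  shipped default T1 = {DEFAULT_RATES['T1']}")

    est = estimator_anchor(args.seed, k_grid=[1.5, 2.0, 2.5, 3.0])
    print("\nqq-estimator anchor: median |error| by deviation multiplier k")
    print(est.pivot(index="k", columns="true_fraction",
                    values="median_abs_error").to_string())
    print("  shipped default k = 2.0")

    casc.to_csv(args.out / "cascade_T1_grid.csv", index=False)
    est.to_csv(args.out / "estimator_k_grid.csv", index=False)
    (args.out / "feedback_anchor.json").write_text(json.dumps(fb, indent=2) + "\n")


if __name__ == "__main__":
    main()
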