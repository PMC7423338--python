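#!/usr/bin/env python
"""Bare autoregulatory feedback loop: bimodal single-cell output.

Simulates 10,000 cells of the BisDC self-activation loop starting from
binomially distributed BisDC (mean 8 molecules per cell).  The population
splits into an exact-zero class — cells whose BisDC stochastically decayed
before the loop engaged — and a positive class whose level is set by the
production/degradation balance, not by the input.  Writes the per-cell
ensemble, summary and histogram under the output directory.
"""

import argparse
import json
from pathlib import Path

from iceswitch.panels import feedback_bimodality


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cells", type=int, default=10_000)
    ap.add_argument("--out", type=Path, default=Path("results/feedback-bimodality"))
    args = ap.parse_args()

    res = feedback_bimodality(args.out, seed=args.seed, n_cells=args.n_cells)
    print(f"n = {res['n']} cells: zero-state fraction {res['zero_fraction']:.3f}; "
          f"positive-state median {res['positive_median']:.0f} "
          f"(IQR {res['positive_iqr']:.0f}) — a bimodal population with a "
          f"distinct exact-zero mode.")
    print(json.dumps(res, indent=2))


if __name__ == "__main__":
    main()
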