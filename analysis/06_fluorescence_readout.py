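#!/usr/bin/env python
"""From molecule counts to the microscope: synthetic fluorescence readout.

Bridges kickstart ensembles at three BisR doses to per-cell intensity
distributions (log-normal autofluorescence background plus a gain times the
BisDC endpoint count), then applies the quantile-quantile subpopulation
estimator.  The activated fraction scales with dose while the activated
subpopulation's intensity median stays put, and the qq estimate tracks the
true (label-known) activated fraction.
"""

import argparse
from pathlib import Path

import pandas as pd

from iceswitch.panels import fluorescence_readout


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cells", type=int, default=5_000)
    ap.add_argument("--out", type=Path, default=Path("results/fluorescence"))
    args = ap.parse_args()

    res = fluorescence_readout(args.out, seed=args.seed, n_cells=args.n_cells)
    print(pd.DataFrame(res["rows"]).to_string(index=False))
    print(f"\nactivated-subpopulation median moves only "
          f"{100 * res['active_median_spread']:.1f}% across a 4-fold dose range, "
          "while the activated fraction scales with dose.")


if __name__ == "__main__":
    main()
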