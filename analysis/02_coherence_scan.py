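#!/usr/bin/env python
"""Show that high dispersal makes the metacommunity coherent and well-mixed.

Fixes one heterogeneous 3x3 landscape (nine independent habitats, N = 50)
and integrates the spatial system at dispersal rates spanning three
decades.  As D grows, the cross-patch spread of each species' density and
the disagreement with the patch-averaged effective system both fall off
roughly like 1/D.  Writes results/coherence_scan.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from metaglv import CommunityParams, ExperimentConfig, run_experiment


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    N = 50
    config = ExperimentConfig(
        experiment="coherence_scan",
        params=CommunityParams(N=N, c=1.0, mu=0.0, sigma=1.25 / np.sqrt(N)),
        rows=3, cols=3, D_list=(1.0, 10.0, 100.0, 1000.0), seed=args.seed)
    table = run_experiment(config)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "coherence_scan.csv", index=False)
    print(table.to_string(index=False))
    last = table.iloc[-1]
    print(f"\nAt D = {last['D']:g} the spatial equilibrium matches the"
          f" effective system to {last['max_relative_density_error']:.1e}"
          f" relative density error with richness difference"
          f" {int(last['richness_difference'])}.")


if __name__ == "__main__":
    main()
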