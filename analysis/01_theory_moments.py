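#!/usr/bin/env python
"""Tabulate the closed-form moments of the averaged interaction matrix and
verify them against Monte-Carlo ensembles.

For each correlation structure (independent, equicorrelated,
nearest-neighbor chain) the script prints the predicted variance of the
habitat-averaged matrix next to the empirical variance from generated
ensembles, and writes results/theory_moments.csv.  The independent and
chain variances vanish as the habitat count G grows; the equicorrelated
variance saturates at rho * sigma^2.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from metaglv import (
    CommunityParams,
    CorrelationSpec,
    empirical_ensemble_moments,
    moments_independent,
    sample_ensemble,
    variance_equicorrelated,
    variance_nn_chain,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-rep", type=int, default=20, help="ensembles per setting")
    args = ap.parse_args()

    N, sigma = 200, 1.0
    rows = []
    settings = []
    for G in (1, 2, 4, 8, 16):
        settings.append((CorrelationSpec("independent"),
                         CommunityParams(N=N, c=0.6, mu=0.8, sigma=sigma),
                         moments_independent(0.6, 0.8, sigma, G).var_bar, G))
        settings.append((CorrelationSpec("equicorrelated", rho=0.4),
                         CommunityParams(N=N, sigma=sigma),
                         variance_equicorrelated(sigma, G, 0.4).var_bar, G))
        settings.append((CorrelationSpec("nn_chain", rho_nn=0.7),
                         CommunityParams(N=N, sigma=sigma),
                         variance_nn_chain(sigma, G, 0.7).var_bar, G))
    for spec, params, predicted, G in settings:
        emp = [
            empirical_ensemble_moments(
                sample_ensemble(G, spec, params, seed=args.seed + 7919 * rep + G)
            )["entry_variance_of_average"]
            for rep in range(args.n_rep)
        ]
        rows.append({
            "kind": spec.kind, "G": G,
            "var_bar_theory": predicted,
            "var_bar_empirical": float(np.mean(emp)),
            "se": float(np.std(emp, ddof=1) / np.sqrt(len(emp))),
        })

    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "theory_moments.csv", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.5f}"))
    print("\nEvery empirical variance should sit within a few standard errors"
          " of its closed form; independent and chain rows shrink with G,"
          " equicorrelated rows level off near rho*sigma^2 ="
          f" {0.4 * sigma**2:.2f}.")


if __name__ == "__main__":
    main()
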