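#!/usr/bin/env python
"""Monte Carlo proton transfer vs exact Boltzmann enumeration.

Samples 20 random clusters of 8-12 ionizable sites (random positions in a
20 A box, random water pKa in [3, 11]) at pH 7 and compares MC-averaged
charges at 1e5 production sweeps against the exact 2^n ensemble. Writes a
per-system table and prints the worst per-site charge deviation.
"""

import argparse
import os

import numpy as np

from memcg import EnergyConfig, MCConfig
from memcg.titration import IonizableSite, exact_titration, mcpt_sample


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/titration_oracle.tsv")
    args = ap.parse_args()

    cfg = EnergyConfig()
    rng = np.random.default_rng(args.seed)
    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    worst = 0.0
    with open(args.out, "w") as fh:
        fh.write("system\tn_sites\tmax_abs_charge_dev\tg_elec_exact"
                 "\tg_elec_mc\n")
        for k in range(20):
            n = int(rng.integers(8, 13))
            pos = rng.uniform(0.0, 20.0, size=(n, 3))
            signs = rng.choice([-1, 1], size=n)
            pkas = rng.uniform(3.0, 11.0, size=n)
            sites = [IonizableSite(i, pos[i], int(signs[i]),
                                   float(pkas[i]), float(pkas[i]))
                     for i in range(n)]
            exact = exact_titration(sites, 7.0, cfg)
            mc = mcpt_sample(
                sites, 7.0,
                MCConfig(seed=(args.seed * 1000 + k) % (2**31 - 1),
                         n_burn_in=2000, n_production=100_000), cfg)
            dev = float(np.max(np.abs(exact.mean_charge - mc.mean_charge)))
            worst = max(worst, dev)
            fh.write(f"{k}\t{n}\t{dev:.6g}\t{exact.g_elec:.6g}"
                     f"\t{mc.g_elec:.6g}\n")
    print(f"Worst per-site |<Q>_MC - <Q>_exact| over 20 systems: "
          f"{worst:.4g} (sampler agrees with the enumeration oracle when "
          f"this stays below 0.02)")
    print(f"Wrote {args.out}")


if __name__ == "__main__":
    main()
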