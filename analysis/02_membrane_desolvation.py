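#!/usr/bin/env python
"""Desolvation of a charged side chain approaching the membrane slab.

Moves a single lysine site from bulk water (z = 50 A) to the slab centre
(z = 0) and records its membrane neighbour count, charging self-energy,
intrinsic pKa, and mean charge at pH 7. The self-energy grows monotonically
as the site enters the slab, pushing the base's intrinsic pKa down — the
energetic signature that buried charges destabilise a conformation.
"""

import argparse
import os

import numpy as np

from memcg import EnergyConfig, GridConfig, build_grid
from memcg.membrane import neighbor_counts
from memcg.synthetic import make_titration_system
from memcg.titration import (
    exact_titration,
    self_energy_from_counts,
    sites_from_structure,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="results/desolvation_profile.tsv")
    args = ap.parse_args()

    cfg = EnergyConfig()
    gc = GridConfig()
    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    rows = []
    for z in np.linspace(50.0, 0.0, 11):
        cg = make_titration_system([[0.0, 0.0, float(z)]], ["LYS"])
        grid = build_grid(cg, gc)
        nc = neighbor_counts(cg, grid, 0, cfg.cutoff)
        dg_self = self_energy_from_counts(nc, cfg)
        site = sites_from_structure(cg, grid, cfg)[0]
        q = exact_titration([site], 7.0, cfg).mean_charge[0]
        rows.append((z, nc.n_mem, dg_self, site.pKa_intrinsic, q))
    with open(args.out, "w") as fh:
        fh.write("z\tn_mem\tdg_self\tpKa_intrinsic\tmean_charge_pH7\n")
        for z, n_mem, dg, pka, q in rows:
            fh.write(f"{z:.1f}\t{n_mem}\t{dg:.6g}\t{pka:.6g}\t{q:.6g}\n")
    shift = abs(rows[-1][3] - 10.5)
    print(f"LYS intrinsic pKa at slab centre: {rows[-1][3]:.2f} "
          f"(shift of {shift:.2f} units from the water value 10.5)")
    print(f"Self-energy rises monotonically from {rows[0][2]:.2f} to "
          f"{rows[-1][2]:.2f} kcal/mol along the approach")
    print(f"Wrote {args.out}")


if __name__ == "__main__":
    main()
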