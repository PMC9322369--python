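#!/usr/bin/env python
"""Free-energy profile of a two-state helix-bundle transition.

Builds the synthetic four-helix bundle whose end states differ by a 15
degree tilt of one helix, morphs between them in 21 frames, and profiles
the folding free energy per frame with exact titration. Reports the
activation barrier and the reaction energy difference, and verifies the
forward/reverse algebra barrier(fwd) - barrier(rev) = -reaction_dg.
"""

import argparse
import os

from memcg import EnergyConfig, GridConfig, interpolate, profile
from memcg.io import write_profile_tsv
from memcg.synthetic import TwoStateSpec, make_two_state_bundle


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/pathway_two_state.tsv")
    args = ap.parse_args()

    cfg = EnergyConfig()
    gc = GridConfig()
    a, b = make_two_state_bundle(TwoStateSpec(seed=args.seed))
    frames = interpolate(a, b, 21)
    fwd = profile(frames, 7.0, cfg, gc, seeds=(args.seed,), mode="exact")
    rev = profile(list(reversed(frames)), 7.0, cfg, gc,
                  seeds=(args.seed,), mode="exact")

    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    write_profile_tsv(fwd, args.out)
    print(f"Forward barrier: {fwd.barrier:.3f} kcal/mol at frame "
          f"{fwd.barrier_frame_index}")
    print(f"Reaction energy difference G(first) - G(last): "
          f"{fwd.reaction_dg:.3f} kcal/mol")
    residual = (fwd.barrier - rev.barrier) + fwd.reaction_dg
    print(f"Forward/reverse algebra residual: {residual:.2e} "
          "(zero by construction)")
    print(f"Wrote {args.out}")


if __name__ == "__main__":
    main()
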