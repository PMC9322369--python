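# memcg

Electrostatics-centred coarse-grained (CG) free energies for membrane-protein
conformational pathways: united-side-chain structures, an implicit membrane
particle grid, constant-pH Monte Carlo proton transfer (MCPT) for ionizable
residues, per-conformation folding free energies, and activation barriers /
reaction energy differences along morphed pathways between end states — with
mutational barrier scans on top.

It is aimed at people studying how large membrane proteins (ion channels,
GPCRs, transporters) move between functional states: all-atom free-energy
methods struggle at that scale, while a CG model that keeps the backbone
explicit and treats electrostatics carefully can rank states and estimate
barriers at negligible cost.

## Model

Each residue keeps its backbone atoms (N, CA, C, O) and collapses its side
chain to one united particle at the heavy-atom centroid. A conformation is
scored as

```
ΔG_fold = c1·ΔG_side_vdw + c2·ΔG_main_solv + c3·ΔG_main_HB
        + ΔG_side_elec + ΔG_side_polar + ΔG_side_hyd
        + ΔG_main-side_elec + ΔG_main-side_vdw
```

with c2 = 0.25 and c3 = 0.15. The electrostatic term is the heart of the
model:

```
ΔG_side_elec = −2.3RT Σ_i ⟨Q_i⟩ (pKa_i^protein − pKa_i^water)
             + ΔG_Qdev + ΔG_QQ^folded − ΔG_QQ^unfolded
```

Intrinsic pKa values are shifted from their water values by a desolvation
self-energy that grows with the nonpolar, polar, and membrane neighbour
counts of each site (`ΔG_self = U_np(N_np) + U_p(N_p) + U_mem(N_mem)`, linear
with saturation). Ensemble charges ⟨Q_i⟩ come from Metropolis Monte Carlo
over charge configurations — proton exchange with the bulk and proton
transfer within site pairs — or from exact Boltzmann enumeration for up to
16 sites, which doubles as the sampler's oracle. The membrane is a regular
cubic lattice of particles filling a slab, excluded around the protein and
frozen during all energy evaluations of a conformation.

Pathways between end states are generated by residue-matched linear
Cartesian morphing (optionally relaxed by bounded steepest descent of the
side particles). The activation barrier is G(transition) − G(first frame),
with the transition state at the highest-energy frame; the reaction energy
difference is G(first) − G(last). Mutational scans re-profile the same
morph schedule with a residue retyped in both end states.

## Worked example

```python
import numpy as np
from memcg import EnergyConfig, GridConfig, interpolate, profile, extract_barrier
from memcg.synthetic import TwoStateSpec, make_two_state_bundle

cfg, gc = EnergyConfig(), GridConfig()
a, b = make_two_state_bundle(TwoStateSpec())     # 4-helix bundle, one helix tilts 15°
frames = interpolate(a, b, 21)                   # linear Cartesian morph
prof = profile(frames, 7.0, cfg, gc, seeds=(1,), mode="exact")
print(round(prof.barrier, 3), round(prof.reaction_dg, 3))
# 0.132 1.161

# barriers and reaction energies from printed state free energies
barrier, idx, dg = extract_barrier([-200.74, -203.95])
print(dg)        # 3.2100000000000080 kcal/mol — inactive vs active state
```

The first numbers say the tilted state of the synthetic bundle is about
1.2 kcal/mol less stable than the packed state and that the morph crosses
no significant barrier. `extract_barrier` applied to the two printed
chloride-channel state energies returns their reaction energy difference,
3.21 kcal/mol: the active state is the more stable one.

The numbered scripts under `analysis/` run the full synthetic studies
(MCPT-vs-oracle agreement, membrane desolvation of a charged side chain,
the two-state pathway, and the mutational scan on the burial fixture) and
write their tables under `results/`.

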