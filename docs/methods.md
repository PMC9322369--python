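# Methods

## Coarse-grained representation

An all-atom structure (fixed-column PDB, first model, altloc A/blank,
HETATM kept only for standard residues) is mapped to a CG structure:
backbone N, CA, C, O (amide H when present) stay explicit; the side chain
becomes one particle at the geometric centroid of its heavy atoms (CB and
beyond; CB alone if that is all there is; glycine has none; a residue whose
side chain is entirely missing from the input falls back to CA). Residues
are classified nonpolar / polar / ionizable from a configurable table;
ionizable residues carry an acid/base sign (ASP, GLU −1; LYS, ARG, HIS +1)
and a water pKa (ASP 3.9, GLU 4.3, HIS 6.5, LYS 10.5, ARG 12.5). Only pKa
*differences* between protein and water enter the energetics, so the
absolute table values matter less than their consistency. Chain termini are
not ionizable by default. Residue identity is (chain, author residue
number, insertion code).

The centroid placement is a package choice: the source model only asks for
a "united" side-chain atom, and the centroid is reproducible and covariant
under rigid motions.

## Membrane grid

The membrane is a cubic lattice (default spacing 3 Å) filling a slab of
half-thickness 15 Å normal to z, covering the protein's lateral bounding
box plus a 15 Å margin. Lattice nodes sit at integer multiples of the
spacing (z anchored at the slab centre) so layouts do not depend on where
the protein happens to sit; nodes within 2.5 Å of any protein particle are
removed. The grid is built once per conformation and frozen for every
energy and MC evaluation of that frame. No thickness fluctuation, phase
behaviour, curvature, or head-group chemistry is modelled, and the slab
frame is fixed — callers orient the protein (the synthetic generators
already do).

## Titration

For each ionizable site the environment is summarised by neighbour counts
within 10 Å of its side particle (boundary inclusive): nonpolar side
particles, polar side particles, membrane particles. The charging
self-energy is linear in each count with saturation,
`ΔG_self = a_np·min(N_np, N_sat) + a_p·min(N_p, N_sat) + a_mem·min(N_mem, N_sat)`
with defaults a_np = 0.05, a_p = −0.05, a_mem = 0.20 kcal/mol per
neighbour and N_sat = 20 for a fully charged site. Desolvation makes
carrying a charge costly, so acids shift up and bases shift down:
`pKa_intrinsic = pKa_water − sign · ΔG_self / (2.3RT)`.

A charge configuration assigns each site 0 or its sign. Its energy is
`ΔG_elec = −2.3RT Σ_i q_i (pKa_i − pH) + ΔG_QQ(q)`, with charge–charge
interactions screened by a uniform effective dielectric (default 40),
clamped below 2 Å, and cut off at 10 Å — the same cutoff used by every
pair term, including the Coulomb sum, so that far-separated subsystems are
exactly additive. The 2.3 prefactor is used as printed rather than ln 10,
so two-state populations follow exp(2.3·Δ) rather than 10^Δ — numerically
within a percent of a base-10 Henderson–Hasselbalch curve; tests use the
model's own closed form.

Metropolis sampling mixes bulk-exchange moves (toggle one site) with
pair proton transfers (relay a proton from a protonated site — a neutral
acid or charged base — to a deprotonated one), 80/20 by default; one sweep
attempts n_sites moves, energies update incrementally, and averages
accumulate once per production sweep, with standard errors from ten block
means. Defaults: 2 000 burn-in and 20 000 production sweeps at 300 K,
fully reproducible given the seed. Systems of ≤ 16 sites can instead be
enumerated exactly (all 2^n configurations, Boltzmann weights); the
enumeration is the oracle the sampler is validated against (worst per-site
charge deviation ≤ 0.02 at 10^5 sweeps across random 8–12-site clusters).
The per-move energy uses the instantaneous configuration charge; apparent
pKa values are read off the pH grid where |⟨Q⟩| crosses 1/2, by linear
interpolation.

## Energy decomposition

All terms are kcal/mol; every pair term shares the 10 Å cutoff.

- side_elec: `−2.3RT Σ ⟨Q_i⟩ (pKa_i − pKa_w) + ΔG_Qdev + ΔG_QQ(folded) −
  ΔG_QQ(unfolded)`, with ⟨Q_i⟩ and the ensemble-averaged charge–charge
  energy from the titration; the unfolded reference (charges at water pKa,
  infinite separation) is zero, and ΔG_Qdev has no published form, so it
  defaults to 0 (configurable per site).
- side_polar / side_hyd: per-contact constants times the number of
  polar–polar (−0.10) and nonpolar–nonpolar (−0.10) side-particle pairs in
  range, plus −0.05 per nonpolar side particle in membrane contact.
- side_vdw: 6-12 potential on side particles with per-type radii (pair
  minimum = r_i + r_j) and a 0.10 kcal/mol well, soft-capped at
  +10 kcal/mol per pair so unrelaxed morph frames stay finite and
  comparable; scaled by c1 = 0.10 in the total (c1 is a package default —
  never published).
- main_HB: backbone N–O pairs at sequence separation ≥ 3 (any separation
  across chains), −1.0 kcal/mol per bond with a linear switch from 3.0 to
  3.5 Å; scaled by c3 = 0.15.
- main_solv: 0.20 kcal/mol per buried backbone amide N/O, where burial
  means ≥ 12 environment particles (side particles of other residues plus
  membrane particles) within 6 Å; counting a residue's own backbone would
  mark every mid-helix amide buried even in water, hence the
  environment-only count; scaled by c2 = 0.25.
- main-side coupling: Coulomb between charged side particles and backbone
  partial charges (C +0.4, O −0.4, N −0.2, H +0.2) and side–backbone 6-12,
  with same-residue and bonded-neighbour (|i−j| ≤ 1 in-chain) pairs
  excluded — adjacent-residue geometry otherwise puts every side particle
  inside its own flanking backbone's repulsive wall.

The total is the stated linear combination; the decomposition identity,
isometry invariance (< 1e-8 kcal/mol under rigid motions of structure +
grid), and extensivity of far-separated copies (< 1e-6) are enforced by
tests. The functional forms of the solvation, hydrogen-bond, polar and
hydrophobic terms and all force-field constants are declared substitutes
chosen for transparency — absolute energies are therefore not comparable
with any particular published force field, while differences along a
pathway, which is what barriers and reaction energies use, are
well-defined.

## Pathways

Intermediates between residue-matched end states (match coverage ≥ 90%
required) are linear Cartesian morphs, 21 frames by default; unmatched
residues ride along from the nearer end state. Optional relaxation moves
side particles downhill on the side–side pair surface by numerical
gradient (central difference, h = 0.01 Å), capped at 0.1 Å per particle
per step, 50 steps by default in the end-to-end pipeline, accepting only
non-increasing steps; the relaxation surface uses the *uncapped* repulsive
wall so clashes actually resolve. Backbone atoms never move.

Per frame: rebuild the grid, (optionally) relax, evaluate the total once
per seed; the profile reports mean ± standard deviation over seeds (zero
spread on the exact-titration path). Barrier = max(g) − g[0] with the
earliest maximum as the transition state; reaction energy difference =
g[0] − g[−1]; the identity barrier(fwd) − barrier(rev) = −reaction_dg
holds algebraically and is tested. Multi-state inputs are chained leg by
leg with shared junction frames and no re-zeroing. Mutational scans retype
one residue in both end states (coordinates kept; X→GLY drops the side
particle), rerun the same schedule and seeds, and report
Δbarrier = barrier_mut − barrier_wt.

## Synthetic data

`make_helix` builds ideal α-helices (rise 1.5 Å, twist 100°, CA radius
2.3 Å) with backbone atoms on fixed per-atom cylindrical offsets fit once
to canonical bond lengths and an (i, i+4) N–O distance of 2.95 Å, with the
(i, i+3) contact pushed beyond 3.6 Å — a 10-residue helix therefore has
exactly 6 backbone hydrogen bonds in the 3.0–3.5 Å window. Side particles
sit radially outward at per-type distances. `make_two_state_bundle` puts
four 24-residue membrane-like helices (nonpolar-dominated sequences drawn
deterministically from the seed, one Lys and one Glu on the moving helix)
on a 10 Å circle spanning the slab; state B tilts one helix by 15° about
its midpoint — angles chosen so both end states are clash-free.
`make_titration_system` places bare ionizable sites at given coordinates
with backbone stubs parked 200+ Å away so only side–side terms couple
sites. `make_burial_barrier_fixture` adds to a static nonpolar bundle a
single lysine arm that sits in bulk water above the slab in one state and
below it in the other: the linear morph drives the charged particle
through the slab centre, so its self-energy (and hence the barrier) peaks
at the mid-frame by construction, and neutralising it must lower the
barrier while a distal mutation must not change it.

What these fixtures do not emulate: real rotamers, loops, sequence-specific
packing, lipid chemistry, ligand binding, or homology-model error. Passing
tests on them validates the machinery (parsing, mapping, grids, titration,
decomposition, pathway algebra) and the qualitative desolvation physics,
not quantitative agreement with any experimental system.

## Numerical choices and limitations

R = 0.0019872 kcal/(mol·K), T = 300 K, Coulomb constant 332.0637
kcal·Å/(mol·e²). Distances exactly at a cutoff count (with a 1e-9 relative
epsilon against floating-point representation). Barrier ties break to the
earliest frame. Empty structures score zero everywhere; an empty protein
with a positive lateral margin still gets a grid (margin box around the
origin), and an empty protein with zero margin yields an empty grid with a
warning. The profile's standard deviation uses the population convention
so single-seed runs report 0 rather than NaN.

Known limitations: no tautomers for His; no coupled
conformational/protonation moves within a frame; no transition-state
search beyond the frame maximum; no kinetics from barriers; titration and
conformation are coupled only through the per-frame environment; absolute
totals depend on the substitute pair-term constants (see above). The
printed multi-thousand-residue systems of the source studies are out of
desk-scale reach — their state energies and barriers depend on a full
proprietary force-field parameterisation and unreleased intermediate
structures — so the package's quantitative claims are confined to what the
tests and `scripts/acceptance.py` themselves compute.
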