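"""Conformational pathways: morphing between end states, per-frame free
energies, activation barriers, reaction energy differences, and mutational
barrier scans.

Intermediates are generated by residue-matched linear Cartesian morphing
between end-state coordinates; each frame gets its own frozen membrane grid,
optional bounded steepest-descent relaxation of the side particles, and a
full energy evaluation per seed. The barrier is G(transition) - G(first
frame) with the transition state at the highest-energy frame; the reaction
energy difference is G(first) - G(last).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EnergyConfig, GridConfig, MCConfig
from .constants import AA3_TO_1
from .energy import total_energy
from .membrane import MembraneGrid, build_grid
from .structures import (
    CGStructure,
    ResidueMatch,
    match_residues,
    mutate_residue,
)


class PathwayError(ValueError):
    pass


@dataclass
class PathwayProfile:
    frames: list                 # CGStructure per frame
    g: np.ndarray                # mean free energy per frame (kcal/mol)
    g_sd: np.ndarray             # std over seeds per frame
    barrier: float
    barrier_frame_index: int
    reaction_dg: float
    pH: float
    seeds: tuple
    config: EnergyConfig | None = None
    labels: list = field(default_factory=list)

    def __len__(self):
        return len(self.g)


@dataclass
class MutationScanRow:
    label: str
    barrier_mut: float
    barrier_wt: float
    delta_barrier: float
    reaction_dg_mut: float


def interpolate(a: CGStructure, b: CGStructure, n_frames: int,
                match: ResidueMatch | None = None) -> list:
    """Linear Cartesian morph between two residue-matched conformations.

    Frame k places every matched particle at (1-t) x_a + t x_b with
    t = k/(n_frames-1); unmatched residues are carried from ``a`` for
    t < 0.5 and from ``b`` otherwise. The end frames are ``a`` and ``b``
    exactly. The match must cover at least 90% of each structure.
    """
    if n_frames < 2:
        raise PathwayError("n_frames must be >= 2")
    if match is None:
        match = match_residues(a, b)
    if match.coverage(len(a), len(b)) < 0.9:
        raise PathwayError(
            f"residue match covers only "
            f"{100 * match.coverage(len(a), len(b)):.1f}% of residues "
            "(need >= 90%)")

    frames = []
    for k in range(n_frames):
        t = k / (n_frames - 1)
        if k == 0:
            frame = a.copy()
        elif k == n_frames - 1:
            frame = b.copy()
        else:
            base = a if t < 0.5 else b
            frame = base.copy()
            lookup = {(a.residues[i].key): (i, j) for i, j in match.pairs}
            for res in frame.residues:
                pair = lookup.get(res.key)
                if pair is None:
                    continue  # unmatched: carried from the base structure
                ra = a.residues[pair[0]]
                rb = b.residues[pair[1]]
                for name in res.backbone:
                    if name in ra.backbone and name in rb.backbone:
                        res.backbone[name] = (
                            (1 - t) * ra.backbone[name]
                            + t * rb.backbone[name])
                if (res.side_particle is not None
                        and ra.side_particle is not None
                        and rb.side_particle is not None):
                    res.side_particle = (
                        (1 - t) * ra.side_particle + t * rb.side_particle)
        frame.label = f"t={t:.3f}"
        frames.append(frame)
    return frames


def _side_pair_energy(pos, klass, radii, config: EnergyConfig):
    """Side-side pairwise surface used for relaxation (vdw + polar + hyd
    contact terms); returns total energy given an (m, 3) position array."""
    m = len(pos)
    if m < 2:
        return 0.0
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu = np.triu_indices(m, k=1)
    dv = d[iu]
    within = dv <= config.cutoff * (1 + 1e-12)
    rm = radii[iu[0]] + radii[iu[1]]
    # uncapped wall: relaxation must feel the clash gradient that the
    # scoring function soft-caps away
    with np.errstate(divide="ignore", over="ignore"):
        x = (rm / np.maximum(dv, 1e-6)) ** 6
        e = config.vdw_well_depth * (x * x - 2.0 * x)
    total = float(np.sum(e[within]))
    both_p = (klass[iu[0]] == "polar") & (klass[iu[1]] == "polar")
    both_np = (klass[iu[0]] == "nonpolar") & (klass[iu[1]] == "nonpolar")
    total += config.k_polar * int(np.sum(both_p & within))
    total += -config.k_hyd * int(np.sum(both_np & within))
    return total


def relax_frame(cg: CGStructure, grid: MembraneGrid, config: EnergyConfig,
                n_steps: int = 50, step_size: float = 0.1) -> CGStructure:
    """Bounded steepest descent of the side particles on the side-side pair
    surface; the backbone is fixed. Each step moves particles along the
    numerical gradient with a per-particle displacement cap and is accepted
    only if the energy does not increase."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    out = cg.copy()
    side_idx = [i for i, r in enumerate(out.residues)
                if r.side_particle is not None]
    if n_steps == 0 or len(side_idx) < 2:
        return out
    pos = np.array([out.residues[i].side_particle for i in side_idx])
    klass = np.array([out.residues[i].klass for i in side_idx],
                     dtype=object)
    radii = np.array([config.side_vdw_radii.get(out.residues[i].name, 2.0)
                      for i in side_idx])
    h = 0.01
    e_cur = _side_pair_energy(pos, klass, radii, config)
    for _ in range(n_steps):
        grad = np.zeros_like(pos)
        # numerical gradient, all particles at once via shifted distances
        diff = pos[:, None, :] - pos[None, :, :]
        d2 = np.sum(diff * diff, axis=-1)
        for axis in range(3):
            for sgn in (1.0, -1.0):
                d2s = d2 + 2.0 * sgn * h * diff[:, :, axis] + h * h
                np.fill_diagonal(d2s, np.inf)
                ds = np.sqrt(d2s)
                within = ds <= config.cutoff * (1 + 1e-12)
                rm = radii[:, None] + radii[None, :]
                with np.errstate(divide="ignore", over="ignore"):
                    x = (rm / np.maximum(ds, 1e-6)) ** 6
                    e = config.vdw_well_depth * (x * x - 2.0 * x)
                both_p = (klass[:, None] == "polar") & \
                    (klass[None, :] == "polar")
                both_np = (klass[:, None] == "nonpolar") & \
                    (klass[None, :] == "nonpolar")
                e_i = np.sum(np.where(within, e, 0.0), axis=1)
                e_i += config.k_polar * np.sum(both_p & within, axis=1)
                e_i += -config.k_hyd * np.sum(both_np & within, axis=1)
                grad[:, axis] += sgn * e_i
        grad /= (2.0 * h)
        gmax = np.max(np.linalg.norm(grad, axis=1))
        if gmax < 1e-8:
            break
        scale = step_size / gmax
        accepted = False
        for _try in range(5):
            trial = pos - scale * grad
            e_new = _side_pair_energy(trial, klass, radii, config)
            if e_new <= e_cur:
                pos, e_cur = trial, e_new
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            break
    for k, i in enumerate(side_idx):
        out.residues[i].side_particle = pos[k]
    return out


def extract_barrier(g):
    """Barrier (earliest maximum, relative to the first frame) and reaction
    energy difference G(first) - G(last)."""
    g = np.asarray(g, dtype=float)
    if len(g) < 2:
        raise ValueError("need at least 2 frame energies")
    barrier_index = int(np.argmax(g))  # argmax takes the earliest maximum
    barrier = float(g[barrier_index] - g[0])
    reaction_dg = float(g[0] - g[-1])
    return barrier, barrier_index, reaction_dg


def profile(frames, pH: float, config: EnergyConfig,
            grid_config: GridConfig, mc: MCConfig | None = None,
            seeds=(1,), relax_steps: int = 0,
            relax_step_size: float = 0.1, mode: str = "auto"
            ) -> PathwayProfile:
    """Free-energy profile over an ordered frame list.

    Per frame: rebuild the membrane grid, optionally relax side particles,
    then evaluate the total energy once per seed; the profile reports the
    mean and standard deviation over seeds (zero spread on the exact
    titration path).
    """
    if len(frames) < 2:
        raise PathwayError("need at least 2 frames")
    seeds = tuple(seeds)
    if not seeds:
        raise PathwayError("need at least one seed")
    for f in frames:
        if len(f) == 0:
            raise PathwayError("frame with no residues")

    g = np.zeros(len(frames))
    g_sd = np.zeros(len(frames))
    for k, frame in enumerate(frames):
        grid = build_grid(frame, grid_config)
        work = relax_frame(frame, grid, config, relax_steps,
                           relax_step_size) if relax_steps else frame
        vals = []
        for seed in seeds:
            bd = total_energy(work, grid, pH, config, mc=mc, seed=seed,
                              mode=mode)
            vals.append(bd.total)
        g[k] = float(np.mean(vals))
        g_sd[k] = float(np.std(vals))

    barrier, b_idx, reaction_dg = extract_barrier(g)
    return PathwayProfile(
        frames=list(frames), g=g, g_sd=g_sd, barrier=barrier,
        barrier_frame_index=b_idx, reaction_dg=reaction_dg, pH=pH,
        seeds=seeds, config=config,
        labels=[f.label for f in frames],
    )


def _mutation_label(cg: CGStructure, key, new_name: str) -> str:
    for res in cg.residues:
        if res.key == tuple(key):
            wt = AA3_TO_1.get(res.name, res.name)
            mut = AA3_TO_1.get(new_name, new_name)
            return f"{wt}{key[1]}{mut}"
    raise KeyError(f"no residue with key {key}")


def mutation_scan(a: CGStructure, b: CGStructure, mutations, pH: float,
                  config: EnergyConfig, grid_config: GridConfig,
                  mc: MCConfig | None = None, seeds=(1,),
                  n_frames: int = 21, relax_steps: int = 0,
                  mode: str = "auto"):
    """Barrier changes for point mutations applied to both end states.

    The wild-type profile is computed once; each mutation is applied to both
    end states, morphed on the same schedule, and profiled with the same
    seeds. Returns (wild-type profile, list of MutationScanRow).
    """
    wt_frames = interpolate(a, b, n_frames)
    wt = profile(wt_frames, pH, config, grid_config, mc=mc, seeds=seeds,
                 relax_steps=relax_steps, mode=mode)
    rows = []
    seen = set()
    for key, new_name in mutations:
        label = _mutation_label(a, key, new_name)
        if label in seen:
            raise PathwayError(f"duplicate mutation label {label}")
        seen.add(label)
        ma = mutate_residue(a, key, new_name, config)
        mb = mutate_residue(b, key, new_name, config)
        frames = interpolate(ma, mb, n_frames)
        prof = profile(frames, pH, config, grid_config, mc=mc, seeds=seeds,
                       relax_steps=relax_steps, mode=mode)
        rows.append(MutationScanRow(
            label=label,
            barrier_mut=prof.barrier,
            barrier_wt=wt.barrier,
            delta_barrier=prof.barrier - wt.barrier,
            reaction_dg_mut=prof.reaction_dg,
        ))
    return wt, rows
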