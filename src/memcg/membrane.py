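"""Implicit membrane: a regular lattice of particles filling a slab.

The slab normal is the z axis; the lattice is cubic with nodes at integer
multiples of the spacing (z anchored at the slab centre), so layouts are
reproducible regardless of where the protein sits. Nodes within the exclusion
radius of any protein particle are removed, and the grid is then frozen for
all energy evaluations of that conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import GridConfig
from .structures import CGStructure


@dataclass
class MembraneGrid:
    particles: np.ndarray  # (n, 3) coordinates in A
    config: GridConfig

    def __len__(self):
        return len(self.particles)

    def tree(self) -> cKDTree | None:
        if len(self.particles) == 0:
            return None
        return cKDTree(self.particles)

    def translated(self, shift) -> "MembraneGrid":
        return MembraneGrid(self.particles + np.asarray(shift), self.config)

    def rotated(self, rotation) -> "MembraneGrid":
        rot = np.asarray(rotation)
        return MembraneGrid(self.particles @ rot.T, self.config)


@dataclass
class NeighborCounts:
    """Environment of one ionizable site within the neighbour cutoff."""

    n_np: int
    n_p: int
    n_mem: int


def _axis_nodes(lo: float, hi: float, spacing: float, anchor: float):
    """Lattice nodes anchor + k*spacing inside [lo, hi] (inclusive)."""
    k_lo = int(np.ceil((lo - anchor) / spacing - 1e-9))
    k_hi = int(np.floor((hi - anchor) / spacing + 1e-9))
    if k_hi < k_lo:
        return np.zeros(0)
    return anchor + spacing * np.arange(k_lo, k_hi + 1)


def build_grid(cg: CGStructure, gc: GridConfig) -> MembraneGrid:
    """Build the membrane lattice over the protein's lateral bounding box.

    The box is the protein's xy extent padded by ``lateral_margin`` (the
    origin, padded by the margin, when the structure is empty); z spans the
    slab. Nodes within ``exclusion_radius`` of any protein particle are
    dropped.
    """
    protein = cg.particles()
    if len(protein) == 0:
        if gc.lateral_margin <= 0:
            warnings.warn("empty protein and no lateral margin: empty grid")
            return MembraneGrid(np.zeros((0, 3)), gc)
        lo = np.array([0.0, 0.0])
        hi = np.array([0.0, 0.0])
    else:
        lo = protein[:, :2].min(axis=0)
        hi = protein[:, :2].max(axis=0)

    xs = _axis_nodes(lo[0] - gc.lateral_margin, hi[0] + gc.lateral_margin,
                     gc.spacing, 0.0)
    ys = _axis_nodes(lo[1] - gc.lateral_margin, hi[1] + gc.lateral_margin,
                     gc.spacing, 0.0)
    zs = _axis_nodes(gc.slab_center_z - gc.slab_half_thickness,
                     gc.slab_center_z + gc.slab_half_thickness,
                     gc.spacing, gc.slab_center_z)
    if min(len(xs), len(ys), len(zs)) == 0:
        return MembraneGrid(np.zeros((0, 3)), gc)

    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    if len(protein) > 0 and gc.exclusion_radius > 0:
        tree = cKDTree(protein)
        dist, _ = tree.query(nodes, k=1)
        nodes = nodes[dist >= gc.exclusion_radius]
    return MembraneGrid(nodes, gc)


def neighbor_counts(cg: CGStructure, grid: MembraneGrid, site_index: int,
                    cutoff: float) -> NeighborCounts:
    """Count nonpolar / polar side particles and membrane particles within
    ``cutoff`` of an ionizable site's side particle (boundary inclusive,
    the site itself excluded)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res = cg.residues[site_index]
    if res.klass != "ionizable":
        raise ValueError(
            f"residue {res.name} {res.key} is not ionizable")
    if res.side_particle is None:
        raise ValueError("ionizable site has no side particle")
    center = res.side_particle
    # small epsilon so distances exactly equal to the cutoff count despite
    # floating-point representation
    tol = 1e-9 * max(1.0, cutoff)

    n_np = n_p = 0
    for j, other in enumerate(cg.residues):
        if j == site_index or other.side_particle is None:
            continue
        d = np.linalg.norm(other.side_particle - center)
        if d <= cutoff + tol:
            if other.klass == "nonpolar":
                n_np += 1
            elif other.klass == "polar":
                n_p += 1
    n_mem = 0
    if len(grid) > 0:
        d = np.linalg.norm(grid.particles - center, axis=1)
        n_mem = int(np.sum(d <= cutoff + tol))
    return NeighborCounts(n_np=n_np, n_p=n_p, n_mem=n_mem)
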