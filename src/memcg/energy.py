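"""Coarse-grained folding free energy of one conformation.

The total is assembled as

    dG_fold = c1*dG_side_vdw + c2*dG_main_solv + c3*dG_main_hb
              + dG_side_elec + dG_side_polar + dG_side_hyd
              + dG_main_side_elec + dG_main_side_vdw

where the side-chain electrostatic term couples the MC/enumerated charge
ensemble to the environment-dependent pKa shifts of ionizable residues, and
all pairwise terms share a single 10 A cutoff (distance exactly at the
cutoff counts). Energies are kcal/mol, distances A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import EnergyConfig, MCConfig
from .constants import BACKBONE_PARTIAL_CHARGES, BACKBONE_VDW_RADII
from .membrane import MembraneGrid, NeighborCounts
from .structures import CGStructure
from .titration import (
    TitrationResult,
    exact_titration,
    mcpt_sample,
    self_energy_from_counts,
    sites_from_structure,
    MAX_EXACT_SITES,
)

_TOL = 1e-9


@dataclass
class EnergyBreakdown:
    """All terms of the folding free energy for one conformation."""

    side_elec: float = 0.0
    side_polar: float = 0.0
    side_hyd: float = 0.0
    side_vdw: float = 0.0
    main_solv: float = 0.0
    main_hb: float = 0.0
    main_side_elec: float = 0.0
    main_side_vdw: float = 0.0
    # bookkeeping components living inside side_elec
    self_energy: float = 0.0
    qq_folded: float = 0.0
    qq_unfolded: float = 0.0
    q_dev: float = 0.0
    total: float = 0.0
    titration: TitrationResult | None = None

    def recompose(self, config: EnergyConfig) -> float:
        """The defining linear combination; must equal ``total``."""
        return (
            config.c1 * self.side_vdw
            + config.c2 * self.main_solv
            + config.c3 * self.main_hb
            + self.side_elec + self.side_polar + self.side_hyd
            + self.main_side_elec + self.main_side_vdw
        )

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k) for k in (
                "side_elec", "side_polar", "side_hyd", "side_vdw",
                "main_solv", "main_hb", "main_side_elec", "main_side_vdw",
                "self_energy", "qq_folded", "qq_unfolded", "q_dev", "total",
            )
        }


def charge_charge(cg: CGStructure, q, config: EnergyConfig) -> float:
    """Screened Coulomb energy of a charge configuration over the ionizable
    side particles (global cutoff; r clamped below 2 A)."""
    idx = cg.ionizable_indices()
    q = np.asarray(q, dtype=float)
    if len(q) != len(idx):
        raise ValueError(
            f"charge vector length {len(q)} != {len(idx)} ionizable sites")
    total = 0.0
    for a in range(len(idx)):
        if q[a] == 0.0:
            continue
        pa = cg.residues[idx[a]].side_particle
        for b in range(a + 1, len(idx)):
            if q[b] == 0.0:
                continue
            r = float(np.linalg.norm(pa - cg.residues[idx[b]].side_particle))
            if r > config.cutoff * (1 + 1e-12):
                continue
            r = max(r, config.clash_clamp)
            total += config.coulomb_k * q[a] * q[b] / (config.eps_eff * r)
    return total


def self_energy_site(site, nc: NeighborCounts, q_i: float,
                     config: EnergyConfig) -> float:
    """Desolvation self-energy of one site scaled by its charge magnitude."""
    return abs(q_i) * self_energy_from_counts(nc, config)


def side_elec(cg: CGStructure, grid: MembraneGrid, titr: TitrationResult,
              config: EnergyConfig, sites=None):
    """Side-chain electrostatic term and its bookkeeping components.

    value = -2.3RT sum_i <Q_i>(pKa_i - pKa_w) + dG_Qdev + dG_QQ(folded)
            - dG_QQ(unfolded), with the unfolded reference at zero (charges
    at water pKa, infinite separation).
    """
    if sites is None:
        sites = sites_from_structure(cg, grid, config)
    if len(sites) != len(titr.mean_charge):
        raise ValueError("titration result does not match the structure's "
                         "ionizable sites")
    shift_term = 0.0
    self_term = 0.0
    for s, q in zip(sites, titr.mean_charge):
        dpka = s.pKa_intrinsic - s.pKa_water
        shift_term += -config.ln10_rt * q * dpka
        self_term += abs(q) * (-s.sign * dpka) * config.ln10_rt
    q_dev = config.q_dev * len(sites)
    qq_folded = titr.qq_mean
    qq_unfolded = 0.0
    value = shift_term + q_dev + qq_folded - qq_unfolded
    components = {
        "self_energy": self_term,
        "qq_folded": qq_folded,
        "qq_unfolded": qq_unfolded,
        "q_dev": q_dev,
    }
    return value, components


def _side_arrays(cg: CGStructure, config: EnergyConfig):
    pos, klass, radii, residx = [], [], [], []
    for i, r in enumerate(cg.residues):
        if r.side_particle is None:
            continue
        pos.append(r.side_particle)
        klass.append(r.klass)
        radii.append(config.side_vdw_radii.get(r.name, 2.0))
        residx.append(i)
    if not pos:
        return (np.zeros((0, 3)), np.array([], dtype=object),
                np.zeros(0), [])
    return np.asarray(pos), np.array(klass, dtype=object), \
        np.asarray(radii), residx


def _lj(r, rm, eps, cap):
    with np.errstate(divide="ignore", over="ignore"):
        x = (rm / np.maximum(r, 1e-6)) ** 6
        e = eps * (x * x - 2.0 * x)
    return np.minimum(e, cap)


def side_polar_hyd_vdw(cg: CGStructure, grid: MembraneGrid,
                       config: EnergyConfig):
    """Polar-contact, hydrophobic-contact, and 6-12 vdW side-chain terms."""
    pos, klass, radii, _ = _side_arrays(cg, config)
    m = len(pos)
    if m == 0:
        return 0.0, 0.0, 0.0
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    iu = np.triu_indices(m, k=1)
    within = d[iu] <= config.cutoff * (1 + 1e-12)

    both_polar = (klass[iu[0]] == "polar") & (klass[iu[1]] == "polar")
    both_np = (klass[iu[0]] == "nonpolar") & (klass[iu[1]] == "nonpolar")
    polar = config.k_polar * int(np.sum(both_polar & within))
    hyd = -config.k_hyd * int(np.sum(both_np & within))

    # membrane contact bonus for nonpolar side chains
    if len(grid) > 0:
        tree = grid.tree()
        nonpolar_idx = np.where(klass == "nonpolar")[0]
        if len(nonpolar_idx) > 0:
            counts = tree.query_ball_point(
                pos[nonpolar_idx], config.cutoff, return_length=True)
            hyd -= config.k_hyd_mem * int(np.sum(np.asarray(counts) > 0))

    rm = radii[iu[0]] + radii[iu[1]]
    e = _lj(d[iu], rm, config.vdw_well_depth, config.vdw_cap)
    vdw = float(np.sum(e[within]))
    return float(polar), float(hyd), vdw


def _backbone_arrays(cg: CGStructure):
    pos, names, residx = [], [], []
    chain_ord = {}
    ordinals = []
    counters: dict = {}
    for i, r in enumerate(cg.residues):
        chain = r.key[0]
        counters[chain] = counters.get(chain, -1) + 1
        chain_ord[i] = (chain, counters[chain])
        for name, xyz in r.backbone.items():
            pos.append(xyz)
            names.append(name)
            residx.append(i)
            ordinals.append(counters[chain])
    if not pos:
        return (np.zeros((0, 3)), np.array([], dtype=object),
                np.array([], dtype=int), np.array([], dtype=int), chain_ord)
    return (np.asarray(pos), np.array(names, dtype=object),
            np.asarray(residx, dtype=int), np.asarray(ordinals, dtype=int),
            chain_ord)


def main_energy(cg: CGStructure, grid: MembraneGrid, config: EnergyConfig):
    """Backbone solvation penalty and hydrogen-bond energy (unscaled; the
    c2/c3 coefficients are applied in the total)."""
    pos, names, residx, ordinals, chain_ord = _backbone_arrays(cg)
    if len(pos) == 0:
        return 0.0, 0.0
    chains = np.array([cg.residues[i].key[0] for i in residx], dtype=object)

    n_mask = names == "N"
    o_mask = names == "O"
    main_hb = 0.0
    if n_mask.any() and o_mask.any():
        pn, po = pos[n_mask], pos[o_mask]
        d = np.linalg.norm(pn[:, None, :] - po[None, :, :], axis=-1)
        same_chain = chains[n_mask][:, None] == chains[o_mask][None, :]
        sep = np.abs(ordinals[n_mask][:, None] - ordinals[o_mask][None, :])
        same_res = (residx[n_mask][:, None] == residx[o_mask][None, :])
        eligible = ~same_res & (~same_chain | (sep >= config.hb_min_sep))
        s = np.clip((config.hb_d_off - d)
                    / (config.hb_d_off - config.hb_d_on), 0.0, 1.0)
        main_hb = config.hb_energy * float(np.sum(s[eligible]))

    # burial of backbone amide N/O: environment particles are side particles
    # of other residues plus membrane particles
    amide_mask = n_mask | o_mask
    amide_pos = pos[amide_mask]
    amide_res = residx[amide_mask]
    side_pos, _, _, side_residx = _side_arrays(cg, config)
    env_counts = np.zeros(len(amide_pos))
    if len(side_pos) > 0:
        tree = cKDTree(side_pos)
        lists = tree.query_ball_point(amide_pos, config.burial_radius)
        own = np.asarray(side_residx)
        for k, lst in enumerate(lists):
            env_counts[k] += sum(1 for j in lst if own[j] != amide_res[k])
    if len(grid) > 0:
        gtree = grid.tree()
        env_counts += gtree.query_ball_point(
            amide_pos, config.burial_radius, return_length=True)
    n_buried = int(np.sum(env_counts >= config.burial_threshold))
    main_solv = config.k_solv * n_buried
    return main_solv, main_hb


def main_side_energy(cg: CGStructure, q, config: EnergyConfig):
    """Main-chain/side-chain coupling: Coulomb between charged side particles
    and backbone partial charges, plus side-backbone 6-12 vdW. Same-residue
    and bonded-neighbour (|i-j| <= 1 within a chain) pairs are excluded."""
    side_pos, _, side_radii, side_residx = _side_arrays(cg, config)
    if len(side_pos) == 0:
        return 0.0, 0.0
    bpos, bnames, bresidx, bords, chain_ord = _backbone_arrays(cg)

    # per-residue ensemble charge for ionizable residues
    ion_idx = cg.ionizable_indices()
    q = np.asarray(q, dtype=float)
    if len(q) != len(ion_idx):
        raise ValueError("charge vector does not match ionizable sites")
    res_charge = {i: qi for i, qi in zip(ion_idx, q)}
    side_q = np.array([res_charge.get(i, 0.0) for i in side_residx])

    d = np.linalg.norm(side_pos[:, None, :] - bpos[None, :, :], axis=-1)
    side_chain = np.array([cg.residues[i].key[0] for i in side_residx],
                          dtype=object)
    side_ord = np.array([chain_ord[i][1] for i in side_residx])
    bchain = np.array([cg.residues[i].key[0] for i in bresidx], dtype=object)
    same_chain = side_chain[:, None] == bchain[None, :]
    bonded = same_chain & (
        np.abs(side_ord[:, None] - bords[None, :]) <= 1)
    within = (d <= config.cutoff * (1 + 1e-12)) & ~bonded

    delta = np.array([BACKBONE_PARTIAL_CHARGES.get(nm, 0.0)
                      for nm in bnames])
    rcl = np.maximum(d, config.clash_clamp)
    ms_elec = float(np.sum(
        np.where(within,
                 config.coulomb_k * side_q[:, None] * delta[None, :]
                 / (config.eps_eff * rcl),
                 0.0)))

    brad = np.array([BACKBONE_VDW_RADII.get(nm, 1.7) for nm in bnames])
    rm = side_radii[:, None] + brad[None, :]
    e = _lj(d, rm, config.vdw_well_depth, config.vdw_cap)
    ms_vdw = float(np.sum(np.where(within, e, 0.0)))
    return ms_elec, ms_vdw


def total_energy(cg: CGStructure, grid: MembraneGrid, pH: float,
                 config: EnergyConfig, mc: MCConfig | None = None,
                 seed: int | None = None, mode: str = "auto"
                 ) -> EnergyBreakdown:
    """Full folding free energy of one conformation on its frozen grid.

    Workflow: environment-dependent intrinsic pKa per ionizable site, then
    the charge ensemble (exact enumeration for <= 16 sites unless
    ``mode='mc'``), then every term of the decomposition.
    """
    if mode not in ("auto", "exact", "mc"):
        raise ValueError(f"unknown mode {mode!r}")
    sites = sites_from_structure(cg, grid, config)
    n = len(sites)
    use_exact = mode == "exact" or (mode == "auto" and n <= MAX_EXACT_SITES)
    if use_exact and n > MAX_EXACT_SITES:
        raise ValueError("exact mode limited to 16 sites")
    if n == 0 or use_exact:
        titr = exact_titration(sites, pH, config)
    else:
        mc = mc or MCConfig()
        if seed is not None:
            mc = mc.replace(seed=seed)
        titr = mcpt_sample(sites, pH, mc, config)

    elec, comps = side_elec(cg, grid, titr, config, sites=sites)
    polar, hyd, vdw = side_polar_hyd_vdw(cg, grid, config)
    main_solv, main_hb = main_energy(cg, grid, config)
    ms_elec, ms_vdw = main_side_energy(cg, titr.mean_charge, config)

    bd = EnergyBreakdown(
        side_elec=elec, side_polar=polar, side_hyd=hyd, side_vdw=vdw,
        main_solv=main_solv, main_hb=main_hb,
        main_side_elec=ms_elec, main_side_vdw=ms_vdw,
        self_energy=comps["self_energy"], qq_folded=comps["qq_folded"],
        qq_unfolded=comps["qq_unfolded"], q_dev=comps["q_dev"],
        titration=titr,
    )
    bd.total = bd.recompose(config)
    assert abs(bd.total - bd.recompose(config)) < _TOL
    return bd
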