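import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memcg import (
    CGStructure,
    EnergyConfig,
    GridConfig,
    build_grid,
    total_energy,
)
from memcg.energy import (
    charge_charge,
    main_energy,
    main_side_energy,
    self_energy_site,
    side_elec,
    side_polar_hyd_vdw,
)
from memcg.membrane import MembraneGrid, NeighborCounts
from memcg.structures import CGResidue
from memcg.synthetic import (
    HelixSpec,
    make_helix,
    make_titration_system,
)
from memcg.titration import exact_titration, sites_from_structure

EMPTY_GRID = MembraneGrid(np.zeros((0, 3)), GridConfig())


def pair_structure(names, positions, klasses=None):
    residues = []
    default_class = {"ALA": "nonpolar", "LEU": "nonpolar", "SER": "polar",
                     "THR": "polar", "ASP": "ionizable", "LYS": "ionizable"}
    for i, (name, pos) in enumerate(zip(names, positions)):
        klass = (klasses or [default_class[n] for n in names])[i]
        sign = {"ASP": -1, "LYS": 1}.get(name, 0) \
            if klass == "ionizable" else 0
        residues.append(CGResidue(
            key=("A", i + 1, " "), name=name,
            backbone={"CA": np.asarray(pos, float) + [0, 0, 400 + 50 * i]},
            side_particle=np.asarray(pos, dtype=float),
            klass=klass, ionizable_sign=sign,
            pKa_water={"ASP": 3.9, "LYS": 10.5}.get(name)))
    return CGStructure(residues)


class TestChargeCharge:
    def test_coulomb_closed_form(self, cfg):
        cg = pair_structure(["LYS", "ASP"], [[0, 0, 0], [10, 0, 0]])
        e = charge_charge(cg, [1.0, -1.0], cfg)
        assert e == pytest.approx(332.0637 * -1.0 / (40.0 * 10.0))
        assert e == pytest.approx(-0.830, abs=5e-4)

    def test_single_site_zero(self, cfg):
        cg = pair_structure(["ASP"], [[0, 0, 0]])
        assert charge_charge(cg, [-1.0], cfg) == 0.0

    def test_all_neutral_zero(self, cfg):
        cg = pair_structure(["LYS", "ASP"], [[0, 0, 0], [5, 0, 0]])
        assert charge_charge(cg, [0.0, 0.0], cfg) == 0.0

    def test_clash_clamped_at_two_angstrom(self, cfg):
        near = pair_structure(["LYS", "ASP"], [[0, 0, 0], [0.5, 0, 0]])
        at2 = pair_structure(["LYS", "ASP"], [[0, 0, 0], [2.0, 0, 0]])
        assert charge_charge(near, [1, -1], cfg) == \
            charge_charge(at2, [1, -1], cfg)


class TestSelfEnergy:
    def test_neutral_site_zero(self, cfg):
        assert self_energy_site(None, NeighborCounts(5, 5, 5), 0.0,
                                cfg) == 0.0

    def test_membrane_contribution(self, cfg):
        e = self_energy_site(None, NeighborCounts(0, 0, 10), -1.0, cfg)
        assert e == pytest.approx(2.0)

    def test_saturation(self, cfg):
        e = self_energy_site(None, NeighborCounts(30, 0, 0), 1.0, cfg)
        assert e == pytest.approx(0.05 * 20)

    def test_scales_with_partial_charge(self, cfg):
        full = self_energy_site(None, NeighborCounts(0, 0, 10), -1.0, cfg)
        half = self_energy_site(None, NeighborCounts(0, 0, 10), -0.5, cfg)
        assert half == pytest.approx(full / 2)


class TestSideElec:
    def test_no_ionizable_residues_zero(self, cfg):
        cg = pair_structure(["ALA", "SER"], [[0, 0, 0], [5, 0, 0]])
        titr = exact_titration([], 7.0, cfg)
        value, comps = side_elec(cg, EMPTY_GRID, titr, cfg)
        assert value == 0.0 and comps["self_energy"] == 0.0

    def test_unshifted_site_contributes_only_qq(self, cfg):
        cg = make_titration_system([[0, 0, 50]], ["ASP"])
        sites = sites_from_structure(cg, EMPTY_GRID, cfg)
        titr = exact_titration(sites, 7.0, cfg)
        value, comps = side_elec(cg, EMPTY_GRID, titr, cfg, sites=sites)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_fully_charged_acid_with_unit_shift(self, cfg):
        # shift of +1 pKa unit and <Q> = -1 gives +2.3RT
        cg = make_titration_system([[0, 0, 50]], ["ASP"])
        sites = sites_from_structure(cg, EMPTY_GRID, cfg)
        sites[0].pKa_intrinsic = sites[0].pKa_water + 1.0
        titr = exact_titration(sites, 14.0, cfg)
        assert titr.mean_charge[0] == pytest.approx(-1.0, abs=1e-6)
        value, comps = side_elec(cg, EMPTY_GRID, titr, cfg, sites=sites)
        assert value == pytest.approx(cfg.ln10_rt, rel=1e-4)
        assert comps["self_energy"] == pytest.approx(value)

    def test_mismatched_titration_rejected(self, cfg):
        cg = make_titration_system([[0, 0, 50], [5, 0, 50]],
                                   ["ASP", "ASP"])
        titr = exact_titration([], 7.0, cfg)
        with pytest.raises(ValueError):
            side_elec(cg, EMPTY_GRID, titr, cfg)


class TestSidePairTerms:
    def test_hydrophobic_pair_count(self, cfg):
        cg = pair_structure(["ALA", "LEU"], [[0, 0, 0], [6, 0, 0]])
        polar, hyd, _ = side_polar_hyd_vdw(cg, EMPTY_GRID, cfg)
        assert polar == 0.0
        assert hyd == pytest.approx(-cfg.k_hyd)

    def test_polar_pair_count(self, cfg):
        cg = pair_structure(["SER", "THR"], [[0, 0, 0], [6, 0, 0]])
        polar, hyd, _ = side_polar_hyd_vdw(cg, EMPTY_GRID, cfg)
        assert polar == pytest.approx(cfg.k_polar)
        assert hyd == 0.0

    def test_vdw_minimum_at_contact(self, cfg):
        rm = 2 * cfg.side_vdw_radii["ALA"]
        cg = pair_structure(["ALA", "ALA"], [[0, 0, 0], [rm, 0, 0]],
                            klasses=["nonpolar", "nonpolar"])
        _, _, vdw = side_polar_hyd_vdw(cg, EMPTY_GRID, cfg)
        assert vdw == pytest.approx(-cfg.vdw_well_depth)

    def test_overlap_capped(self, cfg):
        cg = pair_structure(["ALA", "ALA"], [[0, 0, 0], [0.05, 0, 0]])
        _, _, vdw = side_polar_hyd_vdw(cg, EMPTY_GRID, cfg)
        assert vdw == pytest.approx(cfg.vdw_cap)

    def test_membrane_contact_bonus_for_nonpolar(self, cfg):
        cg = pair_structure(["ALA", "ALA"], [[0, 0, 0], [30, 0, 0]])
        grid = MembraneGrid(np.array([[0.0, 5.0, 0.0]]), GridConfig())
        _, hyd_with, _ = side_polar_hyd_vdw(cg, grid, cfg)
        _, hyd_without, _ = side_polar_hyd_vdw(cg, EMPTY_GRID, cfg)
        assert hyd_with - hyd_without == pytest.approx(-cfg.k_hyd_mem)


class TestMainEnergy:
    def test_ideal_helix_has_six_hbonds(self, cfg):
        helix = make_helix(HelixSpec(sequence="A" * 10))
        _, main_hb = main_energy(helix, EMPTY_GRID, cfg)
        assert main_hb == pytest.approx(6 * cfg.hb_energy)

    def test_extended_chain_has_none(self, cfg):
        # residues 10 A apart: every N-O pair beyond the switch window
        residues = []
        for i in range(6):
            x = 10.0 * i
            residues.append(CGResidue(
                key=("A", i + 1, " "), name="ALA",
                backbone={
                    "N": np.array([x - 1.46, 0.0, 0.0]),
                    "CA": np.array([x, 0.0, 0.0]),
                    "C": np.array([x + 1.52, 0.0, 0.0]),
                    "O": np.array([x + 1.52, 1.23, 0.0]),
                },
                side_particle=np.array([x, -1.53, 0.0]),
                klass="nonpolar", ionizable_sign=0, pKa_water=None))
        chain = CGStructure(residues)
        _, main_hb = main_energy(chain, EMPTY_GRID, cfg)
        assert main_hb == 0.0

    def test_isolated_residue_not_buried(self, cfg):
        cg = make_titration_system([[0, 0, 50]], ["ASP"])
        main_solv, _ = main_energy(cg, EMPTY_GRID, cfg)
        assert main_solv == 0.0

    def test_membrane_burial_penalty(self, cfg):
        helix = make_helix(HelixSpec(sequence="A" * 10))
        grid = build_grid(helix, GridConfig())
        solv_mem, _ = main_energy(helix, grid, cfg)
        solv_free, _ = main_energy(helix, EMPTY_GRID, cfg)
        assert solv_mem > solv_free == 0.0


class TestMainSide:
    def test_all_neutral_no_elec(self, cfg):
        helix = make_helix(HelixSpec(sequence="ALSA"))
        ms_elec, _ = main_side_energy(helix, [], cfg)
        assert ms_elec == 0.0

    def test_charge_near_lone_oxygen(self, cfg):
        # one charged side particle 5 A from a backbone O of another chain
        res1 = CGResidue(
            key=("A", 1, " "), name="ASP",
            backbone={"CA": np.array([0.0, 0.0, 300.0])},
            side_particle=np.array([0.0, 0.0, 0.0]),
            klass="ionizable", ionizable_sign=-1, pKa_water=3.9)
        res2 = CGResidue(
            key=("B", 1, " "), name="ALA",
            backbone={"O": np.array([5.0, 0.0, 0.0])},
            side_particle=np.array([200.0, 0.0, 0.0]),
            klass="nonpolar", ionizable_sign=0, pKa_water=None)
        cg = CGStructure([res1, res2])
        ms_elec, _ = main_side_energy(cg, [-1.0], cfg)
        expected = 332.0637 * (-1.0) * (-0.4) / (40.0 * 5.0)
        assert ms_elec == pytest.approx(expected)
        assert ms_elec == pytest.approx(0.664, abs=5e-4)

    def test_far_side_particle_contributes_nothing(self, cfg):
        res1 = CGResidue(
            key=("A", 1, " "), name="ASP",
            backbone={"CA": np.array([0.0, 0.0, 300.0])},
            side_particle=np.array([0.0, 0.0, 0.0]),
            klass="ionizable", ionizable_sign=-1, pKa_water=3.9)
        res2 = CGResidue(
            key=("B", 1, " "), name="ALA",
            backbone={"O": np.array([50.0, 0.0, 0.0]),
                      "N": np.array([52.0, 0.0, 0.0])},
            side_particle=np.array([200.0, 0.0, 0.0]),
            klass="nonpolar", ionizable_sign=0, pKa_water=None)
        cg = CGStructure([res1, res2])
        ms_elec, ms_vdw = main_side_energy(cg, [-1.0], cfg)
        assert ms_elec == 0.0
        # only res2's own side particle is near its backbone, and
        # same-residue pairs are excluded
        assert ms_vdw == 0.0


class TestTotalEnergy:
    def test_empty_structure_all_zero(self, cfg):
        bd = total_energy(CGStructure([]), EMPTY_GRID, 7.0, cfg)
        assert bd.total == 0.0
        assert all(v == 0.0 for v in bd.as_dict().values())

    def test_decomposition_identity(self, cfg):
        helix = make_helix(HelixSpec(sequence="ADKLSTGAVE"))
        grid = build_grid(helix, GridConfig())
        bd = total_energy(helix, grid, 7.0, cfg)
        assert bd.total == pytest.approx(bd.recompose(cfg), abs=1e-9)

    def test_isometry_invariance(self, cfg):
        helix = make_helix(HelixSpec(sequence="ADKLSTGAVE"))
        grid = build_grid(helix, GridConfig())
        ref = total_energy(helix, grid, 7.0, cfg).total
        rot = Rotation.from_euler("xyz", [31, -57, 123],
                                  degrees=True).as_matrix()
        shift = np.array([3.7, -11.2, 8.8])
        moved = helix.transformed(rotation=rot, translation=shift)
        moved_grid = grid.rotated(rot).translated(shift)
        out = total_energy(moved, moved_grid, 7.0, cfg).total
        assert out == pytest.approx(ref, abs=1e-8)

    def test_extensivity_of_far_copies(self, cfg):
        a = make_helix(HelixSpec(sequence="ADKLSTGAVE"))
        b = make_helix(HelixSpec(sequence="ADKLSTGAVE", chain="B",
                                 origin=(60.0, 0.0, 0.0)))
        both = CGStructure(a.residues + b.residues)
        gc = GridConfig()
        e_single = total_energy(a, build_grid(a, gc), 7.0, cfg).total
        e_single_b = total_energy(b, build_grid(b, gc), 7.0, cfg).total
        e_both = total_energy(both, build_grid(both, gc), 7.0, cfg).total
        assert e_single_b == pytest.approx(e_single, abs=1e-6)
        assert e_both == pytest.approx(2 * e_single, abs=1e-6)

    def test_screening_limit_recovers_henderson_hasselbalch(self):
        # with infinite dielectric and no self-energy slopes the side-chain
        # electrostatics vanish and titration is pure Henderson-Hasselbalch
        cfg0 = EnergyConfig(eps_eff=1e12, a_np=0.0, a_p=0.0, a_mem=0.0)
        cg = make_titration_system([[0, 0, 0], [6, 0, 0]], ["ASP", "LYS"])
        grid = build_grid(cg, GridConfig())
        sites = sites_from_structure(cg, grid, cfg0)
        for s in sites:
            assert s.pKa_intrinsic == pytest.approx(s.pKa_water)
        import math
        titr = exact_titration(sites, 7.0, cfg0)
        # two-state closed form with the model's 2.3RT convention
        hh_asp = -1.0 / (1.0 + math.exp(2.3 * (3.9 - 7.0)))
        hh_lys = 1.0 / (1.0 + math.exp(2.3 * (7.0 - 10.5)))
        assert titr.mean_charge[0] == pytest.approx(hh_asp, abs=1e-9)
        assert titr.mean_charge[1] == pytest.approx(hh_lys, abs=1e-9)
        value, _ = side_elec(cg, grid, titr, cfg0, sites=sites)
        assert value == pytest.approx(0.0, abs=1e-9)
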