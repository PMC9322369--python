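import math

import numpy as np
import pytest

from memcg import (
    EnergyConfig,
    GridConfig,
    MCConfig,
    build_grid,
    config_energy,
    exact_titration,
    intrinsic_pka,
    mcpt_sample,
    sites_from_structure,
    titration_curve,
)
from memcg.membrane import MembraneGrid, NeighborCounts
from memcg.titration import IonizableSite
from memcg.synthetic import make_titration_system

LN10RT = 2.3 * 0.0019872 * 300.0  # 1.3712 kcal/mol


def hh_charge(sign, pka, ph):
    """Two-state charge fraction with the model's 2.3RT convention (close
    to, but not exactly, a base-10 Henderson-Hasselbalch curve)."""
    exponent = 2.3 * (pka - ph) if sign < 0 else 2.3 * (ph - pka)
    return sign / (1.0 + math.exp(exponent))


def isolated_site(sign=-1, pka=4.0):
    return IonizableSite(0, np.zeros(3), sign, pka, pka)


def free_sites(positions, signs, pkas):
    return [
        IonizableSite(i, np.asarray(p, dtype=float), s, k, k)
        for i, (p, s, k) in enumerate(zip(positions, signs, pkas))
    ]


class TestIntrinsicPka:
    def test_no_environment_no_shift(self, cfg):
        site = IonizableSite(0, np.zeros(3), -1, 3.9)
        assert intrinsic_pka(site, NeighborCounts(0, 0, 0), cfg) == 3.9

    def test_acid_shift_is_one_unit_per_2p3rt(self, cfg):
        # 10 membrane neighbours at 0.20 kcal/mol each = 2.0 kcal/mol
        site = IonizableSite(0, np.zeros(3), -1, 3.9)
        shift = intrinsic_pka(site, NeighborCounts(0, 0, 10), cfg) - 3.9
        assert shift == pytest.approx(2.0 / LN10RT)

    def test_base_shift_has_opposite_sign(self, cfg):
        acid = IonizableSite(0, np.zeros(3), -1, 4.0)
        base = IonizableSite(0, np.zeros(3), +1, 10.0)
        nc = NeighborCounts(0, 0, 10)
        up = intrinsic_pka(acid, nc, cfg) - 4.0
        down = intrinsic_pka(base, nc, cfg) - 10.0
        assert up == pytest.approx(-down)
        assert up > 0

    def test_saturation_caps_counts(self, cfg):
        site = IonizableSite(0, np.zeros(3), -1, 4.0)
        s30 = intrinsic_pka(site, NeighborCounts(30, 0, 0), cfg)
        s20 = intrinsic_pka(site, NeighborCounts(20, 0, 0), cfg)
        assert s30 == s20 == pytest.approx(4.0 + 0.05 * 20 / LN10RT)


class TestConfigEnergy:
    def test_all_neutral_is_zero(self, cfg):
        sites = free_sites([[0, 0, 0], [5, 0, 0]], [-1, 1], [4.0, 10.0])
        assert config_energy(sites, [0.0, 0.0], 7.0, cfg) == 0.0

    def test_single_acid_closed_form(self, cfg):
        e = config_energy([isolated_site(-1, 4.0)], [-1.0], 7.0, cfg)
        assert e == pytest.approx(-LN10RT * (-1) * (4.0 - 7.0))
        assert e == pytest.approx(-4.114, abs=5e-4)

    def test_vanishes_at_ph_equal_pka(self, cfg):
        assert config_energy([isolated_site(-1, 4.0)], [-1.0], 4.0,
                             cfg) == 0.0

    def test_coupling_follows_coulomb(self, cfg):
        sites = free_sites([[0, 0, 0], [10, 0, 0]], [+1, -1], [7.0, 7.0])
        e = config_energy(sites, [1.0, -1.0], 7.0, cfg)
        assert e == pytest.approx(332.0637 * (-1.0) / (40.0 * 10.0))


class TestExactTitration:
    def test_half_charge_at_pka(self, cfg):
        res = exact_titration([isolated_site(-1, 4.0)], 4.0, cfg)
        assert res.mean_charge[0] == pytest.approx(-0.5)

    def test_closed_form_away_from_pka(self, cfg):
        res = exact_titration([isolated_site(-1, 9.0)], 4.0, cfg)
        assert res.mean_charge[0] == pytest.approx(hh_charge(-1, 9.0, 4.0))
        # five units below the pKa the acid is essentially neutral
        assert abs(res.mean_charge[0]) < 2e-5

    def test_base_henderson_hasselbalch(self, cfg):
        res = exact_titration([isolated_site(+1, 10.5)], 7.0, cfg)
        assert res.mean_charge[0] == pytest.approx(
            hh_charge(+1, 10.5, 7.0), abs=1e-9)
        assert res.mean_charge[0] == pytest.approx(0.99968, abs=1e-3)

    def test_site_limit_enforced(self, cfg):
        sites = free_sites(np.random.default_rng(0).uniform(0, 50, (17, 3)),
                           [-1] * 17, [4.0] * 17)
        with pytest.raises(ValueError):
            exact_titration(sites, 7.0, cfg)

    def test_acid_pair_anticooperative(self, cfg):
        # charging both acids costs +dG_QQ, so each titrates late
        pair = free_sites([[0, 0, 0], [5, 0, 0]], [-1, -1], [4.0, 4.0])
        lone = [isolated_site(-1, 4.0)]
        at_pka_pair = exact_titration(pair, 4.0, cfg)
        at_pka_lone = exact_titration(lone, 4.0, cfg)
        assert abs(at_pka_pair.mean_charge[0]) < \
            abs(at_pka_lone.mean_charge[0])
        assert at_pka_pair.mean_charge[0] == pytest.approx(
            at_pka_pair.mean_charge[1])


class TestMcptSample:
    def test_isolated_acid_half_charge_within_error(self, cfg, mc_cfg):
        res = mcpt_sample([isolated_site(-1, 4.0)], 4.0, mc_cfg, cfg)
        err = max(3 * res.charge_sd[0], 0.02)
        assert res.mean_charge[0] == pytest.approx(-0.5, abs=err)

    def test_base_nearly_fully_charged(self, cfg, mc_cfg):
        res = mcpt_sample([isolated_site(+1, 10.5)], 7.0, mc_cfg, cfg)
        assert res.mean_charge[0] == pytest.approx(0.99968, abs=0.01)

    def test_symmetric_pair_matches_oracle(self, cfg, mc_cfg):
        pair = free_sites([[0, 0, 0], [5, 0, 0]], [-1, -1], [4.0, 4.0])
        mc = mcpt_sample(pair, 4.0, mc_cfg.replace(n_production=30000), cfg)
        ex = exact_titration(pair, 4.0, cfg)
        assert np.allclose(mc.mean_charge, ex.mean_charge, atol=0.02)
        assert mc.mean_charge[0] == pytest.approx(mc.mean_charge[1],
                                                  abs=0.03)

    def test_seed_reproducibility_bit_identical(self, cfg, mc_cfg):
        sites = free_sites([[0, 0, 0], [4, 0, 0], [0, 5, 2]],
                           [-1, +1, -1], [4.0, 10.5, 5.5])
        a = mcpt_sample(sites, 7.0, mc_cfg, cfg)
        b = mcpt_sample(sites, 7.0, mc_cfg, cfg)
        assert np.array_equal(a.mean_charge, b.mean_charge)
        assert a.g_elec == b.g_elec and a.qq_mean == b.qq_mean

    def test_boltzmann_ratio_two_state(self, cfg):
        # detailed balance: occupancy ratio of the two states of one acid
        # must match the Boltzmann factor
        site = [isolated_site(-1, 4.5)]
        mc = MCConfig(seed=11, n_burn_in=1000, n_production=80000,
                      pair_move_fraction=0.0)
        res = mcpt_sample(site, 4.0, mc, cfg)
        p_charged = abs(res.mean_charge[0])
        expected = abs(hh_charge(-1, 4.5, 4.0))
        assert p_charged == pytest.approx(expected, abs=0.01)

    def test_zero_production_rejected(self, cfg):
        with pytest.raises(ValueError):
            MCConfig(n_production=0)

    @pytest.mark.parametrize("sign,pka", [(-1, 5.0), (+1, 9.0)])
    def test_charge_magnitude_monotone_in_ph(self, cfg, sign, pka):
        site = [isolated_site(sign, pka)]
        qs = [exact_titration(site, ph, cfg).mean_charge[0]
              for ph in np.arange(2.0, 13.0, 0.5)]
        qs = np.asarray(qs)
        diffs = np.diff(qs)
        # acids grow more negative, bases less positive: both non-increasing
        assert np.all(diffs <= 1e-12)


class TestTitrationCurve:
    def test_recovers_intrinsic_pka(self, cfg):
        for sign, pka in ((-1, 3.9), (+1, 10.5)):
            grid = np.arange(pka - 3, pka + 3.001, 0.1)
            pka_app, _ = titration_curve([isolated_site(sign, pka)], grid,
                                         cfg)
            assert abs(pka_app[0] - pka) <= 0.05

    def test_repulsive_pair_shifts_apparent_pka_up(self, cfg):
        pair = free_sites([[0, 0, 0], [4, 0, 0]], [-1, -1], [4.0, 4.0])
        grid = np.arange(2.0, 8.001, 0.1)
        pka_app, _ = titration_curve(pair, grid, cfg)
        assert np.nanmax(pka_app) > 4.0

    def test_no_crossing_warns_and_is_nan(self, cfg):
        grid = np.arange(10.0, 12.0, 0.1)  # acid fully charged here
        with pytest.warns(UserWarning):
            pka_app, curves = titration_curve([isolated_site(-1, 4.0)],
                                              grid, cfg)
        assert math.isnan(pka_app[0])
        assert np.all(np.abs(curves) > 0.99)


class TestSitesFromStructure:
    def test_membrane_burial_shifts_intrinsic_pka(self, cfg):
        bulk = make_titration_system([[0, 0, 50]], ["LYS"])
        buried = make_titration_system([[0, 0, 0]], ["LYS"])
        gc = GridConfig()
        s_bulk = sites_from_structure(bulk, build_grid(bulk, gc), cfg)
        s_buried = sites_from_structure(buried, build_grid(buried, gc), cfg)
        assert s_bulk[0].pKa_intrinsic == pytest.approx(10.5)
        # base in the membrane titrates earlier (easier to neutralise)
        assert s_buried[0].pKa_intrinsic < 10.5 - 2.0
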