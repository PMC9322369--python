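import numpy as np
import pytest

from memcg import EnergyConfig, GridConfig, MCConfig


@pytest.fixture(scope="session")
def cfg() -> EnergyConfig:
    return EnergyConfig()


@pytest.fixture(scope="session")
def grid_cfg() -> GridConfig:
    return GridConfig()


@pytest.fixture()
def mc_cfg() -> MCConfig:
    return MCConfig(seed=7, n_burn_in=500, n_production=5000)


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, altloc=" ",
                  element=None, record="ATOM  "):
    """Format one fixed-column PDB ATOM/HETATM record for fixtures."""
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def make_residue_lines(resname, chain, resseq, origin, serial_start=1,
                       side_atoms=()):
    """A complete backbone (N, CA, C, O) plus optional side-chain atoms."""
    ox, oy, oz = origin
    atoms = [
        ("N", (ox - 1.46, oy, oz)),
        ("CA", (ox, oy, oz)),
        ("C", (ox + 1.52, oy, oz)),
        ("O", (ox + 1.52, oy + 1.23, oz)),
    ] + list(side_atoms)
    lines = []
    for k, (name, xyz) in enumerate(atoms):
        lines.append(pdb_atom_line(serial_start + k, name, resname, chain,
                                   resseq, xyz))
    return lines


@pytest.fixture()
def two_residue_pdb(tmp_path):
    """ALA + GLY, 9 atoms total, one CB side-chain atom."""
    lines = make_residue_lines(
        "ALA", "A", 1, (0.0, 0.0, 0.0),
        side_atoms=[("CB", (0.0, -1.53, 0.0))])
    lines += make_residue_lines("GLY", "A", 2, (0.0, 0.0, 3.8),
                                serial_start=len(lines) + 1)
    path = tmp_path / "two_res.pdb"
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
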