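"""All-atom input structures and the united-side-chain coarse-grained model.

Each residue keeps its backbone atoms explicitly (N, CA, C, O, optional amide
H) and collapses its side chain to a single particle at the heavy-atom
centroid. Residues are classified as nonpolar, polar, or ionizable; ionizable
residues carry an acid/base sign and an intrinsic water pKa.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .config import EnergyConfig
from .constants import BACKBONE_ATOMS, IONIZABLE_SIGNS, STANDARD_RESIDUES

ResidueKey = tuple  # (chain id, residue number, insertion code)


class StructureError(ValueError):
    """Raised for malformed or empty structural input."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray


@dataclass
class AllAtomModel:
    """Parsed all-atom structure: ordered residues with their atoms."""

    residues: list  # of (key, resname, {atom name: Atom})

    def __len__(self):
        return len(self.residues)

    @property
    def chains(self):
        seen = []
        for key, _, _ in self.residues:
            if key[0] not in seen:
                seen.append(key[0])
        return seen


@dataclass
class CGResidue:
    key: ResidueKey
    name: str
    backbone: dict  # atom name -> np.ndarray (A)
    side_particle: np.ndarray | None
    klass: str
    ionizable_sign: int
    pKa_water: float | None

    def copy(self) -> "CGResidue":
        return CGResidue(
            key=self.key,
            name=self.name,
            backbone={k: v.copy() for k, v in self.backbone.items()},
            side_particle=None if self.side_particle is None
            else self.side_particle.copy(),
            klass=self.klass,
            ionizable_sign=self.ionizable_sign,
            pKa_water=self.pKa_water,
        )


@dataclass
class CGStructure:
    residues: list  # of CGResidue, ordered by key
    label: str = ""

    def __len__(self):
        return len(self.residues)

    def copy(self) -> "CGStructure":
        return CGStructure([r.copy() for r in self.residues], self.label)

    def particles(self) -> np.ndarray:
        """All particle coordinates (backbone atoms + side particles)."""
        coords = []
        for r in self.residues:
            coords.extend(r.backbone.values())
            if r.side_particle is not None:
                coords.append(r.side_particle)
        if not coords:
            return np.zeros((0, 3))
        return np.asarray(coords)

    def ionizable_indices(self) -> list:
        return [
            i for i, r in enumerate(self.residues)
            if r.klass == "ionizable" and r.side_particle is not None
        ]

    def transformed(self, rotation=None, translation=None) -> "CGStructure":
        """Rigidly transform all particles (rotation applied first)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation)
        tr = np.zeros(3) if translation is None else np.asarray(translation)
        out = self.copy()
        for r in out.residues:
            for name in r.backbone:
                r.backbone[name] = rot @ r.backbone[name] + tr
            if r.side_particle is not None:
                r.side_particle = rot @ r.side_particle + tr
        return out

    def validate(self, min_separation: float = 0.01):
        """Check ordering and the degenerate-coordinate guard."""
        keys = [r.key for r in self.residues]
        if keys != sorted(keys):
            raise StructureError("residues are not ordered by key")
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate residue keys")
        pts = self.particles()
        if len(pts) > 1:
            from scipy.spatial import cKDTree

            tree = cKDTree(pts)
            pairs = tree.query_pairs(min_separation)
            if pairs:
                raise StructureError(
                    f"{len(pairs)} particle pairs closer than "
                    f"{min_separation} A"
                )


@dataclass
class ResidueMatch:
    pairs: list = field(default_factory=list)  # (index in a, index in b)
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    def coverage(self, n_a: int, n_b: int) -> float:
        if max(n_a, n_b) == 0:
            return 1.0
        return len(self.pairs) / max(n_a, n_b)


def read_pdb(path) -> AllAtomModel:
    """Parse a fixed-column PDB file into an :class:`AllAtomModel`.

    First MODEL only; altloc 'A' or blank kept; HETATM records ignored unless
    they carry a standard residue name; residues without a CA are dropped.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("model", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed text
        raise StructureError(f"unreadable PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise StructureError(f"no ATOM records in {path}")
    model = models[0]

    residues = []
    for chain in model:
        for res in chain:
            hetfield, resseq, icode = res.id
            resname = res.get_resname().strip()
            if hetfield not in (" ", "") and resname not in STANDARD_RESIDUES:
                continue
            atoms = {}
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                name = atom.get_name().strip()
                if name in atoms:
                    continue
                element = (atom.element or "").strip() or name[:1]
                atoms[name] = Atom(name, element, np.asarray(
                    atom.get_coord(), dtype=float))
            if "CA" not in atoms:
                continue
            key = (chain.id, int(resseq), icode.strip() or " ")
            residues.append((key, resname, atoms))

    if not residues:
        raise StructureError(f"no usable residues (with CA) in {path}")
    residues.sort(key=lambda item: item[0])
    return AllAtomModel(residues)


def _classify(name: str, config: EnergyConfig):
    klass = config.residue_classes.get(name)
    if klass is None:
        raise StructureError(f"residue type {name} not in the class table")
    if klass == "ionizable":
        sign = IONIZABLE_SIGNS.get(name)
        if sign is None:
            raise StructureError(
                f"ionizable residue {name} has no acid/base sign")
        pka = config.pka_water.get(name)
        if pka is None:
            raise StructureError(f"ionizable residue {name} has no water pKa")
        if not 0.0 <= pka <= 14.0:
            raise StructureError(f"water pKa {pka} for {name} out of [0, 14]")
        return klass, sign, pka
    return klass, 0, None


def coarse_grain(model: AllAtomModel, config: EnergyConfig | None = None,
                 label: str = "") -> CGStructure:
    """Map an all-atom model to the coarse-grained representation.

    The side particle is the geometric centroid of the side-chain heavy atoms
    (CB and beyond); glycine has none. Backbone N, CA, C, O are required
    (missing O tolerated on the final residue of a chain).
    """
    config = config or EnergyConfig()
    cg_residues = []
    n = len(model.residues)
    for idx, (key, resname, atoms) in enumerate(model.residues):
        is_chain_end = (
            idx == n - 1 or model.residues[idx + 1][0][0] != key[0]
        )
        backbone = {}
        for name in BACKBONE_ATOMS:
            if name in atoms:
                backbone[name] = atoms[name].xyz.copy()
        missing = [a for a in ("N", "CA", "C", "O") if a not in backbone]
        if missing == ["O"] and is_chain_end:
            missing = []
        if missing:
            raise StructureError(
                f"residue {resname} {key} missing backbone atoms {missing}")

        side = [
            a.xyz for name, a in atoms.items()
            if name not in BACKBONE_ATOMS and name != "OXT"
            and not a.element.upper().startswith("H")
        ]
        if resname == "GLY" or not side:
            side_particle = None if resname == "GLY" else None
        else:
            side_particle = np.mean(np.asarray(side), axis=0)
        if resname != "GLY" and side_particle is None:
            # side chain entirely missing from the input; fall back to CA so
            # the residue still carries a particle
            side_particle = backbone["CA"].copy()

        klass, sign, pka = _classify(resname, config)
        cg_residues.append(CGResidue(
            key=key, name=resname, backbone=backbone,
            side_particle=side_particle, klass=klass,
            ionizable_sign=sign, pKa_water=pka,
        ))
    cg = CGStructure(cg_residues, label=label)
    cg.validate()
    return cg


def mutate_residue(cg: CGStructure, key: ResidueKey, new_name: str,
                   config: EnergyConfig | None = None) -> CGStructure:
    """Return a copy with one residue retyped; coordinates are retained
    (removed for X -> GLY)."""
    config = config or EnergyConfig()
    if new_name not in config.residue_classes:
        raise KeyError(f"unknown residue type {new_name}")
    out = cg.copy()
    for res in out.residues:
        if res.key == tuple(key):
            klass, sign, pka = _classify(new_name, config)
            res.name = new_name
            res.klass = klass
            res.ionizable_sign = sign
            res.pKa_water = pka
            if new_name == "GLY":
                res.side_particle = None
            elif res.side_particle is None:
                res.side_particle = res.backbone["CA"].copy()
            return out
    raise KeyError(f"no residue with key {key}")


def match_residues(a: CGStructure, b: CGStructure,
                   mutation_map: dict | None = None) -> ResidueMatch:
    """Pair residues with identical keys and names across two conformations.

    ``mutation_map`` maps residue keys to (name in a, name in b) pairs that
    are allowed to differ (declared mutations).
    """
    mutation_map = mutation_map or {}
    index_b = {res.key: j for j, res in enumerate(b.residues)}
    match = ResidueMatch()
    used_b = set()
    for i, res in enumerate(a.residues):
        j = index_b.get(res.key)
        if j is None:
            match.unmatched_a.append(i)
            continue
        other = b.residues[j]
        names_ok = res.name == other.name
        if not names_ok and res.key in mutation_map:
            expect_a, expect_b = mutation_map[res.key]
            names_ok = res.name == expect_a and other.name == expect_b
        if names_ok:
            match.pairs.append((i, j))
            used_b.add(j)
        else:
            match.unmatched_a.append(i)
    match.unmatched_b = [j for j in range(len(b)) if j not in used_b]
    return match


def _format_atom_line(serial, name, resname, chain, resseq, icode, xyz,
                      element):
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}{icode:1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_cg_pdb(cg: CGStructure, path):
    """Write a CG structure as PDB: backbone atoms plus SC1 pseudo-atoms.

    Round-trips through :func:`read_pdb` + :func:`coarse_grain` to within
    1e-3 A (PDB coordinate precision).
    """
    if len(cg) == 0:
        raise StructureError("refusing to write an empty structure")
    lines = []
    serial = 1
    for res in cg.residues:
        chain, resseq, icode = res.key
        icode = icode if icode.strip() else " "
        for name in BACKBONE_ATOMS:
            if name in res.backbone:
                lines.append(_format_atom_line(
                    serial, name, res.name, chain, resseq, icode,
                    res.backbone[name], name[0]))
                serial += 1
        if res.side_particle is not None:
            lines.append(_format_atom_line(
                serial, "SC1", res.name, chain, resseq, icode,
                res.side_particle, "C"))
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
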