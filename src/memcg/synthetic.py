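"""Synthetic membrane-protein structures with known ground truth.

Generators for ideal transmembrane α-helices, two-state helix bundles whose
end states differ by one helix motion, small clusters of ionizable sites
with enumerable titration ensembles, and a membrane-burial barrier fixture
in which a single charged side chain crosses the slab along the morph. All
generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import EnergyConfig
from .constants import AA1_TO_3, CA_TO_SIDE_CENTROID
from .structures import CGResidue, CGStructure, StructureError, _classify

# Cylindrical placement (radius A, phase rad, z A) of each backbone atom of
# an ideal alpha-helix with rise 1.5 A and twist 100 deg, fit once by least
# squares to bond lengths N-CA 1.46, CA-C 1.52, C-O 1.23, C-N(+1) 1.33 and
# the (i, i+4) N-O hydrogen bond at 2.95 A, with the (i, i+3) N-O contact
# pushed beyond 3.6 A so only the canonical i+4 bonds fall in the 3.0-3.5 A
# window.
HELIX_BACKBONE_OFFSETS = {
    "N": (1.850536464, -0.541175053, -0.861637972),
    "CA": (2.3, 0.0, 0.0),
    "C": (1.854149059, 0.501776529, 1.040608448),
    "O": (2.087352270, 0.470005041, 2.253957114),
}


@dataclass
class HelixSpec:
    sequence: str
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (0.0, 0.0, 1.0)
    chain: str = "A"
    first_residue: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be positive")


@dataclass
class TwoStateSpec:
    n_helices: int = 4
    n_residues: int = 24
    bundle_radius: float = 10.0
    moving_helix: int = 0
    tilt_delta: float = 15.0
    seed: int = 0
    sequences: list = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.moving_helix < self.n_helices:
            raise ValueError("moving_helix out of range")
        if self.tilt_delta < 0:
            raise ValueError("tilt_delta must be >= 0")


def _rotation_to(direction) -> np.ndarray:
    """Rotation matrix taking the z axis onto ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def make_helix(spec: HelixSpec,
               config: EnergyConfig | None = None) -> CGStructure:
    """Ideal α-helix CG structure from a one-letter sequence.

    Backbone atoms follow the frozen cylindrical offsets (scaled to the
    requested radius relative to the canonical 2.3 A); side particles sit
    radially outward from CA at a per-residue-type distance.
    """
    config = config or EnergyConfig()
    twist = math.radians(spec.twist_per_residue)
    rot = _rotation_to(spec.direction)
    origin = np.asarray(spec.origin, dtype=float)
    radius_scale = spec.radius / HELIX_BACKBONE_OFFSETS["CA"][0]

    residues = []
    for k, letter in enumerate(spec.sequence):
        name = AA1_TO_3.get(letter.upper())
        if name is None:
            raise StructureError(f"unknown residue letter {letter!r}")
        backbone = {}
        for atom, (r, phi, dz) in HELIX_BACKBONE_OFFSETS.items():
            a = k * twist + phi
            local = np.array([
                radius_scale * r * math.cos(a),
                radius_scale * r * math.sin(a),
                k * spec.rise_per_residue + dz,
            ])
            backbone[atom] = rot @ local + origin
        if name == "GLY":
            side = None
        else:
            dist = CA_TO_SIDE_CENTROID.get(name, 2.0)
            a = k * twist
            local = np.array([
                (spec.radius + dist) * math.cos(a),
                (spec.radius + dist) * math.sin(a),
                k * spec.rise_per_residue,
            ])
            side = rot @ local + origin
        klass, sign, pka = _classify(name, config)
        residues.append(CGResidue(
            key=(spec.chain, spec.first_residue + k, " "),
            name=name, backbone=backbone, side_particle=side,
            klass=klass, ionizable_sign=sign, pKa_water=pka,
        ))
    cg = CGStructure(residues, label=f"helix-{spec.chain}")
    cg.validate()
    return cg


_MEMBRANE_ALPHABET = "AVLIFMS"  # nonpolar-dominated with occasional SER


def _default_bundle_sequences(spec: TwoStateSpec) -> list:
    """Deterministic membrane-like sequences; the moving helix carries one
    lysine and one glutamate near its ends so charge effects are exercised
    while the total ionizable count stays enumerable."""
    rng = np.random.default_rng(spec.seed)
    seqs = []
    for h in range(spec.n_helices):
        letters = rng.choice(list(_MEMBRANE_ALPHABET), size=spec.n_residues)
        seq = list("".join(letters))
        if h == spec.moving_helix and spec.n_residues >= 6:
            seq[1] = "E"
            seq[-2] = "K"
        seqs.append("".join(seq))
    return seqs


def make_two_state_bundle(spec: TwoStateSpec,
                          config: EnergyConfig | None = None):
    """Two end states of a parallel helix bundle differing by one helix tilt.

    State A: ``n_helices`` ideal helices on a circle, axes along z, centred
    on the membrane slab (z = 0). State B: identical except the moving helix
    is tilted by ``tilt_delta`` degrees about the tangential axis through
    its own midpoint. Residue keys are identical across states.
    """
    config = config or EnergyConfig()
    sequences = spec.sequences or _default_bundle_sequences(spec)
    if len(sequences) != spec.n_helices:
        raise ValueError("need one sequence per helix")

    z0 = -(spec.n_residues - 1) * 1.5 / 2.0
    helices = []
    for h, seq in enumerate(sequences):
        angle = 2.0 * math.pi * h / spec.n_helices
        origin = (spec.bundle_radius * math.cos(angle),
                  spec.bundle_radius * math.sin(angle), z0)
        helices.append(make_helix(
            HelixSpec(sequence=seq, origin=origin,
                      chain=chr(ord("A") + h)), config))

    def merged(hs, label):
        residues = [r for h in hs for r in h.residues]
        cg = CGStructure(residues, label=label)
        cg.validate()
        return cg

    state_a = merged(helices, "state-A")

    mh = helices[spec.moving_helix].copy()
    angle = 2.0 * math.pi * spec.moving_helix / spec.n_helices
    center = np.array([spec.bundle_radius * math.cos(angle),
                       spec.bundle_radius * math.sin(angle), 0.0])
    tangent = np.array([-math.sin(angle), math.cos(angle), 0.0])
    theta = math.radians(spec.tilt_delta)
    k = tangent
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)
    mh = mh.transformed(rotation=np.eye(3), translation=-center)
    mh = mh.transformed(rotation=rot, translation=center)

    moved = list(helices)
    moved[spec.moving_helix] = mh
    state_b = merged(moved, "state-B")
    return state_a, state_b


def _backbone_stub(center: np.ndarray) -> dict:
    """Minimal planar backbone tetrad around a CA position."""
    return {
        "N": center + np.array([-1.46, 0.0, 0.0]),
        "CA": center.copy(),
        "C": center + np.array([1.52, 0.0, 0.0]),
        "O": center + np.array([1.52, 1.23, 0.0]),
    }


def make_titration_system(positions, names,
                          config: EnergyConfig | None = None) -> CGStructure:
    """One-residue-per-site structure with side particles at the given
    positions and backbone stubs parked far away (40 A spacing), so only
    side-side electrostatics couple the sites."""
    config = config or EnergyConfig()
    if len(positions) != len(names):
        raise ValueError("positions and names must have the same length")
    if len(positions) == 0:
        raise StructureError("empty titration system")
    residues = []
    zs = [float(p[2]) for p in positions]
    stub_z0 = max(zs) + 200.0
    for i, (pos, name) in enumerate(zip(positions, names)):
        pos = np.asarray(pos, dtype=float)
        if name == "GLY":
            raise StructureError("titration sites need a side particle")
        stub_center = np.array([float(pos[0]), float(pos[1]),
                                stub_z0 + 40.0 * i])
        klass, sign, pka = _classify(name, config)
        residues.append(CGResidue(
            key=("A", i + 1, " "), name=name,
            backbone=_backbone_stub(stub_center),
            side_particle=pos, klass=klass, ionizable_sign=sign,
            pKa_water=pka,
        ))
    cg = CGStructure(residues, label="titration-system")
    cg.validate()
    return cg


def embed_in_membrane(cg: CGStructure, z_offset: float) -> CGStructure:
    """Translate the structure so its particle centroid sits at
    (0, 0, z_offset) in the slab frame (slab normal = z)."""
    pts = cg.particles()
    if len(pts) == 0:
        return cg.copy()
    centroid = pts.mean(axis=0)
    shift = np.array([0.0, 0.0, z_offset]) - centroid
    return cg.transformed(translation=shift)


def make_burial_barrier_fixture(config: EnergyConfig | None = None):
    """End states in which one charged side chain crosses the membrane slab.

    Three static nonpolar helices span the slab; a separate single-residue
    LYS arm sits in bulk water above the slab in state A (side particle
    z = +28) and below it in state B (z = -28), far enough laterally from
    the bundle that it only feels the membrane. Linear morphing therefore
    drives the charged particle through the slab centre at the mid-frame,
    where its desolvation self-energy peaks — an activation barrier whose
    origin is analytically explainable. Returns (state_a, state_b, info)
    where info names the charged residue key and a distal control key.
    """
    config = config or EnergyConfig()
    helices = []
    seq = "AVLIAVLIAVLIAVLIAVLIAVLI"  # 24 nonpolar residues, spans the slab
    z0 = -(len(seq) - 1) * 1.5 / 2.0
    for h, angle_deg in enumerate((60.0, 180.0, 300.0)):
        angle = math.radians(angle_deg)
        origin = (8.0 * math.cos(angle), 8.0 * math.sin(angle), z0)
        helices.append(make_helix(
            HelixSpec(sequence=seq, origin=origin,
                      chain=chr(ord("A") + h)), config))

    def with_arm(z_arm: float, label: str) -> CGStructure:
        arm_side = np.array([14.0, 0.0, z_arm])
        klass, sign, pka = _classify("LYS", config)
        arm = CGResidue(
            key=("X", 1, " "), name="LYS",
            backbone=_backbone_stub(arm_side + np.array([3.5, 0.0, 0.0])),
            side_particle=arm_side, klass=klass, ionizable_sign=sign,
            pKa_water=pka,
        )
        residues = [r for hx in helices for r in hx.residues] + [arm]
        cg = CGStructure([r.copy() for r in residues], label=label)
        cg.validate()
        return cg

    info = {
        "charged_key": ("X", 1, " "),
        # mid-height residue on the helix opposite the arm
        "distal_key": ("B", 12, " "),
        "z_arm": 28.0,
    }
    return with_arm(28.0, "arm-up"), with_arm(-28.0, "arm-down"), info
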