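"""Periodic molecular configurations with per-atom roles.

A :class:`Configuration` is a single orthorhombic periodic snapshot of
simplified chiral molecules.  Each molecule carries a chirality label
(R or S) and atoms tagged with the roles the downstream analyses need:
the carboxylic donor pair (O_hydroxyl, H_hydroxyl), the carbonyl acceptor
(O_carbonyl), the ring fluorine (F), the ring carbon bearing it
(C_ring_F) and the remaining five ring carbons (C_ring).

Coordinates are stored in angstrom.  File format: extended XYZ with a
``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"`` comment line and per-atom columns
``element x y z mol_id role chirality``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ROLES = ("O_hydroxyl", "H_hydroxyl", "O_carbonyl", "F", "C_ring_F", "C_ring", "other")
_REQUIRED_ROLE_COUNTS = {
    "O_hydroxyl": 1, "H_hydroxyl": 1, "O_carbonyl": 1,
    "F": 1, "C_ring_F": 1, "C_ring": 5,
}


@dataclass
class Atom:
    element: str
    role: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown atom role {self.role!r}")
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be 3 finite reals")


@dataclass
class Molecule:
    molecule_id: int
    chirality: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.chirality not in ("R", "S"):
            raise ValueError("chirality must be 'R' or 'S'")
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.role] = counts.get(a.role, 0) + 1
        for role, n in _REQUIRED_ROLE_COUNTS.items():
            if counts.get(role, 0) != n:
                raise ValueError(
                    f"molecule {self.molecule_id}: expected {n} x {role}, "
                    f"got {counts.get(role, 0)}")

    def atom(self, role: str) -> Atom:
        """The unique atom with the given role."""
        found = [a for a in self.atoms if a.role == role]
        if len(found) != 1:
            raise ValueError(f"role {role!r} is not unique in molecule")
        return found[0]

    def atoms_with_role(self, role: str) -> list[Atom]:
        return [a for a in self.atoms if a.role == role]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])


@dataclass
class Configuration:
    """One periodic orthorhombic snapshot."""

    box_angstrom: np.ndarray
    molecules: list[Molecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.box_angstrom = np.asarray(self.box_angstrom, dtype=float)
        if self.box_angstrom.shape != (3,) or np.any(self.box_angstrom <= 0):
            raise ValueError("box must be 3 positive lengths")
        ids = [m.molecule_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def minimum_image_vector(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shortest periodic displacement for orthorhombic boxes (vectorised)."""
    return dr - box * np.round(dr / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    return float(np.linalg.norm(minimum_image_vector(np.asarray(b) - np.asarray(a),
                                                     np.asarray(box))))


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray,
              box: np.ndarray | None = None) -> float:
    """Angle a-vertex-b in degrees; displacements wrapped if a box is given."""
    va = np.asarray(a) - np.asarray(vertex)
    vb = np.asarray(b) - np.asarray(vertex)
    if box is not None:
        va = minimum_image_vector(va, np.asarray(box))
        vb = minimum_image_vector(vb, np.asarray(box))
    c = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# extended XYZ I/O
# ---------------------------------------------------------------------------

def write_xyz(config: Configuration, path) -> None:
    bx, by, bz = config.box_angstrom
    lines = []
    n_atoms = sum(len(m.atoms) for m in config.molecules)
    lines.append(str(n_atoms))
    lines.append(
        f'Lattice="{bx:.6f} 0 0 0 {by:.6f} 0 0 0 {bz:.6f}" '
        'Properties=species:S:1:pos:R:3:mol_id:I:1:role:S:1:chirality:S:1')
    for m in config.molecules:
        for a in m.atoms:
            x, y, z = a.xyz
            lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f} "
                         f"{m.molecule_id} {a.role} {m.chirality}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> Configuration:
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    if len(raw) < 2:
        raise ValueError("truncated xyz file")
    n_atoms = int(raw[0].split()[0])
    comment = raw[1]
    lat_key = 'Lattice="'
    i = comment.find(lat_key)
    if i < 0:
        raise ValueError("comment line must carry a Lattice specification")
    j = comment.index('"', i + len(lat_key))
    lat = np.array([float(v) for v in comment[i + len(lat_key):j].split()])
    if lat.shape != (9,):
        raise ValueError("Lattice must list 9 numbers")
    mat = lat.reshape(3, 3)
    if not np.allclose(mat, np.diag(np.diag(mat))):
        raise ValueError("only orthorhombic (diagonal) lattices are supported")
    box = np.diag(mat)

    by_mol: dict[int, list[tuple[str, str, str, np.ndarray]]] = {}
    for ln in raw[2:2 + n_atoms]:
        parts = ln.split()
        if len(parts) != 7:
            raise ValueError(f"expected 7 columns per atom line, got {len(parts)}")
        el, x, y, z, mol_id, role, chir = parts
        by_mol.setdefault(int(mol_id), []).append(
            (el, role, chir, np.array([float(x), float(y), float(z)])))

    molecules = []
    for mol_id in sorted(by_mol):
        rows = by_mol[mol_id]
        chir = rows[0][2]
        atoms = [Atom(element=el, role=role, xyz=xyz) for el, role, _, xyz in rows]
        molecules.append(Molecule(molecule_id=mol_id, chirality=chir, atoms=atoms))
    return Configuration(box_angstrom=box, molecules=molecules)
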