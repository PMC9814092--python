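"""Plain-Cartesian molecular structure containers and SDF/XYZ round-tripping.

Structures here are deliberately lightweight: an element list, an (N, 3)
coordinate array in Angstrom and an explicit bond list with integer orders.
Assembly, the surrogate energy backend and the pore analysis all operate on
this container; RDKit molecules are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .elements import atomic_mass

Bond = tuple[int, int, int]  # (atom i, atom j, bond order)


@dataclass
class Structure:
    elements: list[str]
    coords: np.ndarray  # (N, 3) float64, Angstrom
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} elements but {len(self.coords)} coordinates"
            )
        for i, j, _ in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Structure":
        return Structure(list(self.elements), self.coords.copy(), list(self.bonds))

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def centre_of_mass(self) -> np.ndarray:
        masses = np.array([atomic_mass(e) for e in self.elements])
        return (self.coords * masses[:, None]).sum(axis=0) / masses.sum()

    def translated(self, shift: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = out.coords + np.asarray(shift, dtype=float)
        return out

    def rotated(self, rotation: np.ndarray) -> "Structure":
        """Rotate about the origin by a 3x3 rotation matrix."""
        out = self.copy()
        out.coords = out.coords @ np.asarray(rotation, dtype=float).T
        return out

    # ---------------------------------------------------------------- I/O
    def to_xyz(self, path: str | Path, comment: str = "") -> None:
        lines = [str(self.n_atoms), comment.replace("\n", " ")]
        for el, (x, y, z) in zip(self.elements, self.coords):
            lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_xyz(cls, path: str | Path) -> "Structure":
        raw = Path(path).read_text().splitlines()
        n = int(raw[0].split()[0])
        elements, coords = [], []
        for line in raw[2 : 2 + n]:
            el, x, y, z = line.split()[:4]
            elements.append(el)
            coords.append([float(x), float(y), float(z)])
        return cls(elements, np.array(coords))

    def to_rdkit(self):
        """Convert to an RDKit molecule (explicit bonds, no sanitisation pitfalls)."""
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        order_map = {
            1: Chem.BondType.SINGLE,
            2: Chem.BondType.DOUBLE,
            3: Chem.BondType.TRIPLE,
        }
        mol = Chem.RWMol()
        for el in self.elements:
            atom = Chem.Atom(el)
            atom.SetNoImplicit(True)
            mol.AddAtom(atom)
        for i, j, order in self.bonds:
            mol.AddBond(int(i), int(j), order_map.get(order, Chem.BondType.SINGLE))
        conf = Chem.Conformer(self.n_atoms)
        for idx, (x, y, z) in enumerate(self.coords):
            conf.SetAtomPosition(idx, Point3D(float(x), float(y), float(z)))
        out = mol.GetMol()
        out.AddConformer(conf)
        Chem.SanitizeMol(out, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        return out

    def to_sdf(self, path: str | Path, name: str = "", props: dict | None = None) -> None:
        from rdkit import Chem

        mol = self.to_rdkit()
        mol.SetProp("_Name", name)
        for key, value in (props or {}).items():
            mol.SetProp(str(key), str(value))
        with Chem.SDWriter(str(path)) as writer:
            writer.write(mol)

    @classmethod
    def from_sdf(cls, path: str | Path) -> "Structure":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next(iter(supplier))
        if mol is None:
            raise ValueError(f"could not parse SDF file {path}")
        return cls.from_rdkit(mol)

    @classmethod
    def from_rdkit(cls, mol) -> "Structure":
        from rdkit import Chem

        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = conf.GetPositions()
        order_map = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: 1,
        }
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map.get(b.GetBondType(), 1))
            for b in mol.GetBonds()
        ]
        return cls(elements, np.array(coords), bonds)


def concatenate(parts: Sequence[Structure]) -> Structure:
    """Join structures into one, re-indexing bonds."""
    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[Bond] = []
    offset = 0
    for part in parts:
        elements.extend(part.elements)
        coords.append(part.coords)
        bonds.extend((i + offset, j + offset, o) for i, j, o in part.bonds)
        offset += part.n_atoms
    return Structure(elements, np.vstack(coords), bonds)


@dataclass
class CageStructure(Structure):
    """An assembled Tri4Di6 cage with provenance and its imine bonds."""

    node_id: str = ""
    linker_id: str = ""
    imine_bonds: list[tuple[int, int]] = field(default_factory=list)
    energy: float | None = None  # kJ/mol

    def copy(self) -> "CageStructure":
        return CageStructure(
            list(self.elements),
            self.coords.copy(),
            list(self.bonds),
            node_id=self.node_id,
            linker_id=self.linker_id,
            imine_bonds=list(self.imine_bonds),
            energy=self.energy,
        )

    @property
    def cage_id(self) -> str:
        return f"{self.node_id}+{self.linker_id}"

    def with_coords(self, coords: np.ndarray, energy: float | None = None) -> "CageStructure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        out.energy = energy
        return out


@dataclass
class ComplexStructure:
    """A host cage with a C60 guest; guest atoms are kept separable."""

    cage: CageStructure
    guest: Structure
    energy: float | None = None  # kJ/mol

    @property
    def n_atoms(self) -> int:
        return self.cage.n_atoms + self.guest.n_atoms

    def combined(self) -> Structure:
        return concatenate([self.cage, self.guest])

    def host_only(self) -> CageStructure:
        return self.cage.copy()

    def with_coords(self, coords: np.ndarray, energy: float | None = None) -> "ComplexStructure":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = self.cage.n_atoms
        cage = self.cage.with_coords(coords[:n])
        guest = Structure(list(self.guest.elements), coords[n:], list(self.guest.bonds))
        return ComplexStructure(cage, guest, energy=energy)

    def to_sdf(self, path: str | Path, name: str = "") -> None:
        """Write host and guest as two SDF records tagged with a `role` property."""
        from rdkit import Chem

        with Chem.SDWriter(str(path)) as writer:
            for part, role in ((self.cage, "host"), (self.guest, "guest")):
                mol = part.to_rdkit()
                mol.SetProp("_Name", name)
                mol.SetProp("role", role)
                writer.write(mol)
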