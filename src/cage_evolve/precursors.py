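"""Building-block library: loading, validation, similarity and size descriptors.

A Tri4Di6 imine cage is assembled from two kinds of precursor: tri-topic
aromatic aldehydes ("nodes", placed on the vertices of a tetrahedron) and
di-topic primary amines ("linkers", placed on the edges).  Each precursor
carries its detected reactive sites (aldehyde carbons / amine nitrogens) and
a hashed circular substructure fingerprint of radius 2 used by the
similarity-guided mutation operators and the population diversity analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import pdist

from .elements import vdw_radius

ALDEHYDE_SMARTS = Chem.MolFromSmarts("[CX3H1](=O)")
PRIMARY_AMINE_SMARTS = Chem.MolFromSmarts("[NX3;H2;!$(NC=O)]")

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 2048

_MORGAN = None


def _morgan_generator():
    global _MORGAN
    if _MORGAN is None:
        from rdkit.Chem import rdFingerprintGenerator

        _MORGAN = rdFingerprintGenerator.GetMorganGenerator(
            radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
        )
    return _MORGAN

REQUIRED_SITES = {"node": 3, "linker": 2}


class LibraryError(ValueError):
    """Raised on malformed precursor input."""


@dataclass
class Precursor:
    """One validated building block.

    ``reactive_sites`` are atom indices into the RDKit molecule: the aldehyde
    carbons for a node, the primary-amine nitrogens for a linker.
    """

    id: str
    smiles: str
    role: str  # "node" | "linker"
    reactive_sites: list[int]
    fingerprint: np.ndarray  # uint8 0/1 vector of FINGERPRINT_BITS
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @classmethod
    def from_smiles(cls, pid: str, smiles: str, role: str) -> "Precursor":
        if role not in REQUIRED_SITES:
            raise LibraryError(f"precursor {pid!r}: unknown role {role!r}")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise LibraryError(f"precursor {pid!r}: SMILES {smiles!r} failed to parse")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise LibraryError(f"precursor {pid!r}: SMILES must be a single connected molecule")
        pattern = ALDEHYDE_SMARTS if role == "node" else PRIMARY_AMINE_SMARTS
        sites = sorted({match[0] for match in mol.GetSubstructMatches(pattern)})
        need = REQUIRED_SITES[role]
        if len(sites) != need:
            kind = "aldehyde" if role == "node" else "primary-amine"
            raise LibraryError(
                f"precursor {pid!r}: found {len(sites)} {kind} sites, {need} required for role {role!r}"
            )
        fp = _morgan_generator().GetFingerprint(mol)
        vec = np.zeros(FINGERPRINT_BITS, dtype=np.uint8)
        vec[list(fp.GetOnBits())] = 1
        return cls(pid, smiles, role, sites, vec, mol)

    def embedded(self, seed: int = 61409) -> Chem.Mol:
        """Hydrogenated 3-D conformer (deterministic for a given seed)."""
        mol = Chem.AddHs(self.mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            # fall back to unconstrained random coordinates, still seeded
            params.useRandomCoords = True
            if AllChem.EmbedMolecule(mol, params) != 0:
                raise LibraryError(f"precursor {self.id!r}: 3-D embedding failed")
        try:
            AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
        except Exception:
            pass
        return mol


@dataclass
class PrecursorLibrary:
    nodes: list[Precursor]
    linkers: list[Precursor]

    def __post_init__(self) -> None:
        if not self.nodes or not self.linkers:
            raise LibraryError("library must contain at least one node and one linker")
        for group, name in ((self.nodes, "node"), (self.linkers, "linker")):
            ids = [p.id for p in group]
            if len(set(ids)) != len(ids):
                raise LibraryError(f"duplicate {name} ids in library")

    def node(self, pid: str) -> Precursor:
        return self._find(self.nodes, pid)

    def linker(self, pid: str) -> Precursor:
        return self._find(self.linkers, pid)

    @staticmethod
    def _find(group: Sequence[Precursor], pid: str) -> Precursor:
        for p in group:
            if p.id == pid:
                return p
        raise KeyError(pid)

    @property
    def n_combinations(self) -> int:
        return len(self.nodes) * len(self.linkers)

    def combinations(self) -> list[tuple[str, str]]:
        return [(n.id, l.id) for n in self.nodes for l in self.linkers]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["id", "smiles", "role"])
            for p in self.nodes + self.linkers:
                writer.writerow([p.id, p.smiles, p.role])


def load_library(path: str | Path) -> PrecursorLibrary:
    """Read a precursor CSV (``id,smiles,role``; ``#`` comment lines allowed)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nodes: list[Precursor] = []
    linkers: list[Precursor] = []
    with open(path, newline="", encoding="utf-8") as handle:
        rows = [r for r in csv.reader(handle) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise LibraryError(f"{path}: empty precursor file")
    header = [c.strip().lower() for c in rows[0]]
    if header[:3] != ["id", "smiles", "role"]:
        raise LibraryError(f"{path}: expected header id,smiles,role, got {rows[0]}")
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) < 3:
            raise LibraryError(f"{path} row {lineno}: expected 3 columns, got {row}")
        pid, smiles, role = (c.strip() for c in row[:3])
        try:
            precursor = Precursor.from_smiles(pid, smiles, role)
        except LibraryError as exc:
            raise LibraryError(f"{path} row {lineno}: {exc}") from exc
        (nodes if role == "node" else linkers).append(precursor)
    return PrecursorLibrary(nodes, linkers)


def dice_similarity(p1: Precursor | np.ndarray, p2: Precursor | np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) over fingerprint on-bits.

    Two empty fingerprints are defined to have similarity 0.
    """
    a = p1.fingerprint if isinstance(p1, Precursor) else np.asarray(p1)
    b = p2.fingerprint if isinstance(p2, Precursor) else np.asarray(p2)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / total


def most_similar(target: Precursor, pool: Sequence[Precursor]) -> Precursor:
    """Pool member with maximal Dice similarity to ``target``.

    Ties break to the lexicographically smallest id so repeated runs are
    reproducible.  The pool must be non-empty and exclude the target itself.
    """
    candidates = [p for p in pool if p.id != target.id]
    if not candidates:
        raise LibraryError(f"no candidates to compare against {target.id!r}")
    return max(candidates, key=lambda p: (dice_similarity(target, p), _neg_id(p.id)))


def _neg_id(pid: str) -> tuple:
    # max() picks the largest key; invert character order so that among equal
    # similarities the lexicographically *smallest* id wins.
    return tuple(-ord(c) for c in pid)


def spherical_diameter(
    p: Precursor | None = None,
    coords: np.ndarray | None = None,
    elements: Sequence[str] | None = None,
    seed: int = 61409,
) -> float:
    """Largest sphere circumscribing the molecule's van der Waals surface.

    Maximum over atom pairs of (interatomic distance + both endpoint vdW
    radii); for a single atom this is its vdW diameter.  If explicit
    coordinates are not supplied the precursor is embedded in 3-D first.
    """
    if coords is None:
        if p is None:
            raise ValueError("either a precursor or explicit coordinates are required")
        mol = p.embedded(seed=seed)
        coords = mol.GetConformer().GetPositions()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if elements is None:
        raise ValueError("elements are required with explicit coordinates")
    radii = np.array([vdw_radius(e) for e in elements])
    if len(coords) == 1:
        return 2.0 * radii[0]
    dists = pdist(coords)
    idx_i, idx_j = np.triu_indices(len(coords), k=1)
    pair_max = float(np.max(dists + radii[idx_i] + radii[idx_j]))
    return max(pair_max, 2.0 * float(radii.max()))
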