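"""Tri4Di6 cage and C60@cage complex construction.

Four tri-topic aldehyde nodes are placed on the vertices and six di-topic
amine linkers on the edges of a regular-tetrahedron template.  Each aldehyde
carbon is condensed with an amine nitrogen into an imine (C=N) bond,
removing the aldehyde oxygen and two amine hydrogens (one water equivalent
per bond, twelve bonds in total).  For a complex the C60 guest is placed at
the template centre before anything else, so the host is built around it.

The template scale is chosen from the precursor dimensions so that reactive
sites meet at roughly bonding distance; the geometry is a starting point for
optimisation, not a final structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem

from .precursors import Precursor
from .structures import Bond, CageStructure, ComplexStructure, Structure

__all__ = [
    "TopologyTemplate",
    "generate_c60",
    "assemble_cage",
    "assemble_complex",
    "AssemblyError",
]

GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

#: Unit vertex directions of a regular tetrahedron.
TETRA_VERTICES = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)

#: The six vertex pairs forming the tetrahedron edges.
TETRA_EDGES: list[tuple[int, int]] = list(itertools.combinations(range(4), 2))

# |vertex - edge midpoint| per unit circumradius: half the unit edge length.
_VERTEX_TO_MIDPOINT = float(np.linalg.norm(TETRA_VERTICES[0] - TETRA_VERTICES[1]) / 2.0)

#: Target aldehyde-C to amine-N distance at assembly time, Angstrom.
IMINE_GAP = 1.45


class AssemblyError(RuntimeError):
    """Raised when a cage cannot be assembled from the given precursors."""


@dataclass
class TopologyTemplate:
    """Regular tetrahedron scaffold: nodes on vertices, linkers on edges."""

    scale: float  # circumradius, Angstrom
    vertices: np.ndarray = field(default_factory=lambda: TETRA_VERTICES.copy())
    edges: list[tuple[int, int]] = field(default_factory=lambda: list(TETRA_EDGES))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("template scale must be positive")
        norms = np.linalg.norm(self.vertices, axis=1)
        if not np.allclose(norms, norms[0]):
            raise ValueError("template vertices must be equidistant from the origin")

    def vertex_positions(self) -> np.ndarray:
        return self.vertices * self.scale

    def edge_midpoints(self) -> np.ndarray:
        pos = self.vertex_positions()
        return np.array([(pos[a] + pos[b]) / 2.0 for a, b in self.edges])


# --------------------------------------------------------------------- C60
def generate_c60(bond_length: float = 1.44) -> Structure:
    """Closed C60 guest: a truncated icosahedron of 60 carbons and 90 bonds.

    Vertices are the even permutations of (0, ±1, ±3φ), (±1, ±(2+φ), ±2φ)
    and (±φ, ±2, ±(2φ+1)); all edges of that solid have length 2, rescaled
    here to ``bond_length``.  The centroid sits exactly at the origin and the
    nucleus-to-nucleus diameter is ~7.1 Å at the default bond length.
    """
    phi = GOLDEN
    bases = [
        (0.0, 1.0, 3.0 * phi),
        (1.0, 2.0 + phi, 2.0 * phi),
        (phi, 2.0, 2.0 * phi + 1.0),
    ]
    verts: set[tuple[float, float, float]] = set()
    for base in bases:
        for signs in itertools.product((1.0, -1.0), repeat=3):
            v = tuple(s * c for s, c in zip(signs, base))
            for cyc in range(3):  # even (cyclic) permutations only
                verts.add((v[cyc % 3], v[(cyc + 1) % 3], v[(cyc + 2) % 3]))
    coords = np.array(sorted(verts)) * (bond_length / 2.0)
    if len(coords) != 60:
        raise AssemblyError(f"C60 construction produced {len(coords)} vertices")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cutoff = bond_length * 1.05
    bonds: list[Bond] = [
        (i, j, 1) for i in range(60) for j in range(i + 1, 60) if dist[i, j] < cutoff
    ]
    if len(bonds) != 90:
        raise AssemblyError(f"C60 construction produced {len(bonds)} bonds")
    return Structure(["C"] * 60, coords, bonds)


# ----------------------------------------------------------- linear algebra
def _kabsch(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det=+1) minimising sum |R s_i - t_i|^2."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _axis_angle(perp, np.pi)
    return _axis_angle(v, np.arctan2(np.linalg.norm(v), c))


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# --------------------------------------------------------- precursor prep
def _precursor_parts(p: Precursor, seed: int):
    """Embed a precursor and extract elements, coords and Kekulé bonds."""
    mol = p.embedded(seed=seed)
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    elements = [a.GetSymbol() for a in kek.GetAtoms()]
    coords = np.array(kek.GetConformer().GetPositions())
    order_of = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
    }
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_of.get(b.GetBondType(), 1))
        for b in kek.GetBonds()
    ]
    return kek, elements, coords, bonds


def _aldehyde_oxygens(mol: Chem.Mol, sites: list[int]) -> dict[int, int]:
    """Map each aldehyde carbon to its doubly-bonded oxygen."""
    out: dict[int, int] = {}
    for c_idx in sites:
        atom = mol.GetAtomWithIdx(c_idx)
        for nb in atom.GetNeighbors():
            if nb.GetSymbol() == "O":
                bond = mol.GetBondBetweenAtoms(c_idx, nb.GetIdx())
                if bond.GetBondTypeAsDouble() == 2.0:
                    out[c_idx] = nb.GetIdx()
                    break
        if c_idx not in out:
            raise AssemblyError(f"aldehyde carbon {c_idx} has no C=O oxygen")
    return out


def _amine_hydrogens(mol: Chem.Mol, sites: list[int]) -> dict[int, list[int]]:
    """Map each amine nitrogen to its two hydrogens."""
    out: dict[int, list[int]] = {}
    for n_idx in sites:
        hs = [
            nb.GetIdx()
            for nb in mol.GetAtomWithIdx(n_idx).GetNeighbors()
            if nb.GetSymbol() == "H"
        ]
        if len(hs) < 2:
            raise AssemblyError(f"amine nitrogen {n_idx} has {len(hs)} hydrogens, need 2")
        out[n_idx] = sorted(hs)[:2]
    return out


# ------------------------------------------------------------- assembly
def assemble_cage(
    node: Precursor,
    linker: Precursor,
    template: TopologyTemplate | None = None,
    seed: int = 61409,
    clash_threshold: float = 0.7,
) -> CageStructure:
    """Build a Tri4Di6 cage from one node and one linker type.

    Returns a single connected molecule with exactly 12 imine bonds and
    4 node : 6 linker stoichiometry.  Raises :class:`AssemblyError` when the
    reactive-site pairing cannot be completed; warns (but still returns) when
    atoms clash closer than ``clash_threshold`` Angstrom, since a subsequent
    optimisation is expected to relax the geometry.
    """
    if len(node.reactive_sites) != 3 or len(linker.reactive_sites) != 2:
        raise AssemblyError("node must have 3 reactive sites and linker 2")

    node_mol, node_el, node_xyz, node_bonds = _precursor_parts(node, seed)
    link_mol, link_el, link_xyz, link_bonds = _precursor_parts(linker, seed)

    site_pos = node_xyz[node.reactive_sites]
    site_centroid = site_pos.mean(axis=0)
    # plane normal of the three reactive carbons
    _, _, vt = np.linalg.svd(site_pos - site_centroid)
    node_normal = vt[2]
    node_rho = float(np.mean(np.linalg.norm(site_pos - site_centroid, axis=1)))

    n1_idx, n2_idx = linker.reactive_sites
    n1, n2 = link_xyz[n1_idx], link_xyz[n2_idx]
    linker_span = float(np.linalg.norm(n2 - n1))

    # source frame of the node: unit site directions + plane normal
    site_dirs = site_pos - site_centroid
    site_dirs /= np.linalg.norm(site_dirs, axis=1)[:, None]

    unit_verts = TETRA_VERTICES if template is None else (
        template.vertices / np.linalg.norm(template.vertices, axis=1)[:, None]
    )
    edge_list = TETRA_EDGES if template is None else template.edges
    edges_of_vertex = {
        v: [ei for ei, (a, b) in enumerate(edge_list) if v in (a, b)] for v in range(4)
    }
    unit_mids = np.array([(unit_verts[a] + unit_verts[b]) / 2.0 for a, b in edge_list])

    # Orientations depend only on directions, which are scale-free: solve them
    # once, then pick the scale placing reactive partners at bonding distance.
    node_rotations: list[np.ndarray] = []
    site_assignment: dict[tuple[int, int], int] = {}  # (vertex, edge) -> local site idx
    for v in range(4):
        inward = -unit_verts[v]
        targets = []
        for ei in edges_of_vertex[v]:
            t = unit_mids[ei] - unit_verts[v]
            t = t - np.dot(t, unit_verts[v]) * unit_verts[v]  # in-plane projection
            targets.append(t / np.linalg.norm(t))
        targets = np.array(targets)
        best = None
        for perm in itertools.permutations(range(3)):
            src = np.vstack([site_dirs[list(perm)], node_normal[None, :]])
            tgt = np.vstack([targets, inward[None, :]])
            rot = _kabsch(src, tgt)
            resid = float(np.linalg.norm(src @ rot.T - tgt))
            if best is None or resid < best[0]:
                best = (resid, perm, rot)
        _, perm, rot = best
        for k, ei in enumerate(edges_of_vertex[v]):
            site_assignment[(v, ei)] = perm[k]
        node_rotations.append(rot)

    n_mid = (n1 + n2) / 2.0
    heavy = [i for i, e in enumerate(link_el) if e != "H"]
    linker_coords: list[np.ndarray] = []  # centred on edge midpoint direction
    linker_ends: list[tuple[int, int]] = []  # (atom near edge vertex a, near b)
    for ei, (a, b) in enumerate(edge_list):
        edge_dir = unit_verts[b] - unit_verts[a]
        edge_dir /= np.linalg.norm(edge_dir)
        rot1 = _rotation_between(n2 - n1, edge_dir)
        placed = (link_xyz - n_mid) @ rot1.T
        # roll the linker bulk outward, away from the cage centre
        bulk = placed[heavy].mean(axis=0)
        bulk_perp = bulk - np.dot(bulk, edge_dir) * edge_dir
        outward = unit_mids[ei] / np.linalg.norm(unit_mids[ei])
        out_perp = outward - np.dot(outward, edge_dir) * edge_dir
        if np.linalg.norm(bulk_perp) > 1e-6 and np.linalg.norm(out_perp) > 1e-6:
            bulk_perp /= np.linalg.norm(bulk_perp)
            out_perp /= np.linalg.norm(out_perp)
            angle = np.arctan2(
                np.dot(np.cross(bulk_perp, out_perp), edge_dir),
                np.dot(bulk_perp, out_perp),
            )
            placed = placed @ _axis_angle(edge_dir, angle).T
        linker_coords.append(placed)
        linker_ends.append((n1_idx, n2_idx))

    # Geometry of the tetrahedron edge seen from a vertex: the edge direction
    # decomposes into a radial (inward) part and an in-plane part.  A planar
    # node tangent to the vertex sphere cannot reach the edge, so the node is
    # slid inward along its radial axis until the prolongation of each arm
    # meets the edge at the imine bonding distance.
    e01 = unit_verts[1] - unit_verts[0]
    edge_half = float(np.linalg.norm(e01)) / 2.0
    e01 /= 2.0 * edge_half
    c_par = float(np.dot(e01, unit_verts[0]))  # < 0: edges dip inward
    c_perp = float(np.sqrt(1.0 - c_par**2))

    # distance from a vertex to its amine partner, measured along the edge
    q = (node_rho + IMINE_GAP) / c_perp
    if template is None:
        template = TopologyTemplate(scale=(q + linker_span / 2.0) / edge_half)
    else:
        q = edge_half * template.scale - linker_span / 2.0
        if q <= 0:
            raise AssemblyError("template scale too small for this linker span")
    node_radial_offset = c_par * q  # negative: nodes sit inside the vertices

    vpos = template.vertex_positions()
    mids = template.edge_midpoints()
    parts: list[Structure] = []
    for v in range(4):
        centre = vpos[v] + node_radial_offset * unit_verts[v]
        placed = (node_xyz - site_centroid) @ node_rotations[v].T + centre
        parts.append(Structure(list(node_el), placed, list(node_bonds)))
    for ei in range(len(edge_list)):
        parts.append(
            Structure(list(link_el), linker_coords[ei] + mids[ei], list(link_bonds))
        )

    # global indexing
    offsets = np.cumsum([0] + [s.n_atoms for s in parts])
    elements: list[str] = []
    coords = np.vstack([s.coords for s in parts])
    bonds: list[Bond] = []
    for part, off in zip(parts, offsets):
        elements.extend(part.elements)
        bonds.extend((i + off, j + off, o) for i, j, o in part.bonds)

    oxy_of = _aldehyde_oxygens(node_mol, node.reactive_sites)
    hs_of = _amine_hydrogens(link_mol, linker.reactive_sites)

    to_delete: set[int] = set()
    imine_pairs: list[tuple[int, int]] = []
    for ei, (a, b) in enumerate(template.edges):
        for vertex, n_local in zip((a, b), linker_ends[ei]):
            site_local = node.reactive_sites[site_assignment[(vertex, ei)]]
            c_global = int(offsets[vertex] + site_local)
            n_global = int(offsets[4 + ei] + n_local)
            imine_pairs.append((c_global, n_global))
            to_delete.add(int(offsets[vertex] + oxy_of[site_local]))
            to_delete.update(int(offsets[4 + ei] + h) for h in hs_of[n_local])

    if len(imine_pairs) != 12:
        raise AssemblyError(f"site pairing produced {len(imine_pairs)} imine bonds, not 12")

    keep = [i for i in range(len(elements)) if i not in to_delete]
    remap = {old: new for new, old in enumerate(keep)}
    new_elements = [elements[i] for i in keep]
    new_coords = coords[keep]
    new_bonds = [
        (remap[i], remap[j], o)
        for i, j, o in bonds
        if i not in to_delete and j not in to_delete
    ]
    imine_bonds = [(remap[c], remap[n]) for c, n in imine_pairs]
    new_bonds.extend((c, n, 2) for c, n in imine_bonds)

    graph = nx.Graph((i, j) for i, j, _ in new_bonds)
    graph.add_nodes_from(range(len(new_elements)))
    if nx.number_connected_components(graph) != 1:
        raise AssemblyError("assembled cage is not a single connected molecule")

    cage = CageStructure(
        new_elements,
        new_coords,
        new_bonds,
        node_id=node.id,
        linker_id=linker.id,
        imine_bonds=imine_bonds,
    )
    _warn_on_clashes(cage, clash_threshold)
    return cage


def _warn_on_clashes(cage: CageStructure, threshold: float) -> None:
    from scipy.spatial import cKDTree

    bonded = {(min(i, j), max(i, j)) for i, j, _ in cage.bonds}
    tree = cKDTree(cage.coords)
    pairs = tree.query_pairs(threshold)
    clashes = [p for p in pairs if p not in bonded]
    if clashes:
        warnings.warn(
            f"cage {cage.cage_id}: {len(clashes)} atom pairs closer than "
            f"{threshold} A before optimisation",
            stacklevel=3,
        )


def assemble_complex(
    node: Precursor,
    linker: Precursor,
    template: TopologyTemplate | None = None,
    seed: int = 61409,
) -> ComplexStructure:
    """Assemble the cage with a C60 guest pre-placed at the template centre."""
    guest = generate_c60()  # centroid at the origin == template centre
    cage = assemble_cage(node, linker, template=template, seed=seed)
    return ComplexStructure(cage, guest)
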