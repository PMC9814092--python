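"""Cavity, window and asymmetry analysis of assembled cages.

The cavity diameter is that of the largest sphere centred at the cage's
centre of mass that touches no atomic van der Waals surface.  Windows are
found by casting rays from the centre along a dense icosphere direction
grid: a direction "escapes" when its bottleneck clearance (smallest
distance from the ray to any atom surface ahead of the centre) stays
positive; contiguous escaping directions form one window, whose diameter is
twice the best bottleneck clearance in the cluster.  A shape-persistent
Tri4Di6 cage shows four windows; a collapsed cage shows fewer than two (or
no cavity at all) and is discarded by the screening workflow.

The angular resolution of the default grid (5120 directions) bounds the
window-diameter error at roughly ``2 * grid_spacing * shell_radius``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

from .elements import vdw_radius
from .structures import Structure

__all__ = [
    "ShapeMetrics",
    "icosphere_directions",
    "cavity_diameter",
    "find_windows",
    "asymmetry",
    "is_collapsed",
    "compute_shape_metrics",
]

DEFAULT_SUBDIVISIONS = 4  # 20 * 4^4 = 5120 directions


@dataclass
class ShapeMetrics:
    """Pore geometry of one cage (all lengths in Angstrom)."""

    cavity_diameter: float
    window_diameters: list[float]
    asymmetry: float | None  # undefined (None) when < 2 windows
    collapsed: bool


# ------------------------------------------------------------- icosphere
@lru_cache(maxsize=4)
def _icosphere(subdivisions: int):
    """Unit face-centre directions of a subdivided icosahedron + adjacency."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = [
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ]
    verts = [np.array(v, dtype=float) / np.linalg.norm(v) for v in verts]
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces

    varr = np.array(verts)
    centres = varr[np.array(faces)].mean(axis=1)
    centres /= np.linalg.norm(centres, axis=1)[:, None]

    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for i, j in ((a, b), (b, c), (c, a)):
            edge_to_faces.setdefault((min(i, j), max(i, j)), []).append(fi)
    adjacency = [pair for pair in edge_to_faces.values() if len(pair) == 2]
    return centres, np.array(adjacency)


def icosphere_directions(subdivisions: int = DEFAULT_SUBDIVISIONS) -> np.ndarray:
    """Unit direction grid used for window detection."""
    return _icosphere(subdivisions)[0].copy()


def grid_resolution(subdivisions: int = DEFAULT_SUBDIVISIONS) -> float:
    """Approximate angular spacing (radians) between adjacent directions."""
    centres, adjacency = _icosphere(subdivisions)
    a, b = adjacency[0]
    return float(np.arccos(np.clip(np.dot(centres[a], centres[b]), -1, 1)))


# --------------------------------------------------------------- metrics
def _centre(structure: Structure, centre) -> np.ndarray:
    if isinstance(centre, str):
        if centre == "com":
            return structure.centre_of_mass()
        if centre == "centroid":
            return structure.centroid()
        raise ValueError(f"unknown centre mode {centre!r}")
    return np.asarray(centre, dtype=float)


def _radii(structure: Structure, radii) -> np.ndarray:
    if radii is None:
        return np.array([vdw_radius(e) for e in structure.elements])
    if np.isscalar(radii):
        return np.full(structure.n_atoms, float(radii))
    return np.asarray(radii, dtype=float)


def cavity_diameter(
    structure: Structure, radii=None, centre="com"
) -> float:
    """Diameter of the largest sphere at the cage centre, floored at 0 Å."""
    if structure.n_atoms < 4:
        raise ValueError("cavity diameter needs at least 4 atoms")
    rel = structure.coords - _centre(structure, centre)
    dist = np.linalg.norm(rel, axis=1)
    if float(dist.max()) < 1e-9:
        raise ValueError("degenerate geometry: all atoms coincide")
    return max(0.0, 2.0 * float(np.min(dist - _radii(structure, radii))))


def find_windows(
    structure: Structure,
    radii=None,
    centre="com",
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    min_diameter: float = 1.0,
) -> list[float]:
    """Window diameters found by ray casting; empty list when none escape.

    Windows narrower than ``min_diameter`` are discarded: gaps between the
    van der Waals spheres of adjacent atoms register as sub-Angstrom escape
    channels on a fine direction grid but admit no molecular guest, and
    whether they appear depends on the grid orientation.
    """
    directions, adjacency = _icosphere(subdivisions)
    rel = structure.coords - _centre(structure, centre)
    rad = _radii(structure, radii)
    shell = float(np.linalg.norm(rel, axis=1).max())

    proj = rel @ directions.T  # (atoms, directions)
    d2 = np.sum(rel * rel, axis=1)[:, None]
    perp = np.sqrt(np.maximum(d2 - proj**2, 0.0))
    clearance = perp - rad[:, None]
    clearance = np.where(proj > 0.0, clearance, np.inf)  # atoms behind don't block
    bottleneck = clearance.min(axis=0)
    bottleneck = np.minimum(bottleneck, shell)  # cap fully-open directions

    escaping = bottleneck > 0.0
    if not escaping.any():
        return []
    graph = nx.Graph()
    graph.add_nodes_from(np.flatnonzero(escaping))
    esc = escaping[adjacency[:, 0]] & escaping[adjacency[:, 1]]
    graph.add_edges_from(adjacency[esc])
    diameters = (
        2.0 * float(bottleneck[list(component)].max())
        for component in nx.connected_components(graph)
    )
    return sorted((d for d in diameters if d >= min_diameter), reverse=True)


def asymmetry(window_diameters) -> float:
    """Sum of |w_i - w_j| over all unordered window pairs; 0 = symmetric."""
    w = list(window_diameters)
    if len(w) < 2:
        raise ValueError("asymmetry needs at least two windows")
    return float(sum(abs(a - b) for a, b in itertools.combinations(w, 2)))


def is_collapsed(
    structure: Structure, radii=None, centre="com", subdivisions: int = DEFAULT_SUBDIVISIONS
) -> bool:
    """A cage is collapsed when it has lost its cavity or its windows."""
    try:
        cavity = cavity_diameter(structure, radii=radii, centre=centre)
    except ValueError:
        return True
    if cavity <= 0.0:
        return True
    return len(find_windows(structure, radii=radii, centre=centre, subdivisions=subdivisions)) < 2


def compute_shape_metrics(
    structure: Structure, radii=None, centre="com", subdivisions: int = DEFAULT_SUBDIVISIONS
) -> ShapeMetrics:
    """Cavity + window analysis in one pass (guest atoms must be pre-removed)."""
    try:
        cavity = cavity_diameter(structure, radii=radii, centre=centre)
    except ValueError:
        return ShapeMetrics(0.0, [], None, True)
    windows = find_windows(structure, radii=radii, centre=centre, subdivisions=subdivisions)
    if cavity <= 0.0 or len(windows) < 2:
        return ShapeMetrics(cavity, windows, None, True)
    return ShapeMetrics(cavity, windows, asymmetry(windows), False)
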