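"""Structural analytics: chemical diversity, bond character, property space.

Used to follow an evolutionary run (does the population contract onto a
region of chemical space?) and to situate the winning cages within the full
database: mean pairwise Dice similarity of the building-block fingerprints,
rotatable/double-bond fractions, the three-group binding-energy
classification and long-form property tables for overlay plots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem

from .fitness import PARAMETERISATION_LOWER_LIMIT, FitnessRecord
from .precursors import Precursor, PrecursorLibrary, dice_similarity
from .structures import Structure

__all__ = [
    "BondFractions",
    "mean_pairwise_dice",
    "bond_fractions",
    "classify_by_binding",
    "property_space_table",
]


@dataclass(frozen=True)
class BondFractions:
    """Percentages over heavy-atom bonds (hydrogens excluded)."""

    pct_rotatable: float
    pct_double: float
    scope: str  # node | linker | cage


def mean_pairwise_dice(members: Sequence, library: PrecursorLibrary) -> float:
    """Mean over all unordered member pairs of the mean of the node-node and
    linker-linker fingerprint Dice similarities.

    Building blocks are compared within their role only; the per-pair cage
    similarity is the unweighted mean of the two role similarities.
    """
    if len(members) < 2:
        raise ValueError("diversity is undefined for fewer than two members")
    sims = []
    cache: dict[tuple[str, str, str], float] = {}

    def _sim(role: str, id1: str, id2: str) -> float:
        key = (role,) + tuple(sorted((id1, id2)))
        if key not in cache:
            get = library.node if role == "node" else library.linker
            cache[key] = dice_similarity(get(id1), get(id2))
        return cache[key]

    for m1, m2 in itertools.combinations(members, 2):
        node_sim = _sim("node", m1.node_id, m2.node_id)
        linker_sim = _sim("linker", m1.linker_id, m2.linker_id)
        sims.append((node_sim + linker_sim) / 2.0)
    return float(np.mean(sims))


def _heavy_graph(obj) -> nx.Graph:
    """Heavy-atom bond graph with integer Kekule bond orders."""
    graph = nx.Graph()
    if isinstance(obj, Structure):
        heavy = {i for i, e in enumerate(obj.elements) if e != "H"}
        graph.add_nodes_from(heavy)
        for i, j, order in obj.bonds:
            if i in heavy and j in heavy:
                graph.add_edge(i, j, order=order)
        return graph
    mol = obj.mol if isinstance(obj, Precursor) else obj
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    for atom in kek.GetAtoms():
        if atom.GetSymbol() != "H":
            graph.add_node(atom.GetIdx())
    for bond in kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in graph.nodes and j in graph.nodes:
            graph.add_edge(i, j, order=int(bond.GetBondTypeAsDouble()))
    return graph


def bond_fractions(obj, scope: str = "cage") -> BondFractions:
    """Rotatable and double-bond percentages of a molecule or structure.

    Rotatable: acyclic (bridge) single bonds between two non-terminal heavy
    atoms — the conventional pattern, without the amide exclusion (imine
    cages contain no amides).  Double bonds are counted on the Kekule
    structure, so aromatic rings contribute alternating doubles.
    """
    graph = _heavy_graph(obj)
    n_bonds = graph.number_of_edges()
    if n_bonds == 0:
        return BondFractions(0.0, 0.0, scope)
    bridges = set(frozenset(e) for e in nx.bridges(graph))
    rotatable = sum(
        1
        for i, j, data in graph.edges(data=True)
        if data["order"] == 1
        and frozenset((i, j)) in bridges
        and graph.degree(i) > 1
        and graph.degree(j) > 1
    )
    double = sum(1 for _, _, data in graph.edges(data=True) if data["order"] == 2)
    return BondFractions(100.0 * rotatable / n_bonds, 100.0 * double / n_bonds, scope)


def classify_by_binding(
    records: Iterable[FitnessRecord],
    limit: float = PARAMETERISATION_LOWER_LIMIT,
) -> dict[str, list[FitnessRecord]]:
    """Partition complexes by binding energy.

    ``repulsive``: E > 0 (the cage pays more to deform than it gains);
    ``favourable``: limit <= E <= 0 (the target group for the search);
    ``unreasonable``: E < limit (force-field artefacts, typically collapsed
    or over-expanded geometries).
    """
    groups: dict[str, list[FitnessRecord]] = {
        "repulsive": [],
        "favourable": [],
        "unreasonable": [],
    }
    for r in records:
        if r.E_binding > 0:
            groups["repulsive"].append(r)
        elif r.E_binding < limit:
            groups["unreasonable"].append(r)
        else:
            groups["favourable"].append(r)
    return groups


PROPERTY_COLUMNS = ("E_binding", "A_complex", "A_cage", "D_cage", "D_complex")


def property_space_table(
    records: Iterable[FitnessRecord], highlight: set[str] | Sequence[str] = ()
) -> pd.DataFrame:
    """Long-form property table for database-vs-finalists overlay plots.

    One row per (cage, property) for the whole database plus duplicated
    rows (group="highlight") for the highlighted subset.  Unknown highlight
    ids raise KeyError.
    """
    records = list(records)
    known = {r.cage_id for r in records}
    highlight = set(highlight)
    missing = highlight - known
    if missing:
        raise KeyError(f"highlight ids not in the database: {sorted(missing)}")
    rows = []
    for r in records:
        for prop in PROPERTY_COLUMNS:
            value = getattr(r, prop)
            rows.append({"cage_id": r.cage_id, "property": prop, "value": value, "group": "database"})
            if r.cage_id in highlight:
                rows.append({"cage_id": r.cage_id, "property": prop, "value": value, "group": "highlight"})
    return pd.DataFrame(rows, columns=["cage_id", "property", "value", "group"])
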