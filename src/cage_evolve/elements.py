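"""Per-element data used across the package.

Van der Waals radii are Bondi's compilation; covalent radii are the
Cordero single-bond values; Lennard-Jones well depths/distances are the
UFF nonbonded parameters (x_i = van der Waals distance in Angstrom,
D_i = well depth converted from kcal/mol to kJ/mol).
"""

from __future__ import annotations

KCAL_TO_KJ = 4.184

#: Bondi van der Waals radii, Angstrom.
BONDI_VDW: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

#: Cordero covalent radii, Angstrom (sp3 carbon value for C).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
}

#: Standard atomic masses.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}

#: UFF nonbonded parameters: (x_i Angstrom, D_i kJ/mol).
UFF_LJ: dict[str, tuple[float, float]] = {
    "H": (2.886, 0.044 * KCAL_TO_KJ),
    "C": (3.851, 0.105 * KCAL_TO_KJ),
    "N": (3.660, 0.069 * KCAL_TO_KJ),
    "O": (3.500, 0.060 * KCAL_TO_KJ),
    "F": (3.364, 0.050 * KCAL_TO_KJ),
    "P": (4.147, 0.305 * KCAL_TO_KJ),
    "S": (4.035, 0.274 * KCAL_TO_KJ),
    "Cl": (3.947, 0.227 * KCAL_TO_KJ),
    "Br": (4.189, 0.251 * KCAL_TO_KJ),
    "I": (4.50, 0.339 * KCAL_TO_KJ),
}

# Bond-order dependent scaling of the covalent reference length.
BOND_ORDER_SCALE = {1: 1.00, 2: 0.87, 3: 0.78}


class UnknownElementError(KeyError):
    """Raised when an element has no tabulated parameters."""


def vdw_radius(element: str) -> float:
    try:
        return BONDI_VDW[element]
    except KeyError as exc:
        raise UnknownElementError(f"no van der Waals radius for element {element!r}") from exc


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element]
    except KeyError as exc:
        raise UnknownElementError(f"no atomic mass for element {element!r}") from exc


def lj_params(element: str) -> tuple[float, float]:
    try:
        return UFF_LJ[element]
    except KeyError as exc:
        raise UnknownElementError(f"no Lennard-Jones parameters for element {element!r}") from exc


def reference_bond_length(el_i: str, el_j: str, order: int = 1) -> float:
    """Idealised bond length as the scaled sum of covalent radii."""
    try:
        r = COVALENT_RADII[el_i] + COVALENT_RADII[el_j]
    except KeyError as exc:
        raise UnknownElementError(f"no covalent radius for bond {el_i}-{el_j}") from exc
    return r * BOND_ORDER_SCALE.get(order, 1.0)
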