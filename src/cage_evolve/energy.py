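"""Pluggable total-energy / optimisation services and the binding-energy formula.

The production workflow behind this kind of screen uses a classical force
field with a restrained pre-optimisation followed by a high-temperature
conformer search.  Here the same contract is provided by a desk-scale
surrogate: a pairwise 12-6 Lennard-Jones potential (UFF van der Waals
parameters) plus harmonic bond terms, optimised with L-BFGS.  The conformer
search replaces molecular-dynamics sampling with seeded random coordinate
perturbations, each locally re-optimised, keeping the select-the-minimum
contract of the original protocol.

Binding energy of a host-guest complex:

    E_binding = E_complex - E_cage - E_C60

with all three totals evaluated by the same backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .elements import lj_params, reference_bond_length
from .structures import CageStructure, ComplexStructure, Structure

__all__ = [
    "EnergyBackend",
    "SurrogateBackend",
    "ConformerSearchConfig",
    "binding_energy",
    "conformer_search",
    "get_backend",
    "register_backend",
]


class BackendMismatchError(ValueError):
    """Energies from different backends were combined."""


def binding_energy(
    e_complex: float,
    e_cage: float,
    e_c60: float,
    backends: Sequence[str] | None = None,
) -> float:
    """Host-guest binding energy, kJ/mol.  Negative = favourable encapsulation.

    ``backends`` optionally names the backend that produced each energy;
    mixing backends is an error because the totals are not comparable.
    """
    if backends is not None and len(set(backends)) > 1:
        raise BackendMismatchError(f"energies from mixed backends: {sorted(set(backends))}")
    return e_complex - e_cage - e_c60


class EnergyBackend(Protocol):
    """Contract every energy backend satisfies."""

    name: str

    def total_energy(self, structure: Structure) -> float: ...

    def optimize(
        self, structure, restrained_bonds: Sequence[tuple[int, int]] | None = None
    ): ...


# ----------------------------------------------------------------- helpers
def _as_structure(obj) -> tuple[Structure, Callable]:
    """View any container as a flat Structure plus a rebuild function."""
    if isinstance(obj, ComplexStructure):
        flat = obj.combined()
        return flat, lambda coords, energy: obj.with_coords(coords, energy)
    if isinstance(obj, CageStructure):
        return obj, lambda coords, energy: obj.with_coords(coords, energy)

    def rebuild(coords, energy):
        out = obj.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        out.energy = energy  # dynamic attribute on plain Structure
        return out

    return obj, rebuild


class SurrogateBackend:
    """Default 12-6 van der Waals + harmonic-bond surrogate backend.

    Parameters
    ----------
    bond_k:
        Harmonic force constant for covalent bonds, kJ/mol/A^2, referenced
        to idealised covalent lengths.
    restraint_k:
        Stiff force constant used to hold restrained bonds at their input
        lengths during a restrained optimisation.
    gradient_tol:
        Convergence threshold on the projected gradient (kJ/mol/A).
    """

    name = "surrogate"

    def __init__(
        self,
        bond_k: float = 2000.0,
        restraint_k: float = 20000.0,
        gradient_tol: float = 0.05,
        maxiter: int = 800,
    ) -> None:
        self.bond_k = bond_k
        self.restraint_k = restraint_k
        self.gradient_tol = gradient_tol
        self.maxiter = maxiter

    # -- energy terms -----------------------------------------------------
    def _nonbonded_pairs(self, structure: Structure) -> tuple[np.ndarray, np.ndarray]:
        """All atom pairs except 1-2 and 1-3 neighbours."""
        n = structure.n_atoms
        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        graph.add_edges_from((i, j) for i, j, _ in structure.bonds)
        excluded = set()
        for i, j in graph.edges:
            excluded.add((min(i, j), max(i, j)))
        for centre in graph.nodes:
            nbrs = sorted(graph.neighbors(centre))
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    excluded.add((nbrs[a], nbrs[b]))
        ii, jj = np.triu_indices(n, k=1)
        mask = np.array([(i, j) not in excluded for i, j in zip(ii, jj)])
        return ii[mask], jj[mask]

    def _lj_tables(self, structure: Structure, ii, jj):
        x = np.empty(structure.n_atoms)
        d = np.empty(structure.n_atoms)
        for k, el in enumerate(structure.elements):
            x[k], d[k] = lj_params(el)
        x_ij = np.sqrt(x[ii] * x[jj])  # UFF geometric combination
        d_ij = np.sqrt(d[ii] * d[jj])
        return x_ij, d_ij

    def _bond_tables(self, structure: Structure):
        if not structure.bonds:
            return (np.empty((0,), int), np.empty((0,), int), np.empty((0,)))
        bi = np.array([b[0] for b in structure.bonds])
        bj = np.array([b[1] for b in structure.bonds])
        r0 = np.array(
            [
                reference_bond_length(structure.elements[i], structure.elements[j], o)
                for i, j, o in structure.bonds
            ]
        )
        return bi, bj, r0

    def _energy_grad(self, coords, ii, jj, x_ij, d_ij, bi, bj, r0, extra=None):
        coords = coords.reshape(-1, 3)
        grad = np.zeros_like(coords)

        diff = coords[ii] - coords[jj]
        r = np.linalg.norm(diff, axis=1)
        r = np.maximum(r, 1e-2)
        s6 = (x_ij / r) ** 6
        e_lj = float(np.sum(d_ij * (s6 * s6 - 2.0 * s6)))
        de_dr = d_ij * 12.0 * (s6 - s6 * s6) / r
        f = (de_dr / r)[:, None] * diff
        np.add.at(grad, ii, f)
        np.add.at(grad, jj, -f)

        e_bond = 0.0
        # bonded harmonic
        if len(bi):
            bdiff = coords[bi] - coords[bj]
            br = np.maximum(np.linalg.norm(bdiff, axis=1), 1e-6)
            e_bond += float(np.sum(self.bond_k * (br - r0) ** 2))
            bf = (2.0 * self.bond_k * (br - r0) / br)[:, None] * bdiff
            np.add.at(grad, bi, bf)
            np.add.at(grad, bj, -bf)
        # optional stiff restraints (ri, rj, target lengths)
        if extra is not None:
            ri, rj, rt = extra
            if len(ri):
                rdiff = coords[ri] - coords[rj]
                rr = np.maximum(np.linalg.norm(rdiff, axis=1), 1e-6)
                e_bond += float(np.sum(self.restraint_k * (rr - rt) ** 2))
                rf = (2.0 * self.restraint_k * (rr - rt) / rr)[:, None] * rdiff
                np.add.at(grad, ri, rf)
                np.add.at(grad, rj, -rf)
        return e_lj + e_bond, grad.ravel()

    def total_energy(self, structure) -> float:
        """Deterministic total energy (kJ/mol) for fixed coordinates."""
        flat, _ = _as_structure(structure)
        ii, jj = self._nonbonded_pairs(flat)
        x_ij, d_ij = self._lj_tables(flat, ii, jj)
        bi, bj, r0 = self._bond_tables(flat)
        energy, _ = self._energy_grad(flat.coords.ravel(), ii, jj, x_ij, d_ij, bi, bj, r0)
        return energy

    def optimize(self, structure, restrained_bonds=None):
        """Locally minimise the energy; never returns a higher-energy result.

        ``restrained_bonds`` is a list of (i, j) atom pairs held stiffly at
        their current separations during the optimisation (used for the
        first restrained pass where only the newly-formed imine bonds relax).
        """
        flat, rebuild = _as_structure(structure)
        ii, jj = self._nonbonded_pairs(flat)
        x_ij, d_ij = self._lj_tables(flat, ii, jj)
        bi, bj, r0 = self._bond_tables(flat)

        extra = None
        if restrained_bonds:
            ri = np.array([p[0] for p in restrained_bonds])
            rj = np.array([p[1] for p in restrained_bonds])
            rt = np.linalg.norm(flat.coords[ri] - flat.coords[rj], axis=1)
            extra = (ri, rj, rt)

        x0 = flat.coords.ravel()
        e0, _ = self._energy_grad(x0, ii, jj, x_ij, d_ij, bi, bj, r0)

        result = minimize(
            self._energy_grad,
            x0,
            args=(ii, jj, x_ij, d_ij, bi, bj, r0, extra),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": self.gradient_tol, "maxiter": self.maxiter},
        )
        if not np.all(np.isfinite(result.x)):
            raise RuntimeError(f"optimisation diverged: {result.message}")
        e_final, _ = self._energy_grad(result.x, ii, jj, x_ij, d_ij, bi, bj, r0)
        if e_final > e0:  # guard: optimisation must never raise the energy
            return rebuild(flat.coords.copy(), e0)
        return rebuild(result.x.reshape(-1, 3), e_final)


@dataclass
class ConformerSearchConfig:
    """Sampling schedule for the conformer search.

    The temperature/timestep/duration fields mirror the molecular-dynamics
    protocol this search emulates; the surrogate backend interprets them
    only through ``n_samples`` (production time / sampling interval) and
    perturbs coordinates by ``perturbation_sigma`` instead of running MD.
    """

    temperature_K: float = 700.0
    timestep_fs: float = 1.0
    equilibration_ps: float = 10.0
    production_ps: float = 200.0
    sample_every_ps: float = 10.0
    perturbation_sigma: float = 0.3  # Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.production_ps / self.sample_every_ps
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("production_ps must be an integer multiple of sample_every_ps")

    @property
    def n_samples(self) -> int:
        return int(round(self.production_ps / self.sample_every_ps))


def conformer_search(
    structure,
    config: ConformerSearchConfig,
    backend: EnergyBackend,
    restrained_bonds: Sequence[tuple[int, int]] | None = None,
):
    """Restrained pre-optimisation plus N perturb-and-reoptimise samples.

    Returns the lowest-energy candidate; its energy is never above that of
    the restrained-optimised starting point.  Fully reproducible for a
    fixed ``config.seed``.
    """
    start = backend.optimize(structure, restrained_bonds=restrained_bonds)
    start = backend.optimize(start)  # release restraints
    candidates = [start]
    flat, rebuild = _as_structure(start)
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_samples):
        perturbed = flat.coords + rng.normal(0.0, config.perturbation_sigma, flat.coords.shape)
        candidates.append(backend.optimize(rebuild(perturbed, None)))
    return min(candidates, key=lambda s: s.energy)


# ----------------------------------------------------------- backend registry
_BACKENDS: dict[str, Callable[[], EnergyBackend]] = {"surrogate": SurrogateBackend}


def register_backend(name: str, factory: Callable[[], EnergyBackend]) -> None:
    """Plug-in hook: make an external backend selectable by name."""
    _BACKENDS[name] = factory


def get_backend(name: str) -> EnergyBackend:
    try:
        return _BACKENDS[name]()
    except KeyError as exc:
        raise KeyError(f"unknown energy backend {name!r}; registered: {sorted(_BACKENDS)}") from exc
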