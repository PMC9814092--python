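"""Synthetic precursor libraries and an analytic binding landscape.

The real screening problem couples a 3-D assembly and force-field pipeline
to the evolutionary search.  For algorithmic validation this module builds
parametric toy libraries — tri-topic benzene trialdehydes with growing
alkyl arms and alpha,omega-diaminoalkane linkers with growing spacers — and
an analytic stand-in for the binding landscape: a Gaussian well in the
mismatch between the predicted cavity diameter and the guest diameter, with
asymmetries growing linearly away from the well.  Exactly one (node,
linker) combination attains the minimum binding energy, so exhaustive
enumeration provides a ground-truth ranking for the evolutionary engine
and the parameter sweep.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from .fitness import (
    EQ2_PARAMS,
    DEFAULT_LOWER_LIMIT,
    FFParams,
    FitnessRecord,
    rank_population,
    score_population,
)
from .precursors import Precursor, PrecursorLibrary

__all__ = [
    "ToyLibrarySpec",
    "LandscapeSpec",
    "make_toy_library",
    "LandscapeEvaluator",
    "surrogate_landscape",
    "brute_force_rank",
]

BRUTE_FORCE_CAP = 10_000


#: Arm motifs between the benzene core and each CHO group, in order of
#: increasing length and with deliberately varied chemistry so different
#: node sizes have clearly distinct circular fingerprints.
NODE_ARMS = (
    "",          # trialdehyde benzene core
    "C",         # methylene
    "C=C",       # vinylene
    "C#CC",      # propargylic
    "COCC",      # ether spacer
    "C=CC=CC",   # dienyl
    "CC#CC#CC",  # diyne
    "COCC=CCC",  # mixed ether/ene
)


def _node_smiles(i: int) -> str:
    arm = "CC" * (i // len(NODE_ARMS)) + NODE_ARMS[i % len(NODE_ARMS)]
    return f"c1c({arm}C=O)cc({arm}C=O)cc1{arm}C=O"


def _linker_smiles(j: int) -> str:
    """Alpha,omega-diamine with backbone length j+2 and cycled decoration."""
    b = j + 2
    variant = j % 3
    if variant == 1 and b >= 2:  # methyl branch on the second backbone carbon
        return "NC" + "C(C)" + "C" * (b - 2) + "N"
    if variant == 2 and b >= 4:  # central double bond
        k = (b - 2) // 2
        return "N" + "C" * k + "C=C" + "C" * (b - k - 2) + "N"
    return "N" + "C" * b + "N"


@dataclass(frozen=True)
class ToyLibrarySpec:
    """Parameters of a generated toy precursor library.

    Node ``i`` carries three arms of topological length i+1 with varied
    chemistry (alkyl/alkenyl/alkynyl/ether motifs) on a benzene core;
    linker ``j`` is an alpha,omega-diamine with backbone length j+2 and a
    cycled decoration (plain / methyl branch / central alkene).  Arm and
    backbone lengths are all distinct, so every (node, linker) pair maps to
    a distinct predicted cavity diameter.  Generation is deterministic;
    ``rng_seed`` is recorded for provenance and reserved for stochastic
    decorations.
    """

    n_nodes: int = 8
    n_linkers: int = 12
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_linkers < 2:
            raise ValueError("toy library needs at least 2 nodes and 2 linkers")


def make_toy_library(
    spec: ToyLibrarySpec | None = None, csv_path: str | Path | None = None
) -> PrecursorLibrary:
    """Build the toy library (optionally writing the precursor CSV)."""
    spec = spec or ToyLibrarySpec()
    nodes = [
        Precursor.from_smiles(f"node{i + 1:02d}", _node_smiles(i), "node")
        for i in range(spec.n_nodes)
    ]
    linkers = [
        Precursor.from_smiles(f"link{j + 1:02d}", _linker_smiles(j), "linker")
        for j in range(spec.n_linkers)
    ]
    library = PrecursorLibrary(nodes, linkers)
    if csv_path is not None:
        library.to_csv(csv_path)
    return library


@dataclass(frozen=True)
class LandscapeSpec:
    """Analytic binding landscape with a single, known optimum.

    The predicted cavity diameter grows linearly with the node arm length
    (coarse steps: the tri-topic node dominates the cage size, as in real
    Tri4Di6 cages) and with the linker nitrogen-nitrogen path (fine
    tuning).  The binding energy is a Gaussian well of depth ``well_depth``
    (kJ/mol) centred at guest diameter plus ``optimal_mismatch``.
    Asymmetries are flat (small) for well-matched cages — within
    ``asym_onset`` of the optimal diameter — and grow linearly with the
    mismatch beyond it; ``asym_jitter`` adds a deterministic per-cage
    spread so the asymmetries are not an exact function of the binding
    energy.  ``noise_sigma`` adds deterministic per-cage pseudo-noise
    (kJ/mol) to the binding energy itself.

    The default coefficients put exactly one node row within reach of the
    optimal diameter, with the linkers resolving it finely; every
    sub-optimal composition then has a strictly improving single
    building-block swap, so the fitness landscape has no spurious local
    optima under the mutation move set.
    """

    guest_diameter: float = 10.0  # Angstrom, C60 with its vdW surface
    optimal_mismatch: float = 0.4  # Angstrom of slack around the guest
    well_depth: float = 300.0  # kJ/mol
    #: the well is asymmetric: squeezing a guest into an under-sized cavity
    #: costs more than leaving slack in an over-sized one
    well_width_under: float = 1.2  # Angstrom, cavity below the optimum
    well_width_over: float = 1.5  # Angstrom, cavity above the optimum
    noise_sigma: float = 0.0  # kJ/mol
    base_diameter: float = 0.16  # Angstrom
    node_coeff: float = 2.2  # Angstrom per node arm bond
    linker_coeff: float = 0.16  # Angstrom per linker N-N bond
    asym_onset: float = 1.0  # Angstrom of mismatch before asymmetry grows
    asym_complex_base: float = 0.02
    asym_complex_coeff: float = 0.08
    asym_cage_base: float = 0.03
    asym_cage_coeff: float = 0.11
    #: optional deterministic per-cage spread of the asymmetries (Angstrom)
    asym_jitter: float = 0.0
    rng_seed: int = 0

    @property
    def optimal_diameter(self) -> float:
        return self.guest_diameter + self.optimal_mismatch

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LandscapeSpec":
        return cls(**json.loads(Path(path).read_text()))


def _arm_length(node: Precursor) -> float:
    """Mean topological distance from each aldehyde carbon to the ring."""
    mol = node.mol
    dmat = Chem.GetDistanceMatrix(mol)
    aromatic = [a.GetIdx() for a in mol.GetAtoms() if a.GetIsAromatic()]
    if not aromatic:  # acyclic node: measure to the graph barycentre
        ecc = dmat.max(axis=1)
        aromatic = [int(np.argmin(ecc))]
    return float(np.mean([min(dmat[s, a] for a in aromatic) for s in node.reactive_sites]))


def _nn_path(linker: Precursor) -> float:
    """Topological distance between the two amine nitrogens."""
    dmat = Chem.GetDistanceMatrix(linker.mol)
    i, j = linker.reactive_sites
    return float(dmat[i, j])


class LandscapeEvaluator:
    """Maps a (node, linker) pair to a FitnessRecord via the analytic landscape."""

    def __init__(self, spec: LandscapeSpec | None = None) -> None:
        self.spec = spec or LandscapeSpec()

    def predicted_diameter(self, node: Precursor, linker: Precursor) -> float:
        s = self.spec
        return s.base_diameter + s.node_coeff * _arm_length(node) + s.linker_coeff * _nn_path(linker)

    def binding_energy_at(self, cavity_diameter: float) -> float:
        """Noise-free well profile; the minimum sits at the optimal diameter."""
        s = self.spec
        mismatch = cavity_diameter - s.optimal_diameter
        width = s.well_width_under if mismatch < 0 else s.well_width_over
        return -s.well_depth * float(np.exp(-(mismatch**2) / (2.0 * width**2)))

    def _uniform(self, *tokens: str) -> float:
        """Deterministic pseudo-uniform draw in [0, 1) tied to the seed."""
        token = "|".join((str(self.spec.rng_seed),) + tokens).encode()
        return float(np.random.default_rng(zlib.crc32(token)).random())

    def _noise(self, node_id: str, linker_id: str) -> float:
        if self.spec.noise_sigma == 0.0:
            return 0.0
        token = f"{self.spec.rng_seed}|{node_id}|{linker_id}".encode()
        sub_rng = np.random.default_rng(zlib.crc32(token))
        return float(sub_rng.normal(0.0, self.spec.noise_sigma))

    def evaluate(self, node: Precursor, linker: Precursor) -> FitnessRecord:
        s = self.spec
        d_cage = self.predicted_diameter(node, linker)
        mismatch = abs(d_cage - s.optimal_diameter)
        growth = max(0.0, mismatch - s.asym_onset)
        e = self.binding_energy_at(d_cage) + self._noise(node.id, linker.id)
        return FitnessRecord(
            cage_id=f"{node.id}+{linker.id}",
            E_binding=e,
            A_complex=s.asym_complex_base
            + s.asym_complex_coeff * growth
            + s.asym_jitter * self._uniform(node.id, linker.id, "Ac"),
            A_cage=s.asym_cage_base
            + s.asym_cage_coeff * growth
            + s.asym_jitter * self._uniform(node.id, linker.id, "Ag"),
            D_cage=d_cage,
            D_complex=max(d_cage, s.guest_diameter),
        )


def surrogate_landscape(
    node: Precursor, linker: Precursor, spec: LandscapeSpec | None = None
) -> FitnessRecord:
    """One-shot evaluation of a pair on the analytic landscape."""
    return LandscapeEvaluator(spec).evaluate(node, linker)


def brute_force_rank(
    library: PrecursorLibrary,
    evaluator,
    params: FFParams = EQ2_PARAMS,
    lower_limit: float = DEFAULT_LOWER_LIMIT,
) -> list[FitnessRecord]:
    """Exact ranking of every (node, linker) combination.

    The oracle for the evolutionary search: evaluates the full cartesian
    product (capped at 10^4 combinations), scores it as one population and
    returns the ranked valid records.
    """
    n = library.n_combinations
    if n > BRUTE_FORCE_CAP:
        raise ValueError(
            f"{n} combinations exceed the brute-force cap ({BRUTE_FORCE_CAP}); "
            "use the evolutionary engine instead"
        )
    records = [
        evaluator.evaluate(node, linker)
        for node in library.nodes
        for linker in library.linkers
    ]
    score_population(records, params=params, lower_limit=lower_limit)
    return rank_population(records)
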