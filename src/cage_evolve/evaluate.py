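"""Full physical evaluation of a (node, linker) composition.

Mirrors the property-assessment pipeline: assemble the empty cage and the
C60 complex on the tetrahedral template, run the restrained optimisation and
conformer search on both (and on the isolated guest), compute the binding
energy, and extract pore metrics from the optimised structures (guest atoms
removed before analysing the cage inside the complex).  The result is the
same FitnessRecord the analytic landscape produces, so the evolutionary
engine and the sweep are agnostic to which evaluator stands behind them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import assemble_cage, assemble_complex, generate_c60
from .energy import ConformerSearchConfig, EnergyBackend, SurrogateBackend, binding_energy, conformer_search
from .fitness import FitnessRecord
from .pores import compute_shape_metrics
from .precursors import Precursor


@dataclass
class PhysicalEvaluator:
    """Assembly + energy-backend + pore-metric evaluator.

    ``conformer_config.n_samples`` controls the cost; the full protocol uses
    20 perturb-and-reoptimise samples, which is expensive for large batches —
    reduce ``production_ps`` for quick surveys.
    """

    backend: EnergyBackend = field(default_factory=SurrogateBackend)
    conformer_config: ConformerSearchConfig = field(default_factory=ConformerSearchConfig)
    embed_seed: int = 61409

    def __post_init__(self) -> None:
        self._e_c60: float | None = None

    def _guest_energy(self) -> float:
        if self._e_c60 is None:
            guest = generate_c60()
            best = conformer_search(guest, self.conformer_config, self.backend)
            self._e_c60 = best.energy
        return self._e_c60

    def evaluate(self, node: Precursor, linker: Precursor) -> FitnessRecord:
        cage = assemble_cage(node, linker, seed=self.embed_seed)
        complx = assemble_complex(node, linker, seed=self.embed_seed)
        non_imine = [
            (i, j) for i, j, _ in cage.bonds if (i, j) not in set(cage.imine_bonds)
        ]
        cage_opt = conformer_search(
            cage, self.conformer_config, self.backend, restrained_bonds=non_imine
        )
        complx_opt = conformer_search(
            complx, self.conformer_config, self.backend, restrained_bonds=non_imine
        )
        e_bind = binding_energy(
            complx_opt.energy, cage_opt.energy, self._guest_energy(),
            backends=[self.backend.name] * 3,
        )
        cage_metrics = compute_shape_metrics(cage_opt)
        host_metrics = compute_shape_metrics(complx_opt.host_only())
        return FitnessRecord(
            cage_id=f"{node.id}+{linker.id}",
            E_binding=e_bind,
            A_complex=host_metrics.asymmetry,
            A_cage=cage_metrics.asymmetry,
            D_cage=cage_metrics.cavity_diameter,
            D_complex=host_metrics.cavity_diameter,
            cage_collapsed=cage_metrics.collapsed,
            complex_collapsed=host_metrics.collapsed,
        )
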