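"""Population-normalised fitness functions for cage encapsulant screening.

A candidate cage is described by its guest binding energy E_binding (kJ/mol,
negative favourable), the asymmetry of the cage extracted from the complex
(A_complex) and of the isolated cage (A_cage).  Within a population each
property list is shifted so its minimum maps to zero and divided by the
post-shift mean, making the components dimensionless and >= 0 with the best
member at exactly 0.  The fitness is the inverse of a weighted power-sum
penalty:

    parameterisable form:  FF = 1 / (a * E~^b + c * A~_complex^d)
    final form:            FF = 1 / (E~^3.25 + 0.5 A~_complex^4.25
                                               + 0.5 A~_cage^4.25)

where the half weights on the two asymmetry terms make asymmetry as a whole
count as much as the binding energy.  Because normalisation is per
population, FF values are comparable only within one population; combining
runs requires re-normalising over the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FFParams",
    "EQ2_PARAMS",
    "FitnessRecord",
    "validity_filter",
    "normalize_population",
    "ff_eq1",
    "ff_eq2",
    "score_population",
    "rank_population",
    "PENALTY_FLOOR",
]

#: Floor on the penalty so a member that is best in every component still
#: receives a finite (huge) fitness instead of dividing by zero.
PENALTY_FLOOR = 1e-9

#: Default lower limit on credible force-field binding energies, kJ/mol.
DEFAULT_LOWER_LIMIT = -780.0

#: Lower limit used during the parameterisation study, kJ/mol.
PARAMETERISATION_LOWER_LIMIT = -404.0


@dataclass(frozen=True)
class FFParams:
    """Weights (a, c > 0) and exponents (b, d >= 0) of the penalty terms.

    ``cage_weight``/``cage_exponent`` add the isolated-cage asymmetry term;
    they are zero in the two-component parameterisable form and (0.5, 4.25)
    in the final form.
    """

    a: float = 1.0
    b: float = 3.25
    c: float = 1.0
    d: float = 4.25
    cage_weight: float = 0.0
    cage_exponent: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ValueError("weights a and c must be positive")
        if self.b < 0 or self.d < 0:
            raise ValueError("exponents b and d must be non-negative")
        if self.cage_weight < 0:
            raise ValueError("cage asymmetry weight must be non-negative")


#: The final fitness function: E~^3.25 + 0.5 A~_complex^4.25 + 0.5 A~_cage^4.25.
EQ2_PARAMS = FFParams(a=1.0, b=3.25, c=0.5, d=4.25, cage_weight=0.5, cage_exponent=4.25)


@dataclass
class FitnessRecord:
    """Raw and derived properties of one cage candidate."""

    cage_id: str
    E_binding: float  # kJ/mol
    A_complex: float | None  # Angstrom; None when complex collapsed
    A_cage: float | None  # Angstrom; None when cage collapsed
    D_cage: float = float("nan")
    D_complex: float = float("nan")
    cage_collapsed: bool = False
    complex_collapsed: bool = False
    # filled in by validity_filter / score_population
    valid: bool = True
    invalid_reason: str = "none"
    E_norm: float = float("nan")
    A_complex_norm: float = float("nan")
    A_cage_norm: float = float("nan")
    penalty: float = float("nan")
    ff: float = 0.0


def validity_filter(
    record: FitnessRecord, lower_limit: float = DEFAULT_LOWER_LIMIT
) -> FitnessRecord:
    """Flag collapsed, repulsive or implausibly strong binders as invalid.

    Binding energies below ``lower_limit`` (default -780 kJ/mol; -404 kJ/mol
    mirrors the parameterisation study) indicate force-field artefacts.
    """
    reason = "none"
    if record.cage_collapsed or record.A_cage is None:
        reason = "collapsed_cage"
    elif record.complex_collapsed or record.A_complex is None:
        reason = "collapsed_complex"
    elif record.E_binding > 0:
        reason = "repulsive_binding"
    elif record.E_binding < lower_limit:
        reason = "unreasonable_binding"
    record.valid = reason == "none"
    record.invalid_reason = reason
    return record


def normalize_population(values: Sequence[float]) -> np.ndarray:
    """Shift so the minimum is 0, then divide by the post-shift mean.

    All-equal input returns all zeros (the mean after shifting is zero).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalise an empty population")
    shifted = arr - arr.min()
    mean = shifted.mean()
    if mean == 0.0:
        return np.zeros_like(shifted)
    return shifted / mean


def ff_eq1(e_norm: float, a_complex_norm: float, params: FFParams) -> float:
    """Two-component parameterisable fitness 1 / (a E~^b + c A~^d)."""
    penalty = params.a * e_norm**params.b + params.c * a_complex_norm**params.d
    return 1.0 / max(penalty, PENALTY_FLOOR)


def ff_eq2(e_norm: float, a_complex_norm: float, a_cage_norm: float) -> float:
    """Final three-component fitness with half-weighted asymmetries."""
    penalty = (
        e_norm**EQ2_PARAMS.b
        + EQ2_PARAMS.c * a_complex_norm**EQ2_PARAMS.d
        + EQ2_PARAMS.cage_weight * a_cage_norm**EQ2_PARAMS.cage_exponent
    )
    return 1.0 / max(penalty, PENALTY_FLOOR)


def score_population(
    records: Iterable[FitnessRecord],
    params: FFParams = EQ2_PARAMS,
    lower_limit: float = DEFAULT_LOWER_LIMIT,
) -> list[FitnessRecord]:
    """Validate, normalise within the population, and assign FF values.

    Invalid records do not contribute to the normalisation constants and
    receive FF = 0.  Records are modified in place and returned.
    """
    records = [validity_filter(r, lower_limit) for r in records]
    valid = [r for r in records if r.valid]
    if valid:
        e_norm = normalize_population([r.E_binding for r in valid])
        ac_norm = normalize_population([r.A_complex for r in valid])
        if params.cage_weight > 0:
            ag_norm = normalize_population([r.A_cage for r in valid])
        else:
            ag_norm = np.zeros(len(valid))
        for r, en, acn, agn in zip(valid, e_norm, ac_norm, ag_norm):
            r.E_norm = float(en)
            r.A_complex_norm = float(acn)
            r.A_cage_norm = float(agn)
            penalty = (
                params.a * en**params.b
                + params.c * acn**params.d
                + (params.cage_weight * agn**params.cage_exponent if params.cage_weight else 0.0)
            )
            r.penalty = float(penalty)
            r.ff = 1.0 / max(float(penalty), PENALTY_FLOOR)
    for r in records:
        if not r.valid:
            r.ff = 0.0
            r.penalty = float("inf")
    return records


def rank_population(records: Iterable[FitnessRecord]) -> list[FitnessRecord]:
    """Valid records by descending FF; ties broken by cage id; invalid dropped."""
    return sorted(
        (r for r in records if r.valid),
        key=lambda r: (-r.ff, r.cage_id),
    )
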