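"""Fitness-function parameterisation: the R10 rating and the (a,b,c,d) sweep.

Each candidate parameter set (a, c in 1..5 step 1; b, d in 0..5 step 0.25)
is scored by ranking the population with the two-component fitness, taking
the ten best cages, and rating them on an absolute scale:

    R10 = sum_i (R(E_binding)_i + R(A_complex)_i) / 2

R(E) is 1 for repulsive binders (E > 0) and for implausibly strong binders
(E below the limit, default -404 kJ/mol), and 1 - E/limit in between, so a
binder right at the limit scores 0.  R(A) = A / 11.864, the normaliser being
the worst asymmetry in the reference database.  Lower R10 is better; among
equally-scoring parameter sets the simplest (smallest a+b+c+d, then
lexicographic) is selected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import PARAMETERISATION_LOWER_LIMIT, normalize_population

__all__ = [
    "SweepGrid",
    "SweepResult",
    "rating_E",
    "rating_A",
    "r10",
    "sweep",
    "heatmap_export",
]

#: Worst cage-in-complex asymmetry in the reference database, Angstrom.
WORST_ASYMMETRY = 11.864


@dataclass(frozen=True)
class SweepGrid:
    """Default screening grid: 5x5 weight pairs x 21x21 exponent pairs."""

    a_values: tuple = tuple(range(1, 6))
    c_values: tuple = tuple(range(1, 6))
    b_values: tuple = tuple(np.round(np.arange(0.0, 5.01, 0.25), 2))
    d_values: tuple = tuple(np.round(np.arange(0.0, 5.01, 0.25), 2))


@dataclass
class SweepResult:
    scores: pd.DataFrame  # columns a, b, c, d, R10
    min_score: float
    argmin: pd.DataFrame  # all parameter sets attaining min_score
    selected: tuple[float, float, float, float]  # simplest argmin (a, b, c, d)
    grid: SweepGrid = field(default_factory=SweepGrid)


def rating_E(e_binding: float, limit: float = PARAMETERISATION_LOWER_LIMIT) -> float:
    """Absolute binding-energy rating in [0, 1]; 0 is best.

    Repulsive (E > 0) and implausibly strong (E < limit) binders are fully
    penalised with 1; in between the rating falls linearly from 1 at E = 0
    to 0 at E = limit.
    """
    if limit >= 0:
        raise ValueError("binding-energy limit must be negative")
    e = float(e_binding)
    if e > 0 or e < limit:
        return 1.0
    return 1.0 - e / limit


def rating_A(a_complex: float, worst: float = WORST_ASYMMETRY) -> float:
    """Absolute asymmetry rating A / worst; 0 is perfectly symmetric."""
    if worst <= 0:
        raise ValueError("asymmetry normaliser must be positive")
    if a_complex < 0:
        raise ValueError("asymmetry cannot be negative")
    return float(a_complex) / worst


def r10(
    top10: list[tuple[float, float]],
    limit: float = PARAMETERISATION_LOWER_LIMIT,
    worst: float = WORST_ASYMMETRY,
) -> float:
    """Total rating of the best-ranked set; each member is (E_binding, A_complex)."""
    if not top10:
        raise ValueError("r10 needs a non-empty set")
    if len(top10) < 10:
        warnings.warn(f"r10 computed on {len(top10)} members instead of 10", stacklevel=2)
    return float(
        sum((rating_E(e, limit) + rating_A(a, worst)) / 2.0 for e, a in top10)
    )


def sweep(
    properties: pd.DataFrame,
    grid: SweepGrid | None = None,
    limit: float = PARAMETERISATION_LOWER_LIMIT,
    worst: float = WORST_ASYMMETRY,
    top_n: int = 10,
) -> SweepResult:
    """Score every (a, b, c, d) on the grid and select the simplest optimum.

    ``properties`` needs columns ``cage_id``, ``E_binding``, ``A_complex``
    and optionally ``valid`` (invalid rows are ignored).  The normalised
    components do not depend on the parameters, so they are computed once;
    each grid cell then ranks by the parameterisable penalty
    a E~^b + c A~^d and rates its ``top_n`` best cages.
    """
    grid = grid or SweepGrid()
    df = properties.copy()
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if len(df) < top_n:
        raise ValueError(f"sweep needs at least {top_n} valid records, got {len(df)}")

    cage_ids = df["cage_id"].to_numpy()
    e_raw = df["E_binding"].to_numpy(dtype=float)
    a_raw = df["A_complex"].to_numpy(dtype=float)
    e_norm = normalize_population(e_raw)
    a_norm = normalize_population(a_raw)

    rate = np.array(
        [(rating_E(e, limit) + rating_A(a, worst)) / 2.0 for e, a in zip(e_raw, a_raw)]
    )

    # precompute powers of the normalised components for every exponent
    e_pows = {b: e_norm**b for b in grid.b_values}
    a_pows = {d: a_norm**d for d in grid.d_values}

    rows = []
    for a, c in itertools.product(grid.a_values, grid.c_values):
        for b, d in itertools.product(grid.b_values, grid.d_values):
            penalty = a * e_pows[b] + c * a_pows[d]
            # ascending penalty, ties by cage id, to match rank_population
            order = np.lexsort((cage_ids, penalty))
            top = order[:top_n]
            rows.append((a, b, c, d, float(rate[top].sum())))
    scores = pd.DataFrame(rows, columns=["a", "b", "c", "d", "R10"])

    min_score = float(scores["R10"].min())
    argmin = scores[np.isclose(scores["R10"], min_score, rtol=0, atol=1e-12)].copy()
    argmin["sum"] = argmin[["a", "b", "c", "d"]].sum(axis=1)
    ordered = argmin.sort_values(["sum", "a", "b", "c", "d"], kind="stable")
    best = ordered.iloc[0]
    selected = (float(best["a"]), float(best["b"]), float(best["c"]), float(best["d"]))
    return SweepResult(scores, min_score, argmin.drop(columns="sum"), selected, grid)


def heatmap_export(
    result: SweepResult,
    a: float,
    c: float,
    out_dir: str | Path,
    stem: str | None = None,
) -> tuple[Path, Path]:
    """Write the 21x21 R10 matrix over (b, d) for one (a, c) as CSV + PNG.

    Rows are b values, columns d values; the minimum cell is marked with a
    star in the rendered image.  Returns (csv_path, png_path).
    """
    sub = result.scores[(result.scores["a"] == a) & (result.scores["c"] == c)]
    if sub.empty:
        raise ValueError(f"(a={a}, c={c}) is outside the swept grid")
    matrix = sub.pivot(index="b", columns="d", values="R10")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"heatmap_a{a:g}_c{c:g}"
    csv_path = out_dir / f"{stem}.csv"
    png_path = out_dir / f"{stem}.png"
    matrix.to_csv(csv_path)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        matrix.columns.to_numpy(dtype=float),
        matrix.index.to_numpy(dtype=float),
        matrix.to_numpy(),
        shading="nearest",
        cmap="viridis",
    )
    fig.colorbar(mesh, ax=ax, label="R10")
    bmin, dmin = np.unravel_index(np.argmin(matrix.to_numpy()), matrix.shape)
    ax.plot(float(matrix.columns[dmin]), float(matrix.index[bmin]), marker="*",
            markersize=14, color="white", markeredgecolor="black")
    ax.set_xlabel("exponent d (asymmetry)")
    ax.set_ylabel("exponent b (binding energy)")
    ax.set_title(f"R10 over exponents, a={a:g}, c={c:g}")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path
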