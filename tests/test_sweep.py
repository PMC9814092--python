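"""R10 rating and the fitness-function parameter sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cage_evolve.sweep import (
    SweepGrid,
    WORST_ASYMMETRY,
    heatmap_export,
    r10,
    rating_A,
    rating_E,
    sweep,
)


def synthetic_property_table(n=30, seed=5):
    """Cages whose binding energy and asymmetry improve together, so every
    monotone fitness parameterisation reproduces the oracle ranking."""
    rng = np.random.default_rng(seed)
    quality = np.sort(rng.uniform(0.02, 0.98, size=n))  # 0 = best
    e = -404.0 * (1.0 - quality)
    a = WORST_ASYMMETRY * quality * 0.8
    return pd.DataFrame(
        {
            "cage_id": [f"c{i:03d}" for i in range(n)],
            "E_binding": e,
            "A_complex": a,
            "valid": True,
        }
    )


def oracle_min_r10(table, top_n=10):
    """Brute-force attainable minimum: rate every cage, take the best ten."""
    rates = sorted(
        (rating_E(e) + rating_A(a)) / 2.0
        for e, a in zip(table["E_binding"], table["A_complex"])
    )
    return sum(rates[:top_n])


class TestRatingE:
    @pytest.mark.parametrize(
        "e, expected",
        [(50.0, 1.0), (-500.0, 1.0), (-202.0, 0.5), (-404.0, 0.0), (0.0, 1.0)],
    )
    def test_piecewise_branches(self, e, expected):
        assert rating_E(e) == pytest.approx(expected)

    def test_continuous_inside_the_window(self):
        es = np.linspace(-403.9, -0.1, 200)
        vals = [rating_E(e) for e in es]
        assert np.all(np.diff(vals) > 0)  # strictly increasing toward 0

    def test_nonnegative_limit_rejected(self):
        with pytest.raises(ValueError):
            rating_E(-100.0, limit=10.0)


class TestRatingA:
    def test_database_worst_maps_to_one(self):
        assert rating_A(11.864) == pytest.approx(1.0)

    def test_perfect_symmetry_and_half(self):
        assert rating_A(0.0) == 0.0
        assert rating_A(5.932) == pytest.approx(0.5)

    def test_negative_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            rating_A(-0.1)


class TestR10:
    def test_worst_and_best_cases(self):
        assert r10([(50.0, 11.864)] * 10) == pytest.approx(10.0)
        assert r10([(-404.0, 0.0)] * 10) == pytest.approx(0.0)

    def test_hand_computed_mixture(self):
        # rating_E = 0.4 at E = -0.6*404; rating_A = 0.1 at A = 1.1864
        members = [(-0.6 * 404.0, 1.1864)] * 10
        assert r10(members) == pytest.approx(2.5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        members = [(-float(rng.uniform(0, 404)), float(rng.uniform(0, 11))) for _ in range(10)]
        shuffled = [members[i] for i in rng.permutation(10)]
        assert r10(shuffled) == pytest.approx(r10(members))

    def test_short_set_warns_empty_raises(self):
        with pytest.warns(UserWarning):
            r10([(-100.0, 1.0)] * 7)
        with pytest.raises(ValueError):
            r10([])


class TestSweep:
    def test_grid_cardinality(self):
        grid = SweepGrid()
        assert len(grid.b_values) == 21 and len(grid.d_values) == 21
        assert len(grid.b_values) * len(grid.d_values) == 441
        assert len(grid.a_values) == 5 and len(grid.c_values) == 5

    def test_requires_ten_valid_records(self):
        with pytest.raises(ValueError):
            sweep(synthetic_property_table(n=6))

    def test_attains_oracle_minimum_on_consistent_table(self):
        table = synthetic_property_table()
        result = sweep(table)
        assert result.min_score == pytest.approx(oracle_min_r10(table), abs=1e-9)

    def test_selected_is_global_argmin_and_simplest(self):
        table = synthetic_property_table()
        result = sweep(table)
        assert (result.scores["R10"] >= result.min_score - 1e-12).all()
        sums = result.argmin[["a", "b", "c", "d"]].sum(axis=1)
        assert sum(result.selected) == pytest.approx(sums.min())

    def test_tie_break_by_sum_then_lexicographic(self):
        # two cages: any parameter set gives the same top-10, so every grid
        # point ties and the simplest-in-lexicographic-order set is selected
        table = synthetic_property_table(n=12)
        result = sweep(table)
        tied = result.argmin.copy()
        tied["sum"] = tied[["a", "b", "c", "d"]].sum(axis=1)
        simplest = tied.sort_values(["sum", "a", "b", "c", "d"]).iloc[0]
        assert result.selected == (
            simplest["a"], simplest["b"], simplest["c"], simplest["d"]
        )

    def test_exhaustive_agreement_on_reduced_grid(self):
        """Cross-check the vectorised sweep against a naive re-implementation."""
        table = synthetic_property_table(n=14, seed=9)
        grid = SweepGrid(a_values=(1, 2), c_values=(1,), b_values=(0.5, 1.0), d_values=(1.0, 2.0))
        result = sweep(table, grid)
        from cage_evolve.fitness import normalize_population

        e_norm = normalize_population(table["E_binding"])
        a_norm = normalize_population(table["A_complex"])
        rates = np.array(
            [(rating_E(e) + rating_A(a)) / 2.0 for e, a in zip(table["E_binding"], table["A_complex"])]
        )
        for a, c, b, d in itertools.product(grid.a_values, grid.c_values, grid.b_values, grid.d_values):
            penalty = a * e_norm**b + c * a_norm**d
            top = np.argsort(penalty, kind="stable")[:10]
            expected = rates[top].sum()
            row = result.scores[
                (result.scores["a"] == a) & (result.scores["b"] == b)
                & (result.scores["c"] == c) & (result.scores["d"] == d)
            ]
            assert row["R10"].iloc[0] == pytest.approx(expected, abs=1e-9)


class TestHeatmapExport:
    def test_matrix_shape_and_round_trip(self, tmp_path):
        table = synthetic_property_table()
        result = sweep(table)
        a, b, c, d = result.selected
        csv_path, png_path = heatmap_export(result, a, c, tmp_path)
        matrix = pd.read_csv(csv_path, index_col=0)
        assert matrix.shape == (21, 21)
        assert png_path.exists()
        # the exported matrix contains the global minimum for the selected pair
        assert matrix.to_numpy().min() == pytest.approx(result.min_score, abs=1e-9)

    def test_outside_grid_rejected(self, tmp_path):
        result = sweep(synthetic_property_table())
        with pytest.raises(ValueError):
            heatmap_export(result, 99, 1, tmp_path)
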