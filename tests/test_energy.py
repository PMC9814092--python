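"""Surrogate energy backend, binding energy and conformer search."""

import numpy as np
import pytest

from cage_evolve.elements import UnknownElementError, lj_params
from cage_evolve.energy import (
    BackendMismatchError,
    ConformerSearchConfig,
    SurrogateBackend,
    binding_energy,
    conformer_search,
    get_backend,
    register_backend,
)
from cage_evolve.structures import Structure


@pytest.fixture(scope="module")
def backend():
    return SurrogateBackend()


class TestBindingEnergy:
    @pytest.mark.parametrize(
        "e_complex, e_cage, e_c60, expected",
        [
            (-1000.0, -700.0, -250.0, -50.0),
            (-950.0, -700.0, -250.0, 0.0),  # non-interacting limit
            (-100.0, -200.0, -50.0, 150.0),  # repulsive
        ],
    )
    def test_formula(self, e_complex, e_cage, e_c60, expected):
        assert binding_energy(e_complex, e_cage, e_c60) == pytest.approx(expected)

    def test_negating_inputs_negates_output(self):
        args = (-321.0, -123.0, -45.0)
        assert binding_energy(*(-x for x in args)) == -binding_energy(*args)

    def test_mixed_backends_rejected(self):
        with pytest.raises(BackendMismatchError):
            binding_energy(-1.0, -2.0, -3.0, backends=["surrogate", "other", "surrogate"])


class TestSurrogateEnergy:
    def test_pair_at_lj_minimum(self, backend):
        x, d = lj_params("C")
        s = Structure(["C", "C"], np.array([[0.0, 0, 0], [x, 0, 0]]))
        assert backend.total_energy(s) == pytest.approx(-d, rel=1e-9)

    def test_energy_vanishes_at_long_range(self, backend):
        s = Structure(["C", "C"], np.array([[0.0, 0, 0], [500.0, 0, 0]]))
        assert abs(backend.total_energy(s)) < 1e-9

    def test_unknown_element_rejected(self, backend):
        s = Structure(["Xx", "C"], np.zeros((2, 3)))
        with pytest.raises(UnknownElementError):
            backend.total_energy(s)

    def test_rigid_motion_invariance(self, backend):
        rng = np.random.default_rng(11)
        coords = rng.normal(scale=3.0, size=(12, 3))
        s = Structure(["C"] * 6 + ["N"] * 3 + ["O"] * 3, coords, [(0, 1, 1), (1, 2, 1)])
        e0 = backend.total_energy(s)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Structure(list(s.elements), coords @ q.T + 7.5, list(s.bonds))
        assert backend.total_energy(moved) == pytest.approx(e0, abs=1e-8)

    def test_shell_scan_is_unimodal_around_contact(self, backend):
        """Scanning a host shell radius around a central guest atom gives a
        single binding-energy minimum near the contact distance."""
        from cage_evolve.pores import icosphere_directions

        shell_dirs = icosphere_directions(1)  # 80 directions
        radii = np.arange(2.5, 12.0, 0.25)
        energies = []
        for r in radii:
            host = Structure(["C"] * len(shell_dirs), shell_dirs * r)
            guest = Structure(["C"], np.zeros((1, 3)))
            combined = Structure(
                host.elements + guest.elements,
                np.vstack([host.coords, guest.coords]),
            )
            e_host = backend.total_energy(host)
            energies.append(backend.total_energy(combined) - e_host)
        energies = np.array(energies)
        k = int(np.argmin(energies))
        assert 0 < k < len(radii) - 1
        assert (np.diff(energies[: k + 1]) < 0).all()
        assert (np.diff(energies[k:]) > 0).all()
        # inflating the optimal shell x2 weakens binding
        assert energies[k] < energies[np.searchsorted(radii, radii[k] * 2) - 1]


class TestOptimize:
    def test_restores_bond_length(self, backend):
        s = Structure(["C", "C"], np.array([[0.0, 0, 0], [2.5, 0, 0]]), [(0, 1, 1)])
        out = backend.optimize(s)
        length = np.linalg.norm(out.coords[1] - out.coords[0])
        assert length == pytest.approx(1.52, abs=0.02)  # 2 x Cordero C radius

    def test_never_raises_energy(self, backend):
        rng = np.random.default_rng(3)
        s = Structure(["C"] * 8, rng.normal(scale=2.0, size=(8, 3)), [(i, i + 1, 1) for i in range(7)])
        e0 = backend.total_energy(s)
        out = backend.optimize(s)
        assert out.energy <= e0 + 1e-9

    def test_restrained_bonds_held(self, backend):
        s = Structure(["C", "C", "C"], np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]]),
                      [(0, 1, 1), (1, 2, 1)])
        out = backend.optimize(s, restrained_bonds=[(0, 1)])
        held = np.linalg.norm(out.coords[1] - out.coords[0])
        assert held == pytest.approx(2.0, abs=0.05)


class TestConformerSearch:
    def test_sample_count_from_schedule(self):
        cfg = ConformerSearchConfig()
        assert cfg.n_samples == 20  # 200 ps production / 10 ps sampling
        assert ConformerSearchConfig(production_ps=0.0).n_samples == 0
        with pytest.raises(ValueError):
            ConformerSearchConfig(production_ps=25.0, sample_every_ps=10.0)

    def test_zero_samples_returns_optimised_start(self, backend):
        s = Structure(["C", "C"], np.array([[0.0, 0, 0], [2.2, 0, 0]]), [(0, 1, 1)])
        cfg = ConformerSearchConfig(production_ps=0.0, seed=1)
        out = conformer_search(s, cfg, backend)
        assert out.energy == pytest.approx(backend.optimize(s).energy, abs=1e-9)

    def test_result_never_above_start_and_deterministic(self, backend):
        rng = np.random.default_rng(9)
        s = Structure(["C"] * 6, rng.normal(scale=1.8, size=(6, 3)), [(i, i + 1, 1) for i in range(5)])
        cfg = ConformerSearchConfig(production_ps=30.0, sample_every_ps=10.0, seed=4)
        out1 = conformer_search(s, cfg, backend)
        out2 = conformer_search(s, cfg, backend)
        assert out1.energy <= backend.optimize(s).energy + 1e-9
        assert np.allclose(out1.coords, out2.coords)


class TestRegistry:
    def test_builtin_surrogate(self):
        assert get_backend("surrogate").name == "surrogate"

    def test_plugin_hook(self):
        class Fake:
            name = "fake"

            def total_energy(self, structure):
                return 0.0

            def optimize(self, structure, restrained_bonds=None):
                return structure

        register_backend("fake", Fake)
        assert get_backend("fake").name == "fake"
        with pytest.raises(KeyError):
            get_backend("no-such-backend")
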