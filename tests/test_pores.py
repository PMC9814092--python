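"""Cavity, window and asymmetry analysis on analytic shells and real cages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cage_evolve.pores import (
    asymmetry,
    cavity_diameter,
    compute_shape_metrics,
    find_windows,
    grid_resolution,
    icosphere_directions,
    is_collapsed,
)
from cage_evolve.structures import Structure

ORIGIN = np.zeros(3)


def spherical_shell(radius=5.0, subdivisions=4, open_axes=(), half_angle_deg=30.0):
    """Shell of atoms on an icosphere with circular apertures cut out."""
    pts = icosphere_directions(subdivisions) * radius
    mask = np.ones(len(pts), bool)
    for axis in open_axes:
        axis = np.asarray(axis, float)
        axis /= np.linalg.norm(axis)
        ang = np.arccos(np.clip(pts @ axis / radius, -1, 1))
        mask &= ang > np.radians(half_angle_deg)
    return Structure(["C"] * int(mask.sum()), pts[mask])


class TestCavityDiameter:
    def test_point_atoms_on_sphere(self):
        shell = spherical_shell(radius=5.0)
        assert cavity_diameter(shell, radii=0.0, centre=ORIGIN) == pytest.approx(10.0, abs=1e-9)

    def test_vdw_radius_subtracted(self):
        shell = spherical_shell(radius=8.0)
        # atoms at 8 A with r_vdw = 1.7 -> 2*(8 - 1.7)
        assert cavity_diameter(shell, centre=ORIGIN) == pytest.approx(12.6, abs=1e-9)

    def test_occupied_centre_gives_zero(self):
        shell = spherical_shell(radius=5.0)
        blocked = Structure(shell.elements + ["C"], np.vstack([shell.coords, ORIGIN]))
        assert cavity_diameter(blocked, centre=ORIGIN) == 0.0

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            cavity_diameter(Structure(["C"] * 4, np.zeros((4, 3))))

    def test_rigid_motion_invariance(self, toy_cage):
        d0 = cavity_diameter(toy_cage)
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = toy_cage.rotated(q).translated([3.0, -8.0, 1.0])
        assert cavity_diameter(moved) == pytest.approx(d0, abs=1e-9)


class TestFindWindows:
    def test_closed_shell_has_no_windows(self):
        shell = spherical_shell(radius=5.0)
        assert find_windows(shell, radii=1.0, centre=ORIGIN) == []

    def test_single_aperture_diameter_matches_geometry(self):
        r, a, theta = 5.0, 0.3, 30.0
        shell = spherical_shell(radius=r, open_axes=[(0, 0, 1)], half_angle_deg=theta)
        windows = find_windows(shell, radii=a, centre=ORIGIN)
        assert len(windows) == 1
        expected = 2 * (r * np.sin(np.radians(theta)) - a)
        tolerance = 2 * grid_resolution() * r
        assert windows[0] == pytest.approx(expected, abs=tolerance)

    def test_four_symmetric_apertures(self):
        from cage_evolve.assembly import TETRA_VERTICES

        r, a, theta = 5.0, 0.3, 25.0
        shell = spherical_shell(radius=r, open_axes=TETRA_VERTICES, half_angle_deg=theta)
        windows = find_windows(shell, radii=a, centre=ORIGIN)
        assert len(windows) == 4
        assert max(windows) - min(windows) < 2 * grid_resolution() * r

    def test_intact_cage_shows_four_windows(self, toy_cage):
        windows = find_windows(toy_cage)
        assert len(windows) == 4

    def test_rigid_motion_invariance(self, toy_cage):
        w0 = find_windows(toy_cage)
        moved = toy_cage.translated([11.0, 5.0, -2.0])
        assert np.allclose(find_windows(moved), w0, atol=1e-9)


class TestAsymmetry:
    @pytest.mark.parametrize(
        "windows, expected",
        [
            ([10.0, 10.0, 10.0, 10.0], 0.0),
            ([1.0, 2.0, 3.0, 4.0], 10.0),  # six pairs: 1+2+3+1+2+1
            ([5.0, 7.0], 2.0),
        ],
    )
    def test_pairwise_sum(self, windows, expected):
        assert asymmetry(windows) == pytest.approx(expected)

    def test_fewer_than_two_windows_undefined(self):
        with pytest.raises(ValueError):
            asymmetry([4.2])

    @given(
        windows=st.lists(st.floats(0.1, 50.0), min_size=2, max_size=8),
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariant_and_linear(self, windows, scale, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(windows))
        assert asymmetry(shuffled) == pytest.approx(asymmetry(windows), rel=1e-9)
        assert asymmetry([scale * w for w in windows]) == pytest.approx(
            scale * asymmetry(windows), rel=1e-9
        )

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            windows = rng.uniform(1.0, 20.0, size=rng.integers(2, 7))
            brute = sum(
                abs(windows[i] - windows[j])
                for i in range(len(windows))
                for j in range(i + 1, len(windows))
            )
            assert asymmetry(windows) == pytest.approx(brute, rel=1e-12)


class TestCollapse:
    def test_intact_four_window_fixture(self):
        from cage_evolve.assembly import TETRA_VERTICES

        shell = spherical_shell(radius=5.0, open_axes=TETRA_VERTICES, half_angle_deg=25.0)
        assert not is_collapsed(shell, radii=0.3, centre=ORIGIN)

    def test_filled_centre_fixture(self):
        shell = spherical_shell(radius=5.0)
        blocked = Structure(shell.elements + ["C"], np.vstack([shell.coords, ORIGIN]))
        assert is_collapsed(blocked, radii=1.0, centre=ORIGIN)

    def test_single_aperture_counts_as_collapsed(self):
        shell = spherical_shell(radius=5.0, open_axes=[(0, 0, 1)], half_angle_deg=30.0)
        assert is_collapsed(shell, radii=0.3, centre=ORIGIN)

    def test_metrics_bundle_consistent(self, toy_cage):
        metrics = compute_shape_metrics(toy_cage)
        assert not metrics.collapsed
        assert metrics.cavity_diameter > 0
        assert len(metrics.window_diameters) == 4
        assert metrics.asymmetry == pytest.approx(asymmetry(metrics.window_diameters))
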